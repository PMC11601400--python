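"""Deformation geometry and Hooke's-law strain energetics of the ternary complex.

Designed fusions place the partner so that it clashes with the effector-bound
switch; the predicted ternary-complex structure resolves this clash through a
global rigid-ish pivot of the partner.  This module quantifies that pivot and
relates it to the strain energy inferred from accelerated off-rates:

* Kabsch least-squares superposition (proper rotations only);
* screw (Chasles) decomposition of the clash-to-strained partner transform
  after switch alignment: pivot angle theta (= theta - theta_0), located
  pivot axis, and the residual translation along it;
* the helix axis of the interface binder helix by principal-component line
  fit, and phi, its angle to the pivot axis (folded to [0, pi/2] so that
  sin(phi) measures perpendicularity);
* the strain-energy estimate  DDG = R T ln(k_off,B:AC / k_off,B:A,unstrained)
  with the floor rule k_off,B:A,unstrained = min(k_base, k_off,B:A);
* Hooke's law  k = DDG / theta^2  and the perpendicularity-linear spring
  model  DDG_pred = (m sin(phi) + b) theta^2, with m and b fitted by least
  squares on the cohort's experimental strain energies.

Energies are kcal/mol at 25 C unless configured otherwise; angles radians;
coordinates angstroms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import IdentifiabilityError, ValidationError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "StructurePair",
    "DeformationGeometry",
    "StrainRecord",
    "SpringModel",
    "superpose",
    "pivot_decomposition",
    "experimental_strain_energy",
    "spring_constant",
    "fit_spring_model",
    "predicted_strain_energy",
    "calpha_coords",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.9872e-3

#: Rotation angles below this are treated as no deformation (axis undefined).
DEGENERATE_THETA = 1e-6


@dataclass
class StructurePair:
    """Calpha coordinates of a clashing design model and its strained prediction.

    The switch sets the common reference frame; partner coordinate sets
    correspond residue-by-residue between the clashing and strained models.
    ``helix_axis_residues`` is a half-open index range (start, stop) into the
    reference switch coordinates selecting the interface binder helix.
    """

    switch_coords_ref: np.ndarray
    switch_coords_strained: np.ndarray
    partner_coords_clash: np.ndarray
    partner_coords_strained: np.ndarray
    helix_axis_residues: tuple

    def __post_init__(self) -> None:
        for name in (
            "switch_coords_ref", "switch_coords_strained",
            "partner_coords_clash", "partner_coords_strained",
        ):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 3:
                raise ValidationError(f"{name} must be an (n>=3, 3) coordinate array")
            setattr(self, name, arr)
        if self.switch_coords_ref.shape != self.switch_coords_strained.shape:
            raise ValidationError("switch coordinate sets must be paired (equal length)")
        if self.partner_coords_clash.shape != self.partner_coords_strained.shape:
            raise ValidationError("partner coordinate sets must be paired (equal length)")
        start, stop = (int(v) for v in self.helix_axis_residues)
        n = self.switch_coords_ref.shape[0]
        if not (0 <= start < stop <= n) or stop - start < 7:
            raise ValidationError(
                "helix_axis_residues must select >= 7 residues (two turns) of the switch"
            )
        self.helix_axis_residues = (start, stop)


@dataclass
class DeformationGeometry:
    """Screw-axis description of the clash-to-strained partner pivot."""

    theta: float
    pivot_axis: np.ndarray | None
    pivot_point: np.ndarray | None
    helix_axis: np.ndarray
    phi: float
    sin_phi: float
    translation_residual: float
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "theta_rad": self.theta,
            "pivot_axis": None if self.pivot_axis is None else list(self.pivot_axis),
            "pivot_point_A": None if self.pivot_point is None else list(self.pivot_point),
            "helix_axis": list(self.helix_axis),
            "phi_rad": self.phi,
            "sin_phi": self.sin_phi,
            "translation_residual_A": self.translation_residual,
            "degenerate": self.degenerate,
        }


@dataclass
class StrainRecord:
    """Per-design pairing of measured off-rates and predicted deformation."""

    design_id: str
    k_off_B_AC: float
    k_off_B_A: float
    ddg_exp: float
    geometry: DeformationGeometry
    spring_k: float = math.nan
    ddg_pred: float = math.nan


@dataclass
class SpringModel:
    """Perpendicularity-linear spring model k(phi) = m sin(phi) + b.

    ``k_base_offrate`` is the floor used for the unstrained partner off-rate
    when estimating experimental strain energies (distinct from the k_base of
    the hyperbolic k_app law).  Units: m and b kcal/mol/rad^2; temperature K.
    """

    m: float
    b: float
    k_base_offrate: float = 2e-4
    temperature: float = 298.15
    r_squared: float = math.nan
    flags: tuple = ()

    def __post_init__(self) -> None:
        if not (self.temperature > 0):
            raise ValidationError("temperature must be > 0 K")
        if not (self.k_base_offrate > 0):
            raise ValidationError("k_base_offrate must be > 0")

    def to_json(self, path=None) -> str:
        payload = {
            "m_kcal_mol_rad2_per_sinphi": self.m,
            "b_kcal_mol_rad2": self.b,
            "k_base_offrate_per_s": self.k_base_offrate,
            "temperature_K": self.temperature,
            "r_squared": self.r_squared,
            "flags": list(self.flags),
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# Rigid-body geometry
# ---------------------------------------------------------------------------


def superpose(moving: np.ndarray, fixed: np.ndarray):
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ moving[i] + translation`` best matches ``fixed[i]`` with a
    proper rotation (det = +1; reflections excluded).
    """
    mv = np.asarray(moving, dtype=float)
    fx = np.asarray(fixed, dtype=float)
    if mv.shape != fx.shape or mv.ndim != 2 or mv.shape[1] != 3 or mv.shape[0] < 3:
        raise ValidationError("superpose needs paired (n>=3, 3) coordinate arrays")
    cm, cf = mv.mean(axis=0), fx.mean(axis=0)
    a, b = mv - cm, fx - cf
    if np.linalg.matrix_rank(a, tol=1e-9) < 2:
        raise ValidationError("degenerate (collinear) coordinates: rotation ill-defined")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    diff = (mv @ rot.T + trans) - fx
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return rot, trans, rmsd


def _rotation_angle_axis(rot: np.ndarray):
    """Angle in [0, pi] and unit axis of a proper rotation matrix."""
    # rotation vector via the quaternion-free route: antisymmetric part + trace
    cos_theta = max(-1.0, min(1.0, (np.trace(rot) - 1.0) / 2.0))
    theta = math.acos(cos_theta)
    if theta < 1e-12:
        return theta, None
    if math.pi - theta > 1e-6:
        axis = np.array([
            rot[2, 1] - rot[1, 2],
            rot[0, 2] - rot[2, 0],
            rot[1, 0] - rot[0, 1],
        ]) / (2.0 * math.sin(theta))
    else:
        # near pi: axis from the symmetric part, R + I = 2 nn^T
        m = rot + np.eye(3)
        axis = m[:, int(np.argmax(np.diag(m)))]
    return theta, axis / np.linalg.norm(axis)


def _helix_axis(coords: np.ndarray) -> np.ndarray:
    """Principal-component line direction of a Calpha trace."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    # orient along increasing residue index for reproducibility
    if np.dot(coords[-1] - coords[0], axis) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def pivot_decomposition(pair: StructurePair) -> DeformationGeometry:
    """Screw-axis geometry of the partner's clash-to-strained deformation.

    Steps: (1) align the strained complex onto the reference frame through
    the switch; (2) find the rigid transform carrying the clashing partner
    onto the aligned strained partner; (3) decompose it into rotation angle
    theta about a located axis (the point on the axis with minimal screw
    translation, chosen closest to the origin) plus the residual translation
    along the axis; (4) fit the helix axis over the stated residue range and
    fold its angle to the pivot axis into [0, pi/2].

    A rotation below ``DEGENERATE_THETA`` radians leaves the axis undefined;
    the geometry is returned flagged with theta ~ 0 and sin_phi = 0.
    """
    rot_s, trans_s, _ = superpose(pair.switch_coords_strained, pair.switch_coords_ref)
    partner_strained = pair.partner_coords_strained @ rot_s.T + trans_s

    rot, trans, _ = superpose(pair.partner_coords_clash, partner_strained)
    theta, axis = _rotation_angle_axis(rot)
    helix = _helix_axis(
        pair.switch_coords_ref[pair.helix_axis_residues[0]: pair.helix_axis_residues[1]]
    )

    if axis is None or theta < DEGENERATE_THETA:
        return DeformationGeometry(
            theta=theta, pivot_axis=None, pivot_point=None, helix_axis=helix,
            phi=math.nan, sin_phi=0.0, translation_residual=float(np.linalg.norm(trans)),
            degenerate=True,
        )

    d_along = float(np.dot(trans, axis))
    # point c on the axis: (I - R) c = t - d n ; min-norm solution lies in the
    # plane perpendicular to the axis, i.e. the point on the axis nearest the origin
    rhs = trans - d_along * axis
    c, *_ = np.linalg.lstsq(np.eye(3) - rot, rhs, rcond=None)
    c = c - np.dot(c, axis) * axis

    cos_phi = abs(float(np.dot(axis, helix)))
    cos_phi = min(cos_phi, 1.0)
    phi = math.acos(cos_phi)
    return DeformationGeometry(
        theta=float(theta), pivot_axis=axis, pivot_point=c, helix_axis=helix,
        phi=phi, sin_phi=math.sin(phi), translation_residual=d_along,
    )


# ---------------------------------------------------------------------------
# Strain energetics
# ---------------------------------------------------------------------------


def experimental_strain_energy(
    k_off_B_AC: float, k_off_B_A: float, model: SpringModel
) -> float:
    """DDG = R T ln(k_off,B:AC / k_off,B:A,unstrained), kcal/mol.

    Assumes the effector does not change the partner on-rate, so the
    off-rate ratio reports the destabilisation of the bound state.  Some
    designs form extra stabilising contacts that suppress both off-rates by
    the same factor, so the unstrained off-rate is floored:
    k_off,B:A,unstrained = min(k_base_offrate, k_off,B:A).
    """
    if not (k_off_B_AC > 0 and k_off_B_A > 0):
        raise ValidationError("off-rates must be > 0")
    k_unstrained = min(model.k_base_offrate, k_off_B_A)
    return GAS_CONSTANT_KCAL * model.temperature * math.log(k_off_B_AC / k_unstrained)


def spring_constant(ddg: float, theta: float) -> float:
    """Hooke's-law spring constant k = DDG / theta^2, kcal/mol/rad^2."""
    if not (theta > 0):
        raise ValidationError("spring constant undefined at theta = 0")
    return ddg / theta**2


def predicted_strain_energy(model: SpringModel, geometry: DeformationGeometry) -> float:
    """DDG_pred = (m sin(phi) + b) theta^2, kcal/mol."""
    return (model.m * geometry.sin_phi + model.b) * geometry.theta**2


def fit_spring_model(
    records,
    k_base_offrate: float = 2e-4,
    temperature: float = 298.15,
) -> SpringModel:
    """Fit m, b of the perpendicularity-linear spring model over a cohort.

    The fit is performed on the strain energies themselves, minimising
    sum_i (ddg_exp_i - (m sin(phi_i) + b) theta_i^2)^2, which is linear in
    (m, b).  R^2 reports predicted vs experimental DDG on the fitted cohort.
    Records with theta = 0 carry no signal and are rejected.
    """
    recs = [r for r in records]
    if len(recs) < 3:
        raise IdentifiabilityError("need >= 3 strain records with theta > 0")
    theta = np.array([r.geometry.theta for r in recs])
    sphi = np.array([r.geometry.sin_phi for r in recs])
    ddg = np.array([r.ddg_exp for r in recs])
    if np.any(theta <= 0):
        raise ValidationError("all records must have theta > 0")

    flags = []
    if np.ptp(sphi) < 1e-12:
        # all deformations equally perpendicular: only the combined stiffness
        # m*sin_phi + b is identified; report it in b with m pinned at 0
        flags.append("sin_phi identical across cohort: m unidentifiable, pinned to 0")
        design = theta[:, None] ** 2
        coef, *_ = np.linalg.lstsq(design, ddg, rcond=None)
        m, b = 0.0, float(coef[0])
    else:
        design = np.column_stack([sphi * theta**2, theta**2])
        coef, *_ = np.linalg.lstsq(design, ddg, rcond=None)
        m, b = float(coef[0]), float(coef[1])

    pred = (m * sphi + b) * theta**2
    ss_res = float(np.sum((ddg - pred) ** 2))
    ss_tot = float(np.sum((ddg - ddg.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
    return SpringModel(
        m=m, b=b, k_base_offrate=k_base_offrate, temperature=temperature,
        r_squared=r2, flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Cohort / structure I/O
# ---------------------------------------------------------------------------


def calpha_coords(pdb_path, chain: str | None = None, residue_range=None) -> np.ndarray:
    """Calpha coordinates (angstroms) from a PDB file, optionally filtered."""
    from biotite.structure.io.pdb import PDBFile

    structure = PDBFile.read(str(pdb_path)).get_structure(model=1)
    mask = structure.atom_name == "CA"
    if chain is not None:
        mask &= structure.chain_id == chain
    if residue_range is not None:
        lo, hi = residue_range
        mask &= (structure.res_id >= lo) & (structure.res_id <= hi)
    coords = structure.coord[mask]
    if coords.shape[0] < 3:
        raise ValidationError(f"fewer than 3 Calpha atoms selected from {pdb_path}")
    return np.asarray(coords, dtype=float)


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "design_id": r.design_id,
            "k_off_B_AC_per_s": r.k_off_B_AC,
            "k_off_B_A_per_s": r.k_off_B_A,
            "ddg_exp_kcal_mol": r.ddg_exp,
            "theta_rad": r.geometry.theta,
            "sin_phi": r.geometry.sin_phi,
            "spring_k_kcal_mol_rad2": r.spring_k,
            "ddg_pred_kcal_mol": r.ddg_pred,
        })
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame):
    records = []
    for _, row in df.iterrows():
        theta = float(row["theta_rad"])
        sphi = float(row["sin_phi"])
        phi = math.asin(max(0.0, min(1.0, sphi)))
        geom = DeformationGeometry(
            theta=theta, pivot_axis=None, pivot_point=None,
            helix_axis=np.array([0.0, 0.0, 1.0]), phi=phi, sin_phi=sphi,
            translation_residual=0.0,
        )
        records.append(StrainRecord(
            design_id=str(row["design_id"]),
            k_off_B_AC=float(row["k_off_B_AC_per_s"]),
            k_off_B_A=float(row["k_off_B_A_per_s"]),
            ddg_exp=float(row["ddg_exp_kcal_mol"]),
            geometry=geom,
            spring_k=float(row.get("spring_k_kcal_mol_rad2", math.nan)),
            ddg_pred=float(row.get("ddg_pred_kcal_mol", math.nan)),
        ))
    return records
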