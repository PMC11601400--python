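"""Seeded generators for every input the analysis pipeline consumes.

Each generator is deterministic under a fixed seed and returns (or writes)
the ground truth alongside the data so recovery tests never peek at the
generating code.  Defaults mirror the experimental designs the analyses were
built for: 6 SPR cycles with effector two-fold serially diluted from 5 uM
and 600 s dissociation windows sampled at 1 s; 24-well two-fold FP
titrations; 8-point k_app concentration grids spanning K_1/2; and strain
cohorts of ~30 designs.  Noise defaults to Gaussian at 1% of the maximum
response per dataset, a typical SPR noise floor.  Instrument physics (drift
within cycles, bulk refractive-index jumps, spikes) is deliberately not
emulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curvefits import KappProfile, bound_fraction
from .exceptions import ValidationError
from .kinetics import RateConstants
from .spr import CycleData, CycleSchedule, ResponseModel, SPRDataset, simulate_cycles
from .strain import (
    GAS_CONSTANT_KCAL,
    DeformationGeometry,
    SpringModel,
    StrainRecord,
    StructurePair,
)

__all__ = [
    "NoiseSpec",
    "GroundTruth",
    "default_rates",
    "default_response",
    "generate_spr_dataset",
    "generate_kapp_profile",
    "generate_fp_titration",
    "generate_structure_pair",
    "generate_strain_cohort",
    "rotation_about_axis",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise description.

    ``kind`` is ``gaussian-absolute`` (sd in signal units) or
    ``gaussian-relative-to-max`` (sd as a fraction of the maximum absolute
    signal of the dataset).  The same seed always reproduces the same draws.
    """

    kind: str = "gaussian-relative-to-max"
    sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian-absolute", "gaussian-relative-to-max"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise ValidationError("noise sd must be >= 0")

    def scale(self, signal: np.ndarray) -> float:
        if self.kind == "gaussian-absolute":
            return self.sd
        return self.sd * float(np.max(np.abs(signal))) if signal.size else 0.0


@dataclass
class GroundTruth:
    """Generating parameters echoed next to every synthetic dataset."""

    rates: RateConstants | None = None
    response: ResponseModel | None = None
    mechanism: str | None = None
    mechanism_params: dict | None = None
    spring: SpringModel | None = None
    isotherm: dict | None = None
    geometry: dict | None = None
    noise: NoiseSpec | None = None

    def to_json(self, path=None) -> str:
        payload = {}
        if self.rates is not None:
            payload["rates"] = self.rates.as_dict()
        if self.response is not None:
            payload["response"] = self.response.as_dict()
        if self.mechanism is not None:
            payload["mechanism"] = self.mechanism
        if self.mechanism_params is not None:
            payload["mechanism_params"] = self.mechanism_params
        if self.spring is not None:
            payload["spring"] = {
                "m": self.spring.m, "b": self.spring.b,
                "k_base_offrate_per_s": self.spring.k_base_offrate,
                "temperature_K": self.spring.temperature,
            }
        if self.isotherm is not None:
            payload["isotherm"] = self.isotherm
        if self.geometry is not None:
            payload["geometry"] = self.geometry
        if self.noise is not None:
            payload["noise"] = asdict(self.noise)
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def default_rates() -> RateConstants:
    """Representative facilitated-dissociation rate set (s^-1, M^-1 s^-1).

    A 100-fold effector-induced off-rate acceleration with an effector
    on-rate of 2e4 M^-1 s^-1, chosen so that within the default 6-cycle
    two-fold dilution from 5 uM the lowest cycles approach the base
    off-rate and the highest approach the ternary off-rate -- the regime
    in which the multi-cycle experiment determines both partner off-rates
    (an a-priori identifiability design of the synthetic experiment; see
    docs/methods.md).
    """
    return RateConstants(
        k_off_B_A=5e-4, k_on_BA_C=2e4, k_off_BA_C=5e-3,
        k_off_B_AC=5e-2, k_off_B_An=5e-5,
    )


def default_response(n_cycles: int = 6, f_responsive: float = 0.9) -> ResponseModel:
    """Equal 100-RU amplitudes, unit cycle factors, 90% responsive host."""
    return ResponseModel(
        a_ba=100.0, a_bac=100.0, a_ban=100.0,
        f_responsive=f_responsive, f_scale=(1.0,) * n_cycles,
    )


# ---------------------------------------------------------------------------
# SPR
# ---------------------------------------------------------------------------


def generate_spr_dataset(
    rates: RateConstants | None = None,
    schedule: CycleSchedule | None = None,
    response: ResponseModel | None = None,
    noise: NoiseSpec | None = None,
):
    """Noisy multi-cycle dissociation dataset plus its ground truth.

    Noise is drawn per cycle relative to that cycle's noise-free maximum
    when ``kind='gaussian-relative-to-max'``.
    """
    schedule = schedule or CycleSchedule.serial_dilution()
    rates = rates or default_rates()
    response = response or default_response(schedule.n_cycles)
    noise = noise or NoiseSpec()

    clean = simulate_cycles(rates, schedule, response)
    rng = np.random.default_rng(noise.seed)
    cycles = []
    for c in clean.cycles:
        sd = noise.scale(c.response)
        noisy = c.response + rng.normal(0.0, sd, size=c.response.shape) if sd > 0 else c.response.copy()
        cycles.append(CycleData(c.times.copy(), noisy))
    dataset = SPRDataset(
        cycles=cycles, schedule=schedule,
        meta={"source": "generate_spr_dataset", "noise": asdict(noise)},
    )
    truth = GroundTruth(rates=rates, response=response, noise=noise)
    return dataset, truth


# ---------------------------------------------------------------------------
# k_app profiles
# ---------------------------------------------------------------------------


def generate_kapp_profile(
    mechanism: str,
    params: dict | None = None,
    concs=None,
    noise: NoiseSpec | None = None,
):
    """Apparent-rate profile from one of the two printed k_app laws.

    ``mechanism`` is ``'induced_fit'`` (alias ``'linear'``) or
    ``'conformational_selection'`` (alias ``'hyperbolic'``).  Default
    parameters: linear k_on = 5e4 M^-1 s^-1, k_off = 1e-3 s^-1; hyperbolic
    k_switch = 0.02 s^-1, k_base = 1e-4 s^-1, K_half = 2e-7 M.  The default
    grid is an 8-point two-fold dilution spanning K_half.
    """
    noise = noise or NoiseSpec(sd=0.05)
    if mechanism in ("induced_fit", "linear"):
        mechanism = "induced_fit"
        p = {"k_on": 5e4, "k_off": 1e-3}
        p.update(params or {})
        if concs is None:
            concs = 3.2e-6 / 2.0 ** np.arange(8)
        concs = np.asarray(concs, dtype=float)
        kapps = p["k_on"] * concs + p["k_off"]
    elif mechanism in ("conformational_selection", "hyperbolic"):
        mechanism = "conformational_selection"
        p = {"k_switch": 0.02, "k_base": 1e-4, "k_half": 2e-7}
        p.update(params or {})
        if concs is None:
            concs = 16.0 * p["k_half"] / 2.0 ** np.arange(8)
        concs = np.asarray(concs, dtype=float)
        kapps = (p["k_switch"] - p["k_base"]) * concs / (p["k_half"] + concs) + p["k_base"]
    else:
        raise ValidationError(f"unknown mechanism {mechanism!r}")

    rng = np.random.default_rng(noise.seed)
    sd = noise.scale(kapps)
    if sd > 0:
        kapps = kapps + rng.normal(0.0, sd, size=kapps.shape)
    profile = KappProfile(concs=concs, kapps=kapps, source=mechanism)
    truth = GroundTruth(mechanism=mechanism, mechanism_params=p, noise=noise)
    return profile, truth


# ---------------------------------------------------------------------------
# FP titrations
# ---------------------------------------------------------------------------


def generate_fp_titration(
    p0: float = 50.0,
    p1: float = 150.0,
    kd: float = 1e-8,
    effector_conc: float = 1e-9,
    host_concs=None,
    noise: NoiseSpec | None = None,
):
    """24-well two-fold host titration on the exact binding isotherm.

    Returns a DataFrame (host_conc_M, polarization_mP) plus the truth.  The
    default series runs from 2 uM down 24 wells, bracketing typical K_D
    values, with the labeled effector held at 1 nM.
    """
    noise = noise or NoiseSpec(sd=0.02)
    if host_concs is None:
        host_concs = 2e-6 / 2.0 ** np.arange(24)
    host_concs = np.asarray(host_concs, dtype=float)
    f = np.array([bound_fraction(a, effector_conc, kd) if a > 0 else 0.0 for a in host_concs])
    pol = p0 + p1 * f
    rng = np.random.default_rng(noise.seed)
    sd = noise.scale(pol)
    if sd > 0:
        pol = pol + rng.normal(0.0, sd, size=pol.shape)
    table = pd.DataFrame({"host_conc_M": host_concs, "polarization_mP": pol})
    truth = GroundTruth(
        isotherm={"P0_mP": p0, "P1_mP": p1, "K_D_M": kd, "effector_conc_M": effector_conc},
        noise=noise,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------


def rotation_about_axis(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    n = np.asarray(axis, dtype=float)
    n = n / np.linalg.norm(n)
    kx = np.array([
        [0.0, -n[2], n[1]],
        [n[2], 0.0, -n[0]],
        [-n[1], n[0], 0.0],
    ])
    return np.eye(3) + math.sin(angle) * kx + (1.0 - math.cos(angle)) * (kx @ kx)


def _ideal_helix(n_res: int, origin, direction) -> np.ndarray:
    """Calpha trace of an ideal alpha helix (1.5 A rise, 2.3 A radius, 100 deg/res)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # orthonormal frame around the helix axis
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    i = np.arange(n_res)
    ang = np.deg2rad(100.0) * i
    return (
        np.asarray(origin, dtype=float)
        + np.outer(1.5 * i, d)
        + 2.3 * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    )


def generate_structure_pair(
    n_residues: int = 80,
    axis=(0.0, 0.0, 1.0),
    point=(0.0, 0.0, 0.0),
    angle: float = 0.349,
    helix_range: tuple = (20, 32),
    helix_axis=(1.0, 0.0, 0.0),
    n_partner: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Synthetic switch/partner coordinate pair with a known pivot.

    The strained partner is the clashing partner rotated by ``angle`` about
    the located ``axis`` through ``point``; the switch is shared (up to
    coordinate noise) so switch alignment is the identity.  An ideal helix
    along ``helix_axis`` occupies ``helix_range`` of the switch, setting the
    ground-truth perpendicularity.  ``noise_sd`` adds isotropic Gaussian
    coordinate noise (angstroms) to the strained model only, emulating
    prediction error.
    """
    rng = np.random.default_rng(seed)
    switch = rng.uniform(-15.0, 15.0, size=(n_residues, 3))
    start, stop = helix_range
    switch[start:stop] = _ideal_helix(stop - start, switch[start], helix_axis)

    partner = rng.uniform(-10.0, 10.0, size=(n_partner, 3)) + np.array([35.0, 0.0, 0.0])
    rot = rotation_about_axis(axis, angle)
    p0 = np.asarray(point, dtype=float)
    partner_strained = (partner - p0) @ rot.T + p0

    switch_strained = switch.copy()
    if noise_sd > 0:
        switch_strained = switch_strained + rng.normal(0.0, noise_sd, switch.shape)
        partner_strained = partner_strained + rng.normal(0.0, noise_sd, partner.shape)

    pair = StructurePair(
        switch_coords_ref=switch,
        switch_coords_strained=switch_strained,
        partner_coords_clash=partner,
        partner_coords_strained=partner_strained,
        helix_axis_residues=(start, stop),
    )
    n = np.asarray(axis, dtype=float)
    n = n / np.linalg.norm(n)
    # the realized helix axis: a finite discretely-sampled helix has its
    # principal axis tilted slightly from the nominal direction, so the truth
    # records the axis of the clean coordinates actually emitted
    from .strain import _helix_axis

    h = _helix_axis(switch[start:stop])
    phi = math.acos(min(abs(float(np.dot(n, h))), 1.0))
    truth = GroundTruth(geometry={
        "axis": list(n), "point": list(map(float, p0)), "angle_rad": float(angle),
        "helix_axis": list(h), "phi_rad": phi, "sin_phi": math.sin(phi),
        "noise_sd_A": noise_sd,
    })
    return pair, truth


# ---------------------------------------------------------------------------
# Strain cohorts
# ---------------------------------------------------------------------------


def generate_strain_cohort(
    spring: SpringModel | None = None,
    n_designs: int = 30,
    theta_range: tuple = (0.1, 0.6),
    phi_range: tuple = (0.2, 1.4),
    ddg_noise: float = 0.0,
    seed: int = 0,
):
    """Cohort of designs obeying the perpendicularity-linear spring model.

    Each design gets theta ~ U(theta_range) and phi ~ U(phi_range) (radians),
    an experimental strain energy (m sin(phi) + b) theta^2 with optional
    multiplicative Gaussian noise of fractional sd ``ddg_noise``, and
    off-rates consistent with that energy: k_off,B:A at the floor rate and
    k_off,B:AC = floor * exp(DDG / RT).
    """
    spring = spring or SpringModel(m=30.0, b=5.0)
    rng = np.random.default_rng(seed)
    records = []
    rt = GAS_CONSTANT_KCAL * spring.temperature
    for i in range(n_designs):
        theta = rng.uniform(*theta_range)
        phi = rng.uniform(*phi_range)
        sphi = math.sin(phi)
        ddg = (spring.m * sphi + spring.b) * theta**2
        if ddg_noise > 0:
            ddg *= 1.0 + ddg_noise * rng.normal()
        k_off_b_a = spring.k_base_offrate
        k_off_b_ac = k_off_b_a * math.exp(ddg / rt)
        axis = np.array([0.0, 0.0, 1.0])
        helix = np.array([math.sin(phi), 0.0, math.cos(phi)])
        geom = DeformationGeometry(
            theta=theta, pivot_axis=axis, pivot_point=np.zeros(3),
            helix_axis=helix, phi=phi, sin_phi=sphi, translation_residual=0.0,
        )
        records.append(StrainRecord(
            design_id=f"SYN{i:03d}",
            k_off_B_AC=k_off_b_ac, k_off_B_A=k_off_b_a,
            ddg_exp=ddg, geometry=geom, spring_k=ddg / theta**2,
        ))
    truth = GroundTruth(spring=spring, noise=NoiseSpec(kind="gaussian-absolute", sd=ddg_noise, seed=seed))
    return records, truth
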