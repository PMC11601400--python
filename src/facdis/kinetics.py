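"""Facilitated-dissociation rate network and chip-occupancy kinetics.

A host protein A (a conformational switch rigidly fused to a binder) is
loaded onto chip-immobilised partner B.  An effector C in the flow buffer can
bind the partner-host complex BA to form a strained ternary complex BAC from
which the partner is released much faster than from BA alone.  A small
fraction of host is unresponsive to the effector and is tracked as a separate
chip species BAn.  During a dissociation window at constant effector
concentration [C] the occupancies obey the pure-loss linear system

    d[BAC]/dt = -k_off,B:AC [BAC] + k_on,BA:C [BA][C] - k_off,BA:C [BAC]
    d[BA]/dt  = -k_off,B:A  [BA]  - k_on,BA:C [BA][C] + k_off,BA:C [BAC]
    d[BAn]/dt = -k_off,B:An [BAn]

The BAC/BA pair is a 2x2 constant-coefficient system solved here in closed
form; BAn decays as an independent single exponential.  Occupancies are
dimensionless fractions of chip capacity, concentrations are molar, rates are
s^-1 (first order) or M^-1 s^-1 (second order).

The effective rate of the whole facilitated-dissociation process at a given
[C] is defined through the half-time of total partner-bound occupancy
starting from [BA] = 1, [BAC] = 0:

    [BA](t_half) + [BAC](t_half) = 1/2,    k_eff = ln 2 / t_half.

k_eff interpolates monotonically between the binary off-rate k_off,B:A at
[C] = 0 and the ternary off-rate k_off,B:AC at saturating effector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .exceptions import NonDissociatingError, ValidationError

__all__ = [
    "RateConstants",
    "ChipState",
    "OccupancyTrajectory",
    "propagate_dissociation",
    "half_time",
    "effective_rate",
]

#: Relative eigenvalue gap below which the repeated-eigenvalue limit is used.
DEGENERATE_EIG_RTOL = 1e-12

#: Slack allowed on the chip-capacity bound ba + bac + ban + b <= 1.
CAPACITY_TOL = 1e-6


def _require_rate(name: str, value: float) -> float:
    v = float(value)
    if not math.isfinite(v) or v < 0.0:
        raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")
    return v


@dataclass(frozen=True)
class RateConstants:
    """The four-to-five rate parameters of the facilitated-dissociation network.

    Parameters
    ----------
    k_off_B_A : float
        Partner off-rate from the binary partner-host complex, s^-1.
    k_on_BA_C : float
        Effector on-rate to the partner-host complex, M^-1 s^-1 (the only
        second-order rate in the network).
    k_off_BA_C : float
        Effector off-rate from the ternary complex, s^-1.
    k_off_B_AC : float
        Partner off-rate from the strained ternary complex, s^-1.
    k_off_B_An : float
        Partner off-rate from the effector-unresponsive host population, s^-1.
    """

    k_off_B_A: float
    k_on_BA_C: float
    k_off_BA_C: float
    k_off_B_AC: float
    k_off_B_An: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_off_B_A", "k_off_BA_C", "k_off_B_AC", "k_off_B_An"):
            object.__setattr__(self, name, _require_rate(name, getattr(self, name)))
        object.__setattr__(self, "k_on_BA_C", _require_rate("k_on_BA_C", self.k_on_BA_C))

    def as_dict(self) -> dict:
        return {
            "k_off_B_A_per_s": self.k_off_B_A,
            "k_on_BA_C_per_M_per_s": self.k_on_BA_C,
            "k_off_BA_C_per_s": self.k_off_BA_C,
            "k_off_B_AC_per_s": self.k_off_B_AC,
            "k_off_B_An_per_s": self.k_off_B_An,
        }


@dataclass(frozen=True)
class ChipState:
    """Occupancy fractions of the chip species at one instant.

    ``ba``, ``bac``, ``ban`` are the bound-complex fractions; ``b`` is the
    free capture-site fraction.  All are dimensionless fractions of total
    chip capacity and must sum to at most 1 (within tolerance).
    """

    ba: float
    bac: float = 0.0
    ban: float = 0.0
    b: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ba", "bac", "ban", "b"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0.0:
                raise ValidationError(f"ChipState.{name} must be finite and >= 0")
            object.__setattr__(self, name, v)
        total = self.ba + self.bac + self.ban + self.b
        if total > 1.0 + CAPACITY_TOL:
            raise ValidationError(f"chip occupancies sum to {total} > 1")

    @property
    def bound(self) -> float:
        """Total partner-bound responsive fraction [BA] + [BAC]."""
        return self.ba + self.bac


@dataclass
class OccupancyTrajectory:
    """Closed-form occupancy time course over one dissociation window."""

    times: np.ndarray
    ba: np.ndarray
    bac: np.ndarray
    ban: np.ndarray
    effector_conc: float

    @property
    def bound(self) -> np.ndarray:
        return self.ba + self.bac

    @property
    def states(self) -> list[ChipState]:
        out = []
        for i in range(len(self.times)):
            ba, bac, ban = self.ba[i], self.bac[i], self.ban[i]
            b = max(0.0, 1.0 - ba - bac - ban)
            out.append(ChipState(ba=ba, bac=bac, ban=ban, b=b))
        return out


def _pair_matrix(rates: RateConstants, conc: float) -> tuple[float, float, float, float]:
    """Entries (a, b, c, d) of the BAC/BA generator, state order (bac, ba)."""
    a = -(rates.k_off_B_AC + rates.k_off_BA_C)
    b = rates.k_on_BA_C * conc
    c = rates.k_off_BA_C
    d = -(rates.k_off_B_A + rates.k_on_BA_C * conc)
    return a, b, c, d


def _propagate_pair(
    rates: RateConstants, conc: float, bac0: float, ba0: float, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution of the 2x2 BAC/BA system at the given times.

    Spectral form of the matrix exponential; the eigenvalues are real because
    the off-diagonal product k_on[C] * k_off,BA:C is non-negative, and both
    are <= 0 because the system is pure loss, so the exponentials never
    overflow.  Near-degenerate eigenvalues fall back to the exact repeated-
    root limit e^{mu t}(I + (M - mu I) t).
    """
    a, b, c, d = _pair_matrix(rates, conc)
    mu = 0.5 * (a + d)
    disc = (0.5 * (a - d)) ** 2 + b * c  # >= 0 always
    delta = math.sqrt(max(disc, 0.0))
    lam_p, lam_m = mu + delta, mu - delta

    t = np.asarray(times, dtype=float)
    if delta <= DEGENERATE_EIG_RTOL * max(abs(lam_p), abs(lam_m), 1e-300):
        base = np.exp(mu * t)
        bac = base * ((1.0 + (a - mu) * t) * bac0 + b * t * ba0)
        ba = base * (c * t * bac0 + (1.0 + (d - mu) * t) * ba0)
    else:
        ep = np.exp(lam_p * t)
        em = np.exp(lam_m * t)
        inv = 1.0 / (2.0 * delta)
        p11 = (ep * (a - lam_m) - em * (a - lam_p)) * inv
        p12 = (ep - em) * b * inv
        p21 = (ep - em) * c * inv
        p22 = (ep * (d - lam_m) - em * (d - lam_p)) * inv
        bac = p11 * bac0 + p12 * ba0
        ba = p21 * bac0 + p22 * ba0
    # Round-off can produce tiny negative occupancies; clip.
    return np.clip(bac, 0.0, None), np.clip(ba, 0.0, None)


def propagate_dissociation(
    rates: RateConstants,
    effector_conc: float,
    state0: ChipState,
    times: np.ndarray,
) -> OccupancyTrajectory:
    """Propagate the chip occupancies over a dissociation window.

    Parameters
    ----------
    rates : RateConstants
    effector_conc : float
        Effector concentration in the flow buffer, molar; held constant over
        the window (flow conditions, no depletion).
    state0 : ChipState
        Occupancies at the start of the window.
    times : array-like
        Strictly increasing time grid in seconds with ``times[0] == 0``.

    Returns
    -------
    OccupancyTrajectory
        Exact closed-form occupancies at each grid point.  Free capture
        sites are not propagated during dissociation.
    """
    conc = float(effector_conc)
    if not math.isfinite(conc) or conc < 0.0:
        raise ValidationError(f"effector_conc must be finite and >= 0, got {effector_conc!r}")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValidationError("times must be a 1-D array with at least one point")
    if t[0] != 0.0:
        raise ValidationError("times must start at 0 (window-relative seconds)")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValidationError("times must be strictly increasing")

    bac, ba = _propagate_pair(rates, conc, state0.bac, state0.ba, t)
    ban = state0.ban * np.exp(-rates.k_off_B_An * t)
    return OccupancyTrajectory(times=t, ba=ba, bac=bac, ban=ban, effector_conc=conc)


def _bound_fraction_closed_form(rates: RateConstants, conc: float, t: float) -> float:
    bac, ba = _propagate_pair(rates, conc, 0.0, 1.0, np.array([0.0, t]))
    return float(bac[1] + ba[1])


def half_time(rates: RateConstants, effector_conc: float) -> float:
    """Half-time of total partner-bound occupancy from [BA]=1, [BAC]=0.

    Found by bracketed root-finding on the closed-form solution; the root is
    unique because total bound occupancy is strictly decreasing whenever any
    dissociation pathway is open.

    Raises
    ------
    NonDissociatingError
        If no pathway removes the partner (both partner off-rates zero, or
        the only open pathway is through a ternary complex that cannot form).
    """
    conc = float(effector_conc)
    if not math.isfinite(conc) or conc < 0.0:
        raise ValidationError("effector_conc must be finite and >= 0")
    k_ba = rates.k_off_B_A
    k_bac = rates.k_off_B_AC
    if k_ba == 0.0 and k_bac == 0.0:
        raise NonDissociatingError("both partner off-rates are zero; no root exists")
    if k_ba == 0.0 and (conc == 0.0 or rates.k_on_BA_C == 0.0 or k_bac == 0.0):
        raise NonDissociatingError(
            "partner can only leave through the ternary complex, which never forms"
        )

    # Fast exact limit: at [C]=0 the system is a bare single exponential.
    if conc == 0.0 or rates.k_on_BA_C == 0.0:
        return math.log(2.0) / k_ba

    positive = [k for k in (k_ba, k_bac) if k > 0.0]
    hi = 10.0 * math.log(2.0) / min(positive)
    f = lambda t: _bound_fraction_closed_form(rates, conc, t) - 0.5
    for _ in range(200):
        if f(hi) < 0.0:
            break
        hi *= 4.0
    else:  # pragma: no cover - unreachable for valid open pathways
        raise NonDissociatingError("bound fraction never crosses 1/2")
    return float(brentq(f, 0.0, hi, rtol=1e-14, xtol=1e-300, maxiter=200))


def effective_rate(rates: RateConstants, effector_concs) -> list[float]:
    """k_eff([C]) = ln 2 / t_half([C]) for each concentration, input order."""
    ln2 = math.log(2.0)
    return [ln2 / half_time(rates, c) for c in np.atleast_1d(effector_concs)]
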