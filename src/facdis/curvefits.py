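"""Closed-form curve fits for kinetic and equilibrium binding readouts.

Covers every elementary fit used around the chip-occupancy model:

* single- and double-exponential decays/rises for dissociation, association
  and kinetic-competition time courses, with the population-reporting rule
  for heterogeneous host (report the faster exponential when it also carries
  substantial amplitude);
* the linear and hyperbolic laws for apparent effector on-rates versus
  effector concentration,

      k_app = k_on,BA:C [C] + k_off,BA:C            (induced fit)
      k_app = (k_switch - k_base)[C]/(K_1/2 + [C]) + k_base   (conformational
                                                               selection)

  and AIC-based discrimination between them;
* fluorescence polarization: P = (I_par - I_perp)/(I_par + I_perp) * 1000,
  the exact two-component binding isotherm with its quadratic bound
  fraction, and the K_D < [C] censoring rule;
* the logistic baseline-drift model S = S1/(1 + e^{-k(t - t_half)}) + S0.

Exponential and isotherm fits use variable projection: amplitudes enter
linearly, so for any trial rate (or K_D) they are solved exactly by linear
least squares and only the nonlinear parameter is searched, followed by a
full-parameter polish.  This makes the noiseless fits exact to solver
precision regardless of starting point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from .exceptions import IdentifiabilityError, ValidationError

__all__ = [
    "ExpFitResult",
    "KappProfile",
    "MechanismFit",
    "IsothermFit",
    "DriftFit",
    "fit_single_exponential",
    "fit_double_exponential",
    "fit_kapp_linear",
    "fit_kapp_hyperbolic",
    "discriminate_mechanism",
    "polarization",
    "bound_fraction",
    "fit_isotherm",
    "fit_competition_timecourse",
    "fit_baseline_drift",
    "subtract_drift",
]

# Double-exponential collapse / reporting thresholds (see docs/methods.md).
RATE_RATIO_COLLAPSE = 1.2      # k1/k2 below this: one population
AMPLITUDE_COLLAPSE = 0.01      # minor amplitude fraction below this: one population
FAST_REPORT_MIN_FRACTION = 0.25  # faster component must carry >= this to be reported


@dataclass
class ExpFitResult:
    """Result of a single- or double-exponential fit.

    ``reported_k`` follows the population rule: the faster exponential is
    reported when its amplitude is at least 25% of the total, otherwise the
    higher-amplitude one, and the conflict is flagged.
    """

    s0: float
    s1: float
    k1: float
    s2: float = 0.0
    k2: float = 0.0
    t0: float = 0.0
    reported_k: float = 0.0
    n_components: int = 1
    flags: tuple = ()
    sse: float = 0.0

    def as_dict(self) -> dict:
        return {
            "S0": self.s0, "S1": self.s1, "k_app_1_per_s": self.k1,
            "S2": self.s2, "k_app_2_per_s": self.k2, "t0_s": self.t0,
            "reported_k_per_s": self.reported_k,
            "n_components": self.n_components, "flags": list(self.flags),
            "sse": self.sse,
        }


@dataclass
class KappProfile:
    """Apparent rates versus effector concentration for one readout."""

    concs: np.ndarray
    kapps: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.concs = np.asarray(self.concs, dtype=float)
        self.kapps = np.asarray(self.kapps, dtype=float)
        if self.concs.shape != self.kapps.shape or self.concs.ndim != 1:
            raise ValidationError("concs and kapps must be equal-length 1-D arrays")
        if np.any(self.concs < 0):
            raise ValidationError("concentrations must be >= 0")


@dataclass
class MechanismFit:
    """Linear vs hyperbolic description of a k_app-concentration profile.

    The linear law is the induced-fit signature (slope k_on,BA:C, intercept
    k_off,BA:C); the hyperbolic law is the conformational-selection
    signature saturating at k_switch with floor k_base and midpoint K_1/2.
    ``model`` names the form with the lower (small-sample corrected) AIC.
    """

    model: str = ""
    k_on: float = math.nan
    k_off_intercept: float = math.nan
    k_switch: float = math.nan
    k_base: float = math.nan
    k_half: float = math.nan
    aic_linear: float = math.nan
    aic_hyperbolic: float = math.nan
    flags: tuple = ()

    def as_dict(self) -> dict:
        return {
            "selected_model": self.model,
            "linear": {"k_on_per_M_per_s": self.k_on, "k_off_per_s": self.k_off_intercept},
            "hyperbolic": {
                "k_switch_per_s": self.k_switch,
                "k_base_per_s": self.k_base,
                "K_half_M": self.k_half,
            },
            "aicc_linear": self.aic_linear,
            "aicc_hyperbolic": self.aic_hyperbolic,
            "flags": list(self.flags),
        }


@dataclass
class IsothermFit:
    """Equilibrium polarization titration fit.

    When the fitted K_D falls below the labeled-effector concentration the
    affinity is too strong for the method; ``censored`` is set and ``kd``
    reports the upper bound [C] (the raw fit is kept in ``kd_fit``).
    """

    p0: float
    p1: float
    kd: float
    censored: bool = False
    kd_fit: float = math.nan
    flags: tuple = ()


@dataclass
class DriftFit:
    """Logistic baseline drift S = S1/(1 + exp(-k (t - t_half))) + S0."""

    s0: float
    s1: float
    k: float
    t_half: float
    flags: tuple = ()


# ---------------------------------------------------------------------------
# Exponential fits (variable projection)
# ---------------------------------------------------------------------------


def _check_timeseries(times, signals, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    s = np.asarray(signals, dtype=float)
    if t.shape != s.shape or t.ndim != 1:
        raise ValidationError("times and signals must be equal-length 1-D arrays")
    if t.size < min_points:
        raise ValidationError(f"need at least {min_points} points")
    if not np.all(np.diff(t) > 0):
        raise ValidationError("times must be strictly increasing")
    if not np.all(np.isfinite(s)):
        raise ValidationError("signals must be finite")
    return t, s


def _k_grid(tau: np.ndarray, n: int = 60) -> np.ndarray:
    span = tau[-1] - tau[0] if tau[-1] > tau[0] else 1.0
    dt = max(np.min(np.diff(tau)), span * 1e-6)
    return np.geomspace(0.02 / span, 20.0 / dt, n)

def _linear_amplitudes(basis: np.ndarray, s: np.ndarray):
    coef, *_ = np.linalg.lstsq(basis, s, rcond=None)
    resid = s - basis @ coef
    return coef, float(resid @ resid)


def fit_single_exponential(times, signals, mode: str = "decay", t0: float | None = None) -> ExpFitResult:
    """Fit S = S0 + S1 e^{-k(t-t0)} (decay) or S = S0 + S1(1 - e^{-k(t-t0)}) (rise).

    ``t0`` defaults to the first time point.  A flat signal yields S1 = 0
    with ``k`` unidentifiable and flagged.
    """
    if mode not in ("decay", "rise"):
        raise ValidationError("mode must be 'decay' or 'rise'")
    t, s = _check_timeseries(times, signals, 4)
    t0 = float(t[0]) if t0 is None else float(t0)
    tau = t - t0

    if np.ptp(s) == 0.0:
        return ExpFitResult(
            s0=float(s[0]), s1=0.0, k1=0.0, t0=t0, reported_k=0.0,
            n_components=1, flags=("amplitude-zero: k unidentifiable",), sse=0.0,
        )

    def basis(k: float) -> np.ndarray:
        e = np.exp(-k * tau)
        col = e if mode == "decay" else 1.0 - e
        return np.column_stack([np.ones_like(tau), col])

    grid = _k_grid(tau)
    sses = [_linear_amplitudes(basis(k), s)[1] for k in grid]
    k_best = grid[int(np.argmin(sses))]

    res = minimize_scalar(
        lambda lk: _linear_amplitudes(basis(math.exp(lk)), s)[1],
        bounds=(math.log(k_best) - 2.0, math.log(k_best) + 2.0),
        method="bounded", options={"xatol": 1e-12},
    )
    k_best = math.exp(res.x)
    (s0, s1), _ = _linear_amplitudes(basis(k_best), s)

    def model(p):
        e = np.exp(-p[2] * tau)
        col = e if mode == "decay" else 1.0 - e
        return p[0] + p[1] * col - s

    sol = least_squares(model, [s0, s1, k_best], xtol=1e-15, ftol=1e-15, gtol=1e-15)
    s0, s1, k = sol.x
    flags = []
    if k <= 0.0:
        k = 0.0
        flags.append("rate pinned at zero bound")
    sse = float(2.0 * sol.cost)
    return ExpFitResult(
        s0=float(s0), s1=float(s1), k1=float(k), t0=t0, reported_k=float(k),
        n_components=1, flags=tuple(flags), sse=sse,
    )


def fit_double_exponential(times, signals, t0: float | None = None) -> ExpFitResult:
    """Fit S = S0 + S1 e^{-k1(t-t0)} + S2 e^{-k2(t-t0)} for heterogeneous host.

    Components are ordered k1 >= k2.  The fit collapses to a single
    exponential when the two rates nearly coincide or one amplitude is
    negligible (a single host population).  ``reported_k`` applies the
    population rule; when the faster component has the lower amplitude the
    conflict is flagged explicitly.
    """
    t, s = _check_timeseries(times, signals, 6)
    t0 = float(t[0]) if t0 is None else float(t0)
    tau = t - t0

    single = fit_single_exponential(t, s, mode="decay", t0=t0)
    if "amplitude-zero: k unidentifiable" in single.flags:
        return single

    grid = _k_grid(tau, n=40)
    best = (math.inf, None)
    for i in range(len(grid)):
        e1 = np.exp(-grid[i] * tau)
        for j in range(i + 1, len(grid)):
            basis = np.column_stack([np.ones_like(tau), e1, np.exp(-grid[j] * tau)])
            _, sse = _linear_amplitudes(basis, s)
            if sse < best[0]:
                best = (sse, (grid[i], grid[j]))
    ka, kb = best[1]
    basis = np.column_stack([np.ones_like(tau), np.exp(-ka * tau), np.exp(-kb * tau)])
    (s0, sa, sb), _ = _linear_amplitudes(basis, s)

    def model(p):
        return p[0] + p[1] * np.exp(-p[3] * tau) + p[2] * np.exp(-p[4] * tau) - s

    sol = least_squares(
        model, [s0, sa, sb, ka, kb],
        bounds=([-np.inf] * 3 + [0.0, 0.0], [np.inf] * 5),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    s0, sa, sb, ka, kb = sol.x
    sse = float(2.0 * sol.cost)

    # order: component 1 is the faster one
    if ka >= kb:
        k1, a1, k2, a2 = ka, sa, kb, sb
    else:
        k1, a1, k2, a2 = kb, sb, ka, sa

    total_amp = abs(a1) + abs(a2)
    minor = min(abs(a1), abs(a2)) / total_amp if total_amp > 0 else 0.0
    rate_ratio = k1 / k2 if k2 > 0 else math.inf
    if rate_ratio < RATE_RATIO_COLLAPSE or minor < AMPLITUDE_COLLAPSE or sse >= single.sse * (1 - 1e-9):
        out = single
        out.flags = out.flags + ("collapsed to single exponential: one host population",)
        return out

    frac_fast = abs(a1) / total_amp
    flags = []
    if frac_fast >= FAST_REPORT_MIN_FRACTION:
        reported = k1
        if frac_fast < 0.5:
            flags.append("reporting-rule conflict: faster component has lower amplitude")
    else:
        reported = k2
        flags.append(
            "reporting-rule conflict: faster component amplitude < 25% of total; "
            "reporting the higher-amplitude rate"
        )
    return ExpFitResult(
        s0=float(s0), s1=float(a1), k1=float(k1), s2=float(a2), k2=float(k2),
        t0=t0, reported_k=float(reported), n_components=2, flags=tuple(flags), sse=sse,
    )


# ---------------------------------------------------------------------------
# k_app vs concentration: mechanism fits
# ---------------------------------------------------------------------------


def fit_kapp_linear(profile: KappProfile) -> MechanismFit:
    """Ordinary least squares k_app = k_on [C] + k_off (induced-fit law)."""
    c, k = profile.concs, profile.kapps
    if np.unique(c).size < 3:
        raise IdentifiabilityError("need >= 3 distinct concentrations for the linear fit")
    design = np.column_stack([c, np.ones_like(c)])
    (slope, intercept), *_ = np.linalg.lstsq(design, k, rcond=None)
    resid = k - design @ np.array([slope, intercept])
    sse = float(resid @ resid)
    return MechanismFit(
        model="linear", k_on=float(slope), k_off_intercept=float(intercept),
        aic_linear=_aicc(sse, n=c.size, n_params=2),
    )


def _hyperbola(c, k_switch, k_base, k_half):
    return (k_switch - k_base) * c / (k_half + c) + k_base


def fit_kapp_hyperbolic(profile: KappProfile) -> MechanismFit:
    """Bounded NLLS of the saturating (conformational-selection) k_app law."""
    c, k = profile.concs, profile.kapps
    if np.unique(c).size < 4:
        raise IdentifiabilityError("need >= 4 distinct concentrations for the hyperbolic fit")

    k_lo, k_hi = float(np.min(k)), float(np.max(k))
    pos = c[c > 0]
    half_guess = float(np.median(pos)) if pos.size else 1e-7
    best = None
    for kh in (half_guess / 10, half_guess, half_guess * 10):
        sol = least_squares(
            lambda p: _hyperbola(c, *p) - k,
            [max(k_hi, 1e-12), max(k_lo, 0.0), kh],
            bounds=([0.0, 0.0, 0.0], [np.inf] * 3),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    k_switch, k_base, k_half = best.x
    sse = float(2.0 * best.cost)

    flags = []
    pos_span = (np.min(pos), np.max(pos)) if pos.size else (0.0, 0.0)
    if not (pos_span[0] <= k_half <= pos_span[1]):
        flags.append("K_half outside the sampled concentration range: poorly identified")
    return MechanismFit(
        model="hyperbolic", k_switch=float(k_switch), k_base=float(k_base),
        k_half=float(k_half),
        aic_hyperbolic=_aicc(sse, n=c.size, n_params=3), flags=tuple(flags),
    )


def _aicc(sse: float, n: int, n_params: int) -> float:
    """Small-sample corrected AIC under a Gaussian residual likelihood.

    k counts the model parameters plus the residual variance.  The
    correction 2k(k+1)/(n-k-1) matters at the ~8-point concentration grids
    typical here; it vanishes as n grows.
    """
    k = n_params + 1
    sse = max(sse, 1e-300)
    aic = n * math.log(sse / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = math.inf
    return aic


def discriminate_mechanism(profile: KappProfile) -> MechanismFit:
    """Fit both k_app laws and select by (corrected) AIC.

    A linear profile is the induced-fit signature; a saturating hyperbola is
    the conformational-selection signature.  Both parameter sets are kept in
    the result regardless of which is selected.
    """
    if np.unique(profile.concs).size < 4:
        raise IdentifiabilityError(
            "mechanism discrimination needs >= 4 distinct concentrations"
        )
    lin = fit_kapp_linear(profile)
    hyp = fit_kapp_hyperbolic(profile)
    selected = "linear" if lin.aic_linear <= hyp.aic_hyperbolic else "hyperbolic"
    return MechanismFit(
        model=selected,
        k_on=lin.k_on, k_off_intercept=lin.k_off_intercept,
        k_switch=hyp.k_switch, k_base=hyp.k_base, k_half=hyp.k_half,
        aic_linear=lin.aic_linear, aic_hyperbolic=hyp.aic_hyperbolic,
        flags=hyp.flags,
    )


# ---------------------------------------------------------------------------
# Fluorescence polarization
# ---------------------------------------------------------------------------


def polarization(parallel: float, perpendicular: float) -> float:
    """P = (I_par - I_perp) / (I_par + I_perp) * 1000, in mP."""
    total = parallel + perpendicular
    if total <= 0.0:
        raise ValidationError("total fluorescence intensity must be positive")
    return (parallel - perpendicular) / total * 1000.0


def bound_fraction(host_conc: float, effector_conc: float, kd: float) -> float:
    """Exact bound fraction of labeled effector at total concentrations.

    Solves the two-component equilibrium exactly:

        f = ( s - sqrt(s^2 - 4 [A][C]) ) / (2 [C]),   s = [A] + [C] + K_D.

    Evaluated in the algebraically equivalent product form
    f = 2[A] / (s + sqrt(s^2 - 4[A][C])) which avoids catastrophic
    cancellation when [A][C] << s^2.
    """
    a, c, kd = float(host_conc), float(effector_conc), float(kd)
    if a < 0 or kd < 0:
        raise ValidationError("host_conc and kd must be >= 0")
    if c <= 0:
        raise ValidationError("effector_conc must be > 0")
    if a == 0.0:
        return 0.0
    s = a + c + kd
    disc = max(s * s - 4.0 * a * c, 0.0)
    return min(2.0 * a / (s + math.sqrt(disc)), 1.0)


_bound_fraction_vec = np.vectorize(bound_fraction, otypes=[float])


def fit_isotherm(host_concs, polarizations, effector_conc: float) -> IsothermFit:
    """Fit P = P0 + P1 f_bound([A]; [C], K_D) to a host titration.

    P0 and P1 are projected out linearly at each trial K_D; K_D is searched
    on a log grid and polished.  The censoring rule is applied exactly as
    stated for the method: a fitted K_D below the labeled-effector
    concentration is reported as the upper bound K_D < [C].
    """
    a = np.asarray(host_concs, dtype=float)
    p = np.asarray(polarizations, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise ValidationError("host_concs and polarizations must be equal-length 1-D")
    if a.size < 6:
        raise ValidationError("need >= 6 titration points")
    if np.any(a < 0):
        raise ValidationError("host concentrations must be >= 0")
    c = float(effector_conc)
    if c <= 0:
        raise ValidationError("effector_conc must be > 0")

    if np.ptp(p) == 0.0:
        return IsothermFit(
            p0=float(p[0]), p1=0.0, kd=math.nan, censored=False,
            flags=("flat titration: K_D unidentifiable",),
        )

    pos = a[a > 0]
    lo, hi = np.min(pos) / 100.0, np.max(pos) * 100.0

    def sse_for(kd):
        f = _bound_fraction_vec(a, c, kd)
        basis = np.column_stack([np.ones_like(f), f])
        return _linear_amplitudes(basis, p)

    grid = np.geomspace(lo, hi, 80)
    sses = [sse_for(kd)[1] for kd in grid]
    kd0 = grid[int(np.argmin(sses))]
    res = minimize_scalar(
        lambda lk: sse_for(math.exp(lk))[1],
        bounds=(math.log(kd0) - 2.0, math.log(kd0) + 2.0),
        method="bounded", options={"xatol": 1e-12},
    )
    kd_fit = math.exp(res.x)
    (p0, p1), _ = sse_for(kd_fit)

    sol = least_squares(
        lambda q: q[0] + q[1] * _bound_fraction_vec(a, c, math.exp(q[2])) - p,
        [p0, p1, math.log(kd_fit)], xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    p0, p1, kd_fit = sol.x[0], sol.x[1], math.exp(sol.x[2])

    if kd_fit < c:
        return IsothermFit(
            p0=float(p0), p1=float(p1), kd=c, censored=True, kd_fit=float(kd_fit),
            flags=("K_D < [C]: affinity too strong for the method; upper bound reported",),
        )
    return IsothermFit(p0=float(p0), p1=float(p1), kd=float(kd_fit), kd_fit=float(kd_fit))


def fit_competition_timecourse(times, polarizations) -> ExpFitResult:
    """Kinetic-competition polarization rise P = P0 + P1 (1 - e^{-k_app t})."""
    return fit_single_exponential(times, polarizations, mode="rise")


# ---------------------------------------------------------------------------
# Baseline drift
# ---------------------------------------------------------------------------


def fit_baseline_drift(times, signals) -> DriftFit:
    """Fit the logistic drift S = S1/(1 + e^{-k (t - t_half)}) + S0."""
    t, s = _check_timeseries(times, signals, 5)

    if np.ptp(s) == 0.0:
        return DriftFit(
            s0=float(s[0]), s1=0.0, k=0.0, t_half=float(np.median(t)),
            flags=("amplitude pinned at zero: flat input",),
        )

    span = t[-1] - t[0]
    k_grid = np.geomspace(0.1 / span, 100.0 / span, 25)
    th_grid = np.linspace(t[0], t[-1], 25)
    best = (math.inf, None)
    for k in k_grid:
        for th in th_grid:
            logistic = 1.0 / (1.0 + np.exp(-k * (t - th)))
            basis = np.column_stack([np.ones_like(t), logistic])
            _, sse = _linear_amplitudes(basis, s)
            if sse < best[0]:
                best = (sse, (k, th))
    k0, th0 = best[1]
    logistic = 1.0 / (1.0 + np.exp(-k0 * (t - th0)))
    (s0, s1), _ = _linear_amplitudes(np.column_stack([np.ones_like(t), logistic]), s)

    def model(p):
        return p[1] / (1.0 + np.exp(-p[2] * (t - p[3]))) + p[0] - s

    sol = least_squares(model, [s0, s1, k0, th0], xtol=1e-15, ftol=1e-15, gtol=1e-15)
    s0, s1, k, th = sol.x
    flags = []
    if abs(s1) < 1e-12 * max(1.0, abs(s0)):
        flags.append("amplitude pinned at zero: flat input")
    return DriftFit(s0=float(s0), s1=float(s1), k=float(k), t_half=float(th), flags=tuple(flags))


def subtract_drift(times, signals, drift: DriftFit) -> np.ndarray:
    """Signals minus the fitted logistic drift (baseline S0 retained)."""
    t = np.asarray(times, dtype=float)
    s = np.asarray(signals, dtype=float)
    return s - drift.s1 / (1.0 + np.exp(-drift.k * (t - drift.t_half)))
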