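"""Multi-cycle SPR experiment model and global dissociation fitting.

An experiment is a sequence of cycles: in each cycle the chip is re-loaded
with host, then dissociation is recorded under flow of one effector
concentration from a two-fold serial dilution.  Across cycles a small
effector-unresponsive host population (BAn) accumulates on the chip.  The
per-cycle initial conditions follow the recursion

    [BA]final,0  = 0
    [BAn]final,0 = 0
    [B]final,n-1   = 1 - [BA]final,n-1 - [BAn]final,n-1
    [BAC]initial,n = 0
    [BA]initial,n  = [BA]final,n-1  + f_responsive * [B]final,n-1
    [BAn]initial,n = [BAn]final,n-1 + (1 - f_responsive) * [B]final,n-1

where "final" occupancies come from propagating the previous cycle's
dissociation window at that cycle's effector concentration.  Any ternary
complex left at the end of a window is folded into [BA]final (the effector
washes out between cycles).  The occupancies map to the instrument response
through

    S(t) = f_n * (a_BA [BA] + a_BAC [BAC] + a_BAn [BAn])

with per-cycle amplitude factors f_n (f_1 pinned to 1 as the gauge choice)
and species amplitudes in response units (RU) per unit occupancy.  The model
is globally fit to all cycles at once by trust-region nonlinear least
squares with rates in log-space.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import IdentifiabilityError, ValidationError
from .kinetics import ChipState, RateConstants, propagate_dissociation

__all__ = [
    "CycleSchedule",
    "CycleData",
    "SPRDataset",
    "ResponseModel",
    "GlobalFitResult",
    "cycle_initial_states",
    "simulate_cycles",
    "fit_global",
    "fold_change",
]

_RATE_NAMES = ("k_off_B_A", "k_on_BA_C", "k_off_BA_C", "k_off_B_AC", "k_off_B_An")
_LOG_BOUNDS = (-12.0, 8.0)  # log10 bounds on every rate during fitting


@dataclass(frozen=True)
class CycleSchedule:
    """Design of a multi-cycle dissociation experiment.

    ``effector_concs`` holds the molar effector concentration of each cycle
    (typically a two-fold serial dilution); ``dissociation_window`` and
    ``sample_interval`` are in seconds and shared across cycles.
    """

    effector_concs: tuple
    dissociation_window: float = 600.0
    sample_interval: float = 1.0

    def __post_init__(self) -> None:
        concs = tuple(float(c) for c in self.effector_concs)
        if len(concs) < 1:
            raise ValidationError("schedule needs at least one cycle")
        if any((not math.isfinite(c)) or c < 0.0 for c in concs):
            raise ValidationError("effector concentrations must be finite and >= 0")
        if not (self.dissociation_window > 0.0):
            raise ValidationError("dissociation_window must be > 0")
        if not (0.0 < self.sample_interval <= self.dissociation_window):
            raise ValidationError("sample_interval must be in (0, window]")
        object.__setattr__(self, "effector_concs", concs)

    @property
    def n_cycles(self) -> int:
        return len(self.effector_concs)

    @classmethod
    def serial_dilution(
        cls,
        top_conc: float = 5e-6,
        n_cycles: int = 6,
        dilution: float = 2.0,
        dissociation_window: float = 600.0,
        sample_interval: float = 1.0,
    ) -> "CycleSchedule":
        """Descending ``dilution``-fold series starting at ``top_conc`` molar."""
        concs = tuple(top_conc / dilution**i for i in range(n_cycles))
        return cls(concs, dissociation_window, sample_interval)

    def cycle_times(self, n: int) -> np.ndarray:
        """Window-relative sampling grid of cycle ``n`` (starts at 0)."""
        npts = int(math.floor(self.dissociation_window / self.sample_interval)) + 1
        return np.arange(npts) * self.sample_interval

    def to_dict(self) -> dict:
        return {
            "effector_concs_M": list(self.effector_concs),
            "dissociation_window_s": self.dissociation_window,
            "sample_interval_s": self.sample_interval,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CycleSchedule":
        return cls(
            tuple(d["effector_concs_M"]),
            float(d["dissociation_window_s"]),
            float(d["sample_interval_s"]),
        )


@dataclass
class CycleData:
    """One cycle's recorded time series (absolute seconds, RU)."""

    times: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.shape != self.response.shape or self.times.ndim != 1:
            raise ValidationError("cycle time/response arrays must be equal-length 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("cycle times must be strictly increasing")


@dataclass
class SPRDataset:
    """Multi-cycle sensorgram dissociation phases plus their schedule."""

    cycles: list
    schedule: CycleSchedule
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cycles) != self.schedule.n_cycles:
            raise ValidationError("number of cycles must match the schedule")

    def max_response(self) -> float:
        return max(float(np.max(c.response)) for c in self.cycles)

    # -- CSV + JSON sidecar I/O -------------------------------------------

    def to_csv(self, path) -> Path:
        """Write long-format CSV (cycle, time_s, response_RU) + schedule sidecar."""
        path = Path(path)
        frames = [
            pd.DataFrame(
                {"cycle": i + 1, "time_s": c.times, "response_RU": c.response}
            )
            for i, c in enumerate(self.cycles)
        ]
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")
        sidecar = path.with_suffix(".schedule.json")
        payload = {"schedule": self.schedule.to_dict(), "meta": self.meta}
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_csv(cls, path) -> "SPRDataset":
        path = Path(path)
        df = pd.read_csv(path)
        payload = json.loads(path.with_suffix(".schedule.json").read_text())
        schedule = CycleSchedule.from_dict(payload["schedule"])
        cycles = []
        for i in range(1, schedule.n_cycles + 1):
            sub = df[df["cycle"] == i]
            cycles.append(CycleData(sub["time_s"].to_numpy(), sub["response_RU"].to_numpy()))
        return cls(cycles=cycles, schedule=schedule, meta=payload.get("meta", {}))


@dataclass(frozen=True)
class ResponseModel:
    """Occupancy-to-response map of the sensorgram model.

    ``a_ba``, ``a_bac``, ``a_ban`` are RU per unit occupancy; ``f_scale``
    are the per-cycle amplitude factors (first entry fixed to 1 as the
    gauge); ``f_responsive`` is the fraction of freshly loaded host that
    responds to the effector.
    """

    a_ba: float
    a_bac: float
    a_ban: float
    f_responsive: float
    f_scale: tuple = (1.0,)

    def __post_init__(self) -> None:
        for name in ("a_ba", "a_bac", "a_ban"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0.0:
                raise ValidationError(f"ResponseModel.{name} must be finite and >= 0")
            object.__setattr__(self, name, v)
        fr = float(self.f_responsive)
        if not (0.0 <= fr <= 1.0):
            raise ValidationError("f_responsive must lie in [0, 1]")
        object.__setattr__(self, "f_responsive", fr)
        fs = tuple(float(f) for f in self.f_scale)
        if len(fs) < 1 or abs(fs[0] - 1.0) > 1e-12:
            raise ValidationError("f_scale[0] is the gauge and must equal 1")
        if any((not math.isfinite(f)) or f < 0.0 for f in fs):
            raise ValidationError("f_scale entries must be finite and >= 0")
        object.__setattr__(self, "f_scale", fs)

    def as_dict(self) -> dict:
        return {
            "a_BA_RU": self.a_ba,
            "a_BAC_RU": self.a_bac,
            "a_BAn_RU": self.a_ban,
            "f_responsive": self.f_responsive,
            "f_scale": list(self.f_scale),
        }


@dataclass
class GlobalFitResult:
    """Outcome of the global multi-cycle dissociation fit."""

    rates: RateConstants
    response: ResponseModel
    residual_sse: float
    per_cycle_residuals: tuple
    covariance_flags: tuple = ()
    converged: bool = True
    n_starts: int = 1

    def to_json(self, path=None) -> str:
        payload = {
            "rates": self.rates.as_dict(),
            "response": self.response.as_dict(),
            "residual_sse_RU2": self.residual_sse,
            "per_cycle_residuals_RU2": list(self.per_cycle_residuals),
            "covariance_flags": list(self.covariance_flags),
            "converged": self.converged,
            "n_starts": self.n_starts,
            "weighting": "unweighted SSE across all cycles",
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def cycle_initial_states(
    rates: RateConstants, schedule: CycleSchedule, f_responsive: float
) -> list[ChipState]:
    """Per-cycle initial chip states from the accumulation recursion.

    Residual ternary complex at the end of a window is folded into the
    carried-over [BA] (the effector washes out between cycles).
    """
    fr = float(f_responsive)
    if not (0.0 <= fr <= 1.0):
        raise ValidationError("f_responsive must lie in [0, 1]")
    ba_final, ban_final = 0.0, 0.0
    endpoint = np.array([0.0, schedule.dissociation_window])
    states = []
    for conc in schedule.effector_concs:
        b_free = max(0.0, 1.0 - ba_final - ban_final)
        ba0 = ba_final + fr * b_free
        ban0 = ban_final + (1.0 - fr) * b_free
        state = ChipState(ba=ba0, bac=0.0, ban=ban0, b=max(0.0, 1.0 - ba0 - ban0))
        states.append(state)
        traj = propagate_dissociation(rates, conc, state, endpoint)
        ba_final = float(traj.ba[-1] + traj.bac[-1])
        ban_final = float(traj.ban[-1])
    return states


def _model_cycle_responses(
    rates: RateConstants, schedule: CycleSchedule, response: ResponseModel,
    time_grids=None,
) -> list[np.ndarray]:
    """Noise-free modeled response of every cycle on its sampling grid."""
    fs = response.f_scale
    if len(fs) != schedule.n_cycles:
        raise ValidationError("f_scale length must equal the number of cycles")
    states = cycle_initial_states(rates, schedule, response.f_responsive)
    out = []
    for n, (conc, state) in enumerate(zip(schedule.effector_concs, states)):
        tau = schedule.cycle_times(n) if time_grids is None else time_grids[n]
        traj = propagate_dissociation(rates, conc, state, tau)
        s = fs[n] * (
            response.a_ba * traj.ba + response.a_bac * traj.bac + response.a_ban * traj.ban
        )
        out.append(s)
    return out


def simulate_cycles(
    rates: RateConstants, schedule: CycleSchedule, response: ResponseModel
) -> SPRDataset:
    """Deterministic noise-free multi-cycle dataset from the chip model.

    Cycle ``n`` starts at absolute time ``n * dissociation_window`` (the
    association phases between windows are not modeled).
    """
    signals = _model_cycle_responses(rates, schedule, response)
    cycles = []
    for n, s in enumerate(signals):
        t0 = n * schedule.dissociation_window
        cycles.append(CycleData(t0 + schedule.cycle_times(n), s))
    return SPRDataset(cycles=cycles, schedule=schedule, meta={"source": "simulate_cycles"})


# ---------------------------------------------------------------------------
# Global fitting
# ---------------------------------------------------------------------------


def _default_init(dataset: SPRDataset) -> dict:
    """Data-driven starting guesses for the global fit."""
    concs = dataset.schedule.effector_concs
    smax = dataset.max_response()

    def crude_rate(cycle: CycleData) -> float:
        # time for the signal to fall to half its initial value
        s = cycle.response
        tau = cycle.times - cycle.times[0]
        target = 0.5 * (s[0] + s[-1] * 0.0)
        idx = np.nonzero(s <= target)[0]
        t_half = tau[idx[0]] if idx.size else tau[-1]
        return math.log(2.0) / max(t_half, tau[1] if tau.size > 1 else 1.0)

    i_lo = int(np.argmin(concs))
    i_hi = int(np.argmax(concs))
    k_slow = crude_rate(dataset.cycles[i_lo])
    k_fast = max(crude_rate(dataset.cycles[i_hi]), k_slow)
    return {
        "k_off_B_A": k_slow,
        "k_on_BA_C": 1e5,
        "k_off_BA_C": 1e-3,
        "k_off_B_AC": k_fast,
        "k_off_B_An": max(k_slow / 10.0, 1e-7),
        "a_ba": smax,
        "a_bac": smax,
        "a_ban": smax,
        "f_responsive": 0.9,
    }


def fit_global(
    dataset: SPRDataset,
    init: dict | None = None,
    fixed: dict | None = None,
    n_starts: int = 3,
    seed: int = 0,
) -> GlobalFitResult:
    """Globally fit the cycle ODE model to all dissociation cycles.

    Free parameters are the five rate constants (optimised in log10 space),
    the three species amplitudes, the per-cycle amplitude factors f_n for
    n >= 2 (f_1 pinned to 1), and f_responsive (bounded to [0, 1]).  The sum
    of squared residuals is unweighted across cycles.  Multi-start with
    jittered rate initialisations guards against the flat valleys created by
    the tightly covarying pair (k_on,BA:C, k_off,BA:C); that covariance is
    reported as a flag, not treated as a failure.

    Parameters
    ----------
    dataset : SPRDataset
        Needs >= 2 cycles at distinct effector concentrations for the
        binary/ternary off-rates to be separable.
    init : dict, optional
        Partial overrides of the data-driven initial guesses (keys as in
        :func:`_default_init`, plus ``f_scale``).
    fixed : dict, optional
        Parameters pinned at the given values and excluded from optimisation.
    n_starts : int
        Number of jittered starts (the first start is un-jittered).
    seed : int
        Seed for the jitter RNG.
    """
    schedule = dataset.schedule
    concs = schedule.effector_concs
    if schedule.n_cycles < 2 or len(set(concs)) < 2:
        raise IdentifiabilityError(
            "need >= 2 cycles at distinct effector concentrations to separate "
            "k_off,B:AC from k_off,B:A"
        )
    if all(c == 0.0 for c in concs):
        raise IdentifiabilityError("all cycles at [C] = 0: effector rates unidentifiable")

    fixed = dict(fixed or {})
    guesses = _default_init(dataset)
    guesses.update(init or {})

    n_cycles = schedule.n_cycles
    f_scale0 = list(guesses.get("f_scale", [1.0] * n_cycles))
    if len(f_scale0) != n_cycles:
        raise ValidationError("init f_scale length must equal the number of cycles")

    free_names: list[str] = []
    x0, lo, hi = [], [], []

    def add(name, value, lo_v, hi_v):
        if name in fixed:
            return
        free_names.append(name)
        x0.append(value)
        lo.append(lo_v)
        hi.append(hi_v)

    for rn in _RATE_NAMES:
        add(rn, math.log10(max(guesses[rn], 1e-12)), *_LOG_BOUNDS)
    for an in ("a_ba", "a_bac", "a_ban"):
        add(an, max(guesses[an], 1e-9), 0.0, np.inf)
    add("f_responsive", min(max(guesses["f_responsive"], 0.0), 1.0), 0.0, 1.0)
    for n in range(1, n_cycles):
        add(f"f_{n + 1}", f_scale0[n], 0.0, np.inf)

    time_grids = [c.times - c.times[0] for c in dataset.cycles]
    data = [c.response for c in dataset.cycles]

    def unpack(x) -> tuple[RateConstants, ResponseModel]:
        vals = dict(zip(free_names, x))

        def get(name, log=False):
            if name in fixed:
                return float(fixed[name])
            return 10.0 ** vals[name] if log else float(vals[name])

        rates = RateConstants(*(get(rn, log=True) for rn in _RATE_NAMES))
        fs = [1.0] + [get(f"f_{n + 1}") for n in range(1, n_cycles)]
        response = ResponseModel(
            a_ba=get("a_ba"),
            a_bac=get("a_bac"),
            a_ban=get("a_ban"),
            f_responsive=min(max(get("f_responsive"), 0.0), 1.0),
            f_scale=tuple(fs),
        )
        return rates, response

    def residuals(x) -> np.ndarray:
        rates, response = unpack(x)
        model = _model_cycle_responses(rates, schedule, response, time_grids)
        return np.concatenate([m - d for m, d in zip(model, data)])

    rng = np.random.default_rng(seed)
    x0 = np.array(x0)
    best = None
    n_rate_free = sum(1 for rn in _RATE_NAMES if rn not in fixed)
    for start in range(max(1, n_starts)):
        xs = x0.copy()
        if start > 0:
            # jitter free log-rates by up to a factor of ~3 either way
            jit = rng.uniform(-math.log10(3.0), math.log10(3.0), size=n_rate_free)
            xs[:n_rate_free] = np.clip(xs[:n_rate_free] + jit, *_LOG_BOUNDS)
        try:
            sol = least_squares(
                residuals, xs, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=4000,
            )
        except Exception:  # a pathological start must not sink the fit
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        raise IdentifiabilityError("global fit failed from every start")

    rates, response = unpack(best.x)
    model = _model_cycle_responses(rates, schedule, response, time_grids)
    per_cycle = tuple(float(np.sum((m - d) ** 2)) for m, d in zip(model, data))
    sse = float(sum(per_cycle))

    flags = []
    # pre-equilibrium regime: effector association at the top concentration
    # outpaces both exits from the ternary complex, so only ratios of the
    # effector-binding pair are constrained
    kon_c_max = rates.k_on_BA_C * max(concs)
    if kon_c_max > rates.k_off_BA_C + rates.k_off_B_AC:
        flags.append(
            "k_on_BA_C and k_off_BA_C tightly covary (effector binding much faster "
            "than partner dissociation); their individual values are not reliable"
        )
    converged = bool(best.status > 0)
    if not converged:
        flags.append("optimizer did not report convergence; treat estimates with caution")

    return GlobalFitResult(
        rates=rates,
        response=response,
        residual_sse=sse,
        per_cycle_residuals=per_cycle,
        covariance_flags=tuple(flags),
        converged=converged,
        n_starts=max(1, n_starts),
    )


def fold_change(result: GlobalFitResult) -> float:
    """Headline metric: effector-induced off-rate acceleration k_off,B:AC / k_off,B:A."""
    if result.rates.k_off_B_A <= 0.0:
        raise ValidationError("fold change undefined: fitted k_off_B_A is zero")
    return result.rates.k_off_B_AC / result.rates.k_off_B_A
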