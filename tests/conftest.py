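import numpy as np
import pytest

from facdis import RateConstants


@pytest.fixture
def example_rates():
    """The rate set used by the worked propagation examples."""
    return RateConstants(
        k_off_B_A=1e-4, k_on_BA_C=1e5, k_off_BA_C=1e-3,
        k_off_B_AC=0.1, k_off_B_An=1e-5,
    )


def random_rate_sets(n, seed=0, with_conc=True):
    """Log-uniform random rate draws for oracle-equivalence sweeps.

    First-order rates in 1e-6..1 s^-1, k_on in 1e3..1e7 M^-1 s^-1,
    effector concentrations in 0..1e-5 M (including exact zeros).
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        first_order = 10.0 ** rng.uniform(-6, 0, size=4)
        k_on = 10.0 ** rng.uniform(3, 7)
        rates = RateConstants(
            k_off_B_A=first_order[0], k_on_BA_C=k_on,
            k_off_BA_C=first_order[1], k_off_B_AC=first_order[2],
            k_off_B_An=first_order[3],
        )
        conc = 0.0 if rng.random() < 0.1 else 10.0 ** rng.uniform(-9, -5)
        out.append((rates, conc) if with_conc else rates)
    return out


def rk_oracle(rates, conc, state0, times, rtol=1e-11, atol=1e-13):
    """Independent adaptive Runge-Kutta integration of the chip ODEs."""
    from scipy.integrate import solve_ivp

    def rhs(_, y):
        bac, ba, ban = y
        return [
            -rates.k_off_B_AC * bac + rates.k_on_BA_C * ba * conc - rates.k_off_BA_C * bac,
            -rates.k_off_B_A * ba - rates.k_on_BA_C * ba * conc + rates.k_off_BA_C * bac,
            -rates.k_off_B_An * ban,
        ]

    sol = solve_ivp(
        rhs, (times[0], times[-1]), [state0.bac, state0.ba, state0.ban],
        t_eval=times, rtol=rtol, atol=atol, method="DOP853",
    )
    return sol.y  # rows: bac, ba, ban
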