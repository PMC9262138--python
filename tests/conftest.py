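import numpy as np
import pytest

from autosplice.model_core import ModelParameters


@pytest.fixture(scope="session")
def default_params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_params(rng: np.random.Generator, *, active: bool = True,
                  max_tries: int = 200) -> ModelParameters:
    """Random parameter set in the functional-circuit regime.

    Rates are drawn over broad biologically plausible ranges with the
    turnover hierarchy the circuit presumes (pre-mRNA much faster than mRNA,
    mRNA faster than protein, as for a typical splicing factor); when
    ``active`` the set is rejection-sampled so the Hill repression at the
    high-induction operating point is genuinely engaged (0.05 < H < 0.95),
    i.e. the feedback loop is neither saturated nor inert.
    """
    from autosplice.model_core import (hill_repression, effective_protein,
                                       steady_state_feedback)

    for _ in range(max_tries):
        beta_p = float(rng.uniform(0.03, 0.12))
        beta_m = beta_p * float(rng.uniform(3.0, 8.0))
        beta_u = beta_m * float(rng.uniform(3.0, 8.0))
        p = ModelParameters(
            alpha_ec_lo=float(rng.uniform(0.5, 5.0)),
            alpha_ec_hi=float(rng.uniform(5.0, 20.0)),
            alpha_en=float(rng.uniform(5.0, 50.0)),
            gamma=float(rng.uniform(0.3, 3.0)),
            beta_u=beta_u,
            beta_m=beta_m,
            beta_p=beta_p,
            kappa=float(rng.uniform(0.5, 5.0)),
            k_half=float(rng.uniform(5.0, 300.0)),
            h_hill=float(rng.uniform(1.0, 5.0)),
            reservoir=float(rng.uniform(30.0, 1000.0)),
            t_delay_lo=float(rng.uniform(6.0, 9.0)),
            t_delay_hi=float(rng.uniform(0.0, 1.0)),
            bg=float(rng.uniform(0.0, 5.0)),
            u0_en=0.0, m0_en=0.0, p0_en=0.0,
            sigma_obs=1.0,
        )
        if not active:
            return p
        ss = steady_state_feedback(p, p.alpha_ec_hi)
        p_eff = effective_protein(ss.u_en, ss.u_ec, p.reservoir,
                                  ss.p_ec + ss.p_en)
        h = hill_repression(p_eff, p.k_half, p.h_hill)
        if 0.05 < h < 0.95:
            return p
    raise RuntimeError("could not draw an active parameter set")
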