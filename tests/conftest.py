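import numpy as np
import pytest

from symbiovade import ModelParams, ReducedParams, compute_Q

#: log-uniform draw range for random rates/coefficients in property tests
LOG_RANGE = (np.log(1e-2), np.log(1e1))


def draw_model_params(rng: np.random.Generator, d: float | None = None) -> ModelParams:
    """Random full parameter set, log-uniform over [1e-2, 10]."""
    vals = {
        name: float(np.exp(rng.uniform(*LOG_RANGE)))
        for name in ModelParams.field_names()
    }
    vals["d"] = float(np.exp(rng.uniform(np.log(0.5), np.log(2.0)))) if d is None else d
    return ModelParams.from_dict(vals)


def draw_reduced_params(
    rng: np.random.Generator, d: float = 1.0, regime: str | None = None
) -> ReducedParams:
    """Random reduced pair; optionally rejection-sampled into a regime."""
    while True:
        rp = ReducedParams(
            **{
                name: float(np.exp(rng.uniform(*LOG_RANGE)))
                for name in ("r_p", "q_hp", "q_cp", "q_cm", "q_hm",
                             "alpha", "beta", "mu_p", "mu_m")
            },
            d=d,
        )
        if regime is None:
            return rp
        Q = compute_Q(rp)
        if regime == "mutualistic" and Q.Q_p > 0 and Q.Q_m > 0:
            return rp


def draw_state(rng: np.random.Generator, n: int = 4, scale: float = 2.0) -> np.ndarray:
    return rng.uniform(1e-3, scale, n)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture
def defaults() -> ModelParams:
    return ModelParams()
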