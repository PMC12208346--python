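"""Shared fixtures: small synthetic studies and hand-built posterior fits."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sleepcoda.composition import DEFAULT_SBP, ilr_basis
from sleepcoda.decompose import decompose
from sleepcoda.model import Design, McmcSpec, ModelSpec, PosteriorFit, fit
from sleepcoda.simulate import GeneratorConfig, generate

#: an alternative sequential binary partition (sleep-first hierarchy)
ALT_SBP = np.array(
    [
        [1, 1, -1, -1],
        [1, -1, 0, 0],
        [0, 0, 1, -1],
    ],
    dtype=float,
)


@pytest.fixture(scope="session")
def small_dataset():
    """Complete 30-person x 8-night synthetic study (no missingness)."""
    return generate(GeneratorConfig(n_persons=30, n_days=8, seed=2024))


@pytest.fixture(scope="session")
def small_decomposed(small_dataset):
    return decompose(small_dataset.table, ilr_basis(DEFAULT_SBP))


@pytest.fixture(scope="session")
def small_fit_d(small_decomposed):
    """One variant-d fit reused by tests that only need plausible draws."""
    spec = ModelSpec(outcome="hana", variant="d", mcmc=McmcSpec(seed=99))
    return fit(spec, small_decomposed)


ILR_COLUMNS = ["b1", "b2", "b3", "w1", "w2", "w3"]


def make_linear_fit(
    coef: dict[str, float],
    n_draws: int = 200,
    jitter: float = 0.0,
    seed: int = 0,
) -> PosteriorFit:
    """Posterior fit with known (optionally jittered) coefficient draws.

    Used as the noiseless analytic truth for substitution oracles: the
    expected-outcome difference for any composition contrast is exactly
    beta' (z' - z).
    """
    columns = ["intercept"] + ILR_COLUMNS
    p = len(columns)
    beta = np.zeros((1, n_draws, p))
    for name, value in coef.items():
        beta[0, :, columns.index(name)] = value
    if jitter:
        rng = np.random.default_rng(seed)
        beta = beta + jitter * rng.standard_normal(beta.shape)
    design = Design(
        X=np.zeros((2, p)),
        columns=columns,
        y=np.array([0.0, 1.0]),
        Zrows=np.ones((2, 1)),
        z_columns=["intercept"],
        group_idx=np.array([0, 0]),
        group_ids=np.array([1]),
        centers={},
        row_index=np.array([0, 1]),
    )
    draws = {
        "beta": beta,
        "u": np.zeros((1, n_draws, 1, 1)),
        "Sigma_u": np.zeros((1, n_draws, 1, 1)),
        "sigma2": np.full((1, n_draws), 1e-12),
    }
    return PosteriorFit(
        spec=ModelSpec(outcome="hap", variant="d"),
        design=design,
        draws=draws,
        diagnostics={"max_rhat": 1.0, "min_ess": float(n_draws)},
        converged=True,
        data_hash="synthetic",
    )


def tiny_table() -> pd.DataFrame:
    """Five persons, hand-sized table in the input-CSV dialect."""
    rng = np.random.default_rng(7)
    rows = []
    for pid in range(1, 6):
        for day in range(1, 5):
            props = rng.dirichlet([4, 12, 6, 7])
            tib = 420.0 + 30 * rng.standard_normal()
            mins = props * tib
            rows.append(
                {
                    "id": pid,
                    "day": day,
                    "twt_min": mins[0],
                    "light_min": mins[1],
                    "sws_min": mins[2],
                    "rem_min": mins[3],
                    "tib_min": tib,
                    "hap": float(np.clip(2.5 + rng.standard_normal(), 1, 5)),
                    "lap": 3.0,
                    "hana": 1.5,
                    "lana": 1.5,
                    "presleep_hap": 2.5,
                    "presleep_lap": 3.0,
                    "presleep_hana": 1.5,
                    "presleep_lana": 1.5,
                    "weekend": int(day >= 3),
                    "cpd": float(rng.standard_normal()),
                    "age": 21.0 + pid,
                    "gender": "female" if pid % 2 else "male",
                    "ethnicity": "asian",
                    "sss": 5.0,
                    "bmi": 22.0,
                }
            )
    return pd.DataFrame(rows)
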