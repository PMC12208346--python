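"""Synthetic multilevel sleep-composition + affect datasets.

Emulates the statistical structure of an intensive EEG + EMA daily study:
~96 adults observed for ~2 weeks, nightly 4-part sleep compositions with
more within- than between-person variance (coordinate ICCs around 0.3-0.4),
morning affect on a 1-5 scale with more between- than within-person
variance (ICCs around 0.55-0.67), daily and baseline covariates, and
missing-completely-at-random gaps (about 4% of sleep nights and 19% of
morning affect reports).

Compositions are generated logistic-normally — person means and daily
deviations are multivariate normal in ilr space — which matches the
analysis model's geometry and makes the true substitution curves analytic.
Affect is linear in the between/within ilr coordinates with a person random
intercept and random within-coordinate slopes, then clipped to [1, 5]
(defaults keep clipping below 1%).  Night-to-night dynamics (e.g. REM
rebound) and floor effects of negative affect are deliberately not
emulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .composition import DEFAULT_SBP, ilr, ilr_basis, ilr_inv
from .decompose import OUTCOME_COLUMNS, SLEEP_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeEffects",
    "GeneratorConfig",
    "SyntheticDataset",
    "generate",
    "apply_missingness",
    "compute_icc",
]

#: grand geometric-mean proportions of (TWT, light, SWS, REM) being emulated
TARGET_PROPORTIONS = np.array([0.13, 0.43, 0.21, 0.23])

#: total ilr coordinate variances consistent with nightly stage-minute
#: spreads (CV ~0.3-0.6); split 35% between / 65% within persons
_TOTAL_ILR_VAR = np.array([0.23, 0.10, 0.13])
_BETWEEN_SHARE = 0.35


@dataclass(frozen=True)
class OutcomeEffects:
    """True fixed effects for one affect outcome (outcome-scale units)."""

    intercept: float
    between: tuple[float, float, float]
    within: tuple[float, float, float]
    tib: float = 0.0
    presleep: float = 0.2
    weekend: float = 0.05
    cpd: float = -0.03


def _default_betas() -> dict[str, OutcomeEffects]:
    return {
        "hap": OutcomeEffects(2.6, (-0.40, -0.30, 0.50), (-0.10, -0.08, 0.15)),
        "lap": OutcomeEffects(2.9, (-0.35, -0.25, 0.45), (-0.08, -0.05, 0.12)),
        "hana": OutcomeEffects(2.5, (0.35, 0.20, -0.45), (0.08, 0.05, -0.14)),
        "lana": OutcomeEffects(2.5, (0.30, 0.10, -0.30), (0.14, -0.04, -0.10)),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    n_persons: int = 96
    n_days: int = 14
    mu_b: np.ndarray | None = None  # default: ilr of TARGET_PROPORTIONS
    sigma_b: np.ndarray | None = None
    sigma_w: np.ndarray | None = None
    tib_mean_min: float = 448.66
    tib_sd_min: float = 95.47
    tib_floor_min: float = 180.0
    betas: dict[str, OutcomeEffects] = field(default_factory=_default_betas)
    random_intercept_sd: float = 0.48
    random_slope_sd: float = 0.06
    residual_sd: float = 0.38
    presleep_between_sd: float = 0.45
    presleep_within_sd: float = 0.35
    missing_sleep_rate: float = 0.04
    missing_affect_rate: float = 0.19
    seed: int = 0

    def resolved(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        mu = (
            ilr(TARGET_PROPORTIONS, ilr_basis(DEFAULT_SBP))
            if self.mu_b is None
            else np.asarray(self.mu_b, float)
        )
        sb = (
            np.diag(_BETWEEN_SHARE * _TOTAL_ILR_VAR)
            if self.sigma_b is None
            else np.asarray(self.sigma_b, float)
        )
        sw = (
            np.diag((1.0 - _BETWEEN_SHARE) * _TOTAL_ILR_VAR)
            if self.sigma_w is None
            else np.asarray(self.sigma_w, float)
        )
        for m in (sb, sw):
            if not np.allclose(m, m.T) or np.any(np.linalg.eigvalsh(m) < -1e-12):
                raise ValueError("covariances must be symmetric positive semidefinite")
        for r in (self.missing_sleep_rate, self.missing_affect_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("missingness rates must be in [0, 1]")
        return mu, sb, sw


@dataclass
class SyntheticDataset:
    """Generated table plus the ground truth that produced it."""

    table: pd.DataFrame
    config: GeneratorConfig
    person_b: np.ndarray  # (G, 3) true person-mean ilr coordinates
    person_intercepts: dict[str, np.ndarray]
    person_slopes: dict[str, np.ndarray]  # per outcome (G, 3)


def generate(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Draw a complete (pre-missingness) dataset; bit-reproducible per seed."""
    config = config or GeneratorConfig()
    mu_b, sigma_b, sigma_w = config.resolved()
    if stats.norm.cdf(0.0, config.tib_mean_min, config.tib_sd_min) > 0.01:
        raise ValueError("infeasible config: >1% of time-in-bed draws negative")
    basis = ilr_basis(DEFAULT_SBP)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    G, D = config.n_persons, config.n_days
    n = G * D

    person_id = np.repeat(np.arange(1, G + 1), D)
    day = np.tile(np.arange(1, D + 1), G)
    pidx = person_id - 1

    # baseline covariates
    age = np.clip(rng.normal(20.55, 1.65, G), 18, 25)
    gender = rng.choice(["female", "male"], G, p=[0.773, 0.227])
    ethnicity = rng.choice(["asian", "white", "other"], G, p=[0.845, 0.093, 0.062])
    sss = np.clip(rng.normal(5.49, 1.43, G), 2, 9)
    bmi = np.clip(rng.normal(21.92, 3.49, G), 15, 40)

    # compositions: logistic-normal with person random effects in ilr space
    b = rng.multivariate_normal(mu_b, sigma_b, size=G)
    w = rng.multivariate_normal(np.zeros(3), sigma_w, size=n)
    props = ilr_inv(b[pidx] + w, basis)
    lo = (config.tib_floor_min - config.tib_mean_min) / config.tib_sd_min
    tib = stats.truncnorm.rvs(
        lo, np.inf, loc=config.tib_mean_min, scale=config.tib_sd_min,
        size=n, random_state=rng,
    )
    minutes = props * tib[:, None]

    # daily covariates; persons enter the study on different weekdays
    start_weekday = rng.integers(0, 7, G)
    weekend = (((start_weekday[pidx] + day - 1) % 7) >= 5).astype(int)
    cpd_person = rng.normal(1.27, 0.65, G)
    cpd = cpd_person[pidx] + rng.normal(0.0, 0.8, n)

    data = {
        "id": person_id,
        "day": day,
        **{c: minutes[:, k] for k, c in enumerate(SLEEP_COLUMNS)},
        "tib_min": tib,
        "weekend": weekend,
        "cpd": cpd,
        "age": age[pidx],
        "gender": gender[pidx],
        "ethnicity": ethnicity[pidx],
        "sss": sss[pidx],
        "bmi": bmi[pidx],
    }

    person_intercepts: dict[str, np.ndarray] = {}
    person_slopes: dict[str, np.ndarray] = {}
    n_clipped = 0
    for outcome in OUTCOME_COLUMNS:
        eff = config.betas[outcome]
        u0 = rng.normal(0.0, config.random_intercept_sd, G)
        us = rng.normal(0.0, config.random_slope_sd, (G, 3))
        presleep = np.clip(
            eff.intercept
            + rng.normal(0.0, config.presleep_between_sd, G)[pidx]
            + rng.normal(0.0, config.presleep_within_sd, n),
            1.0,
            5.0,
        )
        lin = (
            eff.intercept
            + b[pidx] @ np.asarray(eff.between)
            + w @ np.asarray(eff.within)
            + eff.tib * (tib - config.tib_mean_min)
            + eff.presleep * (presleep - eff.intercept)
            + eff.weekend * weekend
            + eff.cpd * (cpd - 1.27)
            + u0[pidx]
            + np.einsum("nk,nk->n", us[pidx], w)
            + rng.normal(0.0, config.residual_sd, n)
        )
        y = np.clip(lin, 1.0, 5.0)
        n_clipped += int((y != lin).sum())
        data[outcome] = y
        data[f"presleep_{outcome}"] = presleep
        person_intercepts[outcome] = u0
        person_slopes[outcome] = us
    if n_clipped > 0.01 * n * len(OUTCOME_COLUMNS):
        logger.warning(
            "affect clipping rate %.1f%% exceeds 1%%; consider weaker effects",
            100.0 * n_clipped / (n * len(OUTCOME_COLUMNS)),
        )

    from .decompose import REQUIRED_COLUMNS  # canonical column order

    table = pd.DataFrame(data)[REQUIRED_COLUMNS]
    return SyntheticDataset(
        table=table,
        config=config,
        person_b=b,
        person_intercepts=person_intercepts,
        person_slopes=person_slopes,
    )


def apply_missingness(
    dataset: SyntheticDataset,
    sleep_rate: float | None = None,
    affect_rate: float | None = None,
) -> SyntheticDataset:
    """Mask sleep nights and morning-affect reports completely at random.

    A masked sleep night blanks all stage minutes and tib; a masked affect
    report blanks the four morning scores jointly.  Seed-reproducible from
    the generator config.
    """
    cfg = dataset.config
    sleep_rate = cfg.missing_sleep_rate if sleep_rate is None else sleep_rate
    affect_rate = cfg.missing_affect_rate if affect_rate is None else affect_rate
    for r in (sleep_rate, affect_rate):
        if not 0.0 <= r <= 1.0:
            raise ValueError("missingness rates must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])
    table = dataset.table.copy()
    n = len(table)
    sleep_mask = rng.random(n) < sleep_rate
    affect_mask = rng.random(n) < affect_rate
    table.loc[sleep_mask, SLEEP_COLUMNS + ["tib_min"]] = np.nan
    table.loc[affect_mask, OUTCOME_COLUMNS] = np.nan
    return SyntheticDataset(
        table=table,
        config=cfg,
        person_b=dataset.person_b,
        person_intercepts=dataset.person_intercepts,
        person_slopes=dataset.person_slopes,
    )


def compute_icc(df: pd.DataFrame, variable: str) -> float:
    """Intraclass correlation (between-person variance / total variance).

    Method-of-moments one-way random-effects decomposition with the
    unbalanced-design correction for group sizes.  ``variable`` may be any
    column of the table, or ``ilr1``/``ilr2``/``ilr3`` for the nightly
    composition coordinates (computed on complete nights).
    """
    if variable.startswith("ilr") and variable not in df.columns:
        k = int(variable[3:]) - 1
        sub = df.dropna(subset=SLEEP_COLUMNS)[["id"] + SLEEP_COLUMNS]
        vals = ilr(sub[SLEEP_COLUMNS].to_numpy(float), ilr_basis(DEFAULT_SBP))[:, k]
        work = pd.DataFrame({"id": sub["id"].to_numpy(), "v": vals})
    else:
        work = df[["id", variable]].rename(columns={variable: "v"}).dropna()
    counts = work.groupby("id")["v"].count()
    counts = counts[counts >= 2]
    if len(counts) < 2:
        raise ValueError("ICC needs >= 2 persons with >= 2 records each")
    work = work[work["id"].isin(counts.index)]
    if work["v"].var() == 0:
        raise ValueError("ICC undefined: variable has zero variance")
    grand = work["v"].mean()
    g = len(counts)
    n_total = counts.sum()
    means = work.groupby("id")["v"].mean()
    ss_between = float((counts * (means - grand) ** 2).sum())
    ss_within = float(
        ((work["v"] - means.loc[work["id"]].to_numpy()) ** 2).sum()
    )
    ms_between = ss_between / (g - 1)
    ms_within = ss_within / (n_total - g)
    n0 = (n_total - (counts**2).sum() / n_total) / (g - 1)
    var_b = max((ms_between - ms_within) / n0, 0.0)
    return float(var_b / (var_b + ms_within))
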