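"""Posterior compositional substitution (time-reallocation) analysis.

For a reference sleep composition, reallocate t minutes from a donor stage
to a recipient stage (time in bed fixed), and contrast the model-expected
affect under the reallocated composition with that under the reference.
Because minutes map non-linearly into ilr coordinates, +t and -t
reallocations are not mirror images, so the grid runs in both directions.

Estimates are population-level (random effects at their zero mean):
* between level — the person-mean composition moves, daily deviation 0;
* within level  — the person mean stays at the reference and the day's
  deviation becomes ilr(reallocated) - ilr(reference).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import PARTS, SleepComposition, ilr
from .decompose import BETWEEN_COLUMNS, WITHIN_COLUMNS
from .model import PosteriorFit, posterior_expectation

logger = logging.getLogger(__name__)

__all__ = [
    "ReallocationSpec",
    "SubstitutionEstimate",
    "reallocate_minutes",
    "build_grid",
    "substitute",
    "summarize_draws",
    "standardize_difference",
    "estimates_to_frame",
]


@dataclass(frozen=True)
class ReallocationSpec:
    """One grid point: move ``minutes`` from donor stage to recipient stage.

    ``level`` is "between" or "within"; negative minutes encode the reverse
    direction (equivalent to swapping donor and recipient).
    """

    level: str
    donor: str
    recipient: str
    minutes: float

    def __post_init__(self) -> None:
        if self.level not in ("between", "within"):
            raise ValueError("level must be 'between' or 'within'")
        for stage in (self.donor, self.recipient):
            if stage not in PARTS:
                raise ValueError(f"unknown sleep stage {stage!r}")
        if self.donor == self.recipient:
            raise ValueError("donor and recipient must differ")


@dataclass
class SubstitutionEstimate:
    spec: ReallocationSpec
    mean_diff: float
    ci_low: float
    ci_high: float
    std_diff: float
    significant: bool


def reallocate_minutes(
    comp: SleepComposition, donor: str, recipient: str, minutes: float
) -> SleepComposition:
    """Move ``minutes`` from donor to recipient, all else unchanged exactly.

    Raises on an infeasible reallocation (donor — or, for negative minutes,
    recipient — would be exhausted).
    """
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    m = comp.minutes
    i, j = PARTS.index(donor), PARTS.index(recipient)
    m[i] -= minutes
    m[j] += minutes
    if m[i] <= 0 or m[j] <= 0:
        raise ValueError(
            f"infeasible reallocation: {minutes} min {donor}->{recipient} "
            f"exhausts a stage"
        )
    return SleepComposition.from_minutes(m, comp.tib_min)


def build_grid(
    level: str,
    max_minutes: int = 60,
    pairs: list[tuple[str, str]] | None = None,
) -> list[ReallocationSpec]:
    """All ordered stage pairs x 1..max_minutes in both directions."""
    if pairs is None:
        pairs = [(a, b) for a, b in itertools.permutations(PARTS, 2)]
    return [
        ReallocationSpec(level, a, b, float(t))
        for a, b in pairs
        for t in range(1, max_minutes + 1)
    ]


def summarize_draws(diff_draws: np.ndarray) -> tuple[float, float, float, bool]:
    """(mean, 2.5%, 97.5%, significant); significant iff the equal-tailed
    95% credible interval excludes zero."""
    d = np.asarray(diff_draws, float)
    if d.size < 100:
        raise ValueError("need >= 100 draws to summarise")
    lo, hi = np.percentile(d, [2.5, 97.5])
    sig = bool(lo > 0.0 or hi < 0.0)
    return float(d.mean()), float(lo), float(hi), sig


def standardize_difference(mean_diff: float, scale: float) -> float:
    """Unstandardised mean difference divided by an outcome SD."""
    if scale <= 0:
        raise ValueError("standardisation scale must be positive")
    return mean_diff / scale


def _design_row(
    fit: PosteriorFit, b: np.ndarray, w: np.ndarray, covariate_row: dict | None
) -> np.ndarray:
    """Design row at the covariate reference with given ilr coordinates.

    Centred numeric covariates default to 0 (the sample mean) and dummies to
    0 (the reference level); ``covariate_row`` overrides by column name.
    tib x ilr interaction columns are consistent products.
    """
    cols = fit.design.columns
    row = np.zeros(len(cols))
    values = dict(covariate_row or {})
    values["intercept"] = 1.0
    for k, name in enumerate(BETWEEN_COLUMNS):
        if name in cols:
            values[name] = b[k]
    for k, name in enumerate(WITHIN_COLUMNS):
        if name in cols:
            values[name] = w[k]
    for j, name in enumerate(cols):
        if ":" in name:
            left, right = name.split(":", 1)
            row[j] = values.get(left, 0.0) * values.get(right, 0.0)
        else:
            row[j] = values.get(name, 0.0)
    return row


def substitute(
    fit: PosteriorFit,
    reference: SleepComposition,
    grid: list[ReallocationSpec],
    basis: np.ndarray | None = None,
    covariate_row: dict | None = None,
    scale: float | None = None,
) -> list[SubstitutionEstimate]:
    """Substitution estimates for each feasible grid point.

    Per draw, the difference of posterior expected affect between the
    reallocated and the reference composition is computed through the fixed
    effects (population level); summaries are the posterior mean, the
    equal-tailed 95% CI, the CI-exclusion significance flag, and the mean
    standardised by ``scale`` (default: the observed outcome SD).

    Infeasible grid points (a stage exhausted) are skipped with a log
    entry, never clamped.
    """
    levels = {g.level for g in grid}
    if "between" in levels and not fit.spec.between_terms:
        raise ValueError("fit has no between-person ilr terms")
    if "within" in levels and not fit.spec.within_terms:
        raise ValueError("fit has no within-person ilr terms")
    if scale is None:
        scale = float(np.std(fit.design.y))
    z_ref = ilr(reference.proportions, basis)
    base_between = _design_row(fit, z_ref, np.zeros(3), covariate_row)
    base_within = base_between  # within level: w = 0 at the reference

    out: list[SubstitutionEstimate] = []
    for g in grid:
        try:
            realloc = reallocate_minutes(reference, g.donor, g.recipient, g.minutes)
        except ValueError:
            logger.info(
                "skipping infeasible grid point %s->%s %+g min",
                g.donor,
                g.recipient,
                g.minutes,
            )
            continue
        z_new = ilr(realloc.proportions, basis)
        if g.level == "between":
            row = _design_row(fit, z_new, np.zeros(3), covariate_row)
            base = base_between
        else:
            row = _design_row(fit, z_ref, z_new - z_ref, covariate_row)
            base = base_within
        diff = posterior_expectation(fit, row[None, :])[:, 0] - posterior_expectation(
            fit, base[None, :]
        )[:, 0]
        mean, lo, hi, sig = summarize_draws(diff)
        out.append(
            SubstitutionEstimate(
                spec=g,
                mean_diff=mean,
                ci_low=lo,
                ci_high=hi,
                std_diff=standardize_difference(mean, scale),
                significant=sig,
            )
        )
    return out


def estimates_to_frame(estimates: list[SubstitutionEstimate]) -> pd.DataFrame:
    """Machine-readable table: level, donor, recipient, minutes, mean,
    ci_low, ci_high, std, significant."""
    return pd.DataFrame(
        [
            {
                "level": e.spec.level,
                "donor": e.spec.donor,
                "recipient": e.spec.recipient,
                "minutes": e.spec.minutes,
                "mean": e.mean_diff,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "std": e.std_diff,
                "significant": e.significant,
            }
            for e in estimates
        ],
        columns=[
            "level",
            "donor",
            "recipient",
            "minutes",
            "mean",
            "ci_low",
            "ci_high",
            "std",
            "significant",
        ],
    )
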