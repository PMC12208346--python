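"""Between/within-person decomposition of nightly ilr coordinates.

Repeated nightly compositions contain two sources of variability: stable
differences between people and night-to-night deviations within a person.
Each night's ilr vector is split as ``z_ij = b_i + w_ij`` where ``b_i`` is
the ilr of person i's geometric-mean composition and ``w_ij`` the daily
deviation; both enter the affect models as separate predictors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .composition import (
    DEFAULT_SBP,
    PARTS,
    SleepComposition,
    close,
    geometric_mean,
    ilr,
    ilr_basis,
    ilr_inv,
    replace_zeros,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SLEEP_COLUMNS",
    "OUTCOME_COLUMNS",
    "REQUIRED_COLUMNS",
    "read_table",
    "decompose",
    "reference_composition",
    "BETWEEN_COLUMNS",
    "WITHIN_COLUMNS",
]

SLEEP_COLUMNS = ["twt_min", "light_min", "sws_min", "rem_min"]
OUTCOME_COLUMNS = ["hap", "lap", "hana", "lana"]
PRESLEEP_COLUMNS = [f"presleep_{o}" for o in OUTCOME_COLUMNS]
BASELINE_COLUMNS = ["age", "gender", "ethnicity", "sss", "bmi"]
DAILY_COLUMNS = ["weekend", "cpd"]
REQUIRED_COLUMNS = (
    ["id", "day"]
    + SLEEP_COLUMNS
    + ["tib_min"]
    + OUTCOME_COLUMNS
    + PRESLEEP_COLUMNS
    + DAILY_COLUMNS
    + BASELINE_COLUMNS
)

BETWEEN_COLUMNS = ["b1", "b2", "b3"]
WITHIN_COLUMNS = ["w1", "w2", "w3"]


def read_table(path) -> pd.DataFrame:
    """Read the long-format daily records CSV and validate its contract.

    Expected columns: id, day (1-based), nightly stage minutes and tib_min,
    the four morning-affect scores, matched previous-night pre-sleep affect,
    daily covariates (weekend 0/1, cpd) and baseline covariates.  Missing
    cells are empty.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table is missing columns: {missing}")
    if df.duplicated(["id", "day"]).any():
        raise ValueError("duplicate (id, day) records in input table")
    return df


def _complete_sleep_mask(df: pd.DataFrame) -> pd.Series:
    cols = SLEEP_COLUMNS + ["tib_min"]
    return df[cols].notna().all(axis=1)


def decompose(
    df: pd.DataFrame,
    basis: np.ndarray | None = None,
    zero_delta: float = 0.5,
) -> pd.DataFrame:
    """Attach between-person (b1..b3) and within-person (w1..w3) ilr columns.

    Nights with any missing sleep part are dropped (listwise at the night
    level); persons left with no complete nights are dropped with a logged
    warning.  Zeros in stage minutes are replaced multiplicatively with
    ``zero_delta`` minutes before transforming.  Within each person the
    arithmetic mean of w is zero and b + w reconstructs the night's ilr
    exactly.
    """
    if basis is None:
        basis = ilr_basis(DEFAULT_SBP)
    keep = _complete_sleep_mask(df)
    dropped_persons = sorted(
        set(df.loc[~keep, "id"]) - set(df.loc[keep, "id"])
    )
    if dropped_persons:
        logger.warning(
            "dropping %d person(s) with no complete sleep nights: %s",
            len(dropped_persons),
            dropped_persons,
        )
    out = df.loc[keep].copy()
    if out.empty:
        raise ValueError("no complete sleep nights in table")

    parts = out[SLEEP_COLUMNS].to_numpy(float)
    tib = out["tib_min"].to_numpy(float)
    for i in np.flatnonzero((parts == 0).any(axis=1)):
        parts[i] = replace_zeros(parts[i], tib[i], zero_delta)
    z = ilr(parts, basis)

    b = np.empty_like(z)
    for _, idx in out.groupby("id", sort=False).indices.items():
        b[idx] = ilr(geometric_mean(close(parts[idx])), basis)
    w = z - b

    out[BETWEEN_COLUMNS] = b
    out[WITHIN_COLUMNS] = w
    return out


def reference_composition(
    df: pd.DataFrame,
    basis: np.ndarray | None = None,
    weighting: str = "person",
    zero_delta: float = 0.5,
) -> SleepComposition:
    """Grand reference composition, scaled to the mean time in bed.

    ``weighting="person"`` (default) takes the closed geometric mean over
    persons of each person's geometric-mean composition, so every person
    counts once regardless of how many nights they contributed;
    ``"pooled"`` pools all nights.
    """
    if basis is None:
        basis = ilr_basis(DEFAULT_SBP)
    if weighting not in ("person", "pooled"):
        raise ValueError("weighting must be 'person' or 'pooled'")
    dec = df if set(BETWEEN_COLUMNS) <= set(df.columns) else decompose(
        df, basis, zero_delta
    )
    keep = _complete_sleep_mask(dec)
    dec = dec.loc[keep]
    tib_mean = float(dec["tib_min"].mean())
    if weighting == "person":
        person_b = dec.groupby("id", sort=False)[BETWEEN_COLUMNS].first().to_numpy()
        props = ilr_inv(person_b.mean(axis=0), basis)
    else:
        z = dec[BETWEEN_COLUMNS].to_numpy() + dec[WITHIN_COLUMNS].to_numpy()
        props = ilr_inv(z.mean(axis=0), basis)
    return SleepComposition.from_proportions(props, tib_mean)
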