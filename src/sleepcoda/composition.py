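"""Aitchison-geometry primitives for sleep-architecture compositions.

A night's sleep architecture is treated as a 4-part composition: total wake
time in bed (TWT), light sleep (NREM 1+2), slow-wave sleep (SWS) and REM
sleep, with time in bed (TIB) the closed total.  Compositions carry only
relative information; all modelling happens in isometric log-ratio (ilr)
coordinates built from a sequential binary partition (SBP).

Conventions
-----------
* Part order is fixed as ``(twt, light, sws, rem)`` everywhere.
* Internally compositions are proportions; the night total (minutes in bed)
  is carried separately and minutes are reconstructed on demand.
* The default SBP contrasts wake against sleep, then light against deep
  (SWS+REM), then SWS against REM.  Downstream estimates are SBP-invariant,
  so the choice is presentational and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PARTS",
    "DEFAULT_SBP",
    "SleepComposition",
    "close",
    "geometric_mean",
    "validate_sbp",
    "ilr_basis",
    "ilr",
    "ilr_inv",
    "replace_zeros",
]

#: canonical part order for 4-part sleep compositions
PARTS: tuple[str, ...] = ("twt", "light", "sws", "rem")

#: wake vs sleep, light vs deep, SWS vs REM
DEFAULT_SBP: np.ndarray = np.array(
    [
        [1, -1, -1, -1],
        [0, 1, -1, -1],
        [0, 0, 1, -1],
    ],
    dtype=float,
)


def close(parts: np.ndarray, total: float = 1.0) -> np.ndarray:
    """Rescale nonnegative parts to sum to ``total`` (closure operation).

    Works on a single composition or row-wise on an array of shape
    ``(..., D)``.  Raises ``ValueError`` on negative entries or an all-zero
    composition.
    """
    parts = np.asarray(parts, dtype=float)
    if np.any(parts < 0):
        raise ValueError("composition parts must be nonnegative")
    s = parts.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("degenerate composition: all parts are zero")
    return parts * (float(total) / s)


def geometric_mean(comps: np.ndarray) -> np.ndarray:
    """Closed per-part geometric mean of compositions (rows of ``comps``).

    This is the compositional centre: it equals ``ilr_inv(mean(ilr(x)))``
    for any ilr basis.  All parts must be strictly positive.
    """
    comps = np.asarray(comps, dtype=float)
    if comps.ndim == 1:
        comps = comps[None, :]
    if comps.shape[0] == 0:
        raise ValueError("need at least one composition")
    if np.any(comps <= 0):
        raise ValueError(
            "geometric mean requires strictly positive parts; "
            "call replace_zeros first"
        )
    return close(np.exp(np.log(comps).mean(axis=0)))


# ---------------------------------------------------------------------------
# sequential binary partitions and ilr bases
# ---------------------------------------------------------------------------

def validate_sbp(sbp: np.ndarray) -> np.ndarray:
    """Validate a sequential binary partition sign matrix.

    ``sbp`` is ``(D-1, D)`` with entries in {+1, -1, 0}.  Each row splits one
    group of parts into a positive and a negative subgroup; the supports must
    form a binary hierarchy that fully resolves the D parts.
    """
    sbp = np.asarray(sbp, dtype=float)
    if sbp.ndim != 2:
        raise ValueError("SBP must be a 2-D sign matrix")
    n_rows, d = sbp.shape
    if n_rows != d - 1:
        raise ValueError(f"SBP for {d} parts needs {d - 1} rows, got {n_rows}")
    if not np.isin(sbp, (-1.0, 0.0, 1.0)).all():
        raise ValueError("SBP entries must be in {+1, -1, 0}")
    supports = [frozenset(np.flatnonzero(row != 0)) for row in sbp]
    for i, row in enumerate(sbp):
        if not (row > 0).any() or not (row < 0).any():
            raise ValueError(f"SBP row {i} needs >=1 positive and >=1 negative part")
    if frozenset(range(d)) not in supports:
        raise ValueError("SBP has no root row splitting all parts")
    if len(set(supports)) != n_rows:
        raise ValueError("SBP rows must have distinct supports")
    # laminar family: supports nest or are disjoint, and a nested support
    # sits entirely on one side of the enclosing split
    for i, si in enumerate(supports):
        for j, sj in enumerate(supports):
            if i == j:
                continue
            inter = si & sj
            if inter and not (si <= sj or sj <= si):
                raise ValueError(f"SBP rows {i} and {j} overlap without nesting")
            if si < sj:
                sides = {int(np.sign(sbp[j, k])) for k in si}
                if len(sides) != 1:
                    raise ValueError(
                        f"SBP row {i} straddles both sides of row {j}"
                    )
    return sbp


def ilr_basis(sbp: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal ilr contrast matrix ``V`` of shape ``(D-1, D)`` from an SBP.

    Row k with r positive and s negative parts carries ``+sqrt(s/(r(r+s)))``
    on the positive parts and ``-sqrt(r/(s(r+s)))`` on the negative parts, so
    ``V @ V.T == I`` and each row sums to zero.
    """
    sbp = validate_sbp(DEFAULT_SBP if sbp is None else sbp)
    v = np.zeros_like(sbp)
    for k, row in enumerate(sbp):
        pos, neg = row > 0, row < 0
        r, s = pos.sum(), neg.sum()
        v[k, pos] = np.sqrt(s / (r * (r + s)))
        v[k, neg] = -np.sqrt(r / (s * (r + s)))
    return v


def ilr(parts: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Forward ilr transform: ``z = V @ ln(close(parts))``.

    Scale-invariant in the input total; accepts a single composition or rows.
    """
    if basis is None:
        basis = ilr_basis()
    parts = np.asarray(parts, dtype=float)
    if np.any(parts <= 0):
        raise ValueError("ilr requires strictly positive parts")
    return np.log(close(parts)) @ basis.T


def ilr_inv(z: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Inverse ilr transform back to proportions (closed to 1).

    Guarded against overflow for large-magnitude coordinates by subtracting
    the row maximum before exponentiating (log-sum-exp trick).
    """
    if basis is None:
        basis = ilr_basis()
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("ilr coordinates must be finite")
    logp = z @ basis
    logp = logp - logp.max(axis=-1, keepdims=True)
    return close(np.exp(logp))


def replace_zeros(parts: np.ndarray, total: float, delta: float = 0.5) -> np.ndarray:
    """Multiplicative zero replacement preserving the night total.

    Each zero part is set to ``delta`` (minutes); nonzero parts are scaled
    down proportionally so the parts still sum to ``total``.  Ratios between
    observed parts are preserved.
    """
    parts = np.asarray(parts, dtype=float)
    if total <= 0:
        raise ValueError("total must be positive")
    if np.any(parts < 0):
        raise ValueError("parts must be nonnegative")
    zero = parts == 0
    n_zero = int(zero.sum())
    if n_zero == 0:
        return parts.copy()
    if delta * n_zero >= total:
        raise ValueError(
            f"zero-replacement delta {delta} x {n_zero} zeros exceeds total {total}"
        )
    out = parts * (1.0 - delta * n_zero / total)
    out[zero] = delta
    return out


# ---------------------------------------------------------------------------
# the simplex object everything transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SleepComposition:
    """One night's minutes in (TWT, light, SWS, REM) plus time in bed.

    Parts must be nonnegative and sum to ``tib_min`` within 1e-6 minutes.
    Zeros are permitted at construction; transforms that need strict
    positivity direct the caller to :func:`replace_zeros`.
    """

    twt_min: float
    light_min: float
    sws_min: float
    rem_min: float
    tib_min: float

    def __post_init__(self) -> None:
        m = self.minutes
        if np.any(m < 0):
            raise ValueError("sleep stage minutes must be nonnegative")
        if self.tib_min <= 0:
            raise ValueError("time in bed must be positive")
        if abs(m.sum() - self.tib_min) > 1e-6:
            raise ValueError(
                f"stage minutes sum to {m.sum():.6f}, not tib {self.tib_min:.6f}"
            )

    @property
    def minutes(self) -> np.ndarray:
        return np.array(
            [self.twt_min, self.light_min, self.sws_min, self.rem_min], dtype=float
        )

    @property
    def proportions(self) -> np.ndarray:
        return close(self.minutes)

    @classmethod
    def from_minutes(cls, parts: np.ndarray, tib_min: float | None = None) -> "SleepComposition":
        parts = np.asarray(parts, dtype=float)
        if tib_min is None:
            tib_min = float(parts.sum())
        return cls(*parts, tib_min=tib_min)

    @classmethod
    def from_proportions(cls, props: np.ndarray, tib_min: float) -> "SleepComposition":
        return cls.from_minutes(close(props, tib_min), tib_min)

    def replace_zeros(self, delta: float = 0.5) -> "SleepComposition":
        return SleepComposition.from_minutes(
            replace_zeros(self.minutes, self.tib_min, delta), self.tib_min
        )

    def ilr(self, basis: np.ndarray | None = None) -> np.ndarray:
        return ilr(self.minutes, basis)
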