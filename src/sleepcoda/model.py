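"""Bayesian multilevel models of morning affect on sleep-composition coordinates.

Four nested model variants are considered per affect outcome:

* ``a`` — covariates only, random person intercept;
* ``b`` — a + between-person ilr coordinates (3 fixed effects);
* ``c`` — a + within-person ilr coordinates, with correlated random slopes
  on the three within coordinates;
* ``d`` — a + both between- and within-person coordinates, with the
  variant-c random structure.

Affect (1-5 scale) is modelled as Gaussian with identity link; effects are
additive point differences on the outcome scale.  Priors are weakly
informative and scale-adapted: coefficient j gets Normal(0, c*sd(y)/sd(x_j)),
the intercept Normal(median(y), c*sd(y)), and all SDs half-t(3) scaled by
sd(y), with the random-effect covariance under the Huang-Wand hierarchical
inverse-Wishart (see :mod:`sleepcoda.sampler`).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd

from .decompose import BETWEEN_COLUMNS, OUTCOME_COLUMNS, WITHIN_COLUMNS
from .sampler import LmmPrior, gibbs_lmm

logger = logging.getLogger(__name__)

__all__ = [
    "PriorSpec",
    "McmcSpec",
    "ModelSpec",
    "Design",
    "PosteriorFit",
    "build_design",
    "fit",
    "posterior_expectation",
    "pointwise_log_likelihood",
    "bayes_r2",
]

DEFAULT_COVARIATES = [
    "tib_min",
    "presleep",
    "weekend",
    "cpd",
    "age",
    "gender",
    "ethnicity",
    "sss",
    "bmi",
]

RHAT_LIMIT = 1.05
ESS_LIMIT = 400.0


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative prior configuration (all scales > 0)."""

    coef_scale: float = 5.0
    intercept_scale: float = 5.0
    sd_scale: float = 2.5
    nu: float = 3.0

    def __post_init__(self) -> None:
        if min(self.coef_scale, self.intercept_scale, self.sd_scale) <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class McmcSpec:
    """Sampler settings. Paper-scale runs (8 chains x 5000 kept draws) are
    available by overriding the desk defaults of 4 x (500 + 500)."""

    chains: int = 4
    warmup: int = 500
    samples: int = 500
    seed: int = 0

    @property
    def total_draws(self) -> int:
        return self.chains * self.samples


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    variant: str = "d"
    include_tib_interaction: bool = False
    covariates: tuple[str, ...] = tuple(DEFAULT_COVARIATES)
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSpec = field(default_factory=McmcSpec)

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"outcome must be one of {OUTCOME_COLUMNS}")
        if self.variant not in "abcd":
            raise ValueError("variant must be one of a, b, c, d")

    @property
    def between_terms(self) -> list[str]:
        return BETWEEN_COLUMNS if self.variant in ("b", "d") else []

    @property
    def within_terms(self) -> list[str]:
        return WITHIN_COLUMNS if self.variant in ("c", "d") else []


@dataclass
class Design:
    """Resolved design: fixed-effect matrix, random structure, outcome."""

    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    Zrows: np.ndarray
    z_columns: list[str]
    group_idx: np.ndarray
    group_ids: np.ndarray
    centers: dict[str, float]
    row_index: np.ndarray  # original dataframe index of retained rows

    @property
    def n(self) -> int:
        return self.y.size

    def column(self, name: str) -> int:
        return self.columns.index(name)


def _is_numeric(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s)


def build_design(df: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build fixed-effects matrix, random structure and outcome vector.

    Rows with a missing outcome or any missing covariate are dropped
    (complete-case, per outcome).  Numeric covariates are mean-centred;
    categorical covariates enter as dummies against the most frequent level.
    Rows are sorted by person for the sampler.
    """
    needed = set(BETWEEN_COLUMNS) | set(WITHIN_COLUMNS)
    if not needed <= set(df.columns):
        raise ValueError("dataframe lacks ilr columns; run decompose first")

    covs = [
        f"presleep_{spec.outcome}" if c == "presleep" else c
        for c in spec.covariates
    ]
    for c in covs + [spec.outcome]:
        if c not in df.columns:
            raise ValueError(f"missing column in data: {c}")

    work = df.dropna(subset=[spec.outcome] + covs).copy()
    if work.empty:
        raise ValueError(f"no complete cases for outcome {spec.outcome}")
    work = work.sort_values(["id", "day"], kind="stable")

    ilr_cols = list(spec.between_terms) + list(spec.within_terms)
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(work))}
    centers: dict[str, float] = {}
    for c in ilr_cols:
        cols[c] = work[c].to_numpy(float)
    for c in covs:
        s = work[c]
        if _is_numeric(s):
            center = float(s.mean())
            centers[c] = center
            cols[c] = s.to_numpy(float) - center
        else:
            levels = s.value_counts()
            ref = levels.index[0]
            for lev in levels.index[1:]:
                cols[f"{c}[{lev}]"] = (s == lev).to_numpy(float)
    if spec.include_tib_interaction:
        if "tib_min" not in centers:
            raise ValueError("tib interaction requires tib_min covariate")
        tib_c = cols["tib_min"]
        for c in ilr_cols:
            cols[f"tib_min:{c}"] = tib_c * cols[c]

    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    for j, name in enumerate(names):
        if name != "intercept" and np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant design column: {name}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")

    z_cols = ["intercept"] + list(spec.within_terms)
    Zrows = np.column_stack([cols[c] for c in z_cols])

    ids, group_idx = np.unique(work["id"].to_numpy(), return_inverse=True)
    return Design(
        X=X,
        columns=names,
        y=work[spec.outcome].to_numpy(float),
        Zrows=Zrows,
        z_columns=z_cols,
        group_idx=group_idx,
        group_ids=ids,
        centers=centers,
        row_index=work.index.to_numpy(),
    )


@dataclass
class PosteriorFit:
    """Posterior draws, diagnostics and pointwise log-likelihood inputs."""

    spec: ModelSpec
    design: Design
    draws: dict[str, np.ndarray]  # chain-shaped arrays from the sampler
    diagnostics: dict[str, float]
    converged: bool
    data_hash: str

    # -- flattened (chains merged) views --------------------------------
    @property
    def beta(self) -> np.ndarray:
        d = self.draws["beta"]
        return d.reshape(-1, d.shape[-1])

    @property
    def u(self) -> np.ndarray:
        d = self.draws["u"]
        return d.reshape(-1, *d.shape[-2:])

    @property
    def Sigma_u(self) -> np.ndarray:
        d = self.draws["Sigma_u"]
        return d.reshape(-1, *d.shape[-2:])

    @property
    def sigma2(self) -> np.ndarray:
        return self.draws["sigma2"].reshape(-1)

    @property
    def n_draws(self) -> int:
        return self.sigma2.size

    def coef(self, name: str) -> np.ndarray:
        return self.beta[:, self.design.column(name)]

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "spec": {
                "outcome": self.spec.outcome,
                "variant": self.spec.variant,
                "include_tib_interaction": self.spec.include_tib_interaction,
                "covariates": list(self.spec.covariates),
                "mcmc": vars(self.spec.mcmc).copy(),
            },
            "columns": self.design.columns,
            "z_columns": self.design.z_columns,
            "centers": self.design.centers,
            "diagnostics": self.diagnostics,
            "converged": self.converged,
            "data_hash": self.data_hash,
        }
        np.savez_compressed(
            path,
            meta=json.dumps(meta),
            X=self.design.X,
            y=self.design.y,
            Zrows=self.design.Zrows,
            group_idx=self.design.group_idx,
            group_ids=self.design.group_ids.astype(str),
            row_index=self.design.row_index,
            **self.draws,
        )

    @classmethod
    def load(cls, path) -> "PosteriorFit":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            spec = ModelSpec(
                outcome=meta["spec"]["outcome"],
                variant=meta["spec"]["variant"],
                include_tib_interaction=meta["spec"]["include_tib_interaction"],
                covariates=tuple(meta["spec"]["covariates"]),
                mcmc=McmcSpec(**meta["spec"]["mcmc"]),
            )
            design = Design(
                X=z["X"],
                columns=meta["columns"],
                y=z["y"],
                Zrows=z["Zrows"],
                z_columns=meta["z_columns"],
                group_idx=z["group_idx"],
                group_ids=z["group_ids"],
                centers=meta["centers"],
                row_index=z["row_index"],
            )
            draws = {k: z[k] for k in ("beta", "u", "Sigma_u", "sigma2")}
        return cls(
            spec=spec,
            design=design,
            draws=draws,
            diagnostics=meta["diagnostics"],
            converged=meta["converged"],
            data_hash=meta["data_hash"],
        )


def _resolve_prior(design: Design, priors: PriorSpec) -> LmmPrior:
    y = design.y
    sd_y = float(np.std(y)) or 1.0
    p = len(design.columns)
    beta_mean = np.zeros(p)
    beta_sd = np.empty(p)
    for j, name in enumerate(design.columns):
        if name == "intercept":
            beta_mean[j] = float(np.median(y))
            beta_sd[j] = priors.intercept_scale * sd_y
        else:
            sd_x = float(np.std(design.X[:, j]))
            beta_sd[j] = priors.coef_scale * sd_y / sd_x
    q = design.Zrows.shape[1]
    return LmmPrior(
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        ranef_scale=np.full(q, priors.sd_scale * sd_y),
        resid_scale=priors.sd_scale * sd_y,
        nu=priors.nu,
    )


def _diagnostics(draws: dict[str, np.ndarray], columns: list[str]) -> dict[str, float]:
    beta = draws["beta"]
    sds = np.sqrt(np.einsum("csii->csi", draws["Sigma_u"]))
    ds = az.convert_to_dataset(
        {"beta": beta, "ranef_sd": sds, "sigma2": draws["sigma2"][..., None]}
    )
    rhat = az.rhat(ds)
    ess = az.ess(ds)
    max_rhat = float(
        max(np.nanmax(rhat[v].values) for v in ("beta", "ranef_sd", "sigma2"))
    )
    min_ess = float(
        min(np.nanmin(ess[v].values) for v in ("beta", "ranef_sd", "sigma2"))
    )
    return {"max_rhat": max_rhat, "min_ess": min_ess}


def fit(spec: ModelSpec, df: pd.DataFrame) -> PosteriorFit:
    """Fit one model variant by blocked Gibbs sampling.

    Seed-reproducible: identical spec + data + seed give identical draws.
    Non-convergence (R-hat >= 1.05 or ESS <= 400) never raises — the fit is
    returned with ``converged=False`` and a logged warning.
    """
    design = build_design(df, spec)
    prior = _resolve_prior(design, spec.priors)
    draws = gibbs_lmm(
        design.X,
        design.y,
        design.Zrows,
        design.group_idx,
        prior,
        chains=spec.mcmc.chains,
        warmup=spec.mcmc.warmup,
        samples=spec.mcmc.samples,
        seed=spec.mcmc.seed,
    )
    diag = _diagnostics(draws, design.columns)
    converged = diag["max_rhat"] < RHAT_LIMIT and diag["min_ess"] > ESS_LIMIT
    if not converged:
        logger.warning(
            "fit(%s, variant %s) not converged: max R-hat %.3f, min ESS %.0f",
            spec.outcome,
            spec.variant,
            diag["max_rhat"],
            diag["min_ess"],
        )
    h = hashlib.sha256()
    h.update(design.X.tobytes())
    h.update(design.y.tobytes())
    return PosteriorFit(
        spec=spec,
        design=design,
        draws=draws,
        diagnostics=diag,
        converged=converged,
        data_hash=h.hexdigest()[:16],
    )


def posterior_expectation(
    fit: PosteriorFit,
    newX: np.ndarray | pd.DataFrame,
    include_person_effects: bool = False,
    person_idx: np.ndarray | None = None,
    Znew: np.ndarray | None = None,
) -> np.ndarray:
    """Per-draw linear predictor on new design rows, shape (S, M).

    Population-level by default (random effects at their zero mean); with
    ``include_person_effects`` the rows' known persons' effects are added.
    """
    if isinstance(newX, pd.DataFrame):
        unknown = [c for c in newX.columns if c not in fit.design.columns]
        if unknown:
            raise ValueError(f"unknown design columns: {unknown}")
        full = pd.DataFrame(
            0.0, index=newX.index, columns=fit.design.columns
        )
        full[list(newX.columns)] = newX
        newX = full.to_numpy(float)
    newX = np.atleast_2d(np.asarray(newX, float))
    if newX.shape[1] != len(fit.design.columns):
        raise ValueError("newdata columns do not match the fitted design")
    mu = fit.beta @ newX.T
    if include_person_effects:
        if person_idx is None:
            raise ValueError("person_idx required to include person effects")
        if Znew is None:
            Znew = np.column_stack(
                [newX[:, fit.design.column(c)] if c != "intercept" else np.ones(len(newX))
                 for c in fit.design.z_columns]
            )
        mu = mu + np.einsum("smq,mq->sm", fit.u[:, person_idx, :], Znew)
    return mu


def pointwise_log_likelihood(fit: PosteriorFit) -> np.ndarray:
    """Gaussian log density of each observation under each draw, (S, N).

    Person effects are included, matching the fitted (conditional)
    likelihood.
    """
    d = fit.design
    mu = fit.beta @ d.X.T
    mu += np.einsum("snq,nq->sn", fit.u[:, d.group_idx, :], d.Zrows)
    s2 = fit.sigma2[:, None]
    return -0.5 * (np.log(2.0 * np.pi * s2) + (d.y[None, :] - mu) ** 2 / s2)


def bayes_r2(fit: PosteriorFit, kind: str = "marginal") -> dict[str, float]:
    """Bayesian R^2: per draw, var(predicted) / (var(predicted) + sigma^2).

    ``marginal`` uses fixed-effects-only predictions; ``conditional`` adds
    person effects.  Returns posterior mean and equal-tailed 95% CI.
    """
    if kind not in ("marginal", "conditional"):
        raise ValueError("kind must be 'marginal' or 'conditional'")
    d = fit.design
    mu = fit.beta @ d.X.T
    if kind == "conditional":
        mu = mu + np.einsum("snq,nq->sn", fit.u[:, d.group_idx, :], d.Zrows)
    var_pred = mu.var(axis=1)
    r2 = var_pred / (var_pred + fit.sigma2)
    lo, hi = np.percentile(r2, [2.5, 97.5])
    return {"mean": float(r2.mean()), "ci_low": float(lo), "ci_high": float(hi)}
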