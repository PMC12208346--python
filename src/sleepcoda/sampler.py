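"""Blocked Gibbs sampler for the Gaussian multilevel (mixed-effects) model.

The likelihood is

    y_ij = x_ij' beta + z_ij' u_i + e_ij,   e_ij ~ N(0, sigma^2),
    u_i ~ N(0, Sigma_u),

with person i contributing n_i nights.  Two standard devices keep the chain
well mixed where naive (centred) Gibbs is known to stall:

* the fixed effects beta are drawn from their partially collapsed
  conditional with the random effects integrated out (Woodbury identities
  per person), which decouples person-level covariates from the person
  intercepts;
* the random effects are fully non-centred and parameter-expanded:
  u_i = diag(xi) L eta_i with eta_i ~ N(0, I), L an unconstrained
  lower-triangular factor and xi a redundant row-scale vector
  (Sigma_u = diag(xi) L L' diag(xi)).  Given eta the likelihood is linear
  in the entries of L and in xi, so both have conjugate normal
  conditionals: the L entries move freely when a variance component is
  near zero (where sampling Sigma_u directly gets trapped), and the xi
  draw moves well-identified scales in one likelihood-informed step
  (where a pure non-centred chain crawls).  A Metropolis move on the row
  scales of L against the random-effects-marginalised likelihood
  (adaptive log-scale random walk) completes the scheme, giving
  full-posterior-width scale moves in both regimes.

Priors: independent normals on beta, on the entries of L and on xi
(heavy-tailed half-normal-product marginals on the random-effect SDs,
induced near-uniform correlations) and a half-t on the residual SD via
inverse-gamma parameter expansion.
Everything is vectorised over persons; a chain of a few thousand iterations
on ~1000 observations runs in a couple of seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LmmPrior", "gibbs_lmm"]


@dataclass
class LmmPrior:
    """Resolved (numeric) prior for one model fit.

    beta_mean/beta_sd are per-column normal priors on the fixed effects;
    ranef_scale is the normal scale per random-effect SD (applied to the
    Cholesky-factor entries); resid_scale the half-t scale for the residual
    SD; nu the half-t degrees of freedom.
    """

    beta_mean: np.ndarray
    beta_sd: np.ndarray
    ranef_scale: np.ndarray
    resid_scale: float
    nu: float = 3.0


def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape, 1.0)


def _mvn_from_precision(
    rng: np.random.Generator, Q: np.ndarray, rhs: np.ndarray
) -> np.ndarray:
    """One draw from N(Q^{-1} rhs, Q^{-1})."""
    L = np.linalg.cholesky(Q)
    mean = np.linalg.solve(Q, rhs)
    return mean + np.linalg.solve(L.T, rng.standard_normal(len(rhs)))


def _marginal_loglik(
    S_u: np.ndarray,
    sigma2: float,
    ZtZ: np.ndarray,
    Ztr: np.ndarray,
    rtr: float,
    n: int,
) -> float:
    """Log p(y | beta, Sigma_u, sigma2) with the random effects integrated
    out, up to a beta-free constant; per-person Woodbury/determinant
    identities on the q x q blocks."""
    A = np.eye(S_u.shape[0]) + ZtZ @ S_u / sigma2
    _, logdet = np.linalg.slogdet(A)
    M = S_u @ np.linalg.inv(A)
    quad = np.einsum("gq,gqr,gr->", Ztr, 0.5 * (M + np.transpose(M, (0, 2, 1))), Ztr)
    return -0.5 * (n * np.log(sigma2) + logdet.sum() + rtr / sigma2 - quad / sigma2**2)


def gibbs_lmm(
    X: np.ndarray,
    y: np.ndarray,
    Zrows: np.ndarray,
    group_idx: np.ndarray,
    prior: LmmPrior,
    chains: int = 4,
    warmup: int = 500,
    samples: int = 500,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Run the Gibbs sampler; returns draws keyed by parameter.

    Rows must be sorted by ``group_idx`` (contiguous groups).  Returns
    arrays with leading (chain, draw) axes: ``beta`` (C,S,p), ``u`` (C,S,G,q),
    ``Sigma_u`` (C,S,q,q), ``sigma2`` (C,S).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    Zrows = np.asarray(Zrows, float)
    group_idx = np.asarray(group_idx)
    n, p = X.shape
    q = Zrows.shape[1]
    if np.any(np.diff(group_idx) < 0):
        raise ValueError("rows must be sorted by group index")
    groups = np.unique(group_idx)
    G = groups.size
    starts = np.searchsorted(group_idx, groups)

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    ZtZ = np.add.reduceat(
        np.einsum("ni,nj->nij", Zrows, Zrows).reshape(n, q * q), starts, axis=0
    ).reshape(G, q, q)
    ZtX = np.stack(
        [np.add.reduceat(Zrows[:, k, None] * X, starts, axis=0) for k in range(q)],
        axis=1,
    )  # (G, q, p)
    Zty = np.add.reduceat(Zrows * y[:, None], starts, axis=0)  # (G, q)
    eye_q = np.eye(q)

    # lower-triangular index pairs (j, k), k <= j, for the factor L
    tri_j, tri_k = np.tril_indices(q)
    n_tri = tri_j.size

    prior_prec = 1.0 / prior.beta_sd**2
    prior_mp = prior.beta_mean * prior_prec
    lam_prec = 1.0 / prior.ranef_scale[tri_j] ** 2  # row j's scale for row j's entries
    nu = prior.nu

    out = {
        "beta": np.empty((chains, samples, p)),
        "u": np.empty((chains, samples, G, q)),
        "Sigma_u": np.empty((chains, samples, q, q)),
        "sigma2": np.empty((chains, samples)),
    }

    for c, ss in enumerate(np.random.SeedSequence(seed).spawn(chains)):
        rng = np.random.default_rng(ss)
        Lfac = np.zeros((q, q))
        Lfac[np.diag_indices(q)] = 0.3 * (1.0 + 0.3 * rng.standard_normal(q))
        xi = np.ones(q) + 0.1 * rng.standard_normal(q)
        eta = rng.standard_normal((G, q))
        sigma2 = max(float(np.var(y)), 1e-6) / 2.0
        a_s = 1.0
        mh_step = 0.25  # log-scale proposal sd, adapted during warmup
        mh_accepts = 0

        for it in range(warmup + samples):
            # --- fixed effects, random effects integrated out ------------
            # V_i^{-1} = I/s2 - Z_i M_i Z_i'/s2^2 with M_i = S (I + B_i S)^{-1},
            # S = D L L' D the random-effect covariance and B_i = Z'Z_i / s2
            DL = xi[:, None] * Lfac
            S_u = DL @ DL.T
            M = S_u @ np.linalg.inv(eye_q + ZtZ @ S_u / sigma2)
            M = 0.5 * (M + np.transpose(M, (0, 2, 1)))
            xvx = XtX / sigma2 - np.einsum("gqp,gqr,grs->ps", ZtX, M, ZtX) / sigma2**2
            xvy = Xty / sigma2 - np.einsum("gqp,gqr,gr->p", ZtX, M, Zty) / sigma2**2
            beta = _mvn_from_precision(
                rng, 0.5 * (xvx + xvx.T) + np.diag(prior_prec), xvy + prior_mp
            )

            # --- row scales of L: marginal Metropolis (eta integrated out)
            Ztr = Zty - ZtX @ beta  # (G, q): Z_i' (y_i - X_i beta)
            rtr = yty - 2.0 * beta @ Xty + beta @ XtX @ beta
            step = mh_step * rng.standard_normal(q)
            L_prop = np.exp(step)[:, None] * Lfac
            DL_prop = xi[:, None] * L_prop
            cur = _marginal_loglik(S_u, sigma2, ZtZ, Ztr, rtr, n)
            prop = _marginal_loglik(DL_prop @ DL_prop.T, sigma2, ZtZ, Ztr, rtr, n)
            # normal prior on the entries of L plus the row-scaling Jacobian
            d_prior = -0.5 * np.sum(
                lam_prec * (L_prop[tri_j, tri_k] ** 2 - Lfac[tri_j, tri_k] ** 2)
            )
            jac = float(step @ (np.arange(q) + 1.0))
            if np.log(rng.random()) < prop - cur + d_prior + jac:
                Lfac = L_prop
                DL = DL_prop
                mh_accepts += 1
            if it < warmup and (it + 1) % 50 == 0:
                rate = mh_accepts / 50.0
                mh_step = float(np.clip(mh_step * np.exp(rate - 0.3), 0.01, 2.0))
                mh_accepts = 0

            # --- person effects (non-centred, standard-normal prior) -----
            Qi = np.einsum("jl,glm,mk->gjk", DL.T, ZtZ, DL) / sigma2 + eye_q
            Li = np.linalg.cholesky(Qi)
            mi = np.linalg.solve(Qi, (Ztr @ DL / sigma2)[..., None])[..., 0]
            noise = np.linalg.solve(
                np.transpose(Li, (0, 2, 1)), rng.standard_normal((G, q))[..., None]
            )[..., 0]
            eta = mi + noise

            # --- covariance factor: y - X beta is linear in L given eta --
            # feature for entry L[j, k] on row n is xi_j Z[n, j] * eta[g(n), k]
            ZtZ_s = (xi[:, None] * ZtZ) * xi[None, :]
            gram = np.einsum("gjJ,gk,gK->jkJK", ZtZ_s, eta, eta)
            FtF = gram[tri_j[:, None], tri_k[:, None], tri_j[None, :], tri_k[None, :]]
            Ftr = np.einsum("gj,gk->jk", xi[None, :] * Ztr, eta)[tri_j, tri_k]
            lam = _mvn_from_precision(
                rng, FtF / sigma2 + np.diag(lam_prec), Ftr / sigma2
            )
            Lfac = np.zeros((q, q))
            Lfac[tri_j, tri_k] = lam

            # --- redundant row scales: also linear in xi given (L, eta) --
            # feature for xi_k on row n is Z[n, k] * (L eta_g)_k
            v = eta @ Lfac.T  # (G, q)
            WtW = np.einsum("gkl,gk,gl->kl", ZtZ, v, v)
            Wtr = np.einsum("gk,gk->k", Ztr, v)
            xi = _mvn_from_precision(rng, WtW / sigma2 + eye_q, Wtr / sigma2)

            # --- residual variance (half-t via parameter expansion) ------
            u = v * xi
            resid = y - X @ beta - np.einsum("nq,nq->n", Zrows, u[group_idx])
            sigma2 = _inv_gamma(rng, (nu + n) / 2.0, nu / a_s + 0.5 * resid @ resid)
            a_s = _inv_gamma(
                rng, (nu + 1) / 2.0, nu / sigma2 + prior.resid_scale**-2.0
            )

            if it >= warmup:
                s = it - warmup
                DL_now = xi[:, None] * Lfac
                out["beta"][c, s] = beta
                out["u"][c, s] = u
                out["Sigma_u"][c, s] = DL_now @ DL_now.T
                out["sigma2"][c, s] = sigma2

    return out
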