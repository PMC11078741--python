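"""Batched IRLS fits for many small GLMs sharing one design matrix.

Thousands of genes (negative binomial) or SNPs (logistic) are fit against
the same few-column design, so the per-fit overhead of a generic GLM
implementation dominates runtime. These routines vectorize the IRLS
iterations across the batch dimension; correctness is cross-checked
against statsmodels in the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln

_ETA_MAX = 30.0  # caps exp(eta); beyond this the likelihood is flat anyway


def nb_irls(Y, X, offset, alpha, ridge=0.01, max_iter=60, tol=1e-8):
    """Fit negative-binomial log-linear models, one per row of ``Y``.

    var(y) = mu + alpha * mu^2 with ``alpha`` fixed per gene (``alpha`` may
    be a scalar or a length-G vector; 0 gives Poisson). ``offset`` is added
    to the linear predictor (log effective library size). A small ridge
    penalty on all non-intercept coefficients keeps estimates finite when
    an arm is all-zero. Returns (beta (G,p), mu (G,n), converged (G,)).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (G,)).copy()
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (n,))

    pen = np.full(p, ridge)
    if np.ptp(X[:, 0]) == 0:  # leave the intercept unpenalized
        pen[0] = 0.0
    pen_mat = np.diag(pen)

    mu = 0.5 * (Y + Y.mean(axis=1, keepdims=True)) + 0.1
    eta = np.log(mu)
    beta = np.zeros((G, p))
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        W = mu / (1.0 + alpha[:, None] * mu)          # IRLS weights
        z = (eta - offset) + (Y - mu) / mu            # working response
        XtWX = np.einsum("ni,gn,nj->gij", X, W, X) + pen_mat
        XtWz = np.einsum("ni,gn->gi", X, W * z)
        beta_new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        step = np.abs(beta_new - beta).max(axis=1)
        beta = beta_new
        eta = np.clip(beta @ X.T + offset, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        converged = step < tol
        if converged.all():
            break
    return beta, mu, converged


def nb_loglik(Y, mu, alpha):
    """Row-wise NB log-likelihood; alpha -> 0 falls back to Poisson."""
    Y = np.asarray(Y, dtype=float)
    G = Y.shape[0]
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), (G,))
    mu = np.maximum(mu, 1e-12)
    out = np.empty(G)
    pois = alpha < 1e-8
    if pois.any():
        m = mu[pois]
        y = Y[pois]
        out[pois] = (y * np.log(m) - m - gammaln(y + 1)).sum(axis=1)
    nb = ~pois
    if nb.any():
        a = alpha[nb][:, None]
        m = mu[nb]
        y = Y[nb]
        r = 1.0 / a
        ll = (
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + y * np.log(a * m / (1.0 + a * m))
            - r * np.log1p(a * m)
        )
        out[nb] = ll.sum(axis=1)
    return out


def moment_dispersion(Y, mu, n_params):
    """Method-of-moments NB dispersion per gene, df-corrected."""
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[1]
    corr = n / max(n - n_params, 1)
    num = (corr * (Y - mu) ** 2 - mu).sum(axis=1)
    den = (mu**2).sum(axis=1)
    return np.clip(num / np.maximum(den, 1e-12), 1e-6, 10.0)


def logistic_batch(d, C, y, max_iter=30, tol=1e-8):
    """Fit logit(y) ~ C + d_s for each dosage column s simultaneously.

    ``d``: (S, n) per-SNP predictors; ``C``: (n, c) shared covariates
    (including intercept); ``y``: (n,) binary outcome. Returns a dict with
    beta/se/p for the per-SNP coefficient plus separation flags. Wald test.
    """
    d = np.asarray(d, dtype=float)
    C = np.asarray(C, dtype=float)
    y = np.asarray(y, dtype=float)
    S, n = d.shape
    c = C.shape[1]
    p = c + 1
    beta = np.zeros((S, p))
    # warm start: fit covariate-only model once, shared by all SNPs
    b0 = _logistic_single(C, y)
    beta[:, :c] = b0

    Xc = C  # shared block
    ok = np.ones(S, dtype=bool)
    for _ in range(max_iter):
        eta = beta[:, :c] @ Xc.T + beta[:, c:] * d  # (S,n)
        eta = np.clip(eta, -_ETA_MAX, _ETA_MAX)
        muv = expit(eta)
        W = muv * (1.0 - muv)
        resid = y[None, :] - muv
        # gradient blocks
        g_c = resid @ Xc                              # (S,c)
        g_d = (resid * d).sum(axis=1, keepdims=True)  # (S,1)
        grad = np.concatenate([g_c, g_d], axis=1)
        # Hessian blocks
        H_cc = np.einsum("ni,sn,nj->sij", Xc, W, Xc)
        H_cd = np.einsum("ni,sn->si", Xc, W * d)[:, :, None]
        H_dd = (W * d * d).sum(axis=1)[:, None, None]
        H = np.concatenate(
            [
                np.concatenate([H_cc, H_cd], axis=2),
                np.concatenate([np.swapaxes(H_cd, 1, 2), H_dd], axis=2),
            ],
            axis=1,
        )
        H += 1e-10 * np.eye(p)
        try:
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(
                H.reshape(-1, p), grad.reshape(-1, 1), rcond=None
            )[0].reshape(S, p)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    eta = np.clip(beta[:, :c] @ Xc.T + beta[:, c:] * d, -_ETA_MAX, _ETA_MAX)
    muv = expit(eta)
    W = muv * (1.0 - muv)
    H_cc = np.einsum("ni,sn,nj->sij", Xc, W, Xc)
    H_cd = np.einsum("ni,sn->si", Xc, W * d)[:, :, None]
    H_dd = (W * d * d).sum(axis=1)[:, None, None]
    H = np.concatenate(
        [
            np.concatenate([H_cc, H_cd], axis=2),
            np.concatenate([np.swapaxes(H_cd, 1, 2), H_dd], axis=2),
        ],
        axis=1,
    ) + 1e-10 * np.eye(p)
    cov = np.linalg.inv(H)
    se = np.sqrt(np.maximum(cov[:, c, c], 0.0))
    b = beta[:, c]
    separated = (np.abs(b) > 15) | ~np.isfinite(b) | ~np.isfinite(se) | (se > 100)
    ok &= ~separated
    from scipy.stats import norm

    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, b / se, 0.0)
    pvals = 2.0 * norm.sf(np.abs(zstat))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    pvals[separated] = 1.0
    return {"beta": b, "se": se, "p": pvals, "separated": separated}


def _logistic_single(X, y, max_iter=50, tol=1e-10):
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)
        muv = expit(eta)
        W = muv * (1 - muv)
        H = X.T @ (W[:, None] * X) + 1e-10 * np.eye(X.shape[1])
        g = X.T @ (y - muv)
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    return beta
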