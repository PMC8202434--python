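"""Batched negative-binomial GLM fitting (log link, known dispersion).

All genes share one design matrix, so iteratively reweighted least squares
can be vectorized across the whole matrix: each IRLS step solves one small
(p x p) weighted normal system per gene via a batched ``numpy.linalg.solve``.
Dispersion alpha (Var = mu + alpha * mu^2) is supplied per gene and held
fixed during the fit, as is a per-sample offset (log size factor).

Convergence is declared when a gene's deviance changes by less than ``tol``
relative to its magnitude; genes that never converge within ``max_iter``
iterations are flagged rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

ETA_CLIP = 30.0


@dataclass
class NBFit:
    """Result of a batched fit: arrays indexed by gene along axis 0."""

    coef: np.ndarray  # (G, p)
    cov: np.ndarray  # (G, p, p) inverse expected information
    deviance: np.ndarray  # (G,)
    converged: np.ndarray  # (G,) bool
    mu: np.ndarray  # (G, n) fitted means


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB deviance; Poisson limit used when alpha is tiny.

    Stable for integer counts: the gamma-function terms of the likelihood
    cancel between the saturated and fitted model, so no gammaln is needed.
    """
    y = np.asarray(y, float)
    mu = np.maximum(mu, 1e-300)
    alpha = np.asarray(alpha, float).reshape(-1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    poisson = 2.0 * (term1 - (y - mu))
    r = 1.0 / np.maximum(alpha, 1e-300)
    term2 = (y + r) * np.log((y + r) / (mu + r))
    nb = 2.0 * (term1 - term2)
    use_poisson = np.broadcast_to(alpha < 1e-6, y.shape)
    return np.where(use_poisson, poisson, nb).sum(axis=1)


def fit_nb_glm(
    y: np.ndarray,
    X: np.ndarray,
    alpha: np.ndarray,
    offset: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> NBFit:
    """Fit one NB log-link GLM per row of ``y`` against the shared design X.

    Parameters
    ----------
    y : (G, n) counts; X : (n, p) full-rank design; alpha : scalar or (G,)
    dispersions; offset : (n,) added to the linear predictor (log size
    factors), default zero.
    """
    y = np.asarray(y, float)
    G, n = y.shape
    X = np.asarray(X, float)
    p = X.shape[1]
    alpha = np.broadcast_to(np.asarray(alpha, float), (G,)).copy()
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, float)

    mu = np.maximum(y, 0.5) + y.mean(axis=1, keepdims=True) * 0.1
    eta = np.log(mu)
    dev = nb_deviance(y, mu, alpha)
    converged = np.zeros(G, bool)
    alpha_col = alpha.reshape(-1, 1)
    ridge = 1e-10 * np.eye(p)

    beta = np.zeros((G, p))
    for _ in range(max_iter):
        w = mu / (1.0 + alpha_col * mu)  # (G, n)
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("ni,gn,nj->gij", X, w, X, optimize=True)
        XtWz = np.einsum("ni,gn->gi", X, w * z, optimize=True)
        # ridge keeps degenerate genes (all-zero cells) solvable
        scale = np.maximum(XtWX.reshape(G, -1).max(axis=1), 1.0)
        beta_new = np.linalg.solve(
            XtWX + ridge * scale[:, None, None], XtWz[..., None]
        )[..., 0]
        beta = np.where(converged[:, None], beta, beta_new)
        eta = np.clip(offset + beta @ X.T, -ETA_CLIP, ETA_CLIP)
        mu = np.exp(eta)
        dev_new = nb_deviance(y, mu, alpha)
        delta = np.abs(dev_new - dev)
        newly = (~converged) & (delta < tol * (np.abs(dev_new) + tol))
        converged |= newly
        dev = dev_new
        if converged.all():
            break

    w = mu / (1.0 + alpha_col * mu)
    XtWX = np.einsum("ni,gn,nj->gij", X, w, X, optimize=True)
    scale = np.maximum(XtWX.reshape(G, -1).max(axis=1), 1.0)
    cov = np.linalg.inv(XtWX + ridge * scale[:, None, None])
    return NBFit(coef=beta, cov=cov, deviance=dev, converged=converged, mu=mu)


def build_design(
    design: pd.DataFrame,
    condition: bool = True,
    time: bool = True,
    interaction: bool = False,
) -> tuple[np.ndarray, list[str], int | None]:
    """Design matrix with intercept, treated indicator, categorical time
    dummies (first level dropped), and optionally their interaction.

    Returns (X, column names, index of the condition column or None). Time
    terms are dropped automatically when only one time point is present.
    """
    n = len(design)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    cond_idx: int | None = None
    if condition:
        treated = (design["condition"].values == "treated").astype(float)
        cond_idx = len(names)
        cols.append(treated)
        names.append("condition[treated]")
    times = np.sort(design["time_h"].unique())
    time_dummies: list[np.ndarray] = []
    if time and len(times) > 1:
        for t in times[1:]:
            d = (design["time_h"].values == t).astype(float)
            time_dummies.append(d)
            cols.append(d)
            names.append(f"time[{t:g}]")
    if interaction:
        if not (condition and time_dummies):
            raise ValueError("interaction requires condition and >=2 time points")
        for d, t in zip(time_dummies, times[1:]):
            cols.append(cols[cond_idx] * d)
            names.append(f"condition:time[{t:g}]")
    X = np.column_stack(cols)
    return X, names, cond_idx
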