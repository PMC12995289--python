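"""Per-gene negative-binomial GLM differential expression for the 2x2 factorial design.

The model for each gene is  mu_j = s_j * 2**(Xb)  with design matrix
X = [1, diet, temperature, diet*temperature]  (treatment coding, reference
level Ctrl_RT) and NB variance  mu + alpha*mu**2.  Coefficients are fit by
IRLS alternated with a per-gene Cox-Reid adjusted profile-likelihood
estimate of the dispersion alpha; Wald statistics for the four contrasts of
interest use the inverse observed Fisher information and a two-sided normal
reference.  Multiple testing is controlled per contrast by the
Benjamini-Hochberg step-up.

Contrasts (coefficient vectors over [intercept, diet, temp, int]):
  A   = (0, 0, 1, 0)   cold effect in control-fed animals (Ctrl_CE vs Ctrl_RT)
  B   = (0, 1, 0, 0)   diet effect at room temperature     (MetR_RT vs Ctrl_RT)
  AB  = (0, 1, 1, 1)   combined exposure                   (MetR_CE vs Ctrl_RT)
  INT = (0, 0, 0, 1)   diet x temperature interaction

All reported fold changes are in log2 units; fits are done on the natural
log scale internally and converted once at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .simulate import CountMatrix

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)

CONTRASTS = {
    "A": np.array([0.0, 0.0, 1.0, 0.0]),
    "B": np.array([0.0, 1.0, 0.0, 0.0]),
    "AB": np.array([0.0, 1.0, 1.0, 1.0]),
    "INT": np.array([0.0, 0.0, 0.0, 1.0]),
}
CONTRAST_ORDER = ("A", "B", "AB", "INT")

DISPERSION_FLOOR = 1e-8
DISPERSION_CAP = 10.0
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
OUTER_MAX_ITER = 25


@dataclass
class GeneFit:
    """Fitted NB GLM for one gene: log2-scale coefficients and covariance."""

    gene_id: str
    coef: np.ndarray  # (intercept, diet, temperature, interaction), log2 units
    cov: np.ndarray  # 4x4, log2 units squared
    dispersion_hat: float
    converged: bool


def design_matrix(design: pd.DataFrame) -> np.ndarray:
    """Treatment-coded design matrix [1, diet, temp, diet*temp], Ctrl_RT reference."""
    x_d = (design["diet"] == "MetR").to_numpy(float)
    x_t = (design["temperature"] == "CE").to_numpy(float)
    return np.column_stack([np.ones(len(design)), x_d, x_t, x_d * x_t])


def filter_low_counts(cm: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes whose total count across all samples is below ``min_total``.

    Keeps genes with row sum >= min_total, preserving order.  The default of
    10 removes genes too sparse to normalize or fit.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = cm.counts.sum(axis=1) >= min_total
    if not keep.any():
        warnings.warn("low-count filter removed every gene", stacklevel=2)
    truth = None
    if cm.truth is not None:
        truth = cm.truth[cm.truth["gene_id"].isin(cm.counts.index[keep])].reset_index(drop=True)
    return CountMatrix(counts=cm.counts.loc[keep], design=cm.design, truth=truth)


def estimate_size_factors(cm: CountMatrix | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors.

    For each gene with all-positive counts, compute the ratio of each
    sample's count to the gene's geometric mean; the sample's size factor is
    the median of those ratios over genes.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    mat = counts.to_numpy(float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("cannot normalize: no gene has all-positive counts")
    sub = mat[all_pos]
    log_geo_mean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo_mean[:, None]
    return np.exp(np.median(ratios, axis=0))


def _nb_negloglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    if alpha < 1e-12:
        return float(np.sum(mu - y * np.log(mu) + special.gammaln(y + 1)))
    inv = 1.0 / alpha
    ll = (
        special.gammaln(y + inv)
        - special.gammaln(inv)
        - special.gammaln(y + 1)
        + y * np.log(alpha * mu / (1 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    )
    return float(-np.sum(ll))


def _irls(y, X, offset, alpha, beta0=None):
    """IRLS for NB regression with natural-log link and fixed dispersion."""
    n, p = X.shape
    if beta0 is None:
        z0 = np.log((y + 0.5)) - offset
        beta = np.linalg.lstsq(X, z0, rcond=None)[0]
    else:
        beta = beta0.copy()
    converged = False
    for _ in range(IRLS_MAX_ITER):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            return beta, False
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < IRLS_TOL:
            converged = True
            break
    return beta, converged


def _cr_profile_nll(log_alpha, y, X, offset, beta):
    """Cox-Reid adjusted negative profile log-likelihood in log(alpha)."""
    alpha = float(np.exp(log_alpha))
    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    nll = _nb_negloglik(y, mu, alpha)
    w = mu / (1.0 + alpha * mu)
    sign, logdet = np.linalg.slogdet((X.T * w) @ X)
    if sign <= 0:
        return np.inf
    return nll + 0.5 * logdet


def fit_nb_glm(
    counts: np.ndarray,
    design: pd.DataFrame,
    size_factors: np.ndarray,
    gene_id: str = "",
) -> GeneFit:
    """Fit the interaction model to one gene's counts.

    Alternates IRLS for the coefficients with a bounded 1-D optimization of
    the Cox-Reid adjusted profile likelihood for the dispersion, starting
    from a method-of-moments estimate.  The covariance is the inverse
    observed Fisher information at the optimum.  Coefficients and covariance
    are returned in log2 units.
    """
    y = np.asarray(counts, float)
    X = design_matrix(design)
    offset = np.log(np.asarray(size_factors, float))
    n, p = X.shape
    if len(y) != n:
        raise ValueError("counts and design lengths differ")

    # method-of-moments start for alpha from residual variance around group means
    mu0 = max(y.mean(), 1e-8)
    var0 = y.var(ddof=1) if n > 1 else mu0
    alpha = float(np.clip((var0 - mu0) / mu0**2, 1e-4, DISPERSION_CAP))

    beta, conv = _irls(y, X, offset, alpha)
    converged = conv
    for _ in range(OUTER_MAX_ITER):
        res = optimize.minimize_scalar(
            _cr_profile_nll,
            bounds=(np.log(DISPERSION_FLOOR), np.log(DISPERSION_CAP)),
            args=(y, X, offset, beta),
            method="bounded",
            options={"xatol": 1e-6},
        )
        alpha = float(np.exp(res.x))
        beta_new, conv = _irls(y, X, offset, alpha, beta0=beta)
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        converged = conv
        if delta < IRLS_TOL:
            break

    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    # observed information: -d2 loglik / d beta2 = X' diag(mu (1+alpha y)/(1+alpha mu)^2) X
    w_obs = mu * (1.0 + alpha * y) / (1.0 + alpha * mu) ** 2
    info = (X.T * w_obs) @ X
    try:
        cov_nat = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_nat = np.full((p, p), np.nan)
        converged = False
    return GeneFit(
        gene_id=gene_id,
        coef=beta / LN2,
        cov=cov_nat / LN2**2,
        dispersion_hat=alpha,
        converged=bool(converged),
    )


def wald_contrast(fit: GeneFit, contrast: str):
    """Wald test of one linear contrast: (log2fc, se, wald, pvalue).

    Returns NaNs for unconverged fits.  ``wald`` is log2fc/se and the
    p-value is two-sided normal; a zero contrast estimate with zero wald
    statistic yields p = 1.
    """
    c = CONTRASTS[contrast]
    if not fit.converged:
        return (np.nan, np.nan, np.nan, np.nan)
    l2fc = float(c @ fit.coef)
    var = float(c @ fit.cov @ c)
    se = float(np.sqrt(var)) if var > 0 else np.nan
    if not np.isfinite(se) or se == 0:
        return (l2fc, np.nan, np.nan, np.nan)
    w = l2fc / se
    p = float(2.0 * stats.norm.sf(abs(w)))
    return (l2fc, se, float(w), p)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the number of tests m and stay NaN.
    padj_(i) = min_{k>=i} p_(k) * m / k, capped at 1, in the original order.
    """
    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def run_de(cm: CountMatrix, min_total: int = 10) -> pd.DataFrame:
    """Full DE pipeline: filter, normalize, per-gene fit, four Wald contrasts, BH.

    Returns a tidy table with one row per gene x contrast and columns
    ``gene_id, contrast, log2fc, se, wald, pvalue, padj``.  BH adjustment is
    applied within each contrast across all genes that survived the count
    filter; genes whose fit fails carry NaN statistics and are excluded from
    the adjustment universe.
    """
    cm = filter_low_counts(cm, min_total=min_total)
    sf = estimate_size_factors(cm)
    mat = cm.counts.to_numpy(float)
    rows = []
    n_fail = 0
    for i, gid in enumerate(cm.counts.index):
        fit = fit_nb_glm(mat[i], cm.design, sf, gene_id=gid)
        if not fit.converged:
            n_fail += 1
        for contrast in CONTRAST_ORDER:
            l2fc, se, w, p = wald_contrast(fit, contrast)
            rows.append(
                {
                    "gene_id": gid,
                    "contrast": contrast,
                    "log2fc": l2fc,
                    "se": se,
                    "wald": w,
                    "pvalue": p,
                }
            )
    if n_fail:
        logger.warning("%d of %d gene fits did not converge", n_fail, cm.n_genes)
    de = pd.DataFrame(rows)
    de["padj"] = np.nan
    for contrast in CONTRAST_ORDER:
        mask = de["contrast"] == contrast
        de.loc[mask, "padj"] = adjust_bh(de.loc[mask, "pvalue"].to_numpy())
    return de
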