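"""Empirical-Bayes multisite (batch) harmonization of edge features.

Implements the ComBat location/scale model: each feature (connectome edge)
is modelled as

    y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg

for site ``i``, subject ``j``, feature ``g``, with biological covariates
``X`` (e.g. diagnosis, age, sex, FIQ, mFD) whose associated variance must
be preserved. Per-site location (``gamma``) and scale (``delta``)
estimates are shrunk toward empirical-Bayes priors pooled across features
— parametrically (normal / inverse-gamma priors, moment-matched, solved by
fixed-point iteration) or nonparametrically (Monte Carlo integration over
the other features' estimates) — and then removed; covariate effects are
restored afterwards.

Estimation conventions (pooled variance with 1/n, site variances with
1/(n_i - 1), prior moment matching, 1e-4 fixed-point tolerance) follow the
standard reference implementations, so results are directly comparable to
``sva::ComBat``. A dataset from a single site is returned unchanged: there
is no between-site variability to remove, and pass-through keeps the
operation exactly idempotent in that case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("cpmconn")

#: Default biological covariates to preserve, when present in a phenotype.
DEFAULT_BIO_COVARIATES = ["diagnosis", "age", "sex", "fiq", "mfd"]


@dataclass
class CombatModel:
    """Fitted harmonization model (one row per site in site order)."""

    sites: list
    n_per_site: np.ndarray
    gamma_star: np.ndarray      # B x G shrunken location effects
    delta_star: np.ndarray      # B x G shrunken scale effects (variances)
    grand_mean: np.ndarray      # G
    beta_cov: np.ndarray        # k x G covariate coefficients
    var_pooled: np.ndarray      # G
    mode: str

    def __post_init__(self):
        if not np.all(np.isfinite(self.gamma_star)):
            raise ValueError("non-finite location estimates")
        if not np.all(self.delta_star > 0):
            raise ValueError("non-positive scale estimates")


def _check_design(covariates: np.ndarray | None, batch_design: np.ndarray,
                  names: list[str]) -> None:
    if covariates is None:
        return
    base = batch_design
    for k in range(covariates.shape[1]):
        cand = np.column_stack([base, covariates[:, : k + 1]])
        if np.linalg.matrix_rank(cand) < cand.shape[1]:
            raise ValueError(
                f"covariate design is rank deficient: column "
                f"'{names[k]}' is collinear with the site indicators "
                f"and/or preceding covariates")


def _parametric_eb(z_site: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
                   n_i: int, tol: float = 1e-4, max_iter: int = 1000):
    """Fixed-point solution of the parametric EB posterior (per site)."""
    g_bar = g_hat.mean()
    t2 = g_hat.var(ddof=1) if len(g_hat) > 1 else 0.0
    m = d_hat.mean()
    s2 = d_hat.var(ddof=1) if len(d_hat) > 1 else 0.0
    if t2 <= 0 or s2 <= 0:
        # Degenerate prior (e.g. all features identical): no information to
        # shrink with; keep the raw per-feature estimates.
        return g_hat.copy(), d_hat.copy()
    a = (2 * s2 + m ** 2) / s2
    b = (m * s2 + m ** 3) / s2
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n_i * t2 * g_hat + d_old * g_bar) / (n_i * t2 + d_old)
        sum2 = ((z_site - g_new[None, :]) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n_i / 2 + a - 1)
        change = max(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                     np.max(np.abs(d_new - d_old) / d_old))
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def _nonparametric_eb(z_site: np.ndarray, g_hat: np.ndarray,
                      d_hat: np.ndarray, n_i: int):
    """Monte Carlo integration of the EB posterior over the empirical prior.

    For each feature, the posterior mean weights every *other* feature's
    (gamma_hat, delta_hat) by the likelihood of this feature's standardized
    data under that candidate parameter pair. O(G^2) — intended for feature
    counts in the thousands, not tens of thousands.
    """
    G = len(g_hat)
    S1 = z_site.sum(axis=0)
    S2 = (z_site ** 2).sum(axis=0)
    # sum of squared residuals of feature g's data around candidate g_hat[j]
    A = S2[None, :] - 2 * g_hat[:, None] * S1[None, :] + n_i * g_hat[:, None] ** 2
    logLH = (-A / (2 * d_hat[:, None])
             - (n_i / 2) * np.log(2 * np.pi * d_hat)[:, None])
    np.fill_diagonal(logLH, -np.inf)  # leave-one-feature-out prior
    logLH -= logLH.max(axis=0, keepdims=True)
    LH = np.exp(logLH)
    wsum = LH.sum(axis=0)
    g_star = (g_hat @ LH) / wsum
    d_star = (d_hat @ LH) / wsum
    return g_star, d_star


def combat_fit_transform(features, site, covariates=None, *,
                         mode: str = "parametric",
                         covariate_names: list[str] | None = None,
                         allow_singleton_sites: bool = False,
                         ) -> tuple[np.ndarray | pd.DataFrame, CombatModel]:
    """Remove site location/scale effects from a subjects x features matrix.

    Parameters
    ----------
    features : (n, G) array or DataFrame
        One row per subject (e.g. Fisher-z edge vectors).
    site : length-n array-like
        Site / batch label per subject.
    covariates : (n, k) array or DataFrame, optional
        Biological covariates whose variance is preserved (fit, removed
        for standardization, restored after adjustment).
    mode : {"parametric", "nonparametric"}
        Empirical-Bayes prior handling (see module docstring).
    allow_singleton_sites : bool
        A site with a single subject cannot support a scale estimate; by
        default this is an error. If allowed, that site's scale is fixed
        at 1 (location still estimated and shrunk) with a logged warning.

    Returns
    -------
    harmonized : same type/shape as ``features``
    model : CombatModel
    """
    if mode not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown mode: {mode}")
    is_frame = isinstance(features, pd.DataFrame)
    Y = np.asarray(features, dtype=float)
    if Y.ndim != 2:
        raise ValueError("features must be 2-D (subjects x features)")
    n, G = Y.shape
    site = np.asarray(pd.Series(list(site)).astype(str))
    if len(site) != n:
        raise ValueError("site labels do not match number of subjects")

    if isinstance(covariates, pd.DataFrame):
        covariate_names = covariate_names or list(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    elif covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        covariate_names = covariate_names or [f"cov{k}" for k in range(C.shape[1])]
    else:
        C, covariate_names = None, []
    k = 0 if C is None else C.shape[1]

    sites = list(dict.fromkeys(site))
    B = len(sites)
    n_per = np.array([(site == s).sum() for s in sites])

    if B == 1:
        logger.info("combat: single site, returning input unchanged")
        model = CombatModel(sites=sites, n_per_site=n_per,
                            gamma_star=np.zeros((1, G)),
                            delta_star=np.ones((1, G)),
                            grand_mean=Y.mean(axis=0),
                            beta_cov=np.zeros((k, G)),
                            var_pooled=np.maximum(Y.var(axis=0), 1e-300),
                            mode=mode)
        return (features.copy() if is_frame else Y.copy()), model

    singleton = [s for s, m in zip(sites, n_per) if m < 2]
    if singleton and not allow_singleton_sites:
        raise ValueError(
            f"site(s) with a single subject: {singleton}; scale effects "
            f"cannot be estimated (pass allow_singleton_sites=True to keep "
            f"them with unit scale)")
    if singleton:
        logger.warning("combat: singleton site(s) %s kept with unit scale",
                       singleton)

    batch_design = np.column_stack([(site == s).astype(float) for s in sites])
    _check_design(C, batch_design, covariate_names)
    design = batch_design if C is None else np.column_stack([batch_design, C])

    B_hat, *_ = np.linalg.lstsq(design, Y, rcond=None)
    grand_mean = (n_per / n) @ B_hat[:B]
    beta_cov = B_hat[B:]
    stand_mean = np.tile(grand_mean, (n, 1))
    if C is not None:
        stand_mean = stand_mean + C @ beta_cov
    resid = Y - design @ B_hat
    var_pooled = (resid ** 2).mean(axis=0)
    if np.any(var_pooled <= 0):
        raise ValueError("zero pooled variance for some feature(s)")
    sd = np.sqrt(var_pooled)
    Z = (Y - stand_mean) / sd

    gamma_star = np.empty((B, G))
    delta_star = np.empty((B, G))
    for bi, s in enumerate(sites):
        rows = site == s
        n_i = int(rows.sum())
        z_i = Z[rows]
        g_hat = z_i.mean(axis=0)
        d_hat = z_i.var(axis=0, ddof=1) if n_i > 1 else np.ones(G)
        d_hat = np.maximum(d_hat, 1e-300)
        if n_i == 1:
            gamma_star[bi], delta_star[bi] = g_hat, np.ones(G)
            continue
        if mode == "parametric":
            g_st, d_st = _parametric_eb(z_i, g_hat, d_hat, n_i)
        else:
            g_st, d_st = _nonparametric_eb(z_i, g_hat, d_hat, n_i)
        gamma_star[bi], delta_star[bi] = g_st, np.maximum(d_st, 1e-300)

    out = Z.copy()
    for bi, s in enumerate(sites):
        rows = site == s
        out[rows] = (Z[rows] - gamma_star[bi]) / np.sqrt(delta_star[bi])
    out = out * sd + stand_mean

    model = CombatModel(sites=sites, n_per_site=n_per, gamma_star=gamma_star,
                        delta_star=delta_star, grand_mean=grand_mean,
                        beta_cov=beta_cov, var_pooled=var_pooled, mode=mode)
    if is_frame:
        out = pd.DataFrame(out, index=features.index, columns=features.columns)
    return out, model


def covariate_matrix(pheno: pd.DataFrame, names: list[str]) -> np.ndarray:
    """Numeric design columns from a phenotype table.

    ``sex`` is coded M=1/F=0; ``diagnosis``/``group`` patient=1/control=0;
    other columns must already be numeric.
    """
    cols = []
    for name in names:
        if name not in pheno.columns:
            raise ValueError(f"phenotype table has no column '{name}'")
        v = pheno[name]
        if name == "sex":
            cols.append((v == "M").astype(float).to_numpy())
        elif name in ("diagnosis", "group"):
            cols.append((v == "patient").astype(float).to_numpy())
        else:
            cols.append(v.to_numpy(dtype=float))
    out = np.column_stack(cols)
    if not np.all(np.isfinite(out)):
        bad = [names[k] for k in range(out.shape[1])
               if not np.all(np.isfinite(out[:, k]))]
        raise ValueError(f"non-finite covariate values in columns {bad}")
    return out
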