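"""Connectome-based predictive modelling (CPM) engine.

The protocol: for a behavioural score y over n subjects with edge features
X (n x E Fisher-z values) and nuisance covariates C (age, sex, motion):

1. *Edge selection* — partial correlation of every edge with y given C;
   edges with two-sided p below a threshold (default 0.01) form the
   positive (r > 0) and negative (r < 0) networks.
2. *Network strength* — per subject, the sum of edge weights over each
   selected network.
3. *Linear model* — ordinary least squares of y on network strength
   (one single-predictor model per tail).
4. *Leave-one-out cross-validation* — steps 1-3 are refit on every
   training fold (all subjects but one) and applied to the held-out
   subject; edges retained in **every** fold are the consensus network.
5. *Evaluation* — partial correlation (given C) between the pooled
   held-out predictions and the observed scores.
6. *Permutation inference* — the behavioural vector is shuffled (covariates
   stay with the connectomes) and the full LOOCV repeated; the one-sided
   add-one estimator gives p, and the mean of the null correlations
   summarizes chance-level performance.

Implementation note: fold-wise partial correlations are computed through a
leave-one-out projection identity — partialling an indicator column for
the held-out subject out of the full sample is algebraically identical to
computing the partial correlation on the training subjects alone. This
lets one residualization of X serve every fold and every permutation.
Covariates are z-scored within each training fold before residualization;
since z-scoring is an affine map and the design includes an intercept, the
fold residuals (and hence correlations) are unchanged by it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import edge_index, n_edges, n_nodes_from_edges

logger = logging.getLogger("cpmconn")

TAILS = ("pos", "neg")


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------

def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(x, y, covariates=None) -> tuple[float, float, int]:
    """Pearson correlation of x and y after removing covariate effects.

    Both vectors are residualized on ``[1, covariates]`` by OLS; the
    correlation of the residuals is tested against a t distribution with
    ``df = n - 2 - k``. With no covariates this is the plain Pearson
    correlation (df = n - 2).

    Returns
    -------
    (r, p, df) : two-sided p-value.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y length mismatch")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    k = C.shape[1]
    if n < k + 3:
        raise ValueError(f"need n >= k + 3 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariates are rank deficient")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    # relative check: residuals of a covariate-determined vector are ~1e-16
    if sx <= 1e-10 * max(np.linalg.norm(x), 1e-300) or \
       sy <= 1e-10 * max(np.linalg.norm(y), 1e-300):
        raise ValueError("zero residual variance")
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * stats.t.sf(abs(t), df))
    return r, p, df


def r_critical(df: int, p_threshold: float) -> float:
    """|r| above which the two-sided p is below the threshold."""
    t = stats.t.ppf(1 - p_threshold / 2, df)
    return float(t / np.sqrt(df + t * t))


# ---------------------------------------------------------------------------
# Edge masks
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class EdgeMask:
    """Symmetric N x N matrix over {-1, 0, +1} marking selected edges.

    +1 marks positive-network edges, -1 negative-network edges.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise ValueError("edge mask must be square")
        if not np.isin(self.values, [-1, 0, 1]).all():
            raise ValueError("edge mask entries must be in {-1, 0, 1}")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("edge mask must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("edge mask diagonal must be 0")
        self.values = self.values.astype(np.int8)

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_nodes: int | None = None) -> "EdgeMask":
        vec = np.asarray(vec)
        n = n_nodes_from_edges(len(vec)) if n_nodes is None else n_nodes
        m = np.zeros((n, n), dtype=np.int8)
        iu = edge_index(n)
        m[iu] = vec
        return cls(values=m + m.T)

    def to_vector(self) -> np.ndarray:
        """Signed edge vector in canonical upper-triangle order."""
        return self.values[edge_index(self.n_nodes)].astype(int)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of selected (nonzero) undirected edges."""
        return int(np.count_nonzero(self.to_vector()))


# ---------------------------------------------------------------------------
# Edge selection, strength, tail models
# ---------------------------------------------------------------------------

def select_edges(edges: np.ndarray, behaviour, covariates=None,
                 p_threshold: float = 0.01) -> tuple[EdgeMask, EdgeMask]:
    """Select edges whose partial correlation with behaviour passes threshold.

    An edge enters the positive mask iff its covariate-adjusted correlation
    with behaviour is positive with two-sided p < ``p_threshold`` (the test
    is applied as ``|r| > r_critical``, which is equivalent); negative
    analogously. The two masks are disjoint by construction.

    Returns ``(positive EdgeMask, negative EdgeMask)``.
    """
    X = np.asarray(edges, dtype=float)
    y = np.asarray(behaviour, dtype=float).ravel()
    n, E = X.shape
    if len(y) != n:
        raise ValueError("behaviour length mismatch")
    if np.any(~np.isfinite(y)):
        raise ValueError("behaviour contains missing values")
    if y.std() == 0:
        raise ValueError("behaviour has zero variance")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    k = C.shape[1]
    df = n - 2 - k
    if df < 1:
        raise ValueError(f"not enough subjects for {k} covariates")
    design = np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(design)
    U = X - Q @ (Q.T @ X)
    w = y - Q @ (Q.T @ y)
    nx2 = (U ** 2).sum(axis=0)
    ny2 = w @ w
    num = U.T @ w
    rc2 = r_critical(df, p_threshold) ** 2
    ok = nx2 > 0
    sel = np.zeros(E, dtype=bool)
    sel[ok] = num[ok] ** 2 > rc2 * nx2[ok] * ny2
    pos = sel & (num > 0)
    neg = sel & (num < 0)
    n_nodes = n_nodes_from_edges(E)
    return (EdgeMask.from_vector(pos.astype(int), n_nodes),
            EdgeMask.from_vector(-neg.astype(int), n_nodes))


def network_strength(edge_values, mask: EdgeMask, sign: int) -> float | np.ndarray:
    """Sum of edge weights over the mask entries of the requested sign.

    Each undirected edge is counted once (canonical upper-triangle order).
    ``edge_values`` may be a single length-E vector or an (n, E) matrix
    (returns per-subject strengths).
    """
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    v = np.asarray(getattr(edge_values, "values", edge_values), dtype=float)
    mvec = mask.to_vector() == sign
    if v.shape[-1] != len(mvec):
        raise ValueError("edge vector / mask dimension mismatch")
    out = v[..., mvec].sum(axis=-1)
    return float(out) if out.ndim == 0 else out


@dataclass
class TailModel:
    """Single-predictor linear model: behaviour ~ slope * strength + intercept.

    ``degenerate`` marks a fit with zero strength variance; such a model
    predicts the training mean (slope 0).
    """

    slope: float
    intercept: float
    degenerate: bool = False

    def predict(self, strengths) -> np.ndarray:
        s = np.asarray(strengths, dtype=float)
        return self.slope * s + self.intercept


def fit_tail_model(strengths, behaviour) -> TailModel:
    """OLS of behaviour on network strength (intercept included)."""
    s = np.asarray(strengths, dtype=float).ravel()
    y = np.asarray(behaviour, dtype=float).ravel()
    if len(s) != len(y) or len(s) < 3:
        raise ValueError("need matched vectors with n >= 3")
    ds = s - s.mean()
    var = ds @ ds
    if var == 0:
        return TailModel(slope=0.0, intercept=float(y.mean()), degenerate=True)
    slope = float((ds @ (y - y.mean())) / var)
    return TailModel(slope=slope, intercept=float(y.mean() - slope * s.mean()))


# ---------------------------------------------------------------------------
# Fast LOOCV engine
# ---------------------------------------------------------------------------

class _LoocvEngine:
    """Shared precomputation for leave-one-out CPM over fixed X and C.

    For fold ``s`` (subject s held out), the training-set partial
    correlation of edge e with y equals the full-sample correlation of the
    residuals after projecting out ``[1, C, indicator_s]``. With
    ``M = I - P_[1,C]``, ``U = M X``, ``w = M y``, ``h_s = M[s,s]``:

        num_e^(s)  = (U^T w)_e - U[s,e] w[s] / h_s
        ||x||^2    = G_e - U[s,e]^2 / h_s
        ||y||^2    = w'w - w[s]^2 / h_s

    so one matrix residualization of X serves all n folds, and each new
    behaviour vector (observed or permuted) costs one matvec plus O(nE)
    elementwise work.
    """

    def __init__(self, edges: np.ndarray, covariates, p_threshold: float):
        X = np.ascontiguousarray(edges, dtype=float)
        n, E = X.shape
        if n < 10:
            raise ValueError(f"need at least 10 subjects, got {n}")
        if covariates is None:
            C = np.empty((n, 0))
        else:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            if not np.all(np.isfinite(C)):
                raise ValueError("covariates contain non-finite values")
        self.n, self.E, self.k = n, E, C.shape[1]
        self.df_fold = n - 3 - self.k  # training n-1, minus 2, minus k
        if self.df_fold < 1:
            raise ValueError("not enough subjects for the covariate count")
        design = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("covariates are rank deficient")
        self.X = X
        self.C = C
        Q, _ = np.linalg.qr(design)
        self.Q = Q
        h = 1.0 - (Q ** 2).sum(axis=1)
        if np.any(h < 1e-10):
            raise ValueError("a subject has leverage 1 under the covariate "
                             "design; leave-one-out is undefined")
        self.h = h
        self.U = X - Q @ (Q.T @ X)
        self.Uh = self.U / h[:, None]
        G = (self.U ** 2).sum(axis=0)
        self.Dx = G[None, :] - self.U * self.Uh  # n x E fold-wise ||x||^2
        self.rc2 = r_critical(self.df_fold, p_threshold) ** 2
        self.p_threshold = p_threshold

    def residualize(self, y: np.ndarray) -> np.ndarray:
        return y - self.Q @ (self.Q.T @ y)

    def selection(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fold-wise edge selections for behaviour y.

        Returns boolean (n, E) matrices (positive, negative); row s is the
        selection computed from the training subjects of fold s.
        """
        w = self.residualize(y)
        A = self.U.T @ w
        deny = (w @ w) - w ** 2 / self.h
        num = A[None, :] - self.Uh * w[:, None]
        thr = (self.rc2 * deny[:, None]) * self.Dx
        sel = (num * num > thr) & (self.Dx > 0) & (deny[:, None] > 0)
        return sel & (num > 0), sel & (num < 0)

    def predict(self, y: np.ndarray, sel: np.ndarray):
        """Held-out predictions from fold-wise selections.

        For fold s: strengths over sel[s], OLS of y on strength fit on the
        training subjects, applied to subject s. Folds with no selected
        edges (or zero strength variance) predict the training mean.

        Returns (predictions, slopes, intercepts, degenerate_folds).
        """
        n, X = self.n, self.X
        preds = np.empty(n)
        slopes = np.zeros(n)
        intercepts = np.empty(n)
        degenerate = np.zeros(n, dtype=bool)
        ysum = float(y.sum())
        m = n - 1
        for s in range(n):
            idx = np.flatnonzero(sel[s])
            mean_y = (ysum - y[s]) / m
            if idx.size == 0:
                preds[s] = intercepts[s] = mean_y
                degenerate[s] = True
                continue
            st = X[:, idx].sum(axis=1)
            s_sum = st.sum() - st[s]
            s_sq = st @ st - st[s] ** 2
            s_y = st @ y - st[s] * y[s]
            var = s_sq - s_sum ** 2 / m
            if var <= 1e-12 * max(s_sq, 1.0):
                preds[s] = intercepts[s] = mean_y
                degenerate[s] = True
                continue
            slope = (s_y - s_sum * (ysum - y[s]) / m) / var
            intercept = mean_y - slope * s_sum / m
            slopes[s], intercepts[s] = slope, intercept
            preds[s] = slope * st[s] + intercept
        return preds, slopes, intercepts, degenerate

    def predict_combined(self, y: np.ndarray, sel_pos: np.ndarray,
                         sel_neg: np.ndarray):
        """Held-out predictions from a two-predictor model (positive and
        negative strengths jointly). Folds where a tail selects nothing
        drop that predictor; folds with no edges at all predict the
        training mean. Returns (predictions, degenerate_folds)."""
        n, X = self.n, self.X
        preds = np.empty(n)
        degenerate = np.zeros(n, dtype=bool)
        idx_all = np.arange(n)
        for s in range(n):
            tr = idx_all != s
            cols = []
            for sel in (sel_pos, sel_neg):
                idx = np.flatnonzero(sel[s])
                if idx.size:
                    cols.append(X[:, idx].sum(axis=1))
            if not cols:
                preds[s] = y[tr].mean()
                degenerate[s] = True
                continue
            A = np.column_stack([np.ones(n)] + cols)
            beta, *_ = np.linalg.lstsq(A[tr], y[tr], rcond=None)
            preds[s] = A[s] @ beta
        return preds, degenerate

    def evaluate(self, preds: np.ndarray, y: np.ndarray):
        """Partial correlation (given the engine covariates) of predictions
        with the observed behaviour; (r, p, df)."""
        rp = self.residualize(preds)
        ry = self.residualize(y)
        sx = np.sqrt(rp @ rp)
        sy = np.sqrt(ry @ ry)
        if sx == 0 or sy == 0:
            raise ValueError("zero residual variance")
        r = float(np.clip((rp @ ry) / (sx * sy), -1.0, 1.0))
        df = self.n - 2 - self.k
        t = r * np.sqrt(df / max(1.0 - r * r, 1e-300))
        return r, float(2 * stats.t.sf(abs(t), df)), df


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    """One LOOCV fold: masks and tail coefficients fit on its training set."""

    fold: int
    positive: EdgeMask
    negative: EdgeMask
    coefficients: dict          # tail -> (slope, intercept)
    training_index: np.ndarray  # row indices of the training subjects


@dataclass
class PermutationResult:
    """Permutation null for one tail's evaluation correlation."""

    observed_r: float
    p_perm: float
    null_r: np.ndarray
    mean_null_r: float
    n_degenerate: int


@dataclass
class CPMResult:
    """Full CPM output for one behaviour score."""

    subject_ids: list
    observed: np.ndarray
    predictions: dict                  # tail -> per-subject held-out preds
    consensus: dict                    # tail -> EdgeMask
    evaluation: dict                   # tail -> (r, p, df)
    n_empty_folds: dict                # tail -> count
    invalid: dict                      # tail -> all folds empty
    permutation: dict = field(default_factory=dict)  # tail -> PermutationResult
    config: dict = field(default_factory=dict)
    fold_selections: dict = field(default_factory=dict)  # tail -> (n, E) bool

    def fold_model(self, s: int) -> FoldModel:
        """Reconstruct the FoldModel for fold ``s`` from stored selections."""
        n_nodes = next(iter(self.consensus.values())).n_nodes
        pos = self.fold_selections.get("pos")
        neg = self.fold_selections.get("neg")
        E = n_edges(n_nodes)
        pvec = pos[s].astype(int) if pos is not None else np.zeros(E, int)
        nvec = neg[s].astype(int) if neg is not None else np.zeros(E, int)
        coef = {t: self.config.get("fold_coefficients", {}).get(t, (None, None))
                for t in self.predictions}
        coefs = {}
        for t in self.predictions:
            sl = self.config.get("_fold_slopes", {}).get(t)
            ic = self.config.get("_fold_intercepts", {}).get(t)
            coefs[t] = (float(sl[s]), float(ic[s])) if sl is not None else coef[t]
        return FoldModel(
            fold=s,
            positive=EdgeMask.from_vector(pvec, n_nodes),
            negative=EdgeMask.from_vector(-nvec, n_nodes),
            coefficients=coefs,
            training_index=np.delete(np.arange(len(self.observed)), s),
        )


def _tails(tail: str) -> tuple[str, ...]:
    """Mask tails for a tail mode; 'combined' needs both masks."""
    if tail in ("both", "combined"):
        return TAILS
    if tail not in TAILS:
        raise ValueError("tail must be 'pos', 'neg', 'both' or 'combined'")
    return (tail,)


# ---------------------------------------------------------------------------
# LOOCV driver and permutation test
# ---------------------------------------------------------------------------

def loocv_cpm(edges, behaviour, covariates=None, *, p_threshold: float = 0.01,
              tail: str = "both", subject_ids=None) -> CPMResult:
    """Leave-one-out CPM: fold-wise selection + model fit, held-out
    predictions, consensus masks, and covariate-adjusted evaluation r.

    ``tail``: 'pos' / 'neg' for a single-tail model, 'both' for the two
    separate single-predictor models (default), or 'combined' for both
    plus a joint two-predictor model (positive and negative strengths as
    regressors) reported under the key ``"combined"``.

    Subjects with a missing behaviour value must be dropped by the caller
    (per-analysis, not globally). See the module docstring for the protocol.
    """
    X = np.asarray(edges, dtype=float)
    y = np.asarray(behaviour, dtype=float).ravel()
    if np.any(~np.isfinite(y)):
        raise ValueError("behaviour contains missing values; drop those "
                         "subjects for this analysis")
    eng = _LoocvEngine(X, covariates, p_threshold)
    sel_pos, sel_neg = eng.selection(y)
    sel = {"pos": sel_pos, "neg": sel_neg}
    n_nodes = n_nodes_from_edges(eng.E)
    ids = list(subject_ids) if subject_ids is not None else [
        f"s{i}" for i in range(eng.n)]

    predictions, consensus, evaluation = {}, {}, {}
    n_empty, invalid = {}, {}
    fold_slopes, fold_intercepts = {}, {}
    for t in _tails(tail):
        preds, slopes, icpts, degen = eng.predict(y, sel[t])
        predictions[t] = preds
        fold_slopes[t], fold_intercepts[t] = slopes, icpts
        n_empty[t] = int(degen.sum())
        invalid[t] = bool(degen.all())
        cvec = sel[t].all(axis=0).astype(int)
        consensus[t] = EdgeMask.from_vector(cvec if t == "pos" else -cvec,
                                            n_nodes)
        if invalid[t]:
            logger.warning("loocv_cpm: every fold empty for tail %s", t)
            evaluation[t] = (np.nan, np.nan, eng.n - 2 - eng.k)
        else:
            try:
                evaluation[t] = eng.evaluate(preds, y)
            except ValueError:
                evaluation[t] = (np.nan, np.nan, eng.n - 2 - eng.k)
    if tail == "combined":
        preds_c, degen_c = eng.predict_combined(y, sel["pos"], sel["neg"])
        predictions["combined"] = preds_c
        n_empty["combined"] = int(degen_c.sum())
        invalid["combined"] = bool(degen_c.all())
        try:
            evaluation["combined"] = eng.evaluate(preds_c, y)
        except ValueError:
            evaluation["combined"] = (np.nan, np.nan, eng.n - 2 - eng.k)
    return CPMResult(
        subject_ids=ids,
        observed=y,
        predictions=predictions,
        consensus=consensus,
        evaluation=evaluation,
        n_empty_folds=n_empty,
        invalid=invalid,
        config={
            "p_threshold": p_threshold,
            "tail": tail,
            "n_covariates": eng.k,
            "_fold_slopes": fold_slopes,
            "_fold_intercepts": fold_intercepts,
        },
        fold_selections={t: sel[t] for t in _tails(tail)},
    )


def permutation_test(edges, behaviour, covariates=None, *,
                     p_threshold: float = 0.01, tail: str = "neg",
                     n_perm: int = 1000, seed: int = 0) -> dict:
    """Permutation null for the LOOCV evaluation correlation.

    Each permutation shuffles the behaviour vector (covariates stay paired
    with the connectomes), reruns the full LOOCV, and records the
    evaluation r computed against the permuted behaviour. The p-value is
    the one-sided add-one estimator ``(1 + #{null >= observed}) / (1 +
    n_perm)``; permutations whose evaluation is degenerate (e.g. every
    fold empty) contribute r = 0 and are counted.

    Returns ``{tail: PermutationResult}`` for the requested tail(s).
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    X = np.asarray(edges, dtype=float)
    y = np.asarray(behaviour, dtype=float).ravel()
    eng = _LoocvEngine(X, covariates, p_threshold)
    if tail == "combined":
        tails = ("combined",)
    else:
        tails = _tails(tail)

    def one(yv):
        sel_pos, sel_neg = eng.selection(yv)
        sel = {"pos": sel_pos, "neg": sel_neg}
        out = {}
        for t in tails:
            if t == "combined":
                preds, degen = eng.predict_combined(yv, sel_pos, sel_neg)
            else:
                preds, *_, degen = eng.predict(yv, sel[t])
            if degen.all():
                out[t] = (0.0, True)
                continue
            try:
                r, _, _ = eng.evaluate(preds, yv)
                out[t] = (r, False)
            except ValueError:
                out[t] = (0.0, True)
        return out

    obs = one(y)
    rng = np.random.default_rng(seed)
    null = {t: np.empty(n_perm) for t in tails}
    n_degen = {t: 0 for t in tails}
    for p in range(n_perm):
        res = one(rng.permutation(y))
        for t in tails:
            null[t][p] = res[t][0]
            n_degen[t] += res[t][1]
    results = {}
    for t in tails:
        r_obs = obs[t][0]
        p_perm = (1 + int((null[t] >= r_obs).sum())) / (1 + n_perm)
        if n_degen[t]:
            logger.info("permutation_test[%s]: %d degenerate permutation(s) "
                        "contributed r=0", t, n_degen[t])
        results[t] = PermutationResult(
            observed_r=float(r_obs),
            p_perm=float(p_perm),
            null_r=null[t],
            mean_null_r=float(null[t].mean()),
            n_degenerate=int(n_degen[t]),
        )
    return results


def run_cpm(edges, behaviour, covariates=None, *, p_threshold: float = 0.01,
            tail: str = "both", n_perm: int = 1000, seed: int = 0,
            subject_ids=None) -> CPMResult:
    """LOOCV CPM plus permutation inference; fills ``CPMResult.permutation``."""
    res = loocv_cpm(edges, behaviour, covariates, p_threshold=p_threshold,
                    tail=tail, subject_ids=subject_ids)
    res.permutation = permutation_test(
        edges, behaviour, covariates, p_threshold=p_threshold, tail=tail,
        n_perm=n_perm, seed=seed)
    res.config.update({"n_perm": n_perm, "seed": seed})
    return res


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
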