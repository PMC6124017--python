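"""Count normalization, negative-binomial differential testing, and profile clustering.

The differential test is a deliberately simple NB Wald test: a log-linear
model per feature (condition plus optional additive batch), fitted by
iteratively reweighted least squares with a method-of-moments dispersion
floored at 1e-8, no shrinkage and no independent filtering.  It mirrors the
structure of the standard median-of-ratios / NB-GLM workflow while staying
fully transparent and testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8


class DesignError(ValueError):
    """Invalid experimental design (confounding, missing replicates...)."""


@dataclass
class CountMatrix:
    """Integer read counts, features x libraries, with library metadata.

    ``counts``: DataFrame indexed by feature id, one column per library.
    ``meta``: DataFrame indexed by library id with columns ``condition``
    (young/aged), ``replicate`` and optionally ``batch``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    filtered: pd.Series | None = field(default=None)

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if not self.counts.index.is_unique:
            raise ValueError("feature ids must be unique")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"libraries without metadata: {sorted(missing)}")
        self.meta = self.meta.loc[list(self.counts.columns)]
        if self.filtered is None:
            self.filtered = pd.Series(False, index=self.counts.index)

    def libraries(self, condition: str) -> list:
        return list(self.meta.index[self.meta["condition"] == condition])


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    factor_j = median over features with an all-positive geometric mean of
    count_ij / geomean_i.  Factors are not rescaled afterwards.
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    x = mat.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    all_pos = np.isfinite(logx).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in every library; "
            "pseudo-reference fallback is disabled"
        )
    loggeo = logx[all_pos].mean(axis=1)
    ratios = np.exp(logx[all_pos] - loggeo[:, None])
    return pd.Series(np.median(ratios, axis=0), index=mat.columns, name="size_factor")


def filter_low_counts(counts: CountMatrix, min_reads: int = 25, min_reps: int = 2) -> CountMatrix:
    """Flag features failing the minimum-count rule.

    A feature is kept iff at least ``min_reps`` libraries within young OR
    within aged have count >= ``min_reads``.  Flagged features stay in the
    matrix with ``filtered=True``.
    """
    if min_reads < 0 or min_reps < 1:
        raise ValueError("min_reads >= 0 and min_reps >= 1 required")
    keep = np.zeros(len(counts.counts), dtype=bool)
    n_any = 0
    for cond in ("young", "aged"):
        libs = counts.libraries(cond)
        if len(libs) >= min_reps:
            n_any += 1
            sub = counts.counts[libs].to_numpy()
            keep |= (sub >= min_reads).sum(axis=1) >= min_reps
    if n_any == 0:
        raise DesignError("min_reps exceeds the replicate count in both conditions")
    return CountMatrix(counts.counts, counts.meta, filtered=pd.Series(~keep, index=counts.counts.index))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _nb_irls(y: np.ndarray, X: np.ndarray, offset: np.ndarray, disp: np.ndarray,
             max_iter: int = 50, tol: float = 1e-8):
    """Vectorized IRLS for NB log-linear models, one model per feature row.

    y: (F, n) counts; X: (n, p) design; offset: (n,) log size factors;
    disp: (F,) dispersions.  Returns (beta (F, p), cov (F, p, p), ok (F,)).
    """
    F, n = y.shape
    p = X.shape[1]
    # init from log means
    mu0 = np.maximum(y.mean(axis=1), 0.1)
    beta = np.zeros((F, p))
    beta[:, 0] = np.log(mu0)
    ok = np.ones(F, dtype=bool)
    cov = np.zeros((F, p, p))
    for _ in range(max_iter):
        eta = beta @ X.T + offset  # (F, n)
        mu = np.exp(np.clip(eta, -30, 30))
        W = mu / (1.0 + disp[:, None] * mu)  # NB working weights, log link
        z = (eta - offset) + (y - mu) / mu
        XtWX = np.einsum("ni,fn,nj->fij", X, W, X)
        XtWz = np.einsum("ni,fn,fn->fi", X, W, z)
        try:
            new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            # fall back to per-feature solves, flagging singular fits
            new = beta.copy()
            for f in range(F):
                try:
                    new[f] = np.linalg.solve(XtWX[f], XtWz[f])
                except np.linalg.LinAlgError:
                    ok[f] = False
        step = new - beta
        beta = new
        if np.nanmax(np.abs(step)) < tol:
            break
    eta = beta @ X.T + offset
    mu = np.exp(np.clip(eta, -30, 30))
    W = mu / (1.0 + disp[:, None] * mu)
    XtWX = np.einsum("ni,fn,nj->fij", X, W, X)
    for f in range(F):
        try:
            cov[f] = np.linalg.inv(XtWX[f])
        except np.linalg.LinAlgError:
            ok[f] = False
    return beta, cov, ok


@dataclass
class DiffResult:
    """Per-feature differential test results (aged vs young)."""

    table: pd.DataFrame  # baseMean, log2FC, p, padj, filtered

    def __getitem__(self, col):
        return self.table[col]

    def significant(self, alpha: float = 0.05, min_abs_lfc: float = 0.0) -> pd.Index:
        t = self.table
        mask = (t["padj"] < alpha) & (t["log2FC"].abs() > min_abs_lfc) & ~t["filtered"]
        return t.index[mask.fillna(False)]


class NBDifferentialTest:
    """Negative-binomial Wald test for a two-condition (+ optional batch) design.

    sklearn-style estimator: ``fit(counts)`` consumes a :class:`CountMatrix`
    (aged vs young contrast), after which ``results_`` holds a
    :class:`DiffResult` and ``size_factors_`` the normalization factors.

    Dispersion is method-of-moments on normalized counts, pooled within
    condition, floored at 1e-8; the Wald p-value is on the condition
    coefficient; BH correction runs across unfiltered features only.
    """

    def __init__(self, alpha: float = 0.05, use_batch: bool = False,
                 dispersion_floor: float = DISPERSION_FLOOR):
        self.alpha = alpha
        self.use_batch = use_batch
        self.dispersion_floor = dispersion_floor

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "use_batch": self.use_batch,
                "dispersion_floor": self.dispersion_floor}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def _design(self, meta: pd.DataFrame) -> np.ndarray:
        cond = (meta["condition"] == "aged").astype(float).to_numpy()
        cols = [np.ones(len(meta)), cond]
        if self.use_batch:
            if "batch" not in meta.columns:
                raise DesignError("use_batch=True but metadata has no batch column")
            batches = pd.get_dummies(meta["batch"], drop_first=True).to_numpy(dtype=float)
            for j in range(batches.shape[1]):
                cols.append(batches[:, j])
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError("singular design: batch confounded with condition")
        return X

    def fit(self, counts: CountMatrix, size_factors_: pd.Series | None = None):
        meta = counts.meta
        for cond in ("young", "aged"):
            if len(counts.libraries(cond)) < 2:
                raise DesignError(f"need >=2 replicates in condition {cond!r}")
        sf = size_factors(counts) if size_factors_ is None else size_factors_
        X = self._design(meta)
        cond_col = 1  # condition coefficient position

        tested = ~counts.filtered.to_numpy()
        y_all = counts.counts.to_numpy(dtype=float)
        # degenerate all-zero rows cannot be fitted even if unfiltered
        nonzero = y_all.sum(axis=1) > 0
        run = tested & nonzero

        sfv = sf[counts.counts.columns].to_numpy()
        norm = y_all / sfv
        base_mean = norm.mean(axis=1)

        # method-of-moments dispersion, pooled within condition
        disp = np.full(len(y_all), self.dispersion_floor)
        num = np.zeros(len(y_all))
        den = np.zeros(len(y_all))
        dof = 0
        for cond in ("young", "aged"):
            libs = [counts.counts.columns.get_loc(c) for c in counts.libraries(cond)]
            sub = norm[:, libs]
            m = sub.mean(axis=1)
            v = sub.var(axis=1, ddof=1)
            xim = np.mean(1.0 / sfv[libs])  # Poisson part of Var(y/sf) is mu * mean(1/sf)
            num += (v - m * xim) * (len(libs) - 1)
            den += m**2 * (len(libs) - 1)
            dof += len(libs) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            mom = num / den
        disp = np.where(np.isfinite(mom), np.maximum(mom, self.dispersion_floor),
                        self.dispersion_floor)

        lfc = np.full(len(y_all), np.nan)
        pval = np.full(len(y_all), np.nan)
        if run.any():
            beta, cov, ok = _nb_irls(y_all[run], X, np.log(sfv), disp[run])
            se = np.sqrt(np.maximum(cov[:, cond_col, cond_col], 0))
            with np.errstate(divide="ignore", invalid="ignore"):
                wald = beta[:, cond_col] / se
            # t reference with residual df: the plug-in moment dispersion makes
            # the normal reference anti-conservative at small replicate numbers
            df_resid = max(X.shape[0] - X.shape[1], 1)
            p_run = 2 * stats.t.sf(np.abs(wald), df=df_resid)
            p_run[~ok | ~np.isfinite(wald)] = np.nan
            lfc[run] = beta[:, cond_col] / np.log(2)
            pval[run] = p_run

        padj = np.full(len(y_all), np.nan)
        padj[tested] = bh_adjust(pval[tested])
        table = pd.DataFrame(
            {"baseMean": base_mean, "log2FC": lfc, "p": pval, "padj": padj,
             "filtered": ~tested, "dispersion": disp},
            index=counts.counts.index,
        )
        table.loc[~tested, ["log2FC", "p", "padj"]] = np.nan
        self.size_factors_ = sf
        self.dispersion_ = pd.Series(disp, index=counts.counts.index)
        self.results_ = DiffResult(table)
        return self

    def fit_predict(self, counts: CountMatrix) -> DiffResult:
        return self.fit(counts).results_


def nb_test(counts: CountMatrix, use_batch: bool = False,
            size_factors_: pd.Series | None = None) -> DiffResult:
    """Functional wrapper over :class:`NBDifferentialTest`."""
    return NBDifferentialTest(use_batch=use_batch).fit(counts, size_factors_=size_factors_).results_


def correlation_profile_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed distance: Euclidean distance between rows of the Pearson
    correlation matrix of the features."""
    if profiles.shape[1] < 3:
        raise ValueError("Pearson correlation needs >=3 paired observations")
    corr = np.corrcoef(profiles)
    return pdist(corr, metric="euclidean")


class CorrelationProfileClustering:
    """Complete-linkage clustering on the correlation-profile distance.

    The distance between features i and j is the Euclidean distance between
    their vectors of Pearson correlations to all features; the tree is cut to
    exactly ``n_clusters``.  Constant rows (undefined correlation) are dropped
    with a warning and get label 0.
    """

    def __init__(self, n_clusters: int = 9):
        self.n_clusters = n_clusters

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray | pd.DataFrame):
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
        mat = np.asarray(X, dtype=float)
        const = mat.std(axis=1) == 0
        if const.any():
            warnings.warn(f"dropping {const.sum()} constant row(s): Pearson undefined")
        kept = mat[~const]
        if len(kept) < self.n_clusters:
            raise ValueError("fewer usable features than clusters")
        dist = correlation_profile_distance(kept)
        Z = linkage(dist, method="complete")
        labels_kept = fcluster(Z, t=self.n_clusters, criterion="maxclust")
        labels = np.zeros(len(mat), dtype=int)
        labels[~const] = labels_kept
        self.labels_ = pd.Series(labels, index=index, name="cluster")
        self.linkage_ = Z
        order_kept = leaves_list(Z)
        self.leaf_order_ = index[~const][order_kept]
        return self

    def fit_predict(self, X) -> pd.Series:
        return self.fit(X).labels_


def cluster_profiles(profiles: pd.DataFrame, k: int):
    """Cluster feature profiles; returns (labels Series, dendrogram leaf order)."""
    model = CorrelationProfileClustering(n_clusters=k).fit(profiles)
    return model.labels_, model.leaf_order_
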