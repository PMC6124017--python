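"""Chromatin-state segmentation with a multivariate Bernoulli hidden Markov model.

The genome is tiled into fixed-size bins (200 bp by default), each bin carries
a binary vector over chromatin marks (ATAC, H3K4me3, H3K27ac, H3K27me3, CTCF;
1 iff a peak of that mark overlaps the bin), and a single HMM with
product-Bernoulli emissions is trained jointly on the young and aged tracks so
that both conditions share one emission and one transition matrix.  State
locations are then decoded separately per condition by posterior argmax, the
raw states are collapsed to six interpretable classes, and promoters are
characterised by the base-pair coverage of each class in a 5-kb window around
the TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from . import genome_io
from .diffcounts import cluster_profiles

COLLAPSED_STATES = [
    "polycomb",
    "bivalent",
    "active_promoter",
    "active_regulatory",
    "insulator",
    "background",
]
# fixed tie-break priority for dominant_state (background handled separately)
STATE_PRIORITY = ["polycomb", "bivalent", "active_promoter", "active_regulatory", "insulator"]

DEFAULT_MARKS = ["ATAC", "H3K4me3", "H3K27ac", "H3K27me3", "CTCF"]


@dataclass
class BinaryTracks:
    """Per-bin binary mark matrix for one condition.

    ``bins``: DataFrame (chrom, start, end); ``matrix``: (n_bins, n_marks)
    uint8; ``marks``: ordered mark names.
    """

    bins: pd.DataFrame
    matrix: np.ndarray
    marks: list
    condition: str = ""
    bin_size: int = 200

    def __post_init__(self):
        if self.matrix.shape != (len(self.bins), len(self.marks)):
            raise ValueError("matrix shape does not match bins x marks")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be binary")

    def chrom_lengths(self) -> list:
        """Number of bins per chromosome, in bin order."""
        return [len(g) for _, g in self.bins.groupby("chrom", sort=False)]


def genome_bins(genome: genome_io.Genome, bin_size: int = 200) -> pd.DataFrame:
    rows = []
    for chrom, length in genome.chrom_sizes.items():
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def binarize(peaks_by_mark: dict, genome: genome_io.Genome, bin_size: int = 200,
             condition: str = "") -> BinaryTracks:
    """Binarize peak calls over fixed-size bins: 1 iff any peak overlap."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    bins = genome_bins(genome, bin_size)
    marks = list(peaks_by_mark)
    mat = np.zeros((len(bins), len(marks)), dtype=np.uint8)
    offsets = {}
    pos = 0
    for chrom, grp in bins.groupby("chrom", sort=False):
        offsets[chrom] = (pos, len(grp))
        pos += len(grp)
    for j, mark in enumerate(marks):
        peaks = peaks_by_mark[mark]
        if peaks is None or len(peaks) == 0:
            continue
        genome_io.validate_intervals(peaks, genome)
        for chrom, grp in peaks.groupby("chrom", sort=False):
            off, nb = offsets[chrom]
            lo = np.minimum(grp["start"].to_numpy() // bin_size, nb)
            hi = np.minimum(-(-grp["end"].to_numpy() // bin_size), nb)
            for a, b in zip(lo, hi):
                mat[off + a: off + b, j] = 1
    return BinaryTracks(bins, mat, marks, condition=condition, bin_size=bin_size)


# ---------------------------------------------------------------------------
# HMM kernels (scaled forward-backward; numba-compiled)


@njit(cache=True)
def _fb_accumulate(b, transmat, startprob, symbols, n_symbols):
    """One E-step pass over a single sequence.

    b: (T, K) per-frame emission likelihoods, already rescaled per frame.
    Returns loglik contribution (excluding frame rescale constants),
    trans_num (K, K), start_num (K,), symweight (n_symbols, K), gamma (T, K).
    """
    T, K = b.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    tmp = startprob * b[0]
    c[0] = tmp.sum()
    alpha[0] = tmp / c[0]
    for t in range(1, T):
        for j in range(K):
            s = 0.0
            for i in range(K):
                s += alpha[t - 1, i] * transmat[i, j]
            alpha[t, j] = s * b[t, j]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    trans_num = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        for i in range(K):
            s = 0.0
            for j in range(K):
                v = transmat[i, j] * bb[j]
                s += v
                trans_num[i, j] += alpha[t, i] * v / c[t + 1]
            beta[t, i] = s / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    symweight = np.zeros((n_symbols, K))
    for t in range(T):
        symweight[symbols[t]] += gamma[t]
    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    return loglik, trans_num, gamma[0].copy(), symweight, gamma


@njit(cache=True)
def _posteriors(b, transmat, startprob):
    """Scaled forward-backward posteriors for one sequence."""
    T, K = b.shape
    alpha = np.empty((T, K))
    c = np.empty(T)
    tmp = startprob * b[0]
    c[0] = tmp.sum()
    alpha[0] = tmp / c[0]
    for t in range(1, T):
        for j in range(K):
            s = 0.0
            for i in range(K):
                s += alpha[t - 1, i] * transmat[i, j]
            alpha[t, j] = s * b[t, j]
        c[t] = alpha[t].sum()
        alpha[t] /= c[t]
    beta = np.empty((T, K))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        bb = b[t + 1] * beta[t + 1]
        for i in range(K):
            s = 0.0
            for j in range(K):
                s += transmat[i, j] * bb[j]
            beta[t, i] = s / c[t + 1]
    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()
    loglik = np.log(c).sum()
    return gamma, loglik


@njit(cache=True)
def _viterbi(logb, logA, logstart):
    T, K = logb.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    delta[0] = logstart + logb[0]
    for t in range(1, T):
        for j in range(K):
            best = -1e300
            arg = 0
            for i in range(K):
                v = delta[t - 1, i] + logA[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + logb[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = np.argmax(delta[T - 1])
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


def _encode_symbols(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pack binary mark vectors into integer symbols; also return the
    (n_symbols, n_marks) bit table."""
    M = X.shape[1]
    weights = (1 << np.arange(M)).astype(np.int64)
    symbols = X.astype(np.int64) @ weights
    bits = ((np.arange(1 << M)[:, None] >> np.arange(M)) & 1).astype(float)
    return symbols, bits


class BernoulliHMM:
    """Hidden Markov model with independent Bernoulli emissions per mark.

    sklearn-style estimator: ``fit(X, lengths)`` trains by Baum-Welch EM with
    random restarts, ``predict_proba`` gives per-bin posterior state
    probabilities, ``predict`` decodes by posterior argmax (``decode="map"``,
    the chromHMM convention) or Viterbi (``decode="viterbi"``).

    Parameters
    ----------
    n_states : number of hidden chromatin states.
    n_iter, tol : EM stops when the relative log-likelihood improvement drops
        below ``tol`` (default 1e-6) or after ``n_iter`` iterations.
    n_restarts : EM runs from this many random initializations; the
        best-likelihood run wins.
    sticky : initial self-transition mass, controls the expected segment
        length at initialization only.

    Attributes (after fit)
    ----------------------
    emission_ : (n_states, n_marks) Bernoulli probabilities.
    transmat_ : (n_states, n_states) row-stochastic transition matrix.
    startprob_ : initial state distribution.
    loglik_trace_ : per-iteration log-likelihood of the winning restart
        (nondecreasing).
    """

    _EPS = 1e-10

    def __init__(self, n_states: int = 16, n_iter: int = 500, tol: float = 1e-6,
                 n_restarts: int = 1, sticky: float = 0.9, random_state: int | None = None):
        self.n_states = n_states
        self.n_iter = n_iter
        self.tol = tol
        self.n_restarts = n_restarts
        self.sticky = sticky
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("n_states", "n_iter", "tol", "n_restarts", "sticky", "random_state")}

    def set_params(self, **params):
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _split(arr, lengths):
        if lengths is None:
            return [arr]
        out = []
        pos = 0
        for ln in lengths:
            out.append(arr[pos: pos + ln])
            pos += ln
        if pos != len(arr):
            raise ValueError("lengths do not sum to the number of rows")
        return out

    def _frame_likelihoods(self, symbols, emission, bits):
        # per-symbol per-state likelihood, then gather per frame
        p = np.clip(emission, self._EPS, 1 - self._EPS)
        logtab = bits @ np.log(p).T + (1 - bits) @ np.log(1 - p).T  # (S, K)
        logb = logtab[symbols]
        shift = logb.max(axis=1)
        return np.exp(logb - shift[:, None]), shift.sum(), logtab

    def _init_params(self, rng, n_marks):
        K = self.n_states
        emission = rng.uniform(0.1, 0.9, size=(K, n_marks))
        A = rng.dirichlet(np.ones(K), size=K) * (1 - self.sticky)
        A[np.arange(K), np.arange(K)] += self.sticky
        A /= A.sum(axis=1, keepdims=True)
        start = np.full(K, 1.0 / K)
        return emission, A, start

    def _em_run(self, seq_syms, bits, rng):
        n_marks = int(round(np.log2(bits.shape[0])))
        emission, A, start = self._init_params(rng, n_marks)
        trace = []
        prev = -np.inf
        for _ in range(self.n_iter):
            loglik = 0.0
            trans_num = np.zeros_like(A)
            start_num = np.zeros_like(start)
            symweight = np.zeros((bits.shape[0], self.n_states))
            for syms in seq_syms:
                b, shift, _ = self._frame_likelihoods(syms, emission, bits)
                ll, tn, g0, sw, _ = _fb_accumulate(b, A, start, syms, bits.shape[0])
                loglik += ll + shift
                trans_num += tn
                start_num += g0
                symweight += sw
            trace.append(loglik)
            # M-step
            occ = symweight.sum(axis=0)  # expected state occupancy
            emission = (symweight.T @ bits) / np.maximum(occ[:, None], self._EPS)
            rowsum = trans_num.sum(axis=1, keepdims=True)
            A = np.where(rowsum > 0, trans_num / np.maximum(rowsum, self._EPS), A)
            A /= A.sum(axis=1, keepdims=True)
            start = start_num / start_num.sum()
            if np.isfinite(prev) and (loglik - prev) < self.tol * abs(prev):
                break
            prev = loglik
        return emission, A, start, np.asarray(trace)

    # -- public API --------------------------------------------------------

    def fit(self, X: np.ndarray, lengths=None):
        X = np.ascontiguousarray(np.asarray(X, dtype=np.uint8))
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("X must be a non-empty (n_bins, n_marks) binary matrix")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        symbols, bits = _encode_symbols(X)
        seq_syms = self._split(symbols, lengths)
        if X.min() == X.max() and self.n_states > 1:
            warnings.warn("all bins identical: states are unidentifiable")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(max(1, self.n_restarts)):
            em, A, start, trace = self._em_run(seq_syms, bits, rng)
            if best is None or trace[-1] > best[3][-1]:
                best = (em, A, start, trace)
        self.emission_, self.transmat_, self.startprob_, self.loglik_trace_ = best
        self.n_marks_ = X.shape[1]
        self._bits = bits
        return self

    def _check_fitted(self):
        if not hasattr(self, "emission_"):
            raise RuntimeError("model is not fitted")

    def predict_proba(self, X: np.ndarray, lengths=None) -> np.ndarray:
        """Posterior state probabilities per bin (forward-backward)."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.uint8)
        if X.shape[1] != self.n_marks_:
            raise ValueError("mark count mismatch with fitted model")
        symbols, bits = _encode_symbols(X)
        out = []
        for syms in self._split(symbols, lengths):
            b, _, _ = self._frame_likelihoods(syms, self.emission_, bits)
            gamma, _ = _posteriors(b, self.transmat_, self.startprob_)
            out.append(gamma)
        return np.vstack(out)

    def predict(self, X: np.ndarray, lengths=None, decode: str = "map") -> np.ndarray:
        """Per-bin state labels by posterior argmax (default) or Viterbi."""
        self._check_fitted()
        if decode == "map":
            return self.predict_proba(X, lengths).argmax(axis=1)
        if decode != "viterbi":
            raise ValueError("decode must be 'map' or 'viterbi'")
        X = np.asarray(X, dtype=np.uint8)
        symbols, bits = _encode_symbols(X)
        p = np.clip(self.emission_, self._EPS, 1 - self._EPS)
        logtab = bits @ np.log(p).T + (1 - bits) @ np.log(1 - p).T
        logA = np.log(np.maximum(self.transmat_, self._EPS))
        logstart = np.log(np.maximum(self.startprob_, self._EPS))
        return np.concatenate(
            [_viterbi(logtab[s], logA, logstart) for s in self._split(symbols, lengths)]
        )

    def score(self, X: np.ndarray, lengths=None) -> float:
        """Total log-likelihood of the data under the fitted model."""
        self._check_fitted()
        symbols, bits = _encode_symbols(np.asarray(X, dtype=np.uint8))
        total = 0.0
        for syms in self._split(symbols, lengths):
            b, shift, _ = self._frame_likelihoods(syms, self.emission_, bits)
            _, ll = _posteriors(b, self.transmat_, self.startprob_)
            total += ll + shift
        return total


def fit_hmm(young: BinaryTracks, aged: BinaryTracks, n_states: int = 16,
            seed: int | None = None, tol: float = 1e-6, max_iter: int = 500,
            n_restarts: int = 1) -> BernoulliHMM:
    """Train one shared HMM on the concatenated young + aged tracks.

    Chromosome and condition boundaries break transitions (each chromosome of
    each condition is an independent sequence).
    """
    if young.marks != aged.marks:
        raise ValueError("mark sets differ between conditions")
    X = np.vstack([young.matrix, aged.matrix])
    lengths = young.chrom_lengths() + aged.chrom_lengths()
    model = BernoulliHMM(n_states=n_states, n_iter=max_iter, tol=tol,
                         n_restarts=n_restarts, random_state=seed)
    return model.fit(X, lengths)


def model_selection(young: BinaryTracks, aged: BinaryTracks, state_range,
                    seed: int | None = None, **fit_kw) -> pd.DataFrame:
    """Log-likelihood and BIC across candidate state counts; the choice of
    n_states is left to the user."""
    X = np.vstack([young.matrix, aged.matrix])
    lengths = young.chrom_lengths() + aged.chrom_lengths()
    n_obs = len(X)
    rows = []
    for n in state_range:
        m = BernoulliHMM(n_states=n, random_state=seed, **fit_kw).fit(X, lengths)
        ll = m.loglik_trace_[-1]
        n_par = n * X.shape[1] + n * (n - 1) + (n - 1)
        rows.append((n, ll, -2 * ll + n_par * np.log(n_obs)))
    return pd.DataFrame(rows, columns=["n_states", "loglik", "bic"])


@dataclass
class Segmentation:
    """Per-bin raw and collapsed state labels for one condition."""

    bins: pd.DataFrame
    raw_states: np.ndarray
    collapsed: np.ndarray  # strings from COLLAPSED_STATES
    condition: str = ""
    bin_size: int = 200

    def to_bed(self, path) -> None:
        df = self.bins.copy()
        df["name"] = self.collapsed
        genome_io.write_bed(df, path, columns=["chrom", "start", "end", "name"])


def default_collapse_mapping(emission: np.ndarray, marks: list) -> dict:
    """Heuristic raw-state -> collapsed-state mapping keyed on emissions.

    H3K4me3 with H3K27me3 -> bivalent; H3K4me3 alone -> active promoter;
    H3K27me3 -> polycomb; H3K27ac or ATAC without promoter marks -> active
    regulatory; CTCF-dominant -> insulator; quiet states -> background.
    Intended for synthetic runs; real analyses should supply a curated table.
    """
    idx = {m: marks.index(m) for m in marks}
    mapping = {}
    for k in range(emission.shape[0]):
        e = emission[k]
        hi = e > 0.5
        k4 = "H3K4me3" in idx and hi[idx["H3K4me3"]]
        k27me = "H3K27me3" in idx and hi[idx["H3K27me3"]]
        k27ac = "H3K27ac" in idx and hi[idx["H3K27ac"]]
        atac = "ATAC" in idx and hi[idx["ATAC"]]
        ctcf = "CTCF" in idx and hi[idx["CTCF"]]
        if k4 and k27me:
            mapping[k] = "bivalent"
        elif k4:
            mapping[k] = "active_promoter"
        elif k27me:
            mapping[k] = "polycomb"
        elif k27ac or atac:
            mapping[k] = "active_regulatory"
        elif ctcf:
            mapping[k] = "insulator"
        else:
            mapping[k] = "background"
    return mapping


def segment(model: BernoulliHMM, tracks: BinaryTracks, collapse: dict,
            decode: str = "map") -> Segmentation:
    """Decode one condition's tracks and collapse raw states.

    ``collapse`` must map every raw state index to a collapsed state name.
    """
    if tracks.marks is not None and len(tracks.marks) != model.n_marks_:
        raise ValueError("mark mismatch between model and tracks")
    missing = set(range(model.n_states)) - set(collapse)
    if missing:
        raise ValueError(f"collapse mapping misses raw states {sorted(missing)}")
    bad = set(collapse.values()) - set(COLLAPSED_STATES)
    if bad:
        raise ValueError(f"unknown collapsed states {sorted(bad)}")
    raw = model.predict(tracks.matrix, lengths=tracks.chrom_lengths(), decode=decode)
    lut = np.array([collapse[k] for k in range(model.n_states)], dtype=object)
    return Segmentation(tracks.bins, raw, lut[raw], condition=tracks.condition,
                        bin_size=tracks.bin_size)


def state_coverage(seg: Segmentation, region: pd.Series | dict) -> pd.Series:
    """Base-pair coverage of each collapsed state within a region."""
    chrom, start, end = region["chrom"], int(region["start"]), int(region["end"])
    mask = (seg.bins["chrom"] == chrom).to_numpy()
    bs = seg.bins["start"].to_numpy()[mask]
    be = seg.bins["end"].to_numpy()[mask]
    states = seg.collapsed[mask]
    ov = np.minimum(be, end) - np.maximum(bs, start)
    sel = ov > 0
    cov = pd.Series(0, index=COLLAPSED_STATES, dtype=int)
    for st, o in zip(states[sel], ov[sel]):
        cov[st] += int(o)
    return cov


def dominant_state(seg: Segmentation, region) -> tuple[str, pd.Series]:
    """Dominant collapsed state of a region.

    The state with the largest bp coverage wins; background wins only when no
    other state covers any base.  Ties break by a fixed priority
    (polycomb > bivalent > active promoter > active regulatory > insulator).
    """
    cov = state_coverage(seg, region)
    nonbg = cov[STATE_PRIORITY]
    if nonbg.sum() == 0:
        return "background", cov
    best = nonbg.max()
    for st in STATE_PRIORITY:  # priority order resolves ties
        if nonbg[st] == best:
            return st, cov
    raise AssertionError("unreachable")


def promoter_state_coverage(seg: Segmentation, promoters: pd.DataFrame) -> pd.DataFrame:
    """State coverage (bp) of every promoter window; rows = gene_id."""
    rows = {}
    for _, prom in promoters.iterrows():
        rows[prom["gene_id"]] = state_coverage(seg, prom)
    return pd.DataFrame.from_dict(rows, orient="index", columns=COLLAPSED_STATES)


def occupancy_change_clusters(young_seg: Segmentation, aged_seg: Segmentation,
                              promoters: pd.DataFrame, expression=None,
                              top_frac: float = 0.005, k: int = 9):
    """Promoter occupancy-change selection and clustering.

    Delta-bp(state, promoter) = aged - young coverage over the promoter
    window.  Promoters in the top ``top_frac`` for increase or decrease of
    any non-background state are selected; their delta profiles are
    mean-centered per state and clustered (correlation distance, complete
    linkage, cut at ``k``).  Returns a dict with the selected delta matrix,
    cluster labels, leaf order and per-cluster expression log2FC.
    """
    young_cov = promoter_state_coverage(young_seg, promoters)
    aged_cov = promoter_state_coverage(aged_seg, promoters)
    delta = aged_cov - young_cov
    nonbg = delta[STATE_PRIORITY]
    n = len(delta)
    n_top = max(int(np.ceil(top_frac * n)), 1)
    selected = pd.Index([])
    for st in STATE_PRIORITY:
        col = nonbg[st]
        inc = col[col > 0].nlargest(n_top)
        dec = col[col < 0].nsmallest(n_top)
        selected = selected.union(inc.index).union(dec.index)
    result = {"delta": delta, "selected": selected}
    if len(selected) == 0:
        result.update(labels=pd.Series(dtype=int), centered=delta.loc[selected])
        return result
    if len(selected) < k:
        raise ValueError(f"only {len(selected)} selected promoters; choose k < that")
    centered = delta.loc[selected] - delta.loc[selected].mean(axis=0)
    if k == 1:
        labels = pd.Series(1, index=selected, name="cluster")
        result.update(labels=labels, leaf_order=selected, centered=centered)
    else:
        labels, order = cluster_profiles(centered, k)
        result.update(labels=labels, leaf_order=order, centered=centered)
    if expression is not None:
        tab = expression.table if hasattr(expression, "table") else expression
        lfc = tab["log2FC"].reindex(selected)
        result["cluster_expression"] = pd.DataFrame(
            {"cluster": labels, "log2FC": lfc}
        ).groupby("cluster")["log2FC"].describe()
    return result


def tss_overlap(elements: pd.DataFrame, genes: pd.DataFrame, radius: int = 1000) -> np.ndarray:
    """True per element iff it lies within ``radius`` of any annotated TSS."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    genes = genes if "tss" in genes.columns else genome_io.add_tss(genes)
    # an element overlaps iff [start, end) intersects [tss - radius, tss + radius]
    tss_windows = pd.DataFrame(
        {"chrom": genes["chrom"], "start": np.maximum(genes["tss"] - radius, 0),
         "end": genes["tss"] + radius + 1}
    )
    return genome_io.overlaps_any(elements, tss_windows)
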