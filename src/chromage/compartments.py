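"""Hi-C matrix balancing, A/B compartment scores, and compartment-switch calls.

Compartments are read from the sign of the first principal component of the
Pearson correlation matrix of the distance-normalised (observed/expected)
balanced contact map, computed per chromosome at 250-kb resolution.  The sign
is oriented so that bins with higher H3K4me3 enrichment (the active, A
compartment) score positive.  Age-related switches are called per bin from
replicate compartment scores by one-way ANOVA combined with a standardized
mean change filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffcounts import bh_adjust


@dataclass
class ContactMatrix:
    """Symmetric binned contact counts for one chromosome / one replicate."""

    chrom: str
    bin_size: int
    matrix: np.ndarray
    mask: np.ndarray | None = None  # True = valid bin
    bias: np.ndarray | None = None
    balanced: bool = False

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T):
            raise ValueError("contact matrix must be symmetric")
        if (m < 0).any():
            raise ValueError("negative contact counts")
        self.matrix = m
        if self.mask is None:
            self.mask = np.ones(len(m), dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.matrix)


def contacts_to_triplets(cm: ContactMatrix) -> pd.DataFrame:
    """Upper-triangle triplet representation (chrom, bin_i, bin_j, count)."""
    iu = np.triu_indices(cm.n_bins)
    counts = cm.matrix[iu]
    keep = counts > 0
    return pd.DataFrame(
        {"chrom": cm.chrom, "bin_i": iu[0][keep], "bin_j": iu[1][keep], "count": counts[keep]}
    )


def triplets_to_contacts(df: pd.DataFrame, chrom: str, n_bins: int, bin_size: int) -> ContactMatrix:
    sub = df[df["chrom"] == chrom]
    m = np.zeros((n_bins, n_bins))
    i = sub["bin_i"].to_numpy(int)
    j = sub["bin_j"].to_numpy(int)
    m[i, j] = sub["count"].to_numpy(float)
    m[j, i] = m[i, j]
    return ContactMatrix(chrom, bin_size, m)


class IterativeCorrection:
    """Matrix balancing by iterative proportional fitting (ICE).

    sklearn-style transformer over square symmetric count matrices: low
    coverage bins (row sum below ``mask_quantile`` of the nonzero row sums)
    are masked, then biases are updated until every valid row sum is within
    ``tol`` (relative) of their common mean.  The corrected matrix is
    raw / (bias_i * bias_j).
    """

    def __init__(self, tol: float = 1e-5, max_iter: int = 200, mask_quantile: float = 0.02):
        self.tol = tol
        self.max_iter = max_iter
        self.mask_quantile = mask_quantile

    def get_params(self, deep: bool = True) -> dict:
        return {"tol": self.tol, "max_iter": self.max_iter, "mask_quantile": self.mask_quantile}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def transform(self, cm: ContactMatrix) -> ContactMatrix:
        m = cm.matrix
        if cm.n_bins < 10 or (m.sum(axis=1) > 0).sum() < 10:
            raise ValueError("need >=10 valid bins to balance")
        rowsum = m.sum(axis=1)
        nonzero = rowsum > 0
        cutoff = np.quantile(rowsum[nonzero], self.mask_quantile)
        mask = nonzero & (rowsum >= cutoff) & cm.mask
        bias = np.ones(cm.n_bins)
        work = m[np.ix_(mask, mask)].copy()
        b = np.ones(mask.sum())
        converged = False
        for _ in range(self.max_iter):
            s = work.sum(axis=1)
            target = s.mean()
            if np.abs(s - target).max() <= self.tol * target:
                converged = True
                break
            adj = s / target
            adj[s == 0] = 1.0
            work /= np.multiply.outer(adj, adj)  # exactly symmetric update
            b *= adj
        if not converged:
            warnings.warn("ICE did not converge; returning partial result")
        bias[mask] = b
        bias[~mask] = 0.0
        corrected = np.zeros_like(m)
        corrected[np.ix_(mask, mask)] = work
        out = ContactMatrix(cm.chrom, cm.bin_size, corrected, mask=mask, bias=bias,
                            balanced=True)
        out.converged = converged
        return out

    fit_transform = transform


def ice_normalize(cm: ContactMatrix, tol: float = 1e-5, max_iter: int = 200,
                  mask_quantile: float = 0.02) -> ContactMatrix:
    """Functional wrapper over :class:`IterativeCorrection`."""
    return IterativeCorrection(tol, max_iter, mask_quantile).transform(cm)


def observed_over_expected(cm: ContactMatrix) -> np.ndarray:
    """Distance-normalise a balanced matrix: divide each diagonal by its mean
    over valid bin pairs; distances beyond the last valid diagonal reuse the
    last valid mean."""
    n = cm.n_bins
    mask = cm.mask
    oe = np.zeros_like(cm.matrix)
    last = 1.0
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        valid = mask[i] & mask[j]
        vals = cm.matrix[i[valid], j[valid]]
        mean = vals.mean() if valid.any() and np.isfinite(vals.mean()) else np.nan
        if not np.isfinite(mean) or mean == 0:
            mean = last
        last = mean
        oe[i, j] = cm.matrix[i, j] / mean
        oe[j, i] = oe[i, j]
    return oe


@dataclass
class CompartmentTrack:
    """Per-bin signed compartment score for one chromosome/condition."""

    chrom: str
    bin_size: int
    score: np.ndarray
    mask: np.ndarray
    condition: str = ""
    flipped: bool = False  # whether PC1 was negated by the H3K4me3 rule
    replicate_scores: np.ndarray | None = None  # (n_replicates, n_bins)

    def to_bedgraph(self, path) -> None:
        starts = np.arange(len(self.score)) * self.bin_size
        df = pd.DataFrame({"chrom": self.chrom, "start": starts,
                           "end": starts + self.bin_size, "score": self.score})
        df[self.mask].to_csv(path, sep="\t", header=False, index=False)


def compartment_score(balanced: ContactMatrix, h3k4me3: np.ndarray,
                      condition: str = "") -> CompartmentTrack:
    """A/B compartment score: PC1 of the O/E correlation matrix, sign-oriented
    so that bins with higher mean H3K4me3 enrichment are positive."""
    if not balanced.balanced:
        raise ValueError("matrix must be ICE-balanced first")
    mask = balanced.mask.copy()
    if mask.sum() < 10:
        raise ValueError("chromosome has <10 valid bins")
    oe = observed_over_expected(balanced)
    sub = oe[np.ix_(mask, mask)]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    # bins with zero variance in their O/E profile give NaN rows; drop them
    bad = ~np.isfinite(corr).all(axis=1)
    if bad.any():
        keep = ~bad
        idx = np.flatnonzero(mask)
        mask = mask.copy()
        mask[idx[bad]] = False
        corr = corr[np.ix_(keep, keep)]
    vals, vecs = np.linalg.eigh(corr)
    pc1 = vecs[:, -1]
    score = np.zeros(balanced.n_bins)
    score[mask] = pc1
    h3k = np.asarray(h3k4me3, dtype=float)
    pos = mask & (score > 0)
    neg = mask & (score < 0)
    flipped = False
    if pos.any() and neg.any() and np.nanmean(h3k[neg]) > np.nanmean(h3k[pos]):
        score = -score
        flipped = True
    return CompartmentTrack(balanced.chrom, balanced.bin_size, score, mask,
                            condition=condition, flipped=flipped)


CALL_TYPES = ["none", "shift+", "shift-", "A->B", "B->A"]


def diff_compartments(young: list[CompartmentTrack] | np.ndarray,
                      aged: list[CompartmentTrack] | np.ndarray,
                      p_threshold: float = 0.05, z_threshold: float = 3.0,
                      standardize: str = "se_shared") -> pd.DataFrame:
    """Per-bin compartment-switch calls from replicate score tracks.

    A bin is flagged iff the one-way ANOVA of young vs aged replicate scores
    gives unadjusted p < ``p_threshold`` AND the standardized mean change
    exceeds ``z_threshold``.  Flagged bins whose means straddle zero are
    A->B / B->A; otherwise the sign of the change gives shift+ / shift-.

    ``standardize`` selects the divisor of |mean_aged - mean_young|:

    - ``"se_shared"`` (default): the standard error of the mean change with
      the within-group variance pooled genome-wide (compartment-score noise
      is treated as homoscedastic across bins), i.e. a z-score of the change;
    - ``"sd_bin"``: the per-bin pooled within-group SD.
    """
    ys = np.vstack([t.score for t in young]) if not isinstance(young, np.ndarray) else young
    as_ = np.vstack([t.score for t in aged]) if not isinstance(aged, np.ndarray) else aged
    if ys.shape[0] < 2 or as_.shape[0] < 2:
        raise ValueError("need >=2 replicates per age")
    if ys.shape[1] != as_.shape[1]:
        raise ValueError("replicate tracks must cover identical bins")
    mask = np.ones(ys.shape[1], dtype=bool)
    if not isinstance(young, np.ndarray):
        for t in list(young) + list(aged):
            mask &= t.mask
    n_bins = ys.shape[1]
    my, ma = ys.mean(axis=0), as_.mean(axis=0)
    ny, na = ys.shape[0], as_.shape[0]
    ssw = ys.var(axis=0, ddof=1) * (ny - 1) + as_.var(axis=0, ddof=1) * (na - 1)
    pooled_var = ssw / (ny + na - 2)
    delta = ma - my
    if standardize == "se_shared":
        divisor = np.full_like(delta, np.sqrt(pooled_var[mask].mean() * (1 / ny + 1 / na)))
    elif standardize == "sd_bin":
        divisor = np.sqrt(pooled_var)
    else:
        raise ValueError("standardize must be 'se_shared' or 'sd_bin'")
    with np.errstate(divide="ignore", invalid="ignore"):
        std_change = np.abs(delta) / divisor
    inf_change = (divisor == 0) & (delta != 0)
    std_change[inf_change] = np.inf
    pvals = np.full(n_bins, np.nan)
    for b in np.flatnonzero(mask):
        if ys[:, b].var() == 0 and as_[:, b].var() == 0:
            pvals[b] = 1.0 if delta[b] == 0 else 0.0
        else:
            pvals[b] = stats.f_oneway(ys[:, b], as_[:, b]).pvalue
    flagged = mask & (pvals < p_threshold) & (std_change > z_threshold)
    call = np.array(["none"] * n_bins, dtype=object)
    up = flagged & (delta > 0)
    dn = flagged & (delta < 0)
    call[up] = np.where((my[up] < 0) & (ma[up] > 0), "B->A", "shift+")
    call[dn] = np.where((my[dn] > 0) & (ma[dn] < 0), "A->B", "shift-")
    return pd.DataFrame(
        {"bin": np.arange(n_bins), "mean_young": my, "mean_aged": ma,
         "std_change": std_change, "p": pvals, "call": call, "valid": mask}
    )


def expression_trend_by_call(calls: pd.DataFrame, genes: pd.DataFrame,
                             expression, chrom: str, bin_size: int) -> dict:
    """Expression log2FC of genes in bins shifting up vs down, with ANOVA p.

    Mirrors the comparison of gene expression trends across compartment-shift
    directions: each gene is assigned to the bin containing its TSS.
    """
    from . import genome_io as gio

    tab = expression.table if hasattr(expression, "table") else expression
    genes = genes if "tss" in genes.columns else gio.add_tss(genes)
    sub = genes[genes["chrom"] == chrom]
    bins = (sub["tss"].to_numpy() // bin_size).astype(int)
    lfc = tab["log2FC"].reindex(sub["gene_id"]).to_numpy()
    call_of_gene = calls["call"].to_numpy()[np.clip(bins, 0, len(calls) - 1)]
    groups = {}
    for lbl, direction in (("up", ("shift+", "B->A")), ("down", ("shift-", "A->B"))):
        sel = np.isin(call_of_gene, direction) & np.isfinite(lfc)
        groups[lbl] = lfc[sel]
    out = {"up_lfc": groups["up"], "down_lfc": groups["down"], "p": np.nan}
    if len(groups["up"]) >= 2 and len(groups["down"]) >= 2:
        out["p"] = stats.f_oneway(groups["up"], groups["down"]).pvalue
    return out


def calls_to_bed(calls: pd.DataFrame, chrom: str, bin_size: int) -> pd.DataFrame:
    flagged = calls[calls["call"] != "none"]
    return pd.DataFrame(
        {"chrom": chrom, "start": flagged["bin"] * bin_size,
         "end": (flagged["bin"] + 1) * bin_size, "name": flagged["call"]}
    )


def bh_adjust_calls(pvals: np.ndarray) -> np.ndarray:
    """BH adjustment helper (exposed for symmetry; switch calls themselves are
    made on unadjusted p by design)."""
    return bh_adjust(pvals)
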