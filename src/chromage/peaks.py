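"""Consensus peak construction, filtering, peak-gene assignment, and the
fold-change comparisons across datasets and gene categories.

Consensus is by per-base voting: a genomic base belongs to a consensus peak
when it is covered by peaks in at least ``min_support`` replicates; runs of
such bases closer than ``merge_gap`` are merged.  Replicate-level peaks are
merged within each replicate first so that each replicate votes at most once
per base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import genome_io
from .diffcounts import CountMatrix, bh_adjust, size_factors

ASSAY_MIN_READS = {"CTCF": 32}
DEFAULT_MIN_READS = 64


@dataclass
class PeakSet:
    """Non-overlapping consensus intervals for one assay/condition."""

    intervals: pd.DataFrame
    assay: str = ""
    condition: str = "union"
    n_replicates: int | None = None

    def __post_init__(self):
        self.intervals = genome_io.sort_intervals(
            genome_io.validate_intervals(self.intervals))
        ivl = self.intervals
        for chrom, grp in ivl.groupby("chrom", sort=False):
            if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping intervals on {chrom}")

    def __len__(self):
        return len(self.intervals)


def merge_intervals(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge intervals closer than ``gap`` (gap=0 merges touching/overlapping)."""
    if len(df) == 0:
        return df.copy()
    df = genome_io.sort_intervals(df)
    rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        cs, ce = s[0], e[0]
        for i in range(1, len(s)):
            if s[i] - ce < gap or s[i] <= ce:
                ce = max(ce, e[i])
            else:
                rows.append((chrom, cs, ce))
                cs, ce = s[i], e[i]
        rows.append((chrom, cs, ce))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def consensus_peaks(replicate_peaks: list, min_support: int = 3, merge_gap: int = 100,
                    assay: str = "", condition: str = "") -> PeakSet:
    """Base-pair-voting consensus over replicate peak sets.

    Positions covered by >= ``min_support`` replicate sets form candidate
    intervals; candidates separated by < ``merge_gap`` bp are merged.
    Support recorded per consensus peak is the maximum vote reached inside it.
    """
    if min_support > len(replicate_peaks):
        raise ValueError("min_support exceeds the number of replicates")
    merged_reps = [merge_intervals(p) for p in replicate_peaks]
    events = {}
    for rep in merged_reps:
        for chrom, grp in rep.groupby("chrom", sort=False):
            ev = events.setdefault(chrom, [])
            for s, e in zip(grp["start"], grp["end"]):
                ev.append((s, 1))
                ev.append((e, -1))
    rows = []
    for chrom, ev in sorted(events.items()):
        ev.sort()
        depth = 0
        open_start = None
        peak_max = 0
        i = 0
        while i < len(ev):
            pos = ev[i][0]
            while i < len(ev) and ev[i][0] == pos:
                depth += ev[i][1]
                i += 1
            if depth >= min_support and open_start is None:
                open_start = pos
                peak_max = depth
            elif open_start is not None:
                if depth >= min_support:
                    peak_max = max(peak_max, depth)
                else:
                    rows.append((chrom, open_start, pos, peak_max))
                    open_start = None
    cand = pd.DataFrame(rows, columns=["chrom", "start", "end", "support"])
    if len(cand) == 0:
        return PeakSet(pd.DataFrame(columns=["chrom", "start", "end", "support"]),
                       assay=assay, condition=condition, n_replicates=len(replicate_peaks))
    merged = merge_intervals(cand, gap=merge_gap)
    # recompute support as the max vote within each merged interval
    pairs = genome_io.overlaps(merged, cand)
    support = np.zeros(len(merged), dtype=int)
    for ia, ib in zip(pairs["idx_a"], pairs["idx_b"]):
        support[ia] = max(support[ia], cand["support"].iloc[ib])
    merged["support"] = support
    merged["name"] = [f"{assay or 'peak'}_{condition or 'x'}_{i}" for i in range(len(merged))]
    return PeakSet(merged, assay=assay, condition=condition,
                   n_replicates=len(replicate_peaks))


def union_peaks(a: PeakSet, b: PeakSet, merge_gap: int = 100) -> PeakSet:
    """Pool two condition peak sets into one genome-wide union set."""
    pooled = pd.concat([a.intervals[["chrom", "start", "end"]],
                        b.intervals[["chrom", "start", "end"]]], ignore_index=True)
    merged = merge_intervals(pooled, gap=merge_gap)
    merged["name"] = [f"{a.assay or 'peak'}_union_{i}" for i in range(len(merged))]
    return PeakSet(merged, assay=a.assay, condition="union")


def filter_peaks(peaks: PeakSet, counts: CountMatrix | None = None,
                 min_total: int | None = None, blacklist: pd.DataFrame | None = None) -> PeakSet:
    """Drop peaks with too few total reads or any blacklist overlap.

    ``min_total`` defaults to 64 reads, or 32 when ``peaks.assay == "CTCF"``.
    Count rows are matched to peaks by the ``name`` column.
    """
    ivl = peaks.intervals.copy()
    keep = np.ones(len(ivl), dtype=bool)
    if counts is not None:
        thr = min_total if min_total is not None else ASSAY_MIN_READS.get(
            peaks.assay, DEFAULT_MIN_READS)
        missing = set(ivl["name"]) - set(counts.counts.index)
        if missing:
            raise ValueError(f"{len(missing)} peak(s) missing from the count matrix")
        totals = counts.counts.sum(axis=1).reindex(ivl["name"]).to_numpy()
        keep &= totals >= thr
    if blacklist is not None and len(blacklist):
        keep &= ~genome_io.overlaps_any(ivl, blacklist)
    return PeakSet(ivl[keep].reset_index(drop=True), assay=peaks.assay,
                   condition=peaks.condition, n_replicates=peaks.n_replicates)


@dataclass
class PeakGeneMap:
    """Peak -> gene assignment with a gene-expression category per peak."""

    assignments: pd.DataFrame  # peak name, gene_id
    categories: pd.Series  # peak name -> {up, down, unchanged-only, ambiguous}


def gene_categories(deg, alpha: float = 0.05, contaminant_genes=()) -> pd.Series:
    """up/down/unchanged per gene; flagged contaminants are dropped from up."""
    tab = deg.table if hasattr(deg, "table") else deg
    sig = (tab["padj"] < alpha).fillna(False)
    cat = pd.Series("unchanged", index=tab.index, dtype=object)
    cat[sig & (tab["log2FC"] > 0)] = "up"
    cat[sig & (tab["log2FC"] < 0)] = "down"
    cat[cat.index.isin(list(contaminant_genes)) & (cat == "up")] = "excluded"
    return cat


def assign_peaks_to_genes(peaks: PeakSet, genes: pd.DataFrame, deg=None,
                          flank: int = 1000, contaminant_genes=()) -> PeakGeneMap:
    """Assign each peak to genes whose body +- ``flank`` it overlaps.

    The peak's category is "up"/"down" when it overlaps any significantly up-
    or downregulated gene's window, "unchanged-only" when it overlaps only
    genes without significant change, "ambiguous" (excluded from category
    statistics, with a warning) when it overlaps both an up and a down gene.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    windows = pd.DataFrame(
        {"chrom": genes["chrom"], "start": np.maximum(genes["start"] - flank, 0),
         "end": genes["end"] + flank, "gene_id": genes["gene_id"]}
    )
    pairs = genome_io.overlaps(peaks.intervals, windows)
    assign = pd.DataFrame(
        {"peak": peaks.intervals["name"].to_numpy()[pairs["idx_a"]],
         "gene_id": windows["gene_id"].to_numpy()[pairs["idx_b"]]}
    )
    categories = pd.Series(dtype=object)
    if deg is not None:
        tab = deg.table if hasattr(deg, "table") else deg
        unknown = set(assign["gene_id"]) - set(tab.index) - set(genes["gene_id"])
        if unknown:
            raise ValueError(f"DEG table references unknown genes: {sorted(unknown)[:5]}")
        gcat = gene_categories(deg, contaminant_genes=contaminant_genes)
        cats = {}
        for peak, grp in assign.groupby("peak"):
            pcats = set(gcat.reindex(grp["gene_id"]).fillna("unchanged"))
            pcats.discard("excluded")
            if "up" in pcats and "down" in pcats:
                cats[peak] = "ambiguous"
            elif "up" in pcats:
                cats[peak] = "up"
            elif "down" in pcats:
                cats[peak] = "down"
            else:
                cats[peak] = "unchanged-only"
        categories = pd.Series(cats, dtype=object)
        if (categories == "ambiguous").any():
            warnings.warn(f"{(categories == 'ambiguous').sum()} peak(s) overlap both "
                          "up- and down-gene windows; excluded from category stats")
    return PeakGeneMap(assign, categories)


def fc_by_gene_category(peaks: PeakSet, counts: CountMatrix, peak_map: PeakGeneMap,
                        pseudocount: float = 0.5,
                        size_factors_: pd.Series | None = None) -> dict:
    """Per-category distribution of peak log2 fold changes with one-way ANOVA.

    Per peak: log2 of (median normalized aged counts / median normalized
    young counts), a 0.5 pseudocount replacing zero medians.  Categories with
    fewer than 2 peaks are excluded with a warning.  ``size_factors_`` should
    normally come from the genome-wide differential analysis; by default they
    are recomputed from ``counts``.  BH across assays is the caller's
    responsibility (use :func:`diffcounts.bh_adjust`).
    """
    sf = size_factors(counts) if size_factors_ is None else size_factors_
    norm = counts.counts / sf
    med_y = norm[counts.libraries("young")].median(axis=1)
    med_a = norm[counts.libraries("aged")].median(axis=1)
    med_y = med_y.where(med_y > 0, pseudocount)
    med_a = med_a.where(med_a > 0, pseudocount)
    lfc = np.log2(med_a / med_y)
    cats = peak_map.categories
    groups = {}
    for cat in ("up", "down", "unchanged-only"):
        names = cats.index[cats == cat]
        vals = lfc.reindex(names).dropna().to_numpy()
        if len(vals) < 2:
            if len(vals):
                warnings.warn(f"category {cat!r} has <2 peaks; excluded")
            continue
        groups[cat] = vals
    if len(groups) < 2:
        raise ValueError("need >=2 non-empty categories")
    p = stats.f_oneway(*groups.values()).pvalue
    return {"log2fc": lfc, "groups": groups, "anova_p": p,
            "means": {c: float(v.mean()) for c, v in groups.items()}}


def overlap_pair_correlation(datasets: dict, top_frac: float = 0.10,
                             seed: int | None = None) -> dict:
    """Pairwise fold-change correlations between peak datasets.

    ``datasets`` maps name -> (PeakSet, per-peak table with log2FC and p
    indexed by peak name).  For every dataset pair, overlapping peak pairs
    are found; when one peak overlaps several partners, one partner is chosen
    uniformly at random (seeded).  Returns the full-pair Pearson correlation
    matrix and a variant keeping only pairs where either peak's p-rank is in
    the top ``top_frac`` (rank 1 = smallest p).
    """
    names = list(datasets)
    full = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    top = full.copy()
    rng = np.random.default_rng(seed)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            (pa, ta), (pb, tb) = datasets[names[i]], datasets[names[j]]
            pairs = genome_io.overlaps(pa.intervals, pb.intervals)
            # de-duplicate: one random partner per idx_a, then per idx_b
            for col in ("idx_a", "idx_b"):
                if len(pairs) == 0:
                    break
                chosen = []
                for _, grp in pairs.groupby(col, sort=True):
                    chosen.append(grp.index[rng.integers(len(grp))])
                pairs = pairs.loc[sorted(chosen)]
            if len(pairs) < 3:
                full.loc[names[i], names[j]] = full.loc[names[j], names[i]] = np.nan
                top.loc[names[i], names[j]] = top.loc[names[j], names[i]] = np.nan
                warnings.warn(f"<3 overlap pairs for {names[i]} vs {names[j]}")
                continue
            name_a = pa.intervals["name"].to_numpy()[pairs["idx_a"]]
            name_b = pb.intervals["name"].to_numpy()[pairs["idx_b"]]
            fa = ta["log2FC"].reindex(name_a).to_numpy()
            fb = tb["log2FC"].reindex(name_b).to_numpy()
            ok = np.isfinite(fa) & np.isfinite(fb)
            r = stats.pearsonr(fa[ok], fb[ok]).statistic if ok.sum() >= 3 else np.nan
            full.loc[names[i], names[j]] = full.loc[names[j], names[i]] = r
            # top-rank filter on unadjusted p
            rank_a = ta["p"].rank(method="min").reindex(name_a).to_numpy()
            rank_b = tb["p"].rank(method="min").reindex(name_b).to_numpy()
            cut_a = top_frac * ta["p"].notna().sum()
            cut_b = top_frac * tb["p"].notna().sum()
            sel = ok & ((rank_a <= cut_a) | (rank_b <= cut_b))
            r_top = stats.pearsonr(fa[sel], fb[sel]).statistic if sel.sum() >= 3 else np.nan
            top.loc[names[i], names[j]] = top.loc[names[j], names[i]] = r_top
    return {"full": full, "top_filtered": top}
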