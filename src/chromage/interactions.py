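"""Promoter-capture interaction analytics.

Interactions are bait-fragment / other-fragment pairs carrying one confidence
score per age (larger = stronger evidence; scores >= 5 are significant, the
conventional capture-Hi-C threshold).  This module classifies interaction
ends, calls age-related rewiring (gained / lost), measures feature enrichment
at promoter-interacting regions against a distance-matched permutation null,
assigns chromatin states to fragments with the six-way priority rules, and
produces virtual-4C profiles over merged-fragment windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import genome_io
from .diffcounts import bh_adjust
from .genome_io import FragmentMap

SCORE_THRESHOLD = 5.0
MIN_DELTA = 2.0

STATUSES = ["stable-significant", "gained", "lost", "never-significant"]


@dataclass
class InteractionSet:
    """Bait/other fragment pairs with per-age interaction scores.

    ``table`` columns: bait_id, other_id, score_young, score_aged, distance
    (bp between fragment midpoints; NaN for trans contacts).
    ``bait_genes`` maps bait fragment id -> list of gene ids.
    """

    table: pd.DataFrame
    fragmap: FragmentMap
    bait_genes: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.table
        for col in ("score_young", "score_aged"):
            if t[col].isna().any():
                warnings.warn(f"missing {col} treated as 0")
                t[col] = t[col].fillna(0.0)
            if (t[col] < 0).any():
                raise ValueError("interaction scores must be >= 0")
        for bid in t["bait_id"].unique():
            if not self.fragmap.is_baited(bid):
                raise genome_io.GenomeError(f"bait {bid!r} is not flagged baited")

    def __len__(self):
        return len(self.table)


def classify_ends(iset: InteractionSet) -> pd.Series:
    """promoter:promoter when both ends are baited, else promoter:PIR."""
    fm = iset.fragmap
    baited = fm.fragments.set_index("frag_id")["baited"]
    bait_ok = baited.reindex(iset.table["bait_id"]).to_numpy()
    other = baited.reindex(iset.table["other_id"])
    if other.isna().any():
        raise genome_io.GenomeError("interaction references unknown fragment id")
    other_baited = other.to_numpy(dtype=bool)
    if not bait_ok.all():
        raise ValueError("capture design violation: bait end not baited")
    out = np.where(other_baited, "promoter:promoter", "promoter:PIR")
    return pd.Series(out, index=iset.table.index, name="end_class")


def rewiring_status(score_young: float, score_aged: float,
                    score_threshold: float = SCORE_THRESHOLD,
                    min_delta: float = MIN_DELTA) -> str:
    """Rewiring status of one interaction.

    gained: significant only in aged and score_aged - score_young >= min_delta;
    lost: significant only in young and score_young - score_aged >= min_delta;
    significant at both ages -> stable-significant; significant at one age
    with too small a change -> stable-significant; neither -> never-significant.
    """
    sy = score_young >= score_threshold
    sa = score_aged >= score_threshold
    if sy and sa:
        return "stable-significant"
    if sa and not sy and (score_aged - score_young) >= min_delta:
        return "gained"
    if sy and not sa and (score_young - score_aged) >= min_delta:
        return "lost"
    if sy or sa:
        return "stable-significant"
    return "never-significant"


def call_rewiring(iset: InteractionSet, score_threshold: float = SCORE_THRESHOLD,
                  min_delta: float = MIN_DELTA) -> pd.DataFrame:
    """Vectorized rewiring calls plus end classification for a whole set."""
    t = iset.table
    sy = t["score_young"].to_numpy()
    sa = t["score_aged"].to_numpy()
    sig_y = sy >= score_threshold
    sig_a = sa >= score_threshold
    status = np.full(len(t), "never-significant", dtype=object)
    status[sig_y | sig_a] = "stable-significant"
    status[sig_a & ~sig_y & ((sa - sy) >= min_delta)] = "gained"
    status[sig_y & ~sig_a & ((sy - sa) >= min_delta)] = "lost"
    out = t.copy()
    out["end_class"] = classify_ends(iset)
    out["status"] = status
    return out


def _distance_deciles(distances: np.ndarray, n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Assign cis distances to log10-distance quantile bins; returns
    (bin index per distance, bin edges)."""
    logd = np.log10(np.maximum(distances, 1.0))
    edges = np.quantile(logd, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:  # all distances identical
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    idx = np.clip(np.searchsorted(edges, logd, side="right") - 1, 0, len(edges) - 2)
    return idx, edges


def pir_enrichment(iset: InteractionSet, features_by_assay: dict,
                   n_draws: int = 100, seed: int | None = None,
                   n_distance_bins: int = 10, exclude_pirs: bool = True) -> pd.DataFrame:
    """Observed/expected PIR-feature overlap with a distance-matched null.

    For each assay: observed = number of distinct PIR fragments overlapping at
    least one feature peak.  The null redraws, for every PIR, a random
    non-baited, non-interacting fragment on the same chromosome whose distance
    to the PIR's bait falls in the same log10-distance quantile bin (nearest
    bin fallback when empty), ``n_draws`` times; expected is the mean overlap
    count over draws and the CI its 2.5/97.5 percentiles.  PIR fragments are
    excluded from the null pools (``exclude_pirs``) so that the background is
    not contaminated by the signal set.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    rng = np.random.default_rng(seed)
    calls = classify_ends(iset)
    pir_rows = iset.table[calls == "promoter:PIR"]
    frags = iset.fragmap.fragments
    mid = iset.fragmap.midpoints()
    frag_chrom = frags["chrom"].to_numpy()
    not_baited = ~frags["baited"].to_numpy()

    # unique PIR fragments with a representative bait distance
    pir_frag = pir_rows.drop_duplicates("other_id")
    pir_idx = np.array([iset.fragmap.index_of(f) for f in pir_frag["other_id"]])
    bait_idx = np.array([iset.fragmap.index_of(f) for f in pir_frag["bait_id"]])
    if exclude_pirs:
        not_baited = not_baited.copy()
        not_baited[pir_idx] = False
    dist = np.abs(mid[pir_idx] - mid[bait_idx]).astype(float)
    dec, edges = _distance_deciles(dist, n_distance_bins)

    # candidate pools per PIR: same-chromosome non-baited fragments in the
    # same distance bin relative to that PIR's bait
    pools = []
    for p, (bi, d_bin) in enumerate(zip(bait_idx, dec)):
        same = (frag_chrom == frag_chrom[bi]) & not_baited
        cand_idx = np.flatnonzero(same)
        if len(cand_idx) == 0:
            raise ValueError("no non-baited fragments available for the null")
        cand_d = np.log10(np.maximum(np.abs(mid[cand_idx] - mid[bi]), 1.0))
        cbin = np.clip(np.searchsorted(edges, cand_d, side="right") - 1, 0, len(edges) - 2)
        pool = cand_idx[cbin == d_bin]
        if len(pool) == 0:
            order = np.argsort(np.abs(cbin - d_bin), kind="mergesort")
            pool = cand_idx[order[: max(1, len(cand_idx) // 10)]]
            warnings.warn("empty distance bin: nearest-bin fallback used")
        pools.append(pool)

    frag_df = frags[["chrom", "start", "end"]]
    rows = []
    for assay, feats in features_by_assay.items():
        hit = genome_io.overlaps_any(frag_df, feats)
        observed = int(hit[pir_idx].sum())
        draws = np.empty(n_draws)
        for d in range(n_draws):
            sampled = np.array([pool[rng.integers(len(pool))] for pool in pools])
            draws[d] = hit[sampled].sum()
        expected = draws.mean()
        lo, hi = np.percentile(draws, [2.5, 97.5])
        ratio = observed / expected if expected > 0 else np.nan
        rows.append((assay, observed, expected, ratio,
                     observed / hi if hi > 0 else np.nan,
                     observed / lo if lo > 0 else np.nan, lo, hi))
    return pd.DataFrame(
        rows, columns=["assay", "observed", "expected", "ratio",
                       "ratio_ci_low", "ratio_ci_high", "draw_ci_low", "draw_ci_high"]
    ).set_index("assay")


# ---------------------------------------------------------------------------
# fragment chromatin-state assignment


def fragment_state(states_present: set) -> str:
    """Assign one of six chromatin states to a fragment from the set of
    collapsed states it overlaps, by fixed priority rules.

    Rules, in order: active promoter (overlaps active promoter, not polycomb
    or bivalent); polycomb (overlaps polycomb, not active promoter or
    bivalent); bivalent (overlaps bivalent, or both active promoter and
    polycomb); active regulatory (overlaps it, none of the above three);
    insulator (overlaps insulator and nothing else except background);
    background (only background, or nothing).
    """
    s = set(states_present)
    ap, pc, bv = "active_promoter" in s, "polycomb" in s, "bivalent" in s
    if ap and not pc and not bv:
        return "active_promoter"
    if pc and not ap and not bv:
        return "polycomb"
    if bv or (ap and pc):
        return "bivalent"
    if "active_regulatory" in s:
        return "active_regulatory"
    if "insulator" in s and s <= {"insulator", "background"}:
        return "insulator"
    if s <= {"background"}:
        return "background"
    raise AssertionError(f"state rules not total for {sorted(s)}")


def fragment_active(state: str, h3k4me3_peak: bool = False, h3k27ac_peak: bool = False,
                    h3k27me3_peak: bool = False) -> bool:
    """Active fragment: assigned to an active state or carrying an active
    mark peak, unless polycomb/bivalent-assigned or overlapping H3K27me3."""
    if state in ("polycomb", "bivalent") or h3k27me3_peak:
        return False
    return state in ("active_promoter", "active_regulatory") or h3k4me3_peak or h3k27ac_peak


def assign_fragment_states(fragmap: FragmentMap, segmentation,
                           h3k_peaks: dict | None = None) -> pd.DataFrame:
    """Per-fragment collapsed state + active flag from a segmentation.

    ``h3k_peaks`` may carry 'H3K4me3' / 'H3K27ac' / 'H3K27me3' peak frames
    for the active-fragment definition.
    """
    frag_df = fragmap.fragments[["chrom", "start", "end"]]
    bins = segmentation.bins
    labels = segmentation.collapsed
    pairs = genome_io.overlaps(frag_df, bins)
    present = {i: set() for i in range(len(frag_df))}
    for fi, bi in zip(pairs["idx_a"].to_numpy(), pairs["idx_b"].to_numpy()):
        present[fi].add(labels[bi])
    flags = {}
    for mark in ("H3K4me3", "H3K27ac", "H3K27me3"):
        peaks = (h3k_peaks or {}).get(mark)
        flags[mark] = (genome_io.overlaps_any(frag_df, peaks)
                       if peaks is not None and len(peaks) else np.zeros(len(frag_df), bool))
    states = [fragment_state(present[i]) for i in range(len(frag_df))]
    active = [fragment_active(st, flags["H3K4me3"][i], flags["H3K27ac"][i], flags["H3K27me3"][i])
              for i, st in enumerate(states)]
    return pd.DataFrame(
        {"frag_id": fragmap.fragments["frag_id"].to_numpy(), "state": states, "active": active}
    ).set_index("frag_id")


# ---------------------------------------------------------------------------
# gene-category statistics


def _gene_category(gene_ids, deg, contaminant_genes=()):
    """up / down / unchanged per gene from a differential-expression table."""
    tab = deg.table if hasattr(deg, "table") else deg
    out = {}
    for g in gene_ids:
        if g in contaminant_genes:
            out[g] = "excluded"
            continue
        if g not in tab.index or not np.isfinite(tab.loc[g, "padj"]):
            out[g] = "unchanged"
            continue
        if tab.loc[g, "padj"] < 0.05:
            out[g] = "up" if tab.loc[g, "log2FC"] > 0 else "down"
        else:
            out[g] = "unchanged"
    return out


def rewiring_by_gene_category(calls: pd.DataFrame, iset: InteractionSet, deg,
                              pir_counts=None, fragment_states: pd.DataFrame | None = None,
                              contaminant_genes=()) -> dict:
    """Gene-category statistics over promoter interactions.

    Returns a dict with:
      proportions: per category, gained/lost counts and proportions with
        pairwise two-sided Fisher tests (BH-adjusted);
      score_change: per interaction log2((score_aged+0.5)/(score_young+0.5))
        by category, one-way ANOVA p (BH left to the caller across figures);
      pir_readcount_change: per-assay log2 median library-normalized read
        count change over each category's PIRs (requires ``pir_counts``, a
        dict assay -> CountMatrix over PIR fragments);
      active_contacts: per-gene change in the number of contacted active
        fragments with a Fisher test of increase/decrease proportions across
        categories (requires ``fragment_states``).
    """
    genes_per_bait = iset.bait_genes
    all_genes = sorted({g for gs in genes_per_bait.values() for g in gs})
    gene_cat = _gene_category(all_genes, deg, contaminant_genes)

    rows = []
    for _, rec in calls.iterrows():
        for g in genes_per_bait.get(rec["bait_id"], []):
            cat = gene_cat[g]
            if cat == "excluded":
                continue
            rows.append((g, cat, rec["bait_id"], rec["other_id"], rec["status"],
                         rec["score_young"], rec["score_aged"]))
    per_int = pd.DataFrame(
        rows, columns=["gene_id", "category", "bait_id", "other_id", "status",
                       "score_young", "score_aged"])

    out = {}
    # (c) gained/lost proportions + pairwise Fisher
    prop_rows = []
    cats = [c for c in ("up", "unchanged", "down") if (per_int["category"] == c).any()]
    for c in cats:
        sub = per_int[per_int["category"] == c]
        n = len(sub)
        gl = int(sub["status"].isin(["gained", "lost"]).sum())
        prop_rows.append((c, n, int((sub["status"] == "gained").sum()),
                          int((sub["status"] == "lost").sum()), gl, gl / n if n else np.nan))
    props = pd.DataFrame(prop_rows, columns=["category", "n", "gained", "lost",
                                             "rewired", "rewired_frac"]).set_index("category")
    fisher_rows = []
    for i in range(len(cats)):
        for j in range(i + 1, len(cats)):
            a, b = cats[i], cats[j]
            table = [[props.loc[a, "rewired"], props.loc[a, "n"] - props.loc[a, "rewired"]],
                     [props.loc[b, "rewired"], props.loc[b, "n"] - props.loc[b, "rewired"]]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            fisher_rows.append((a, b, odds, p))
    fisher = pd.DataFrame(fisher_rows, columns=["cat_a", "cat_b", "odds_ratio", "p"])
    if len(fisher):
        fisher["padj"] = bh_adjust(fisher["p"].to_numpy())
    out["proportions"] = props
    out["fisher"] = fisher

    # (d) interaction-score log fold change by category
    per_int["score_log2fc"] = np.log2((per_int["score_aged"] + 0.5) /
                                      (per_int["score_young"] + 0.5))
    groups = [per_int.loc[per_int["category"] == c, "score_log2fc"].to_numpy() for c in cats]
    p_anova = stats.f_oneway(*groups).pvalue if len(groups) >= 2 and all(len(g) >= 2 for g in groups) else np.nan
    out["score_change"] = {"per_interaction": per_int, "anova_p": p_anova}

    # (e) chromatin read-count change over category PIRs
    if pir_counts is not None:
        end_class = per_int.merge(
            calls[["bait_id", "other_id", "end_class"]], on=["bait_id", "other_id"], how="left")
        rc_rows = []
        for assay, cm in pir_counts.items():
            libsize = cm.counts.sum(axis=0)
            normed = cm.counts / libsize
            for c in ("up", "down"):
                pirs = end_class.loc[(end_class["category"] == c) &
                                     (end_class["end_class"] == "promoter:PIR"), "other_id"]
                pirs = [p for p in pirs.unique() if p in normed.index]
                if not pirs:
                    continue
                sub = normed.loc[pirs]
                med_y = sub[cm.libraries("young")].median(axis=1)
                med_a = sub[cm.libraries("aged")].median(axis=1)
                lfc = np.log2((med_a + 1e-9) / (med_y + 1e-9))
                rc_rows.append((assay, c, len(pirs), float(np.median(lfc))))
        out["pir_readcount_change"] = pd.DataFrame(
            rc_rows, columns=["assay", "category", "n_pirs", "median_log2fc"])

    # (f) change in contacted active fragments per gene
    if fragment_states is not None:
        active = fragment_states["active"]
        thr = SCORE_THRESHOLD
        per_gene = []
        for g, sub in per_int.groupby("gene_id"):
            others = sub["other_id"]
            act = active.reindex(others).fillna(False).to_numpy(dtype=bool)
            young_n = int(((sub["score_young"] >= thr).to_numpy() & act).sum())
            aged_n = int(((sub["score_aged"] >= thr).to_numpy() & act).sum())
            per_gene.append((g, gene_cat[g], young_n, aged_n, aged_n - young_n))
        pg = pd.DataFrame(per_gene, columns=["gene_id", "category", "active_young",
                                             "active_aged", "delta"])
        f_rows = []
        cats_f = [c for c in ("up", "unchanged", "down") if (pg["category"] == c).any()]
        for i in range(len(cats_f)):
            for j in range(i + 1, len(cats_f)):
                a, b = cats_f[i], cats_f[j]
                ta = pg[pg["category"] == a]
                tb = pg[pg["category"] == b]
                table = [[int((ta["delta"] > 0).sum()), int((ta["delta"] < 0).sum())],
                         [int((tb["delta"] > 0).sum()), int((tb["delta"] < 0).sum())]]
                if min(sum(table[0]), sum(table[1])) > 0:
                    odds, p = stats.fisher_exact(table, alternative="two-sided")
                    f_rows.append((a, b, odds, p))
        out["active_contacts"] = {"per_gene": pg,
                                  "fisher": pd.DataFrame(f_rows, columns=["cat_a", "cat_b",
                                                                          "odds_ratio", "p"])}
    return out


def virtual_4c(ditags: pd.DataFrame, bait: str, fragmap: FragmentMap, k: int = 5) -> pd.DataFrame:
    """Windowed one-vs-all contact profile of a single anchor fragment.

    ``ditags`` columns: frag_i, frag_j, count (fragment ids).  Every ditag
    with one end on the bait accrues its count to the other end's k-fragment
    window.  Returns the merged-fragment windows with a ``count`` column
    (bedGraph-ready).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not fragmap.is_baited(bait):
        warnings.warn(f"fragment {bait!r} is not baited; profile still computed")
    windows = genome_io.merge_fragments(fragmap, k)
    frag_window = np.empty(len(fragmap), dtype=int)
    for w, row in windows.iterrows():
        lo = row["first_frag_index"]
        frag_window[lo: lo + row["n_fragments"]] = w
    counts = np.zeros(len(windows))
    for _, row in ditags.iterrows():
        if row["frag_i"] == bait and row["frag_j"] != bait:
            other = row["frag_j"]
        elif row["frag_j"] == bait and row["frag_i"] != bait:
            other = row["frag_i"]
        else:
            continue
        counts[frag_window[fragmap.index_of(other)]] += row["count"]
    out = windows.copy()
    out["count"] = counts
    return out
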