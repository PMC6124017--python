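"""Synthetic multi-omics generator with planted ground truth.

Everything downstream of sequencing — replicate count matrices, binary mark
tracks, binned contact maps, and capture interaction score tables — is
simulated for a small artificial genome under one seeded configuration, with
truth tables recording every planted effect: differentially expressed genes,
promoter chromatin-state flips, compartment-switch bins, and gained/lost
promoter interactions.  The defaults emulate the study design this package
targets: two conditions (young / aged), 4 replicates for chromatin assays,
3 for expression and 2 for Hi-C, 200-bp chromatin bins and 250-kb Hi-C bins,
an exponential restriction-fragment length of ~4 kb (HindIII-like), and a
six-state sticky chromatin Markov chain emitting five binary marks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import genome_io
from .chromstate import COLLAPSED_STATES, DEFAULT_MARKS, BinaryTracks, genome_bins
from .compartments import ContactMatrix
from .diffcounts import CountMatrix
from .genome_io import FragmentMap, Genome
from .interactions import InteractionSet

# six-state emission truth over (ATAC, H3K4me3, H3K27ac, H3K27me3, CTCF)
DEFAULT_EMISSIONS = {
    "polycomb":          [0.10, 0.05, 0.05, 0.90, 0.05],
    "bivalent":          [0.30, 0.80, 0.10, 0.80, 0.05],
    "active_promoter":   [0.90, 0.90, 0.50, 0.05, 0.10],
    "active_regulatory": [0.80, 0.10, 0.80, 0.05, 0.10],
    "insulator":         [0.50, 0.05, 0.05, 0.05, 0.90],
    "background":        [0.02, 0.02, 0.02, 0.02, 0.02],
}

DEFAULT_FLIP_PATTERNS = [
    ("active_promoter", "polycomb", 20),
    ("active_promoter", "bivalent", 20),
    ("polycomb", "active_regulatory", 20),
]


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Full configuration of one synthetic dataset (YAML-serializable)."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 25_000_000
    bin_size: int = 200
    hic_bin_size: int = 250_000
    fragment_length_mean: int = 4_000
    fragment_length_min: int = 200
    n_genes: int = 500
    gene_length_mean: int = 10_000
    bait_fraction: float = 0.9  # fraction of TSS-covering fragments baited

    # replicate design
    n_reps_chromatin: int = 4
    n_reps_expression: int = 3
    n_reps_hic: int = 2

    # negative-binomial counts
    count_mean_range: tuple = (20.0, 2000.0)
    dispersion: float = 0.05
    de_fraction: float = 0.10
    de_log2fc: float = 2.0
    size_factor_range: tuple = (0.5, 2.0)

    # chromatin-state HMM truth
    state_emissions: dict = field(default_factory=lambda: dict(DEFAULT_EMISSIONS))
    transition_stickiness: float = 0.97
    flip_patterns: list = field(default_factory=lambda: list(DEFAULT_FLIP_PATTERNS))

    # Hi-C truth
    compartment_block_bins: int = 10
    compartment_delta: float = 0.4
    contact_intensity: float = 200.0
    n_switch_bins: int = 5

    # capture interactions
    n_interactions: int = 500
    gained_fraction: float = 0.10
    lost_fraction: float = 0.10
    interaction_distance_logmean: float = 5.0  # log10 bp
    interaction_distance_logsd: float = 0.5

    def __post_init__(self):
        if self.chrom_length_bp < 10 * self.fragment_length_mean:
            raise ConfigError("chrom_length_bp must be >= 10x fragment_length_mean")
        for name in ("n_chroms", "chrom_length_bp", "bin_size", "hic_bin_size",
                     "fragment_length_mean", "n_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("de_fraction", "gained_fraction", "lost_fraction", "bait_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        for st, probs in self.state_emissions.items():
            if np.any((np.asarray(probs) < 0) | (np.asarray(probs) > 1)):
                raise ConfigError(f"emission probabilities for {st} outside [0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("count_mean_range", "size_factor_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "flip_patterns" in raw:
            raw["flip_patterns"] = [tuple(p) for p in raw["flip_patterns"]]
        return cls(**raw)


@dataclass
class TruthTables:
    """Planted effects, addressable by the ids used in the generated data."""

    genes: pd.DataFrame = None          # gene_id, de_status, log2fc
    promoter_flips: pd.DataFrame = None  # gene_id, from_state, to_state, pattern
    compartments: pd.DataFrame = None   # chrom, bin, sign_young, sign_aged, switched
    interactions: pd.DataFrame = None   # bait_id, other_id, status


# ---------------------------------------------------------------------------


def make_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Chromosome table, HindIII-like fragment map and gene models.

    Fragment lengths are exponential (configured mean, floored at the
    configured minimum) and tile each chromosome exactly; fragments covering
    a TSS are flagged baited with probability ``bait_fraction``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chroms = {f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chroms)}
    genome = Genome(chroms)

    frag_rows = []
    for chrom, length in chroms.items():
        pos = 0
        while pos < length:
            ln = max(int(rng.exponential(config.fragment_length_mean)),
                     config.fragment_length_min)
            end = min(pos + ln, length)
            frag_rows.append((chrom, pos, end))
            pos = end
    frags = pd.DataFrame(frag_rows, columns=["chrom", "start", "end"])
    frags["frag_id"] = [f"frag{i}" for i in range(len(frags))]
    frags["baited"] = False

    # genes: evenly spaced TSS slots with jitter, random strand
    per_chrom = config.n_genes // config.n_chroms
    gene_rows = []
    gid = 0
    for chrom, length in chroms.items():
        n = per_chrom + (1 if gid < config.n_genes % config.n_chroms else 0)
        slots = np.linspace(0.02, 0.98, n) * length
        for s in slots:
            glen = max(int(rng.exponential(config.gene_length_mean)), 1_000)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start = int(s)
                end = min(start + glen, length - 1)
            else:
                end = int(s)
                start = max(end - glen, 0)
            if end <= start:
                end = start + 1_000
            gene_rows.append((chrom, start, end, f"gene{gid}", 0.0, strand))
            gid += 1
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id",
                                             "score", "strand"])
    genes = genome_io.add_tss(genome_io.sort_intervals(genes))

    # flag TSS-covering fragments as baited
    tss_df = pd.DataFrame({"chrom": genes["chrom"], "start": genes["tss"],
                           "end": genes["tss"] + 1})
    pairs = genome_io.overlaps(frags, tss_df)
    tss_frag_idx = np.unique(pairs["idx_a"].to_numpy())
    baited = tss_frag_idx[rng.random(len(tss_frag_idx)) < config.bait_fraction]
    frags.loc[frags.index[baited], "baited"] = True
    return genome, FragmentMap(frags), genes


def _hic_bin_signs(config: SimConfig, n_bins: int) -> np.ndarray:
    """Alternating A/B blocks of ``compartment_block_bins`` bins."""
    blocks = np.arange(n_bins) // config.compartment_block_bins
    return np.where(blocks % 2 == 0, 1, -1)


def plant_truth(config: SimConfig, genome: Genome, genes: pd.DataFrame,
                rng: np.random.Generator | None = None) -> TruthTables:
    """Choose the planted DE genes, promoter flips and compartment switches.

    Genes whose TSS lies in a compartment-switch bin are planted as DE with a
    log2FC matching the switch direction (score up -> expression up), so the
    downstream expression-trend checks have signal to find.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    genes = genes.reset_index(drop=True)

    # compartment truth per chromosome
    comp_rows = []
    for chrom, length in genome.chrom_sizes.items():
        n_bins = length // config.hic_bin_size
        signs = _hic_bin_signs(config, n_bins)
        switched = np.zeros(n_bins, dtype=bool)
        switch_idx = rng.choice(n_bins, size=min(config.n_switch_bins, n_bins),
                                replace=False)
        switched[switch_idx] = True
        aged = np.where(switched, -signs, signs)
        for b in range(n_bins):
            comp_rows.append((chrom, b, int(signs[b]), int(aged[b]), bool(switched[b])))
    comp = pd.DataFrame(comp_rows, columns=["chrom", "bin", "sign_young",
                                            "sign_aged", "switched"])

    # promoter flips: disjoint gene groups per pattern
    flip_rows = []
    available = list(rng.permutation(len(genes)))
    for pat, (frm, to, n) in enumerate(config.flip_patterns):
        take, available = available[:n], available[n:]
        for gi in take:
            flip_rows.append((genes["gene_id"].iloc[gi], frm, to, pat))
    flips = pd.DataFrame(flip_rows, columns=["gene_id", "from_state", "to_state",
                                             "pattern"])

    # DE genes: switch-bin genes get direction-matched log2FC, the rest random
    status = pd.Series("null", index=genes["gene_id"], dtype=object)
    lfc = pd.Series(0.0, index=genes["gene_id"])
    comp_idx = comp.set_index(["chrom", "bin"])
    for _, g in genes.iterrows():
        b = int(g["tss"] // config.hic_bin_size)
        key = (g["chrom"], b)
        if key in comp_idx.index and comp_idx.loc[key, "switched"]:
            direction = np.sign(comp_idx.loc[key, "sign_aged"] - comp_idx.loc[key, "sign_young"])
            status[g["gene_id"]] = "de"
            lfc[g["gene_id"]] = config.de_log2fc * direction
    n_extra = max(int(config.de_fraction * len(genes)) - int((status == "de").sum()), 0)
    null_ids = status.index[status == "null"]
    extra = rng.choice(null_ids, size=min(n_extra, len(null_ids)), replace=False)
    signs = rng.choice([-1.0, 1.0], size=len(extra))
    status[extra] = "de"
    lfc[extra] = config.de_log2fc * signs
    gene_truth = pd.DataFrame({"gene_id": status.index, "de_status": status.to_numpy(),
                               "log2fc": lfc.to_numpy()})
    return TruthTables(genes=gene_truth, promoter_flips=flips, compartments=comp)


def simulate_counts(config: SimConfig, features: pd.DataFrame, truth: TruthTables | None,
                    rng: np.random.Generator | None = None, n_reps: int | None = None,
                    feature_id_col: str = "gene_id") -> CountMatrix:
    """Negative-binomial count matrix over features for young + aged replicates.

    counts ~ NB(mean * size_factor * 2^(log2fc * is_aged), dispersion); means
    are log-uniform over ``count_mean_range``; library size factors are
    log-uniform over ``size_factor_range``; planted DE features (from the
    truth table) carry their configured log2FC in aged libraries.
    """
    if len(features) == 0:
        raise ConfigError("features must be non-empty")
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    n_reps = config.n_reps_expression if n_reps is None else n_reps
    ids = features[feature_id_col].to_numpy()
    lo, hi = config.count_mean_range
    mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(ids)))
    lfc = np.zeros(len(ids))
    if truth is not None and truth.genes is not None:
        lut = truth.genes.set_index("gene_id")["log2fc"]
        lfc = lut.reindex(ids).fillna(0.0).to_numpy()
    libs, conds, reps = [], [], []
    cols = {}
    sf_lo, sf_hi = config.size_factor_range
    for cond in ("young", "aged"):
        for r in range(n_reps):
            lib = f"{cond}_{r + 1}"
            sf = np.exp(rng.uniform(np.log(sf_lo), np.log(sf_hi)))
            mean = mu * sf * (2.0 ** lfc if cond == "aged" else 1.0)
            n_param = 1.0 / config.dispersion
            p_param = n_param / (n_param + mean)
            cols[lib] = rng.negative_binomial(n_param, p_param)
            libs.append(lib)
            conds.append(cond)
            reps.append(r + 1)
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="feature"))
    meta = pd.DataFrame({"condition": conds, "replicate": reps},
                        index=pd.Index(libs, name="library"))
    return CountMatrix(counts, meta)


def _state_path(config: SimConfig, n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Sticky first-order Markov chain over the configured states."""
    states = list(config.state_emissions)
    K = len(states)
    stick = config.transition_stickiness
    path = np.empty(n_bins, dtype=np.int64)
    path[0] = rng.integers(K)
    stay = rng.random(n_bins) < stick
    jumps = rng.integers(0, K - 1, size=n_bins)
    for t in range(1, n_bins):
        if stay[t]:
            path[t] = path[t - 1]
        else:
            j = jumps[t]
            path[t] = j if j < path[t - 1] else j + 1
    return path


def simulate_tracks(config: SimConfig, genome: Genome, genes: pd.DataFrame,
                    truth: TruthTables, rng: np.random.Generator | None = None):
    """Binary mark tracks with a planted chromatin-state path per condition.

    The young path is drawn from the sticky state chain; planted flip
    promoters have their 5-kb window forced to the pattern's from-state in
    young and to-state in aged; elsewhere the aged path equals the young one
    (shared chromatin landscape).  Marks are emitted per bin from the
    per-state Bernoulli emissions, independently per condition.  Returns
    ``(tracks, peaks, true_states)``: BinaryTracks per condition, merged peak
    BEDs per condition and mark, and the true per-bin state label arrays.
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    states = list(config.state_emissions)
    emis = np.array([config.state_emissions[s] for s in states])
    state_idx = {s: i for i, s in enumerate(states)}
    marks = DEFAULT_MARKS
    bins = genome_bins(genome, config.bin_size)

    genes = genes if "tss" in genes.columns else genome_io.add_tss(genes)
    flips = truth.promoter_flips.merge(genes[["gene_id", "chrom", "tss"]], on="gene_id")

    paths = {"young": [], "aged": []}
    for chrom, grp in bins.groupby("chrom", sort=False):
        nb = len(grp)
        young = _state_path(config, nb, rng)
        aged = young.copy()
        half = 2_500 // config.bin_size
        for _, fl in flips[flips["chrom"] == chrom].iterrows():
            c = int(fl["tss"] // config.bin_size)
            lo, hi = max(c - half, 0), min(c + half + 1, nb)
            young[lo:hi] = state_idx[fl["from_state"]]
            aged[lo:hi] = state_idx[fl["to_state"]]
        paths["young"].append(young)
        paths["aged"].append(aged)

    tracks, peak_beds, true_states = {}, {}, {}
    for ci, cond in enumerate(("young", "aged")):
        full = np.concatenate(paths[cond])
        emit_rng = np.random.default_rng(rng.integers(2**31))
        mat = (emit_rng.random((len(full), len(marks))) < emis[full]).astype(np.uint8)
        tracks[cond] = BinaryTracks(bins, mat, list(marks), condition=cond,
                                    bin_size=config.bin_size)
        true_states[cond] = full
        peak_beds[cond] = {m: peaks_from_binary(bins, mat[:, j])
                           for j, m in enumerate(marks)}
    return tracks, peak_beds, true_states


def peaks_from_binary(bins: pd.DataFrame, flags: np.ndarray) -> pd.DataFrame:
    """Merge consecutive 1-bins into BED peaks."""
    rows = []
    for chrom, grp in bins.groupby("chrom", sort=False):
        f = flags[grp.index.to_numpy()]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        edges = np.diff(np.concatenate([[0], f, [0]]))
        for lo, hi in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
            rows.append((chrom, int(starts[lo]), int(ends[hi - 1])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def simulate_contacts(config: SimConfig, truth: TruthTables,
                      rng: np.random.Generator | None = None,
                      keep_diagonal: bool = True) -> dict:
    """Poisson contact maps per chromosome and replicate for both ages.

    Expected count at distance d decays as d^-1, modulated by compartment
    membership: pairs in the same compartment gain (1 + delta), cross-
    compartment pairs lose (1 - delta).  Switched bins use the opposite sign
    in aged replicates.  Matrices are exactly symmetric.
    """
    if config.n_reps_hic < 2:
        raise ConfigError("need >=2 Hi-C replicates per age")
    rng = np.random.default_rng(config.seed + 4) if rng is None else rng
    out = {"young": {}, "aged": {}}
    for chrom, sub in truth.compartments.groupby("chrom", sort=False):
        n = len(sub)
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        decay = config.contact_intensity / np.maximum(d, 1.0)
        if not keep_diagonal:
            np.fill_diagonal(decay, 0.0)
        for cond, col in (("young", "sign_young"), ("aged", "sign_aged")):
            signs = sub[col].to_numpy()
            same = np.equal.outer(signs, signs)
            expected = decay * np.where(same, 1 + config.compartment_delta,
                                        1 - config.compartment_delta)
            reps = []
            for _ in range(config.n_reps_hic):
                upper = rng.poisson(np.triu(expected))
                mat = upper + np.triu(upper, 1).T
                reps.append(ContactMatrix(chrom, config.hic_bin_size,
                                          mat.astype(float)))
            out[cond][chrom] = reps
    return out


def simulate_h3k4me3_bin_enrichment(config: SimConfig, truth: TruthTables,
                                    chrom: str, rng: np.random.Generator | None = None,
                                    noise_sd: float = 0.2) -> np.ndarray:
    """Per-Hi-C-bin H3K4me3 enrichment proxy: higher in A (young sign +)."""
    rng = np.random.default_rng(config.seed + 5) if rng is None else rng
    sub = truth.compartments[truth.compartments["chrom"] == chrom]
    signs = sub["sign_young"].to_numpy()
    return 1.0 + 0.5 * signs + rng.normal(0, noise_sd, size=len(signs))


def simulate_interactions(config: SimConfig, fragmap: FragmentMap,
                          genes: pd.DataFrame, truth: TruthTables,
                          rng: np.random.Generator | None = None,
                          de_coupling: float = 0.0,
                          status_assigner=None,
                          bait_weights: dict | None = None) -> InteractionSet:
    """Capture interaction score tables with planted gained/lost pairs.

    Scores come from a two-component model: a noise component with all mass
    below the significance threshold (uniform on [0, 4.8]) and a signal
    component above it (5 + exponential).  Gained pairs swap noise(young) ->
    signal(aged) with an enforced score increase of >= 2, lost pairs the
    reverse.  ``de_coupling`` in [0, 1) biases lost interactions onto baits of
    downregulated genes and gained onto upregulated ones.  Alternatively,
    ``status_assigner(bait_frag_id, bait_genes, rng) -> status`` plants the
    status conditionally on the chosen bait (e.g. category-dependent rewiring
    odds); it overrides the global gained/lost fractions.
    """
    rng = np.random.default_rng(config.seed + 6) if rng is None else rng
    frags = fragmap.fragments
    mid = fragmap.midpoints()
    baited_idx = np.flatnonzero(frags["baited"].to_numpy())
    if len(baited_idx) == 0:
        raise ConfigError("fragment map has no baited fragments")

    genes = genes if "tss" in genes.columns else genome_io.add_tss(genes)
    tss_df = pd.DataFrame({"chrom": genes["chrom"], "start": genes["tss"],
                           "end": genes["tss"] + 1})
    pairs = genome_io.overlaps(frags[["chrom", "start", "end"]], tss_df)
    bait_genes: dict = {}
    for fi, gi in zip(pairs["idx_a"], pairs["idx_b"]):
        if frags["baited"].iloc[fi]:
            bait_genes.setdefault(frags["frag_id"].iloc[fi], []).append(
                genes["gene_id"].iloc[gi])

    gene_lfc = truth.genes.set_index("gene_id")["log2fc"] if truth.genes is not None else None

    n = config.n_interactions
    n_gain = int(config.gained_fraction * n)
    n_lost = int(config.lost_fraction * n)
    statuses = (["gained"] * n_gain + ["lost"] * n_lost +
                ["stable-significant", "never-significant"] *
                ((n - n_gain - n_lost) // 2 + 1))[:n]

    def bait_weight(frag_id, status):
        if de_coupling <= 0 or gene_lfc is None:
            return 1.0
        gs = bait_genes.get(frag_id, [])
        lfcs = [gene_lfc.get(g, 0.0) for g in gs]
        if status == "lost" and any(v < 0 for v in lfcs):
            return 1.0 / (1.0 - de_coupling)
        if status == "gained" and any(v > 0 for v in lfcs):
            return 1.0 / (1.0 - de_coupling)
        return 1.0

    chrom_arr = frags["chrom"].to_numpy()
    rows = []
    seen = set()
    for status in statuses:
        for _ in range(200):  # rejection sampling of a fresh pair
            if status_assigner is None:
                weights = np.array([bait_weight(frags["frag_id"].iloc[b], status)
                                    for b in baited_idx])
                bi = baited_idx[rng.choice(len(baited_idx), p=weights / weights.sum())]
            elif bait_weights is not None:
                w = np.array([bait_weights.get(frags["frag_id"].iloc[b], 1.0)
                              for b in baited_idx])
                bi = baited_idx[rng.choice(len(baited_idx), p=w / w.sum())]
            else:
                bi = baited_idx[rng.integers(len(baited_idx))]
            dist = 10 ** rng.normal(config.interaction_distance_logmean,
                                    config.interaction_distance_logsd)
            side = 1 if rng.random() < 0.5 else -1
            target = mid[bi] + side * dist
            same = np.flatnonzero(chrom_arr == chrom_arr[bi])
            oi = same[np.argmin(np.abs(mid[same] - target))]
            if oi != bi and (bi, oi) not in seen:
                seen.add((bi, oi))
                break
        else:
            continue
        if status_assigner is not None:
            status = status_assigner(frags["frag_id"].iloc[bi], bait_genes, rng)
        noise = lambda: rng.uniform(0.0, 4.8)
        signal = lambda: 5.0 + rng.exponential(2.0)
        if status == "gained":
            sy = noise()
            sa = max(signal(), sy + 2.0)
        elif status == "lost":
            sa = noise()
            sy = max(signal(), sa + 2.0)
        elif status == "stable-significant":
            sy, sa = signal(), signal()
        else:
            sy, sa = noise(), noise()
        rows.append((frags["frag_id"].iloc[bi], frags["frag_id"].iloc[oi],
                     sy, sa, abs(mid[oi] - mid[bi]), status))
    table = pd.DataFrame(rows, columns=["bait_id", "other_id", "score_young",
                                        "score_aged", "distance", "true_status"])
    truth.interactions = table[["bait_id", "other_id", "true_status"]].copy()
    iset = InteractionSet(table.drop(columns="true_status"), fragmap,
                          bait_genes=bait_genes)
    return iset


def simulate_fragment_features(fragmap: FragmentMap, enriched_frag_ids,
                               background_rate: float = 0.1, enrichment: float = 3.0,
                               rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Feature peaks planted on fragments: background_rate everywhere,
    background_rate * enrichment on the listed fragments (for PIR-enrichment
    calibration and recovery checks)."""
    rng = np.random.default_rng() if rng is None else rng
    frags = fragmap.fragments
    enriched = frags["frag_id"].isin(set(enriched_frag_ids)).to_numpy()
    rate = np.where(enriched, min(background_rate * enrichment, 1.0), background_rate)
    hit = rng.random(len(frags)) < rate
    sub = frags[hit]
    centers = ((sub["start"] + sub["end"]) // 2).to_numpy()
    return pd.DataFrame({"chrom": sub["chrom"].to_numpy(),
                         "start": np.maximum(centers - 50, sub["start"].to_numpy()),
                         "end": np.minimum(centers + 50, sub["end"].to_numpy())})


@dataclass
class SimulatedDataset:
    """One fully generated dataset plus its truth tables."""

    config: SimConfig
    genome: Genome
    fragmap: FragmentMap
    genes: pd.DataFrame
    truth: TruthTables
    tracks: dict
    peak_beds: dict
    true_states: dict
    expression: CountMatrix
    contacts: dict
    interactions: InteractionSet


def simulate_dataset(config: SimConfig, de_coupling: float = 0.5) -> SimulatedDataset:
    """Generate every layer of one synthetic dataset under the config seed."""
    genome, fragmap, genes = make_genome(config)
    truth = plant_truth(config, genome, genes)
    tracks, peak_beds, true_states = simulate_tracks(config, genome, genes, truth)
    expression = simulate_counts(config, genes, truth)
    contacts = simulate_contacts(config, truth)
    interactions = simulate_interactions(config, fragmap, genes, truth,
                                         de_coupling=de_coupling)
    return SimulatedDataset(config, genome, fragmap, genes, truth, tracks,
                            peak_beds, true_states, expression, contacts,
                            interactions)


# ---------------------------------------------------------------------------
# file export (the same formats the pipeline reads)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the dataset as plain-text files: config YAML, gene TSV,
    fragment BED, per-condition per-mark peak BEDs, count TSV, triplet-TSV
    contacts, and a WashU-style interaction table with two score columns."""
    import os

    os.makedirs(outdir, exist_ok=True)
    ds.config.to_yaml(os.path.join(outdir, "config.yaml"))
    genome_io.write_bed(ds.genes, os.path.join(outdir, "genes.tsv"),
                        columns=["chrom", "start", "end", "gene_id", "score", "strand"])
    fr = ds.fragmap.fragments.copy()
    fr["baited"] = fr["baited"].astype(int)
    genome_io.write_bed(fr, os.path.join(outdir, "fragments.bed"),
                        columns=["chrom", "start", "end", "frag_id", "baited"])
    for cond, marks in ds.peak_beds.items():
        for mark, bed in marks.items():
            genome_io.write_bed(bed, os.path.join(outdir, f"peaks_{cond}_{mark}.bed"),
                                columns=["chrom", "start", "end"])
    ds.expression.counts.to_csv(os.path.join(outdir, "expression_counts.tsv"), sep="\t")
    ds.expression.meta.to_csv(os.path.join(outdir, "expression_meta.tsv"), sep="\t")
    from .compartments import contacts_to_triplets
    trip = []
    for cond, by_chrom in ds.contacts.items():
        for chrom, reps in by_chrom.items():
            for r, cm in enumerate(reps):
                t = contacts_to_triplets(cm)
                t.insert(0, "replicate", r + 1)
                t.insert(0, "condition", cond)
                trip.append(t)
    pd.concat(trip, ignore_index=True).to_csv(
        os.path.join(outdir, "contacts.tsv"), sep="\t", index=False)
    frag_coords = ds.fragmap.fragments.set_index("frag_id")
    t = ds.interactions.table
    washu = pd.DataFrame({
        "anchor": [f"{frag_coords.loc[b, 'chrom']}:{frag_coords.loc[b, 'start']}-"
                   f"{frag_coords.loc[b, 'end']}" for b in t["bait_id"]],
        "target": [f"{frag_coords.loc[o, 'chrom']}:{frag_coords.loc[o, 'start']}-"
                   f"{frag_coords.loc[o, 'end']}" for o in t["other_id"]],
        "score_young": t["score_young"],
        "score_aged": t["score_aged"],
    })
    washu.to_csv(os.path.join(outdir, "interactions.txt"), sep="\t", index=False)
    for name, tab in (("truth_genes", ds.truth.genes),
                      ("truth_flips", ds.truth.promoter_flips),
                      ("truth_compartments", ds.truth.compartments),
                      ("truth_interactions", ds.truth.interactions)):
        if tab is not None:
            tab.to_csv(os.path.join(outdir, f"{name}.tsv"), sep="\t", index=False)
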