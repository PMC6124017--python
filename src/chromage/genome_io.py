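"""Genomic interval data model, BED/TSV readers and writers, and the overlap engine.

All coordinates are 0-based half-open (BED convention) internally.  Interval
collections are pandas DataFrames with at least ``chrom``, ``start``, ``end``
columns; gene models add ``gene_id``, ``strand`` and a derived ``tss``.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


class GenomeError(ValueError):
    """Validation failure in genomic coordinates or file content."""


@dataclass(frozen=True)
class GenomicInterval:
    """A single half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise GenomeError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise GenomeError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """Chromosome name -> length table."""

    chrom_sizes: dict

    @property
    def chroms(self):
        return list(self.chrom_sizes)

    def validate(self, df: pd.DataFrame) -> None:
        unknown = set(df["chrom"]) - set(self.chrom_sizes)
        if unknown:
            raise GenomeError(f"unknown chromosome(s): {sorted(unknown)}")


def _open_maybe_gzip(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def validate_intervals(df: pd.DataFrame, genome: Genome | None = None) -> pd.DataFrame:
    """Check start < end (and chrom membership if a genome is given)."""
    bad = df.index[~(df["start"].astype(int) < df["end"].astype(int))]
    if len(bad):
        raise GenomeError(f"{len(bad)} interval(s) with start >= end (first at row {bad[0]})")
    if (df["start"] < 0).any():
        raise GenomeError("negative start coordinate")
    if genome is not None:
        genome.validate(df)
    return df


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def read_intervals(path, format: str = "BED", genome: Genome | None = None) -> pd.DataFrame:
    """Read a BED / fragment-BED / gene-TSV file into a sorted DataFrame.

    Parameters
    ----------
    format : {"BED", "fragment-BED", "gene-TSV"}
        ``BED`` accepts 3 or 6 columns. ``fragment-BED`` is BED4 with the
        fragment id in column 4 plus an optional ``baited`` 0/1 column 5.
        ``gene-TSV`` is a 6-column BED-like table (chrom, start, end,
        gene_id, score, strand); the TSS is derived from the strand.

    Malformed lines raise :class:`GenomeError` naming the 1-based line number.
    """
    rows = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenomeError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise GenomeError(f"{path}:{lineno}: non-integer coordinate") from exc
            if not (0 <= start < end):
                raise GenomeError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            rows.append((lineno, parts[0], start, end, parts[3:]))

    if format == "BED":
        df = pd.DataFrame(
            {
                "chrom": [r[1] for r in rows],
                "start": [r[2] for r in rows],
                "end": [r[3] for r in rows],
                "name": [r[4][0] if r[4] else "." for r in rows],
                "score": [float(r[4][1]) if len(r[4]) > 1 and r[4][1] != "." else 0.0 for r in rows],
                "strand": [r[4][2] if len(r[4]) > 2 else "." for r in rows],
            }
        )
    elif format == "fragment-BED":
        df = pd.DataFrame(
            {
                "chrom": [r[1] for r in rows],
                "start": [r[2] for r in rows],
                "end": [r[3] for r in rows],
                "frag_id": [r[4][0] if r[4] else f"frag{i}" for i, r in enumerate(rows)],
                "baited": [bool(int(r[4][1])) if len(r[4]) > 1 else False for r in rows],
            }
        )
    elif format == "gene-TSV":
        for r in rows:
            if len(r[4]) < 3:
                raise GenomeError(f"{path}:{r[0]}: gene-TSV needs 6 columns")
        df = pd.DataFrame(
            {
                "chrom": [r[1] for r in rows],
                "start": [r[2] for r in rows],
                "end": [r[3] for r in rows],
                "gene_id": [r[4][0] for r in rows],
                "score": [float(r[4][1]) if r[4][1] != "." else 0.0 for r in rows],
                "strand": [r[4][2] for r in rows],
            }
        )
        df["tss"] = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    else:
        raise ValueError(f"unknown format {format!r}")

    validate_intervals(df, genome)
    return sort_intervals(df)


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    """Write intervals as BED; column order chrom, start, end then extras."""
    cols = columns or [c for c in BED6_COLS if c in df.columns]
    out = sort_intervals(df)[cols]
    with _open_maybe_gzip(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


def add_tss(genes: pd.DataFrame) -> pd.DataFrame:
    """Derive the TSS column: start on +, end-1 on the minus strand."""
    genes = genes.copy()
    genes["tss"] = np.where(genes["strand"] == "-", genes["end"] - 1, genes["start"])
    return genes


def overlaps(a: pd.DataFrame, b: pd.DataFrame, genome: Genome | None = None) -> pd.DataFrame:
    """All overlapping pairs between two interval collections.

    Half-open semantics: intervals overlap iff ``max(start) < min(end)``.
    Returns a DataFrame with columns ``idx_a``, ``idx_b`` (positional indices
    into the inputs), sorted, deterministic.
    """
    if genome is not None:
        genome.validate(a)
        genome.validate(b)
    out_a, out_b = [], []
    a_idx = np.arange(len(a))
    b_idx = np.arange(len(b))
    for chrom in np.intersect1d(a["chrom"].unique(), b["chrom"].unique()):
        ai = a_idx[(a["chrom"] == chrom).to_numpy()]
        bi = b_idx[(b["chrom"] == chrom).to_numpy()]
        a_start = a["start"].to_numpy()[ai]
        a_end = a["end"].to_numpy()[ai]
        b_start = b["start"].to_numpy()[bi]
        b_end = b["end"].to_numpy()[bi]
        order = np.argsort(b_start, kind="mergesort")
        bs, be, bo = b_start[order], b_end[order], bi[order]
        # sweep: for each a-interval, candidates are b-intervals with
        # b.start < a.end; filter on b.end > a.start
        hi = np.searchsorted(bs, a_end, side="left")
        for k, aix in enumerate(ai):
            cand = np.nonzero(be[: hi[k]] > a_start[k])[0]
            out_a.extend([aix] * len(cand))
            out_b.extend(bo[cand])
    pairs = pd.DataFrame({"idx_a": np.asarray(out_a, dtype=int), "idx_b": np.asarray(out_b, dtype=int)})
    return pairs.sort_values(["idx_a", "idx_b"], kind="mergesort").reset_index(drop=True)


def overlaps_any(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean per interval of ``a``: overlaps at least one interval of ``b``."""
    flag = np.zeros(len(a), dtype=bool)
    if len(a) and len(b):
        pairs = overlaps(a, b)
        flag[pairs["idx_a"].to_numpy()] = True
    return flag


def promoter_windows(genes: pd.DataFrame, halfwidth: int, genome: Genome | None = None) -> pd.DataFrame:
    """One window [tss - halfwidth, tss + halfwidth) per gene, clipped to chromosome bounds."""
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    genes = genes if "tss" in genes.columns else add_tss(genes)
    if genome is not None:
        genome.validate(genes)
    tss = genes["tss"].to_numpy()
    start = np.maximum(tss - halfwidth, 0)
    end = tss + halfwidth
    if genome is not None:
        lim = genes["chrom"].map(genome.chrom_sizes).to_numpy()
        end = np.minimum(end, lim)
    out = pd.DataFrame(
        {"chrom": genes["chrom"].to_numpy(), "start": start, "end": end,
         "gene_id": genes["gene_id"].to_numpy()}
    )
    return out


@dataclass
class FragmentMap:
    """Ordered restriction fragments tiling each chromosome.

    ``fragments`` has columns chrom, start, end, frag_id, baited; fragments
    within a chromosome must be adjacent (end[i] == start[i+1]) starting at 0.
    """

    fragments: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = sort_intervals(self.fragments)
        validate_intervals(df)
        for chrom, grp in df.groupby("chrom", sort=False):
            s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
            if len(s) and not np.array_equal(e[:-1], s[1:]):
                raise GenomeError(f"fragments on {chrom} are not adjacent")
        if "frag_id" not in df.columns:
            df["frag_id"] = [f"frag{i}" for i in range(len(df))]
        if "baited" not in df.columns:
            df["baited"] = False
        df["frag_index"] = np.arange(len(df))
        self.fragments = df
        self._by_id = pd.Series(df["frag_index"].to_numpy(), index=df["frag_id"])

    def __len__(self):
        return len(self.fragments)

    def index_of(self, frag_id) -> int:
        try:
            return int(self._by_id[frag_id])
        except KeyError as exc:
            raise GenomeError(f"unknown fragment id {frag_id!r}") from exc

    def is_baited(self, frag_id) -> bool:
        return bool(self.fragments["baited"].iloc[self.index_of(frag_id)])

    def midpoints(self) -> np.ndarray:
        f = self.fragments
        return ((f["start"] + f["end"]) // 2).to_numpy()


def merge_fragments(fragmap: FragmentMap, k: int) -> pd.DataFrame:
    """Windows of ``k`` adjacent fragments per chromosome.

    A trailing window with fewer than ``k`` fragments is kept and flagged
    ``partial``.  Returns chrom, start, end, window_id, n_fragments, partial,
    first_frag_index.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(fragmap) == 0:
        raise GenomeError("empty fragment map")
    rows = []
    wid = 0
    for chrom, grp in fragmap.fragments.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        first_idx = grp["frag_index"].to_numpy()
        for lo in range(0, len(grp), k):
            hi = min(lo + k, len(grp))
            rows.append(
                (chrom, int(s[lo]), int(e[hi - 1]), f"win{wid}", hi - lo, hi - lo < k, int(first_idx[lo]))
            )
            wid += 1
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "window_id", "n_fragments", "partial", "first_frag_index"]
    )
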