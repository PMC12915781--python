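"""Sliding genomic windows: construction, masking and GC annotation.

Windows are the analysis unit for comparing expression between
mutation-containing regions and the genome at large.  The default
configurations are 10 kb windows sliding by 1 kb and 1 kb windows sliding
by 100 bp; the non-overlapping subset whose starts are multiples of the
window size (the *canonical tiling*) partitions the genome and serves as
the normalisation universe for TPM.

Coordinates are 0-based half-open (BED convention) throughout; 1-based
inputs (VCF positions) are converted at the parser boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from ._stepfun import indicator_step, merge_intervals

__all__ = [
    "GenomeIndex",
    "MaskSet",
    "WindowSet",
    "load_genome_index",
    "make_windows",
    "apply_mask",
    "annotate_gc",
    "write_windows_bed",
]


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths defining the coordinate space."""

    names: tuple[str, ...]
    lengths: dict[str, int]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate sequence names in genome index")
        if not self.names:
            raise ValueError("genome index is empty")
        for name in self.names:
            if self.lengths[name] < 1:
                raise ValueError(f"chromosome {name} has non-positive length")

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


@dataclass
class MaskSet:
    """Merged, sorted, half-open masked intervals per chromosome.

    Masked regions are excluded from mutation calling upstream and are
    therefore excluded here from both expression denominators and GC
    computation, so that mutation and expression are measured over the
    same effective genome.
    """

    intervals: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "MaskSet":
        return cls({})

    @classmethod
    def from_bed(cls, path, index: GenomeIndex) -> "MaskSet":
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if start >= end:
                    raise ValueError(f"{path}:{lineno}: malformed interval start >= end")
                if chrom not in index.lengths:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if start < 0 or end > index.lengths[chrom]:
                    raise ValueError(f"{path}:{lineno}: interval outside chromosome bounds")
                per_chrom.setdefault(chrom, []).append((start, end))
        merged = {}
        for chrom, ivs in per_chrom.items():
            arr = np.array(ivs, dtype=np.int64)
            merged[chrom] = merge_intervals(arr[:, 0], arr[:, 1])
        return cls(merged)

    def get(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self.intervals.get(chrom, (empty, empty))

    def total_masked(self) -> int:
        return int(sum(np.sum(e - s) for s, e in self.intervals.values()))

    def unmasked_step(self, chrom: str, length: int):
        s, e = self.get(chrom)
        return indicator_step(length, s, e, inside=0.0, outside=1.0)


@dataclass
class WindowSet:
    """Sliding windows over a genome, stored as a table.

    Columns of ``df``: chrom, start, end, window_id, canonical,
    effective_length (unmasked bp), gc_fraction (NaN when no unmasked
    non-N base), included (effective_length > 0).
    """

    df: pd.DataFrame
    size: int
    step: int
    index: GenomeIndex

    @property
    def canonical(self) -> pd.DataFrame:
        """The non-overlapping tiling subset (starts at multiples of size)."""
        return self.df[self.df["canonical"]]

    @property
    def included(self) -> pd.DataFrame:
        return self.df[self.df["included"]]

    def chrom_view(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def __len__(self) -> int:
        return len(self.df)


def load_genome_index(fasta_path) -> GenomeIndex:
    """Read chromosome names and lengths from a FASTA file."""
    names: list[str] = []
    lengths: dict[str, int] = {}
    fa = Fasta(str(fasta_path), build_index=True, rebuild=False)
    try:
        for name in fa.keys():
            if name in lengths:
                raise ValueError(f"duplicate sequence name {name!r} in {fasta_path}")
            names.append(name)
            lengths[name] = len(fa[name])
    finally:
        fa.close()
    if not names:
        raise ValueError(f"no sequences found in {fasta_path}")
    return GenomeIndex(tuple(names), lengths)


def make_windows(index: GenomeIndex, size: int, step: int) -> WindowSet:
    """Tile each chromosome with windows of ``size`` bp every ``step`` bp.

    The final window on each chromosome is truncated at the chromosome end
    (as ``bedtools makewindows`` does); ``size`` must be divisible by
    ``step`` so that the canonical tiling is a subset of the sliding set.
    """
    if size < 1:
        raise ValueError("window size must be >= 1")
    if step < 1 or step > size:
        raise ValueError("step must satisfy 1 <= step <= size (gaps would drop genome)")
    if size % step != 0:
        raise ValueError("size must be divisible by step")
    frames = []
    for chrom in index.names:
        length = index.lengths[chrom]
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    df = pd.concat(frames, ignore_index=True)
    df["window_id"] = df["chrom"].astype(str) + ":" + df["start"].astype(str) + "-" + df["end"].astype(str)
    df["canonical"] = (df["start"] % size) == 0
    df["effective_length"] = (df["end"] - df["start"]).astype(np.int64)
    df["gc_fraction"] = np.nan
    df["included"] = True
    return WindowSet(df, size=size, step=step, index=index)


def apply_mask(windows: WindowSet, mask: MaskSet) -> WindowSet:
    """Recompute effective (unmasked) lengths; fully masked windows are excluded."""
    df = windows.df.copy()
    eff = np.empty(len(df), dtype=np.int64)
    for chrom in windows.index.names:
        sel = (df["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        unmasked = mask.unmasked_step(chrom, windows.index.lengths[chrom])
        eff[sel] = np.round(
            unmasked.window_sums(df.loc[sel, "start"].to_numpy(), df.loc[sel, "end"].to_numpy())
        ).astype(np.int64)
    df["effective_length"] = eff
    df["included"] = eff > 0
    return replace(windows, df=df)


_GC_BYTES = frozenset(b"GCgc")
_ACGT_BYTES = frozenset(b"ACGTacgt")


def annotate_gc(windows: WindowSet, fasta_path, mask: MaskSet | None = None) -> WindowSet:
    """GC fraction per window over unmasked, non-N bases.

    N (and other ambiguity codes) count in neither numerator nor
    denominator; a window with no unmasked unambiguous base gets NaN and
    is dropped only from GC-filtered analyses downstream.
    """
    mask = mask or MaskSet.empty()
    df = windows.df.copy()
    gc_out = np.full(len(df), np.nan)
    fa = Fasta(str(fasta_path))
    try:
        for chrom in windows.index.names:
            sel = (df["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            length = windows.index.lengths[chrom]
            seq = np.frombuffer(str(fa[chrom][:]).encode("ascii"), dtype=np.uint8)
            if seq.size != length:
                raise ValueError(f"FASTA length mismatch for {chrom}")
            starts = df.loc[sel, "start"].to_numpy()
            ends = df.loc[sel, "end"].to_numpy()
            if ends.max() > length:
                raise ValueError(f"window beyond end of {chrom}")
            unmasked = np.ones(length, dtype=bool)
            ms, me = mask.get(chrom)
            for s, e in zip(ms, me):
                unmasked[s:e] = False
            is_gc = np.isin(seq, np.frombuffer(b"GCgc", dtype=np.uint8)) & unmasked
            is_acgt = np.isin(seq, np.frombuffer(b"ACGTacgt", dtype=np.uint8)) & unmasked
            cgc = np.concatenate([[0], np.cumsum(is_gc, dtype=np.int64)])
            cat = np.concatenate([[0], np.cumsum(is_acgt, dtype=np.int64)])
            num = cgc[ends] - cgc[starts]
            den = cat[ends] - cat[starts]
            vals = np.full(num.size, np.nan)
            nz = den > 0
            vals[nz] = num[nz] / den[nz]
            gc_out[sel] = vals
    finally:
        fa.close()
    df["gc_fraction"] = gc_out
    return replace(windows, df=df)


def write_windows_bed(windows: WindowSet, path) -> None:
    """Write windows as BED4+ TSV (chrom, start, end, id, eff. length, GC)."""
    cols = ["chrom", "start", "end", "window_id", "effective_length", "gc_fraction"]
    windows.df[cols].to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
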