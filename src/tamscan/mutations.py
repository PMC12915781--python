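"""Mutation calls: parsing, type classification and window/gene overlap.

Mutations (base substitutions, insertions, deletions) come from VCF or a
4-column TSV.  Every variant is anchored at its (leftmost-aligned) VCF POS
base; an indel spanning a window boundary is assigned by that anchor base
only, so the overlap rule is uniform across types.  Strand is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import GenomeIndex, WindowSet

__all__ = [
    "Mutation",
    "MutationSet",
    "OverlapFlags",
    "classify_type",
    "load_mutations",
    "flag_mutation_windows",
    "genic_overlap",
]

MUTATION_TYPES = ("base_substitution", "insertion", "deletion")


@dataclass(frozen=True)
class Mutation:
    chromosome: str
    position: int  # 1-based VCF anchor
    ref_allele: str
    alt_allele: str
    mutation_type: str
    genotype_label: str = ""


@dataclass
class MutationSet:
    """Table of mutations: chrom, pos (1-based), ref, alt, mutation_type, genotype_label."""

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.df["genotype_label"].unique())

    def subset(self, genotype: str | None = None, mutation_type: str | None = None) -> "MutationSet":
        df = self.df
        if genotype is not None:
            df = df[df["genotype_label"] == genotype]
        if mutation_type is not None and mutation_type != "all":
            df = df[df["mutation_type"] == mutation_type]
        return MutationSet(df.reset_index(drop=True))


@dataclass
class OverlapFlags:
    """Which windows (or genes) each mutation hits.

    ``window_flags``: boolean per window_id (ordered like the WindowSet);
    ``n_mutations``: count per window_id; ``mutation_map``: long table
    (mutation_index, window_id).  A mutation overlapping k sliding windows
    contributes k rows to the map; flagged windows are counted once no
    matter how many mutations they contain.
    """

    window_flags: pd.Series
    n_mutations: pd.Series
    mutation_map: pd.DataFrame

    @property
    def flagged_ids(self) -> pd.Index:
        return self.window_flags.index[self.window_flags]


def classify_type(ref_allele: str, alt_allele: str) -> str:
    """base_substitution (1/1), insertion (|alt|>|ref|) or deletion (|alt|<|ref|)."""
    if not ref_allele or not alt_allele:
        raise ValueError("alleles must be non-empty")
    if any(a.startswith("<") or a in (".", "*") for a in (ref_allele, alt_allele)):
        raise ValueError(f"symbolic allele not supported: {ref_allele}/{alt_allele}")
    lr, la = len(ref_allele), len(alt_allele)
    if lr == la:
        if lr == 1:
            return "base_substitution"
        raise ValueError(f"multi-nucleotide substitution {ref_allele}>{alt_allele} is not a supported category")
    return "insertion" if la > lr else "deletion"


def _from_records(records: list[tuple], index: GenomeIndex | None) -> MutationSet:
    df = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt", "genotype_label"])
    df["mutation_type"] = [classify_type(r, a) for r, a in zip(df["ref"], df["alt"])]
    if index is not None:
        for chrom, sub in df.groupby("chrom"):
            if chrom not in index.lengths:
                raise ValueError(f"mutation on unknown chromosome {chrom!r}")
            if (sub["pos"] < 1).any() or (sub["pos"] > index.lengths[chrom]).any():
                raise ValueError(f"mutation position outside chromosome {chrom}")
    return MutationSet(df[["chrom", "pos", "ref", "alt", "mutation_type", "genotype_label"]])


def load_mutations(path, index: GenomeIndex | None = None,
                   genotype_label: str = "") -> MutationSet:
    """Load mutations from VCF (plain or bgzipped) or TSV.

    TSV needs columns chrom, pos, ref, alt and optionally genotype_label
    (header row, or headerless in that order).  Multi-allelic VCF records
    are split into one mutation per ALT.
    """
    path = str(path)
    records: list[tuple] = []
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        from cyvcf2 import VCF

        vcf = VCF(path)
        try:
            for var in vcf:
                for alt in var.ALT:
                    records.append((var.CHROM, var.POS, var.REF, alt, genotype_label))
        finally:
            vcf.close()
    else:
        with open(path) as fh:
            first = fh.readline()
        header = 0 if first.lower().startswith(("chrom", "#chrom")) else None
        names = None if header == 0 else ["chrom", "pos", "ref", "alt", "genotype_label"]
        df = pd.read_csv(path, sep="\t", header=header, names=names, dtype={"chrom": str})
        df.columns = [c.lstrip("#").lower() for c in df.columns]
        if names is None and "genotype_label" not in df.columns:
            df["genotype_label"] = genotype_label
        df = df.dropna(axis=1, how="all")
        if "genotype_label" not in df.columns:
            df["genotype_label"] = genotype_label
        df["genotype_label"] = df["genotype_label"].fillna(genotype_label)
        records = list(df[["chrom", "pos", "ref", "alt", "genotype_label"]].itertuples(index=False, name=None))
    if not records:
        return MutationSet(pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "mutation_type", "genotype_label"]))
    return _from_records(records, index)


def flag_mutation_windows(mutations: MutationSet, windows: WindowSet) -> OverlapFlags:
    """Flag every window whose interval contains a mutation's anchor base.

    A window [start, end) overlaps a mutation at 0-based anchor a iff
    start <= a < end; with fixed size and step this is the run of windows
    with start in (a - size, a], found by binary search on the sorted
    starts.  Mutations falling only in excluded (fully masked) windows are
    kept in the map but raise a warning.
    """
    df = windows.df
    map_rows: list[tuple[int, str]] = []
    for chrom, sub in mutations.df.groupby("chrom", sort=False):
        wsub = df[df["chrom"] == chrom]
        if wsub.empty:
            raise ValueError(f"mutation on chromosome {chrom!r} absent from window set")
        starts = wsub["start"].to_numpy()
        ids = wsub["window_id"].to_numpy()
        incl = wsub["included"].to_numpy()
        anchors = sub["pos"].to_numpy() - 1  # to 0-based
        if (anchors < 0).any() or (anchors >= windows.index.lengths[chrom]).any():
            raise ValueError(f"mutation position outside chromosome {chrom}")
        lo = np.searchsorted(starts, anchors - windows.size, side="right")
        hi = np.searchsorted(starts, anchors, side="right")
        for mi, l, h in zip(sub.index, lo, hi):
            if h <= l:
                continue
            if not incl[l:h].any():
                warnings.warn(
                    f"mutation at {chrom}:{int(mutations.df.loc[mi, 'pos'])} lies only in excluded windows"
                )
            map_rows.extend((mi, ids[j]) for j in range(l, h))
    mutation_map = pd.DataFrame(map_rows, columns=["mutation_index", "window_id"])
    counts = mutation_map["window_id"].value_counts()
    n_mut = pd.Series(0, index=pd.Index(df["window_id"], name="window_id"), dtype=np.int64)
    n_mut.loc[counts.index] = counts.astype(np.int64)
    flags = n_mut > 0
    return OverlapFlags(window_flags=flags, n_mutations=n_mut, mutation_map=mutation_map)


def genic_overlap(mutations: MutationSet, genes: pd.DataFrame) -> OverlapFlags:
    """Flag genes whose half-open span contains a mutation anchor base."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), gid) for s, e, gid in zip(sub["start"], sub["end"], sub["gene_id"])
        )
    map_rows = []
    for mi, row in mutations.df.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for iv in tree[row["pos"] - 1]:
            map_rows.append((mi, iv.data))
    mutation_map = pd.DataFrame(map_rows, columns=["mutation_index", "window_id"])
    counts = mutation_map["window_id"].value_counts()
    n_mut = pd.Series(0, index=pd.Index(genes["gene_id"], name="gene_id"), dtype=np.int64)
    if len(counts):
        n_mut.loc[counts.index] = counts.astype(np.int64)
    flags = n_mut > 0
    return OverlapFlags(window_flags=flags, n_mutations=n_mut, mutation_map=mutation_map)
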