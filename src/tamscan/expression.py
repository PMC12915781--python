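"""Per-window and per-gene expression depth (TPM) and breadth from coverage.

Depth is a length-normalised coverage rate rescaled so the included
normalisation universe sums to one million (a TPM analogue at window
resolution); breadth is the percentage of unmasked bases covered by at
least one read.  For sliding windows the normalisation constant is taken
over the canonical non-overlapping tiling so overlapping windows do not
double-count the library; for genes it is taken over all included genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stepfun import StepFunction, coverage_step
from .windows import GenomeIndex, MaskSet, WindowSet

__all__ = [
    "ProfileLabel",
    "CoverageTrack",
    "ExpressionProfile",
    "load_coverage",
    "merge_tracks",
    "quantify_windows",
    "window_depth_tpm",
    "window_breadth",
    "load_genes",
    "gene_tpm",
    "write_expression_tsv",
]


@dataclass(frozen=True)
class ProfileLabel:
    """Identifies one expression profile: genotype / developmental stage / condition."""

    genotype: str = ""
    stage: str = ""
    condition: str = ""

    def __str__(self) -> str:
        return "/".join(p for p in (self.genotype, self.stage, self.condition) if p) or "profile"


@dataclass
class CoverageTrack:
    """Non-negative per-base read coverage, run-length encoded per chromosome.

    ``intervals[chrom]`` is ``(starts, ends, values)`` with sorted,
    non-overlapping half-open intervals; any base not covered by an
    interval has coverage 0.
    """

    index: GenomeIndex
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    label: ProfileLabel = field(default_factory=ProfileLabel)

    def step(self, chrom: str) -> StepFunction:
        length = self.index.lengths[chrom]
        empty = np.empty(0, dtype=np.int64)
        s, e, v = self.intervals.get(chrom, (empty, empty, empty.astype(float)))
        return coverage_step(length, s, e, v)


@dataclass
class ExpressionProfile:
    """Depth and breadth per window (or gene), for included units only.

    ``table`` is indexed by window_id/gene_id with columns ``depth_tpm``
    and ``breadth_pct``; ``library_rate_total`` is the normalisation
    constant T = sum of per-bp coverage rates over the normalisation
    universe (TPM_i = 1e6 * rate_i / T).
    """

    label: ProfileLabel
    table: pd.DataFrame
    library_rate_total: float


def load_coverage(bedgraph_path, index: GenomeIndex, label: ProfileLabel | None = None) -> CoverageTrack:
    """Parse a 4-column bedGraph (e.g. ``bedtools genomecov -bga`` output)."""
    try:
        df = pd.read_csv(
            bedgraph_path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if (df["value"] < 0).any() if len(df) else False:
        raise ValueError(f"{bedgraph_path}: negative coverage value")
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in index.lengths:
            raise ValueError(f"{bedgraph_path}: unknown chromosome {chrom!r}")
        sub = sub.sort_values("start")
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        v = sub["value"].to_numpy()
        if (s >= e).any():
            raise ValueError(f"{bedgraph_path}: interval with start >= end on {chrom}")
        if s[0] < 0 or e[-1] > index.lengths[chrom]:
            raise ValueError(f"{bedgraph_path}: interval outside {chrom} bounds")
        if (s[1:] < e[:-1]).any():
            raise ValueError(f"{bedgraph_path}: overlapping intervals on {chrom}")
        keep = v != 0
        intervals[chrom] = (s[keep], e[keep], v[keep])
    return CoverageTrack(index=index, intervals=intervals, label=label or ProfileLabel())


def merge_tracks(tracks: list[CoverageTrack], label: ProfileLabel | None = None) -> CoverageTrack:
    """Sum coverage of several libraries belonging to one profile."""
    if not tracks:
        raise ValueError("no tracks to merge")
    index = tracks[0].index
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in index.names:
        total = tracks[0].step(chrom)
        for t in tracks[1:]:
            other = t.step(chrom)
            bp = np.union1d(total.bp, other.bp)
            left = bp[:-1]
            a = total.values[np.clip(np.searchsorted(total.bp, left, "right") - 1, 0, None)]
            b = other.values[np.clip(np.searchsorted(other.bp, left, "right") - 1, 0, None)]
            total = StepFunction(bp, a + b)
        nz = total.values != 0
        out[chrom] = (total.bp[:-1][nz], total.bp[1:][nz], total.values[nz])
    return CoverageTrack(index=index, intervals=out, label=label or tracks[0].label)


def _interval_stats(track: CoverageTrack, mask: MaskSet, index: GenomeIndex,
                    df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-row (coverage sum, covered-base count) over unmasked bases."""
    cov_sum = np.zeros(len(df))
    cov_bases = np.zeros(len(df))
    chroms = df["chrom"].to_numpy()
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    for chrom in index.names:
        sel = chroms == chrom
        if not sel.any():
            continue
        length = index.lengths[chrom]
        unmasked = mask.unmasked_step(chrom, length)
        cov = track.step(chrom)
        cov_sum[sel] = cov.multiply(unmasked).window_sums(starts[sel], ends[sel])
        cov_bases[sel] = cov.threshold(1.0).multiply(unmasked).window_sums(starts[sel], ends[sel])
    return cov_sum, cov_bases


def quantify_windows(track: CoverageTrack, windows: WindowSet,
                     mask: MaskSet | None = None) -> ExpressionProfile:
    """Depth (TPM) and breadth (%) for every included window.

    rate_i = coverage sum over unmasked bases / effective length;
    T = sum of rates over the canonical tiling (the non-overlapping
    normalisation universe); depth_tpm_i = 1e6 * rate_i / T (all zero when
    the library is empty, T = 0).
    """
    mask = mask or MaskSet.empty()
    df = windows.df
    cov_sum, cov_bases = _interval_stats(track, mask, windows.index, df)
    eff = df["effective_length"].to_numpy().astype(float)
    included = df["included"].to_numpy()
    rate = np.zeros(len(df))
    rate[included] = cov_sum[included] / eff[included]
    total = float(rate[(df["canonical"] & df["included"]).to_numpy()].sum())
    depth = np.zeros(len(df)) if total == 0 else 1e6 * rate / total
    breadth = np.zeros(len(df))
    breadth[included] = 100.0 * cov_bases[included] / eff[included]
    table = pd.DataFrame(
        {"depth_tpm": depth[included], "breadth_pct": breadth[included]},
        index=pd.Index(df.loc[included, "window_id"], name="window_id"),
    )
    return ExpressionProfile(label=track.label, table=table, library_rate_total=total)


def window_depth_tpm(track: CoverageTrack, windows: WindowSet,
                     mask: MaskSet | None = None) -> ExpressionProfile:
    """Expression depth (TPM) per window; see :func:`quantify_windows`."""
    return quantify_windows(track, windows, mask)


def window_breadth(track: CoverageTrack, windows: WindowSet,
                   mask: MaskSet | None = None) -> ExpressionProfile:
    """Expression breadth (% unmasked bases with coverage >= 1) per window."""
    return quantify_windows(track, windows, mask)


def load_genes(gff3_path, index: GenomeIndex, feature_type: str = "gene") -> pd.DataFrame:
    """Gene spans from GFF3 as a table (gene_id, chrom, start, end), 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        if feat.seqid not in index.lengths:
            raise ValueError(f"{gff3_path}: unknown chromosome {feat.seqid!r}")
        gid = feat.id or f"{feat.seqid}:{feat.start}-{feat.end}"
        rows.append((gid, feat.seqid, feat.start - 1, feat.end))
    if not rows:
        raise ValueError(f"no {feature_type!r} features in {gff3_path}")
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def gene_tpm(track: CoverageTrack, genes: pd.DataFrame,
             mask: MaskSet | None = None) -> ExpressionProfile:
    """Depth (TPM) and breadth per gene over its full genomic span.

    The normalisation total is taken over all genes with unmasked length
    > 0; fully masked genes are excluded with a warning.
    """
    mask = mask or MaskSet.empty()
    index = track.index
    cov_sum, cov_bases = _interval_stats(track, mask, index, genes)
    eff = np.zeros(len(genes))
    for chrom in index.names:
        sel = (genes["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        unmasked = mask.unmasked_step(chrom, index.lengths[chrom])
        eff[sel] = unmasked.window_sums(genes.loc[sel, "start"].to_numpy(),
                                        genes.loc[sel, "end"].to_numpy())
    included = eff > 0
    if not included.all():
        warnings.warn(f"{int((~included).sum())} gene(s) fully masked; excluded")
    rate = np.zeros(len(genes))
    rate[included] = cov_sum[included] / eff[included]
    total = float(rate[included].sum())
    depth = np.zeros(len(genes)) if total == 0 else 1e6 * rate / total
    breadth = np.zeros(len(genes))
    breadth[included] = 100.0 * cov_bases[included] / eff[included]
    table = pd.DataFrame(
        {"depth_tpm": depth[included], "breadth_pct": breadth[included]},
        index=pd.Index(genes.loc[included, "gene_id"], name="gene_id"),
    )
    return ExpressionProfile(label=track.label, table=table, library_rate_total=total)


def write_expression_tsv(profile: ExpressionProfile, path) -> None:
    profile.table.to_csv(path, sep="\t", float_format="%.10g")
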