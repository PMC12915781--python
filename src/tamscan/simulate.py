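"""Synthetic genomes, masks, coverage tracks, genes and mutation calls.

The generator emulates the statistical structure of a mutation-accumulation
study analysed against RNA-seq coverage: a multi-chromosome genome with a
masked fraction, zero-inflated heavy-tailed window-level expression, tens
of mutations per genotype, and a tunable dependence of mutation placement
on local expression.

The mutation model is multiplicative in standardised log expression: each
mutation's window w is drawn with probability proportional to
exp(beta * z_w), where z_w is the z-score of log1p(lambda_w) across
included tiling windows, and the base within the window is uniform over
unmasked positions.  beta = 0 is the null (placement independent of
expression); beta > 0 enriches mutations in highly transcribed windows.
This is a verification device — the simplest monotone link — not a claim
about any real mutagenesis mechanism.

Everything is drawn from a single numpy Generator seeded by the config, so
two runs with the same config produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CoverageTrack, ProfileLabel
from .mutations import MutationSet
from .windows import GenomeIndex, MaskSet, WindowSet, make_windows

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "SyntheticBundle",
    "SyntheticDataset",
    "simulate_genome",
    "simulate_expression",
    "simulate_mutations",
    "simulate_bundle",
    "simulate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic genome/expression/mutation model.

    Defaults mirror the scale of the study design being emulated: nine
    genotypes with 73 mutations each (657 total) over a few-Mb genome,
    four expression profiles (three developmental stages plus a chemical
    exposure condition), ~10% of the genome masked, window-level
    expression that is 30% zero with a log-normal heavy tail, and
    beta = 0 (no transcription effect) as the null.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_length: int = 1_000_000
    masked_fraction: float = 0.10
    mask_mean_length: int = 1_000
    gc_mean: float = 0.40
    gc_sd: float = 0.05
    window_size: int = 10_000  # resolution at which expression truth is defined
    zero_fraction: float = 0.30
    log_mu: float = 0.0
    log_sigma: float = 1.5
    profile_sigma: float = 0.30  # per-profile multiplicative lognormal noise
    read_depth: float = 2.0  # scales mean per-base coverage
    profiles: tuple[tuple[str, str], ...] = (
        ("neonate", "control"),
        ("juvenile", "control"),
        ("adult", "control"),
        ("adult", "benzotriazole"),
    )
    n_genotypes: int = 9
    mutations_per_genotype: int = 73
    effect_size: float = 0.0  # beta; 0 = null
    type_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)  # substitution, insertion, deletion
    genic_fraction: float = 0.40
    gene_mean_length: int = 2_000

    def __post_init__(self):
        if not (0 <= self.masked_fraction < 1):
            raise ValueError("masked_fraction must be in [0, 1)")
        if not (0 <= self.zero_fraction <= 1):
            raise ValueError("zero_fraction must be in [0, 1]")
        if not (0 <= self.gc_mean <= 1) or self.gc_sd < 0:
            raise ValueError("invalid GC parameters")
        if self.chromosome_length < 1 or self.n_chromosomes < 1:
            raise ValueError("genome dimensions must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if abs(sum(self.type_mix) - 1) > 1e-9 or any(p < 0 for p in self.type_mix):
            raise ValueError("type_mix must be non-negative and sum to 1")

    @classmethod
    def calibration(cls, seed: int = 0, effect_size: float = 0.0,
                    mutations: int = 100) -> "SimulationConfig":
        """Single-chromosome geometry used for statistical calibration runs:
        1 Mb unmasked genome, 10 kb tiling, one genotype, one profile."""
        return cls(
            seed=seed,
            n_chromosomes=1,
            chromosome_length=1_000_000,
            masked_fraction=0.0,
            n_genotypes=1,
            mutations_per_genotype=mutations,
            effect_size=effect_size,
            profiles=(("adult", "control"),),
        )


@dataclass
class SyntheticGenome:
    index: GenomeIndex
    sequences: dict[str, np.ndarray]  # uint8 ASCII per chromosome
    mask: MaskSet
    true_gc: dict[str, np.ndarray]  # per tiling window

    def sequence_str(self, chrom: str) -> str:
        return self.sequences[chrom].tobytes().decode("ascii")


@dataclass
class SyntheticBundle:
    """In-memory dataset: genome, tiling windows, per-profile tracks,
    genes, pooled mutations, and the generative truth."""

    config: SimulationConfig
    genome: SyntheticGenome
    windows: WindowSet
    tracks: list[CoverageTrack]
    genes: pd.DataFrame
    mutations: MutationSet
    truth: dict


@dataclass
class SyntheticDataset:
    """Paths of a bundle written to disk, plus the truth record."""

    root: Path
    fasta: Path
    mask_bed: Path
    bedgraphs: list[Path]
    gff3: Path
    vcfs: list[Path]
    truth_json: Path
    truth: dict


def _random_intervals(rng: np.random.Generator, length: int, fraction: float,
                      mean_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Sorted non-overlapping intervals covering ~fraction of [0, length)."""
    target = int(round(fraction * length))
    if target <= 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty
    k = max(1, int(round(target / mean_len)))
    lens = np.maximum(1, rng.exponential(mean_len, size=k)).astype(np.int64)
    lens = np.maximum(1, np.round(lens * target / lens.sum()).astype(np.int64))
    excess = int(lens.sum()) - target
    lens[-1] = max(1, lens[-1] - excess)
    free = length - int(lens.sum())
    if free < 0:  # fraction close to 1 with rounding overshoot
        lens = (lens * (length - k) // int(lens.sum())).clip(min=1)
        free = length - int(lens.sum())
    gaps = rng.multinomial(free, np.full(k + 1, 1 / (k + 1)))
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lens[:-1]]))
    return starts.astype(np.int64), (starts + lens).astype(np.int64)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, low: float = 0.0, high: float = 1.0) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, low, high))
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, size=todo.size)
        ok = (draw >= low) & (draw <= high)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def simulate_genome(config: SimulationConfig, rng: np.random.Generator) -> SyntheticGenome:
    """Random genome with per-window GC from a truncated normal, plus mask."""
    names = tuple(f"chr{i + 1}" for i in range(config.n_chromosomes))
    lengths = {n: config.chromosome_length for n in names}
    index = GenomeIndex(names, lengths)
    sequences: dict[str, np.ndarray] = {}
    true_gc: dict[str, np.ndarray] = {}
    mask_intervals: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    w = config.window_size
    for chrom in names:
        length = lengths[chrom]
        n_win = (length + w - 1) // w
        gc = _truncated_normal(rng, config.gc_mean, config.gc_sd, n_win)
        sizes = np.minimum(w, length - w * np.arange(n_win))
        p_gc = np.repeat(gc, sizes)
        u = rng.random(length)
        v = rng.random(length)
        is_gc = u < p_gc
        # within each pair choose uniformly: A/T for AT, G/C for GC
        base_idx = np.where(is_gc, np.where(v < 0.5, 1, 2), np.where(v < 0.5, 0, 3))
        sequences[chrom] = _BASES[base_idx]
        true_gc[chrom] = gc
        if config.masked_fraction > 0:
            mask_intervals[chrom] = _random_intervals(
                rng, length, config.masked_fraction, config.mask_mean_length
            )
    return SyntheticGenome(index=index, sequences=sequences,
                           mask=MaskSet(mask_intervals), true_gc=true_gc)


def simulate_expression(
    config: SimulationConfig,
    genome: SyntheticGenome,
    windows: WindowSet,
    rng: np.random.Generator,
    label: ProfileLabel = ProfileLabel(),
    base_rates: dict[str, np.ndarray] | None = None,
) -> tuple[CoverageTrack, dict[str, np.ndarray]]:
    """Zero-inflated log-normal window rates realised as per-base Poisson coverage.

    ``base_rates`` (per canonical tiling window, per chromosome) may be
    supplied to share one underlying transcription landscape across
    profiles; per-profile multiplicative log-normal noise
    (``profile_sigma``) is applied on top.  Returns the coverage track and
    the realised per-window rates (the truth).
    """
    intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    realised: dict[str, np.ndarray] = {}
    canon = windows.canonical
    for chrom in genome.index.names:
        sub = canon[canon["chrom"] == chrom]
        sizes = (sub["end"] - sub["start"]).to_numpy()
        n_win = len(sub)
        if base_rates is None:
            lam = np.where(
                rng.random(n_win) < config.zero_fraction,
                0.0,
                rng.lognormal(config.log_mu, config.log_sigma, size=n_win),
            )
        else:
            lam = base_rates[chrom].copy()
        if config.profile_sigma > 0:
            noise = rng.lognormal(0.0, config.profile_sigma, size=n_win)
            lam_prof = lam * noise
        else:
            lam_prof = lam
        realised[chrom] = lam_prof
        per_base_mean = np.repeat(lam_prof * config.read_depth, sizes)
        cov = rng.poisson(per_base_mean).astype(np.int64)
        # run-length encode the per-base coverage
        change = np.flatnonzero(np.diff(cov)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [cov.size]])
        vals = cov[starts]
        nz = vals != 0
        intervals[chrom] = (starts[nz], ends[nz], vals[nz].astype(np.float64))
    track = CoverageTrack(index=genome.index, intervals=intervals, label=label)
    return track, realised


def _window_probabilities(beta: float, lam: np.ndarray) -> np.ndarray:
    """Softmax of beta * z-score of log1p(rate) across windows."""
    z = np.log1p(lam)
    sd = z.std()
    z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
    w = np.exp(beta * z - (beta * z).max())
    return w / w.sum()


def simulate_mutations(
    config: SimulationConfig,
    rates: dict[str, np.ndarray],
    windows: WindowSet,
    genome: SyntheticGenome,
    rng: np.random.Generator,
    genotype: str,
) -> MutationSet:
    """Place one genotype's mutations with window weight exp(beta * z_w)."""
    canon = windows.canonical
    chroms = canon["chrom"].to_numpy()
    starts = canon["start"].to_numpy()
    ends = canon["end"].to_numpy()
    incl = canon["included"].to_numpy()
    lam = np.concatenate([rates[c] for c in genome.index.names])
    if not incl.any():
        raise ValueError("no included windows to place mutations in")
    probs = np.zeros(len(canon))
    probs[incl] = _window_probabilities(config.effect_size, lam[incl])
    n = config.mutations_per_genotype
    records = []
    if n > 0:
        win_draw = rng.choice(len(canon), size=n, p=probs)
        type_draw = rng.choice(3, size=n, p=np.asarray(config.type_mix))
        for wi, ti in zip(win_draw, type_draw):
            chrom = chroms[wi]
            ms, me = genome.mask.get(chrom)
            ok = np.ones(ends[wi] - starts[wi], dtype=bool)
            for s, e in zip(ms, me):
                lo, hi = max(s, starts[wi]), min(e, ends[wi])
                if lo < hi:
                    ok[lo - starts[wi]:hi - starts[wi]] = False
            positions = np.flatnonzero(ok) + starts[wi]
            # keep room for a short deletion allele before the chromosome end
            positions = positions[positions < genome.index.lengths[chrom] - 4]
            if positions.size == 0:
                raise ValueError(f"window {chrom}:{starts[wi]} has no usable unmasked position")
            pos0 = int(rng.choice(positions))
            seq = genome.sequences[chrom]
            ref_base = chr(seq[pos0])
            if ti == 0:  # substitution
                alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
                ref = ref_base
            elif ti == 1:  # insertion of 1-3 bases after the anchor
                ins_len = int(rng.integers(1, 4))
                ins = "".join(rng.choice(list("ACGT"), size=ins_len))
                ref, alt = ref_base, ref_base + ins
            else:  # deletion of 1-3 bases after the anchor
                del_len = int(rng.integers(1, 4))
                ref = seq[pos0:pos0 + 1 + del_len].tobytes().decode("ascii")
                alt = ref_base
            records.append((chrom, pos0 + 1, ref, alt, "base_substitution" if ti == 0
                            else ("insertion" if ti == 1 else "deletion"), genotype))
    df = pd.DataFrame(records, columns=["chrom", "pos", "ref", "alt", "mutation_type", "genotype_label"])
    return MutationSet(df)


def _simulate_genes(config: SimulationConfig, genome: SyntheticGenome,
                    rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for chrom in genome.index.names:
        s, e = _random_intervals(rng, genome.index.lengths[chrom],
                                 config.genic_fraction, config.gene_mean_length)
        for a, b in zip(s, e):
            i += 1
            rows.append((f"gene{i}", chrom, int(a), int(b)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def simulate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate a full in-memory dataset from the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    genome = simulate_genome(config, rng)
    windows = make_windows(genome.index, config.window_size, config.window_size)
    from .windows import apply_mask

    windows = apply_mask(windows, genome.mask)
    canon = windows.canonical
    # shared transcription landscape across profiles
    base_rates: dict[str, np.ndarray] = {}
    for chrom in genome.index.names:
        n_win = int((canon["chrom"] == chrom).sum())
        base_rates[chrom] = np.where(
            rng.random(n_win) < config.zero_fraction,
            0.0,
            rng.lognormal(config.log_mu, config.log_sigma, size=n_win),
        )
    tracks = []
    profile_rates = {}
    for stage, condition in config.profiles:
        label = ProfileLabel(stage=stage, condition=condition)
        track, realised = simulate_expression(config, genome, windows, rng,
                                              label=label, base_rates=base_rates)
        tracks.append(track)
        profile_rates[f"{stage}/{condition}"] = {c: r.tolist() for c, r in realised.items()}
    genes = _simulate_genes(config, genome, rng)
    genotype_names = [f"G{i + 1}" for i in range(config.n_genotypes)]
    parts = []
    for g in genotype_names:
        parts.append(simulate_mutations(config, base_rates, windows, genome, rng, g).df)
    mutations = MutationSet(pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["chrom", "pos", "ref", "alt", "mutation_type", "genotype_label"]))
    truth = {
        "config": asdict(config),
        "effect_size": config.effect_size,
        "base_rates": {c: r.tolist() for c, r in base_rates.items()},
        "profile_rates": profile_rates,
        "window_ids": canon["window_id"].tolist(),
    }
    return SyntheticBundle(config=config, genome=genome, windows=windows,
                           tracks=tracks, genes=genes, mutations=mutations, truth=truth)


def _write_fasta(genome: SyntheticGenome, path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.index.names:
            fh.write(f">{chrom}\n")
            seq = genome.sequence_str(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _write_mask_bed(mask: MaskSet, index: GenomeIndex, path: Path) -> None:
    with open(path, "w") as fh:
        for chrom in index.names:
            s, e = mask.get(chrom)
            for a, b in zip(s, e):
                fh.write(f"{chrom}\t{a}\t{b}\n")


def _write_bedgraph(track: CoverageTrack, path: Path) -> None:
    frames = []
    for chrom in track.index.names:
        s, e, v = track.intervals.get(chrom, (np.empty(0),) * 3)
        frames.append(pd.DataFrame({"chrom": chrom, "start": s.astype(np.int64),
                                    "end": e.astype(np.int64), "value": v.astype(np.int64)}))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", header=False, index=False)


def _write_gff3(genes: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in genes.iterrows():
            fh.write(
                f"{row['chrom']}\ttamscan\tgene\t{row['start'] + 1}\t{row['end']}\t.\t+\t.\tID={row['gene_id']}\n"
            )


def _write_vcf(mutations: MutationSet, index: GenomeIndex, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in index.names:
            fh.write(f"##contig=<ID={chrom},length={index.lengths[chrom]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        df = mutations.df.sort_values(["chrom", "pos"])
        for _, row in df.iterrows():
            fh.write(f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\n")


def simulate_dataset(config: SimulationConfig, outdir) -> SyntheticDataset:
    """Generate a bundle and write all files (FASTA, BED, bedGraph, GFF3,
    per-genotype VCF, truth JSON) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_bundle(config)
    fasta = outdir / "genome.fa"
    _write_fasta(bundle.genome, fasta)
    mask_bed = outdir / "mask.bed"
    _write_mask_bed(bundle.genome.mask, bundle.genome.index, mask_bed)
    bedgraphs = []
    for track in bundle.tracks:
        name = f"coverage_{track.label.stage}_{track.label.condition}.bedgraph"
        p = outdir / name
        _write_bedgraph(track, p)
        bedgraphs.append(p)
    gff3 = outdir / "genes.gff3"
    _write_gff3(bundle.genes, gff3)
    vcfs = []
    for g in sorted(bundle.mutations.df["genotype_label"].unique()) if len(bundle.mutations) else []:
        p = outdir / f"mutations_{g}.vcf"
        _write_vcf(bundle.mutations.subset(genotype=g), bundle.genome.index, p)
        vcfs.append(p)
    truth_json = outdir / "truth.json"
    truth = dict(bundle.truth)
    truth["files_sha256"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in [fasta, mask_bed, gff3, *bedgraphs, *vcfs]
    }
    truth_json.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return SyntheticDataset(root=outdir, fasta=fasta, mask_bed=mask_bed,
                            bedgraphs=bedgraphs, gff3=gff3, vcfs=vcfs,
                            truth_json=truth_json, truth=truth)
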