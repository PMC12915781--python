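"""End-to-end orchestration: windows -> quantify -> overlap -> tests -> report.

A run consumes a genome FASTA, an optional mask BED, one bedGraph per
expression profile, mutation calls (VCF/TSV, one per genotype or pooled),
and optionally a GFF3 gene annotation; it emits TSV tables (test battery,
quartile report, genic tests), a JSON significance summary and a JSON run
manifest with output checksums.  All randomness flows from the single
config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import quartile_enrichment, run_battery
from .expression import ProfileLabel, gene_tpm, load_coverage, load_genes, quantify_windows
from .mutations import MutationSet, genic_overlap, load_mutations, flag_mutation_windows
from .windows import MaskSet, annotate_gc, apply_mask, load_genome_index, make_windows, write_windows_bed

logger = logging.getLogger("tamscan")

ALPHAS = (0.05, 0.01, 0.001)
_FLOAT_FMT = "%.10g"


@dataclass
class CoverageInput:
    path: str
    stage: str = ""
    condition: str = ""
    genotype: str = ""

    @property
    def label(self) -> ProfileLabel:
        return ProfileLabel(genotype=self.genotype, stage=self.stage, condition=self.condition)


@dataclass
class MutationInput:
    path: str
    genotype: str = ""


@dataclass
class RunConfig:
    fasta: str
    coverage: list[CoverageInput]
    mutations: list[MutationInput]
    outdir: str
    mask_bed: str | None = None
    gff3: str | None = None
    window_configs: list[tuple[int, int]] = field(default_factory=lambda: [(10_000, 1_000), (1_000, 100)])
    metrics: tuple[str, ...] = ("depth_tpm", "breadth_pct")
    mutation_types: tuple[str, ...] = ("all",)
    n_permutations: int = 10_000
    tie_rule: str = "strict_greater"
    gc_band: tuple[float, float] | None = (0.30, 0.50)
    seed: int = 0
    gene_feature: str = "gene"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["coverage"] = [CoverageInput(**c) for c in raw.get("coverage", [])]
        raw["mutations"] = [MutationInput(**m) for m in raw.get("mutations", [])]
        if "window_configs" in raw:
            raw["window_configs"] = [tuple(w) for w in raw["window_configs"]]
        if raw.get("gc_band") is not None:
            raw["gc_band"] = tuple(raw["gc_band"])
        for key in ("metrics", "mutation_types"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        paths = [self.fasta] + [c.path for c in self.coverage] + [m.path for m in self.mutations]
        if self.mask_bed:
            paths.append(self.mask_bed)
        if self.gff3:
            paths.append(self.gff3)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if not self.coverage:
            raise ValueError("at least one coverage track is required")
        if not self.mutations:
            raise ValueError("at least one mutation file is required")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def significance_summary(battery: pd.DataFrame, alphas=ALPHAS) -> dict:
    """Counts of significant tests at each alpha (strict <, so p == alpha is ns)."""
    ok = battery[battery["status"] == "ok"]
    return {
        "n_tests": int(len(ok)),
        "n_skipped": int((battery["status"] == "skipped").sum()),
        "significant": {str(a): int((ok["p_value"] < a).sum()) for a in alphas},
    }


def write_report(battery: pd.DataFrame, quartiles: pd.DataFrame | None,
                 outdir: Path, prefix: str = "report") -> Path:
    """JSON summary with per-alpha significant-test counts (Fig.-2-style stars)."""
    summary = {"battery": significance_summary(battery)}
    if quartiles is not None and len(quartiles):
        summary["quartiles"] = {
            "mean_flagged_fraction": quartiles.groupby("quartile")["flagged_fraction"].mean().to_dict()
        }
    path = outdir / f"{prefix}.json"
    path.write_text(json.dumps(summary, indent=1, sort_keys=True))
    return path


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    t0 = time.time()
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    outputs: list[Path] = []

    index = load_genome_index(config.fasta)
    mask = MaskSet.from_bed(config.mask_bed, index) if config.mask_bed else MaskSet.empty()
    logger.info("genome: %d chromosomes, %d bp, %d bp masked",
                len(index.names), index.total_length, mask.total_masked())

    tracks = [load_coverage(c.path, index, c.label) for c in config.coverage]
    parts = [load_mutations(m.path, index, genotype_label=m.genotype or Path(m.path).stem).df
             for m in config.mutations]
    mutations = MutationSet(pd.concat(parts, ignore_index=True))
    counts["mutations"] = len(mutations)
    logger.info("loaded %d mutations across %d genotypes, %d coverage tracks",
                len(mutations), len(mutations.genotypes), len(tracks))

    quartile_frames = []
    for size, step in config.window_configs:
        tag = f"w{size}_s{step}"
        windows = make_windows(index, size, step)
        windows = apply_mask(windows, mask)
        windows = annotate_gc(windows, config.fasta, mask)
        counts[f"windows_{tag}"] = len(windows)
        wpath = outdir / f"windows_{tag}.bed"
        write_windows_bed(windows, wpath)
        outputs.append(wpath)

        profiles = [quantify_windows(t, windows, mask) for t in tracks]
        for prof in profiles:
            ppath = outdir / f"expression_{tag}_{str(prof.label).replace('/', '_')}.tsv"
            prof.table.to_csv(ppath, sep="\t", float_format=_FLOAT_FMT)
            outputs.append(ppath)

        battery = run_battery(
            windows, profiles, mutations,
            metrics=config.metrics,
            mutation_types=config.mutation_types,
            gc_band=config.gc_band,
            n_permutations=config.n_permutations,
            seed=config.seed,
            tie_rule=config.tie_rule,
        )
        bpath = outdir / f"battery_{tag}.tsv"
        battery.to_csv(bpath, sep="\t", index=False, float_format=_FLOAT_FMT)
        outputs.append(bpath)
        counts[f"battery_{tag}"] = len(battery)
        logger.info("window config %s: %d windows, %d battery rows", tag, len(windows), len(battery))

        if (size, step) == config.window_configs[0]:
            # quartile enrichment on the non-overlapping tiling of the
            # primary (largest-window) configuration
            from dataclasses import replace as _dc_replace

            tiling = _dc_replace(windows, df=windows.canonical.reset_index(drop=True),
                                 step=windows.size)
            for genotype in mutations.genotypes:
                flags = flag_mutation_windows(mutations.subset(genotype=genotype), tiling)
                for prof in profiles:
                    rep = quartile_enrichment(tiling, prof, flags, seed=config.seed)
                    frame = rep.to_frame()
                    frame.insert(0, "genotype", genotype)
                    frame.insert(1, "profile", str(prof.label))
                    quartile_frames.append(frame)
            primary_battery = battery

    quartiles = pd.concat(quartile_frames, ignore_index=True) if quartile_frames else pd.DataFrame(
        columns=["genotype", "profile", "quartile", "n_windows", "n_flagged", "flagged_fraction"])
    qpath = outdir / "quartiles.tsv"
    quartiles.to_csv(qpath, sep="\t", index=False, float_format=_FLOAT_FMT)
    outputs.append(qpath)

    if config.gff3:
        genes = load_genes(config.gff3, index, feature_type=config.gene_feature)
        counts["genes"] = len(genes)
        gene_rows = []
        for track in tracks:
            gprof = gene_tpm(track, genes, mask)
            incl_ids = gprof.table.index
            for genotype in mutations.genotypes:
                gflags = genic_overlap(mutations.subset(genotype=genotype), genes)
                flagged = gflags.window_flags.reindex(incl_ids).fillna(False).to_numpy()
                row = {"genotype": genotype, "profile": str(track.label),
                       "n_genes": len(incl_ids), "n_flagged": int(flagged.sum()),
                       "status": "ok", "p_value": np.nan, "observed_median": np.nan}
                if flagged.any():
                    from .enrichment import permutation_test, _row_seed

                    rng = _row_seed(config.seed, "genic", genotype, str(track.label))
                    res = permutation_test(
                        gprof.table["depth_tpm"].to_numpy(), flagged,
                        n_permutations=config.n_permutations, seed=rng,
                        tie_rule=config.tie_rule, metric="depth_tpm")
                    row.update(p_value=res.p_value, observed_median=res.observed_median)
                else:
                    row.update(status="skipped")
                gene_rows.append(row)
        gpath = outdir / "genic_tests.tsv"
        pd.DataFrame(gene_rows).to_csv(gpath, sep="\t", index=False, float_format=_FLOAT_FMT)
        outputs.append(gpath)

    rpath = write_report(primary_battery, quartiles, outdir)
    outputs.append(rpath)

    manifest = {
        "version": __version__,
        "config": {
            **{k: v for k, v in vars(config).items() if k not in ("coverage", "mutations")},
            "coverage": [vars(c) for c in config.coverage],
            "mutations": [vars(m) for m in config.mutations],
        },
        "counts": counts,
        "outputs_sha256": {p.name: _sha256(p) for p in outputs},
        "wall_clock_s": round(time.time() - t0, 3),
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    logger.info("run complete in %.1fs; outputs in %s", time.time() - t0, outdir)
    return outdir
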