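"""Median permutation tests for expression enrichment in mutated regions.

The core question: do windows (or genes) containing spontaneous mutations
show higher expression than expected by chance?  The test statistic is the
median of the expression metric over the k mutation-containing windows;
the null distribution is built by repeatedly drawing k windows uniformly
without replacement from all included windows and recording their median.
The p-value is one-sided for elevated expression: the fraction of
permutations whose median is greater than (or, under the
``greater_or_equal`` tie rule, at least) the observed median.

Also here: an exhaustive small-instance oracle that enumerates every
k-subset, the GC-matched control (restrict universe and flagged set to a
GC band), expression-quartile enrichment of mutated windows, and the
multi-profile test battery.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .expression import ExpressionProfile
from .mutations import MUTATION_TYPES, MutationSet, OverlapFlags, flag_mutation_windows
from .windows import WindowSet

__all__ = [
    "PermutationResult",
    "GCMatchedResult",
    "QuartileReport",
    "permutation_test",
    "exhaustive_pvalue",
    "gc_matched_test",
    "quartile_enrichment",
    "run_battery",
]

TIE_RULES = ("strict_greater", "greater_or_equal", "add_one")


@dataclass
class PermutationResult:
    metric: str
    observed_median: float
    n_flagged: int
    n_included: int
    n_permutations: int
    p_value: float
    tie_rule: str
    seed: int | None
    null_medians: np.ndarray = field(repr=False, default=None)


@dataclass
class GCMatchedResult:
    """Permutation test restricted to a GC band, with retention diagnostics."""

    result: PermutationResult
    gc_low: float
    gc_high: float
    fraction_retained: float
    gc_flagged: np.ndarray = field(repr=False, default=None)
    gc_universe: np.ndarray = field(repr=False, default=None)


@dataclass
class QuartileReport:
    """Distribution of mutation-containing windows across expression quartiles.

    Quartile 0 is the lowest-expression quarter, quartile 3 the highest.
    Ties (the many zero-TPM windows) are broken by seeded random ranking
    so the four groups have equal size (+-1) and the null is uniform.
    """

    boundaries: np.ndarray  # metric values at the 25/50/75% rank cuts
    window_counts: np.ndarray  # included windows per quartile
    flagged_counts: np.ndarray
    flagged_fractions: np.ndarray
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quartile": ["Q1_low", "Q2", "Q3", "Q4_high"],
                "n_windows": self.window_counts,
                "n_flagged": self.flagged_counts,
                "flagged_fraction": self.flagged_fractions,
            }
        )


def _statistic(values: np.ndarray, kind: str) -> float:
    return float(np.mean(values)) if kind == "mean" else float(np.median(values))


def _as_arrays(values, flagged) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    flagged = np.asarray(flagged, dtype=bool)
    if values.shape != flagged.shape:
        raise ValueError("values and flags must align")
    return values, flagged


def _pvalue(null_stats: np.ndarray, observed: float, tie_rule: str) -> float:
    n = null_stats.size
    if tie_rule == "strict_greater":
        return float(np.count_nonzero(null_stats > observed) / n)
    if tie_rule == "greater_or_equal":
        return float(np.count_nonzero(null_stats >= observed) / n)
    if tie_rule == "add_one":
        return float((np.count_nonzero(null_stats > observed) + 1) / (n + 1))
    raise ValueError(f"unknown tie_rule {tie_rule!r}")


def permutation_test(
    values,
    flagged,
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    tie_rule: str = "strict_greater",
    metric: str = "depth_tpm",
    statistic: str = "median",
) -> PermutationResult:
    """Monte-Carlo permutation test of elevated expression in flagged windows.

    ``values`` are the metric over included windows and ``flagged`` marks
    the k mutation-containing ones; each permutation draws k windows
    uniformly without replacement from all included windows (flagged ones
    are not removed from the pool).
    """
    values, flagged = _as_arrays(values, flagged)
    n = values.size
    k = int(flagged.sum())
    if k == 0:
        raise ValueError("no mutation-containing windows")
    if k > n:
        raise ValueError("more flagged windows than included windows")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = _statistic(values[flagged], statistic)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Draw all permutations at once when the index matrix is small enough;
    # each row of argpartition(random matrix) is a uniform k-subset.
    if n * n_permutations <= 40_000_000:
        r = rng.random((n_permutations, n))
        idx = np.argpartition(r, k - 1, axis=1)[:, :k] if k < n else np.tile(np.arange(n), (n_permutations, 1))
        sampled = values[idx]
        null_stats = np.mean(sampled, axis=1) if statistic == "mean" else np.median(sampled, axis=1)
    else:
        null_stats = np.empty(n_permutations)
        for i in range(n_permutations):
            null_stats[i] = _statistic(values[rng.choice(n, size=k, replace=False)], statistic)
    return PermutationResult(
        metric=metric,
        observed_median=observed,
        n_flagged=k,
        n_included=n,
        n_permutations=n_permutations,
        p_value=_pvalue(null_stats, observed, tie_rule),
        tie_rule=tie_rule,
        seed=seed if isinstance(seed, int) else None,
        null_medians=null_stats,
    )


def exhaustive_pvalue(values, flagged, tie_rule: str = "strict_greater",
                      statistic: str = "median", max_subsets: int = 1_000_000) -> float:
    """Exact p-value by enumerating every k-subset of included windows.

    Verification oracle for :func:`permutation_test`; refuses instances
    with more than ``max_subsets`` subsets (use Monte Carlo there).
    """
    values, flagged = _as_arrays(values, flagged)
    n, k = values.size, int(flagged.sum())
    if k == 0:
        raise ValueError("no mutation-containing windows")
    total = comb(n, k)
    if total > max_subsets:
        raise ValueError(f"C({n},{k}) = {total} subsets exceeds bound; use Monte-Carlo permutation_test")
    observed = _statistic(values[flagged], statistic)
    hits = 0.0
    for subset in combinations(range(n), k):
        m = _statistic(values[list(subset)], statistic)
        if tie_rule == "greater_or_equal":
            hits += m >= observed
        else:
            hits += m > observed
    if tie_rule == "add_one":
        return (hits + 1) / (total + 1)
    return hits / total


def gc_matched_test(
    windows: WindowSet,
    profile: ExpressionProfile,
    flags: OverlapFlags,
    gc_low: float = 0.30,
    gc_high: float = 0.50,
    metric: str = "depth_tpm",
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = None,
    tie_rule: str = "strict_greater",
    statistic: str = "median",
) -> GCMatchedResult:
    """Permutation test restricted to windows in a GC band (inclusive bounds).

    GC content correlates with both expression and mutation rate; over a
    band where the GC distributions of flagged and all windows are
    indistinguishable, any residual expression signal cannot be a GC
    artefact.  Both the flagged set and the sampling universe are
    restricted to gc_low <= GC <= gc_high before delegating to
    :func:`permutation_test`.
    """
    df = windows.df
    incl = df["included"].to_numpy()
    gc = df["gc_fraction"].to_numpy()
    band = incl & np.isfinite(gc) & (gc >= gc_low) & (gc <= gc_high)
    n_incl = int(incl.sum())
    fraction_retained = float(band.sum() / n_incl) if n_incl else 0.0
    ids = df.loc[band, "window_id"]
    values = profile.table.loc[ids, metric].to_numpy()
    flagged = flags.window_flags.reindex(ids).fillna(False).to_numpy()
    if not flagged.any():
        raise ValueError("no mutation-containing window within the GC band")
    result = permutation_test(values, flagged, n_permutations=n_permutations,
                              seed=seed, tie_rule=tie_rule, metric=metric,
                              statistic=statistic)
    all_flagged = flags.window_flags.reindex(df.loc[incl, "window_id"]).fillna(False).to_numpy()
    return GCMatchedResult(
        result=result,
        gc_low=gc_low,
        gc_high=gc_high,
        fraction_retained=fraction_retained,
        gc_flagged=gc[band][flagged],
        gc_universe=gc[incl][np.isfinite(gc[incl])] if n_incl else np.empty(0),
    )


def quartile_enrichment(
    windows: WindowSet,
    profile: ExpressionProfile,
    flags: OverlapFlags,
    seed: int | np.random.Generator | None = None,
    metric: str = "depth_tpm",
) -> QuartileReport:
    """Fraction of mutation-containing windows per expression quartile."""
    df = windows.df
    incl = df["included"].to_numpy()
    if int(incl.sum()) < 4:
        raise ValueError("need at least 4 included windows for quartiles")
    ids = df.loc[incl, "window_id"]
    values = profile.table.loc[ids, metric].to_numpy()
    flagged = flags.window_flags.reindex(ids).fillna(False).to_numpy()
    if not flagged.any():
        raise ValueError("no mutation-containing windows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = values.size
    order = np.lexsort((rng.random(n), values))  # random tie-break, then value
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    quartile = (ranks * 4) // n  # equal group sizes +-1
    window_counts = np.bincount(quartile, minlength=4)
    flagged_counts = np.bincount(quartile[flagged], minlength=4)
    k = flagged_counts.sum()
    boundaries = np.quantile(values, [0.25, 0.5, 0.75])
    return QuartileReport(
        boundaries=boundaries,
        window_counts=window_counts,
        flagged_counts=flagged_counts,
        flagged_fractions=flagged_counts / k,
        seed=seed if isinstance(seed, int) else None,
    )


def _row_seed(master_seed: int, *key: str) -> np.random.Generator:
    """Reproducible per-row stream from the master seed and the row key."""
    entropy = [int(master_seed)] + [zlib.crc32(k.encode()) for k in key]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_battery(
    windows: WindowSet,
    profiles: list[ExpressionProfile],
    mutations: MutationSet,
    metrics: tuple[str, ...] = ("depth_tpm",),
    mutation_types: tuple[str, ...] = ("all",),
    gc_band: tuple[float, float] | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    tie_rule: str = "strict_greater",
    statistic: str = "median",
) -> pd.DataFrame:
    """One permutation test per genotype x profile x metric x type x control.

    Returns a table with one row per combination; empty strata are
    recorded with status "skipped" rather than dropped, so the battery
    shape is always the full Cartesian product.  Benjamini-Hochberg
    adjusted p-values are appended as a separate column (``p_bh``); raw p
    remains primary.  Fully deterministic given ``seed``: each row's
    random stream is derived from the master seed and the row key.
    """
    controls: list[str] = ["none"]
    if gc_band is not None:
        controls.append("gc")
    genotypes = mutations.genotypes or [""]
    incl_ids = windows.included["window_id"]
    rows = []
    for genotype in genotypes:
        for mtype in mutation_types:
            sub = mutations.subset(genotype=genotype, mutation_type=mtype)
            flags = flag_mutation_windows(sub, windows) if len(sub) else None
            for profile in profiles:
                for metric in metrics:
                    for control in controls:
                        key = (genotype, str(profile.label), metric, mtype, control)
                        rng = _row_seed(seed, *key)
                        row = {
                            "genotype": genotype,
                            "profile": str(profile.label),
                            "stage": profile.label.stage,
                            "condition": profile.label.condition,
                            "metric": metric,
                            "mutation_type": mtype,
                            "control": control,
                            "tie_rule": tie_rule,
                            "n_permutations": n_permutations,
                            "seed": seed,
                            "status": "ok",
                            "reason": "",
                            "n_included": int(len(incl_ids)),
                            "n_flagged": 0,
                            "observed_median": np.nan,
                            "p_value": np.nan,
                        }
                        try:
                            if flags is None:
                                raise ValueError(f"no mutations in stratum {key}")
                            if control == "gc":
                                res = gc_matched_test(
                                    windows, profile, flags,
                                    gc_low=gc_band[0], gc_high=gc_band[1],
                                    metric=metric, n_permutations=n_permutations,
                                    seed=rng, tie_rule=tie_rule, statistic=statistic,
                                ).result
                            else:
                                values = profile.table.loc[incl_ids, metric].to_numpy()
                                flagged = flags.window_flags.reindex(incl_ids).fillna(False).to_numpy()
                                res = permutation_test(
                                    values, flagged, n_permutations=n_permutations,
                                    seed=rng, tie_rule=tie_rule, metric=metric,
                                    statistic=statistic,
                                )
                            row.update(
                                n_included=res.n_included,
                                n_flagged=res.n_flagged,
                                observed_median=res.observed_median,
                                p_value=res.p_value,
                            )
                        except ValueError as exc:
                            row.update(status="skipped", reason=str(exc))
                        rows.append(row)
    battery = pd.DataFrame(rows)
    battery["p_bh"] = np.nan
    ok = battery["status"] == "ok"
    if ok.any():
        from statsmodels.stats.multitest import multipletests

        battery.loc[ok, "p_bh"] = multipletests(battery.loc[ok, "p_value"], method="fdr_bh")[1]
    return battery
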