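"""Median permutation tests, exhaustive oracle, GC control, quartiles, battery."""

import numpy as np
import pytest

from tamscan.enrichment import (
    exhaustive_pvalue,
    gc_matched_test,
    permutation_test,
    quartile_enrichment,
    run_battery,
)
from tamscan.expression import quantify_windows
from tamscan.mutations import flag_mutation_windows
from tamscan.simulate import SimulationConfig, simulate_bundle


class TestPermutationTest:
    def test_top_outlier_flagged_gives_zero_p(self):
        values = np.array([1, 2, 3, 4, 100.0])
        flagged = np.array([False, False, False, False, True])
        res = permutation_test(values, flagged, n_permutations=500, seed=0)
        assert res.p_value == 0.0
        assert res.observed_median == 100.0

    def test_tie_degeneracy_motivates_tie_rule(self):
        values = np.full(6, 7.0)
        flagged = np.array([True, True, False, False, False, False])
        strict = permutation_test(values, flagged, n_permutations=200, seed=1,
                                  tie_rule="strict_greater")
        ge = permutation_test(values, flagged, n_permutations=200, seed=1,
                              tie_rule="greater_or_equal")
        assert strict.p_value == 0.0
        assert ge.p_value == 1.0

    def test_all_windows_flagged(self):
        values = np.array([5.0, 1.0, 9.0])
        res = permutation_test(values, np.ones(3, bool), n_permutations=100, seed=2)
        assert res.p_value == 0.0  # every permuted median equals the observed

    def test_errors_on_empty_or_oversized_flag_set(self):
        with pytest.raises(ValueError, match="no mutation-containing"):
            permutation_test(np.arange(5.0), np.zeros(5, bool))

    def test_reproducible_from_seed(self):
        values = np.arange(30.0)
        flagged = values < 4
        a = permutation_test(values, flagged, n_permutations=300, seed=42)
        b = permutation_test(values, flagged, n_permutations=300, seed=42)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_medians, b.null_medians)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(0, 1, 40)
        flagged = np.zeros(40, bool)
        flagged[rng.choice(40, 6, replace=False)] = True
        p1 = permutation_test(values, flagged, n_permutations=400, seed=9).p_value
        p2 = permutation_test(np.log(values), flagged, n_permutations=400, seed=9).p_value
        assert p1 == p2


class TestExhaustiveOracle:
    def test_single_flagged_top_value(self):
        values = np.array([1, 2, 3, 4, 100.0])
        assert exhaustive_pvalue(values, values == 100) == 0.0

    def test_single_flagged_bottom_value(self):
        values = np.array([1, 2, 3, 4, 100.0])
        assert exhaustive_pvalue(values, values == 1) == pytest.approx(4 / 5)

    def test_full_subset_is_degenerate(self):
        values = np.array([1.0, 2.0, 3.0])
        assert exhaustive_pvalue(values, np.ones(3, bool), "strict_greater") == 0.0
        assert exhaustive_pvalue(values, np.ones(3, bool), "greater_or_equal") == 1.0

    def test_twelve_choose_three_instance(self):
        # flagged median 2 among values 1..12: 210 of the 220 subsets beat it
        values = np.arange(1, 13, dtype=float)
        flagged = values <= 3
        assert exhaustive_pvalue(values, flagged) == pytest.approx(210 / 220)

    def test_combinatorial_bound_enforced(self):
        values = np.arange(50.0)
        flagged = values < 20
        with pytest.raises(ValueError, match="Monte-Carlo"):
            exhaustive_pvalue(values, flagged)

    def test_monte_carlo_converges_to_oracle(self):
        values = np.arange(1, 13, dtype=float)
        flagged = values <= 3
        p = 210 / 220
        res = permutation_test(values, flagged, n_permutations=10_000, seed=5)
        assert abs(res.p_value - p) <= 3 * np.sqrt(p * (1 - p) / 10_000)


def small_analysis(config):
    bundle = simulate_bundle(config)
    prof = quantify_windows(bundle.tracks[0], bundle.windows, bundle.genome.mask)
    flags = flag_mutation_windows(bundle.mutations, bundle.windows)
    return bundle, prof, flags


class TestGcMatchedTest:
    def test_band_bounds_are_inclusive(self):
        cfg = SimulationConfig(seed=4, n_chromosomes=1, chromosome_length=100_000,
                               masked_fraction=0.0, n_genotypes=1,
                               mutations_per_genotype=10, profiles=(("a", "c"),),
                               window_size=10_000)
        bundle, prof, flags = small_analysis(cfg)
        from tamscan.windows import annotate_gc
        import tempfile, pathlib
        from tamscan.simulate import _write_fasta
        with tempfile.TemporaryDirectory() as d:
            fa = pathlib.Path(d) / "g.fa"
            _write_fasta(bundle.genome, fa)
            windows = annotate_gc(bundle.windows, fa, bundle.genome.mask)
        gc = windows.df["gc_fraction"].to_numpy()
        lo, hi = np.quantile(gc, [0.1, 0.9])
        res = gc_matched_test(windows, prof, flags, gc_low=lo, gc_high=hi,
                              n_permutations=200, seed=0)
        in_band = (gc >= lo) & (gc <= hi)
        assert res.result.n_included == in_band.sum()
        assert 0 < res.fraction_retained <= 1

    def test_identity_when_all_windows_in_band(self):
        cfg = SimulationConfig(seed=5, n_chromosomes=1, chromosome_length=100_000,
                               masked_fraction=0.0, n_genotypes=1,
                               mutations_per_genotype=10, profiles=(("a", "c"),),
                               window_size=10_000)
        bundle, prof, flags = small_analysis(cfg)
        windows = bundle.windows
        windows.df["gc_fraction"] = 0.40  # uniform GC: the band filter is a no-op
        res = gc_matched_test(windows, prof, flags, 0.30, 0.50,
                              n_permutations=500, seed=11)
        incl = windows.included["window_id"]
        ref = permutation_test(prof.table.loc[incl, "depth_tpm"].to_numpy(),
                               flags.window_flags.reindex(incl).fillna(False).to_numpy(),
                               n_permutations=500, seed=11)
        assert res.result.p_value == ref.p_value
        assert res.fraction_retained == 1.0

    def test_error_when_flagged_outside_band(self):
        cfg = SimulationConfig(seed=6, n_chromosomes=1, chromosome_length=50_000,
                               masked_fraction=0.0, n_genotypes=1,
                               mutations_per_genotype=5, profiles=(("a", "c"),),
                               window_size=10_000)
        bundle, prof, flags = small_analysis(cfg)
        windows = bundle.windows
        windows.df["gc_fraction"] = 0.60
        with pytest.raises(ValueError, match="GC band"):
            gc_matched_test(windows, prof, flags, 0.30, 0.50, n_permutations=50, seed=0)


class FakeProfile:
    def __init__(self, table, label="p"):
        self.table = table
        self.label = label


class TestQuartileEnrichment:
    def make(self, values, flagged_idx, seed=0):
        import pandas as pd
        from tamscan.windows import GenomeIndex, make_windows
        from tamscan.expression import ExpressionProfile, ProfileLabel
        from tamscan.mutations import OverlapFlags

        n = len(values)
        idx = GenomeIndex(("c",), {"c": n * 10})
        ws = make_windows(idx, 10, 10)
        ids = ws.df["window_id"]
        table = pd.DataFrame({"depth_tpm": values, "breadth_pct": 0.0},
                             index=pd.Index(ids, name="window_id"))
        prof = ExpressionProfile(ProfileLabel(), table, 1.0)
        flags = pd.Series(False, index=pd.Index(ids, name="window_id"))
        flags.iloc[list(flagged_idx)] = True
        of = OverlapFlags(flags, flags.astype(int), None)
        return ws, prof, of

    def test_single_top_window_lands_in_top_quartile(self):
        ws, prof, flags = self.make([0, 0, 0, 0, 10, 20, 30, 40], [7])
        rep = quartile_enrichment(ws, prof, flags, seed=0)
        assert rep.flagged_fractions.tolist() == [0, 0, 0, 1.0]

    def test_uniform_flags_give_quarter_each(self):
        ws, prof, flags = self.make(list(range(8)), range(8))
        rep = quartile_enrichment(ws, prof, flags, seed=0)
        assert rep.flagged_fractions.tolist() == [0.25] * 4
        assert rep.window_counts.tolist() == [2, 2, 2, 2]

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(8)
        ws, prof, flags = self.make(rng.lognormal(0, 1, 37).tolist(),
                                    rng.choice(37, 9, replace=False))
        rep = quartile_enrichment(ws, prof, flags, seed=3)
        assert rep.flagged_fractions.sum() == pytest.approx(1.0)
        assert abs(rep.window_counts.max() - rep.window_counts.min()) <= 1

    def test_requires_four_windows(self):
        ws, prof, flags = self.make([1, 2, 3], [0])
        with pytest.raises(ValueError, match="at least 4"):
            quartile_enrichment(ws, prof, flags, seed=0)


@pytest.fixture(scope="module")
def bundle():
    cfg = SimulationConfig(seed=7, n_chromosomes=1, chromosome_length=200_000,
                           masked_fraction=0.05, window_size=10_000,
                           n_genotypes=9, mutations_per_genotype=6)
    b = simulate_bundle(cfg)
    profiles = [quantify_windows(t, b.windows, b.genome.mask) for t in b.tracks]
    return b, profiles


class TestBattery:

    def test_nine_genotypes_four_profiles_give_36_rows(self, bundle):
        b, profiles = bundle
        battery = run_battery(b.windows, profiles, b.mutations,
                              metrics=("depth_tpm",), n_permutations=50, seed=0)
        assert len(battery) == 36
        assert set(battery.columns) >= {"genotype", "profile", "metric", "p_value", "p_bh"}

    def test_two_metrics_double_the_rows(self, bundle):
        b, profiles = bundle
        battery = run_battery(b.windows, profiles[:1],
                              b.mutations.subset(genotype="G1"),
                              metrics=("depth_tpm", "breadth_pct"),
                              n_permutations=50, seed=0)
        assert len(battery) == 2

    def test_rerun_is_byte_identical(self, bundle, tmp_path):
        b, profiles = bundle
        paths = []
        for i in (1, 2):
            battery = run_battery(b.windows, profiles, b.mutations,
                                  n_permutations=100, seed=123)
            p = tmp_path / f"battery{i}.tsv"
            battery.to_csv(p, sep="\t", index=False, float_format="%.10g")
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_empty_stratum_recorded_as_skipped(self, bundle):
        b, profiles = bundle
        only_subs = b.mutations.subset(genotype="G1", mutation_type="base_substitution")
        battery = run_battery(b.windows, profiles[:1], only_subs,
                              mutation_types=("base_substitution", "deletion"),
                              n_permutations=50, seed=0)
        deleted = battery[battery["mutation_type"] == "deletion"]
        assert (deleted["status"] == "skipped").all()
        assert (battery[battery["mutation_type"] == "base_substitution"]["status"] == "ok").all()
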