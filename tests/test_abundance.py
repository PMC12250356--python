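import math

import numpy as np
import pytest
from scipy import stats

from conftest import random_dna
from sexsatkit.abundance import (
    AlignmentSummary,
    SaturationError,
    kimura2p,
    map_reads,
    paired_catalog_test,
    sex_ratio,
)
from sexsatkit.catalog import SatRecord
from sexsatkit.synthetic import SatFamilySpec, simulate_libraries


class TestKimura2P:
    @pytest.mark.parametrize(
        "p,q,expected",
        [
            (0.0, 0.0, 0.0),
            (0.1, 0.05, 0.1702),  # direct evaluation of the closed form
            (0.2, 0.1, 0.4024),
        ],
    )
    def test_closed_form(self, p, q, expected):
        assert kimura2p(p, q) == pytest.approx(expected, abs=1e-4)

    def test_accepts_alignment_summary(self):
        assert kimura2p(AlignmentSummary(p=0.1, q=0.05)) == pytest.approx(0.1702, abs=1e-4)

    @pytest.mark.parametrize("p,q", [(0.5, 0.0), (0.45, 0.1), (0.0, 0.5)])
    def test_saturation_raises(self, p, q):
        with pytest.raises(SaturationError):
            kimura2p(p, q)

    @pytest.mark.parametrize("p,q", [(-0.1, 0.0), (0.0, 1.1), (0.7, 0.5)])
    def test_invalid_proportions_rejected(self, p, q):
        with pytest.raises(ValueError):
            kimura2p(p, q)

    def test_small_divergence_limit(self):
        """K ~ p + q to first order; relative error < 2% at p + q <= 0.01."""
        for p in np.linspace(0.0, 0.01, 6):
            for q in np.linspace(0.0, 0.01 - p, 4):
                if p + q == 0:
                    continue
                k = kimura2p(float(p), float(q))
                assert abs(k - (p + q)) / (p + q) < 0.02

    def test_monotone_in_p_and_q(self):
        grid = np.linspace(0.0, 0.2, 9)
        for q in (0.0, 0.1):
            ks = [kimura2p(float(p), q) for p in grid]
            assert all(a < b for a, b in zip(ks, ks[1:]))
        for p in (0.0, 0.1):
            ks = [kimura2p(p, float(q)) for q in grid]
            assert all(a < b for a, b in zip(ks, ks[1:]))


class TestMapReads:
    def _catalog(self, rng):
        return [
            SatRecord("XSat01-28", "X", 1, 28, random_dna(rng, 28)),
            SatRecord("XSat02-40", "X", 2, 40, random_dna(rng, 40)),
        ]

    def test_pure_signal_library(self, rng):
        catalog = self._catalog(rng)
        array = catalog[0].consensus * 10
        reads = [array[i:i + 150] for i in range(0, 120, 13)]
        results = {r.sat_name: r for r in map_reads(reads, catalog)}
        assert results["XSat01-28"].abundance == 1.0
        assert results["XSat01-28"].mapped_reads == len(reads)
        assert results["XSat01-28"].mean_divergence == 0.0
        assert results["XSat02-40"].abundance == 0.0

    def test_random_background_maps_nowhere(self, rng):
        catalog = self._catalog(rng)
        reads = [random_dna(rng, 150) for _ in range(200)]
        for res in map_reads(reads, catalog):
            assert res.abundance == 0.0

    def test_each_read_counted_at_most_once(self, rng):
        catalog = self._catalog(rng)
        reads = [catalog[0].consensus * 5, catalog[1].consensus * 4] * 10
        results = map_reads(reads, catalog)
        analyzed = results[0].analyzed_bp
        assert sum(r.aligned_bp for r in results) <= analyzed
        assert sum(r.mapped_reads for r in results) == len(reads)

    def test_two_fold_copy_number_recovered(self, rng):
        """Family planted at 2x the array copies yields ~2x the abundance."""
        bias = {"lib_male": 1.0}
        specs = [
            SatFamilySpec("A", rul=28, array_copies_per_genome=200, sex_bias=bias),
            SatFamilySpec("B", rul=28, array_copies_per_genome=100, sex_bias=bias),
        ]
        reads, truth = simulate_libraries(
            specs, n_reads_per_library=2000, seed=5, genome_size=50_000
        )
        catalog = [
            SatRecord("SSat01-28", "S", 1, 28, truth.sat_families[0].consensus),
            SatRecord("SSat02-28", "S", 2, 28, truth.sat_families[1].consensus),
        ]
        res = {r.sat_name: r for r in map_reads(reads["lib_male"], catalog)}
        ratio = res["SSat01-28"].abundance / res["SSat02-28"].abundance
        assert 1.6 < ratio < 2.5

    def test_divergent_library_reports_positive_divergence(self, rng):
        consensus = random_dna(rng, 40)
        mutated = list(consensus)
        for i in rng.choice(40, 4, replace=False):
            mutated[i] = [b for b in "ACGT" if b != mutated[i]][rng.integers(0, 3)]
        reads = ["".join(mutated) * 4] * 5
        res = map_reads(reads, [SatRecord("XSat01-40", "X", 1, 40, consensus)])
        assert res[0].mapped_reads == 5
        assert res[0].mean_divergence > 0.05

    def test_empty_inputs_rejected(self, rng):
        catalog = self._catalog(rng)
        with pytest.raises(ValueError):
            map_reads([], catalog)
        with pytest.raises(ValueError):
            map_reads([random_dna(rng, 150)], [])

    def test_oversized_subsample_warns(self, rng):
        catalog = self._catalog(rng)
        reads = [catalog[0].consensus * 6] * 3
        with pytest.warns(UserWarning, match="subsample"):
            map_reads(reads, catalog, subsample=10)

    def test_subsampling_reproducible(self, rng):
        catalog = self._catalog(rng)
        reads = [catalog[0].consensus * 6] * 30 + [random_dna(rng, 150) for _ in range(30)]
        r1 = map_reads(reads, catalog, subsample=20, seed=3)
        r2 = map_reads(reads, catalog, subsample=20, seed=3)
        assert [r.aligned_bp for r in r1] == [r.aligned_bp for r in r2]


class TestSexRatio:
    def _results(self, abundances, library):
        from sexsatkit.abundance import MappingResult

        return [
            MappingResult(name, library, 0, 0, 1, a, 0.0)
            for name, a in abundances.items()
        ]

    def test_equal_abundances_no_candidates(self):
        male = self._results({"s1": 0.01, "s2": 0.002}, "m")
        female = self._results({"s1": 0.01, "s2": 0.002}, "f")
        table = sex_ratio(male, female)
        assert all(r["ratio"] == 1.0 for r in table.rows)
        assert table.candidates() == []

    def test_two_fold_male_bias_flagged(self):
        table = sex_ratio(
            self._results({"s1": 0.002}, "m"),
            self._results({"s1": 0.001}, "f"),
            candidate_threshold=1.5,
        )
        assert table.rows[0]["ratio"] == pytest.approx(2.0)
        assert table.rows[0]["candidate"]

    def test_male_specific_family_gets_inf_sentinel(self):
        table = sex_ratio(
            self._results({"s1": 0.002}, "m"), self._results({"s1": 0.0}, "f")
        )
        assert table.rows[0]["ratio"] == math.inf
        assert table.rows[0]["candidate"]

    def test_missing_family_treated_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="missing"):
            table = sex_ratio(
                self._results({"s1": 0.002, "s2": 0.001}, "m"),
                self._results({"s1": 0.002}, "f"),
            )
        row = next(r for r in table.rows if r["sat_name"] == "s2")
        assert row["abundance_female"] == 0.0


class TestPairedCatalogTest:
    def test_identical_vectors(self):
        t, p, sig = paired_catalog_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert (t, p, sig) == (0.0, 1.0, False)

    def test_hand_computed_example(self):
        # d = (1, 2, 3): t = mean/sd * sqrt(3) = 2 / 1 * sqrt(3)
        t, p, sig = paired_catalog_test([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(2.0 * math.sqrt(3.0), rel=1e-12)
        assert p == pytest.approx(2.0 * stats.t.sf(2.0 * math.sqrt(3.0), df=2), rel=1e-12)
        assert not sig  # p ~ 0.074 at df 2

    def test_matches_scipy_on_regular_data(self, rng):
        a = rng.random(12)
        b = rng.random(12)
        t, p, _ = paired_catalog_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_constant_nonzero_difference(self):
        t, p, sig = paired_catalog_test([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert t == math.inf and p == 0.0 and sig

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_catalog_test([1.0], [2.0])
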