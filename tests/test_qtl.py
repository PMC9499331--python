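"""Interval mapping (LOD, effects, PVE), permutation thresholds, peak
calling and season combination, the naive association cross-check, and
candidate-variant filtering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from binmap import simulate
from binmap.markers import MarkerMatrix
from binmap.qtl import (
    QTLPeak,
    association_scan,
    build_scan_designs,
    call_peaks,
    candidate_variant_filter,
    combine_seasons,
    interval_mapping_scan,
    permutation_threshold,
)
from conftest import bin_level_map


@pytest.fixture(scope="module")
def small_map():
    """One 150 cM chromosome of true bin genotypes for 172 lines."""
    spec, true, gmap = bin_level_map(31, n_individuals=172, n_chrom=2,
                                     n_bins_per_chrom=80)
    return spec, true, gmap


def _single_bin_lod(g, y):
    """Oracle: LOD of the plain regression of y on one bin's codings."""
    x = g.astype(float) - 1.0
    z = np.where(g == 1, 0.5, 0.0)
    X = np.column_stack([np.ones_like(x), x, z])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    ss1 = ((y - X @ beta) ** 2).sum()
    ss0 = ((y - y.mean()) ** 2).sum()
    return len(y) / 2 * math.log10(ss0 / ss1)


class TestIntervalMapping:
    def test_scan_at_bin_equals_single_bin_regression(self, small_map):
        spec, true, gmap = small_map
        rng = np.random.default_rng(32)
        group = gmap.groups[0]
        j = 20
        g = group.bins[j].genotypes
        y = (g.astype(float) - 1.0) * 0.8 + rng.normal(0, 1, len(g))
        designs = build_scan_designs(gmap, step_cm=1.0)
        curve = interval_mapping_scan(gmap, y, designs=designs)
        at_bin = curve[(curve["lg"] == group.name)
                       & (np.isclose(curve["cm"], group.cm[j]))]
        if len(at_bin) == 0:
            pytest.skip("no grid point exactly at the chosen bin")
        assert at_bin["lod"].iloc[0] == pytest.approx(_single_bin_lod(g, y),
                                                      rel=1e-9)

    def test_lod_invariant_to_affine_phenotype_rescaling(self, small_map):
        _, _, gmap = small_map
        rng = np.random.default_rng(33)
        g = gmap.groups[0].bins[10].genotypes
        y = (g.astype(float) - 1.0) + rng.normal(0, 1.5, len(g))
        c1 = interval_mapping_scan(gmap, y)
        c2 = interval_mapping_scan(gmap, 7.0 - 3.0 * y)
        assert np.allclose(c1["lod"], c2["lod"], atol=1e-8)
        assert np.allclose(c1["pve"], c2["pve"], atol=1e-8)

    def test_constant_phenotype_gives_zero_lod(self, small_map):
        _, _, gmap = small_map
        curve = interval_mapping_scan(gmap, np.full(172, 3.0))
        assert (curve["lod"] == 0).all()

    def test_pve_bounded_and_monotone_in_effect_size(self, small_map):
        _, _, gmap = small_map
        rng = np.random.default_rng(34)
        g = gmap.groups[1].bins[40].genotypes
        noise = rng.normal(0, 1, len(g))
        pves = []
        for a in (0.3, 0.8, 1.5, 3.0):
            y = (g.astype(float) - 1.0) * a + noise
            curve = interval_mapping_scan(gmap, y)
            pves.append(curve["pve"].max())
        assert all(0 <= p <= 100 for p in pves)
        assert pves == sorted(pves)

    def test_wild_allele_decreasing_gives_negative_additive(self, small_map):
        # parent-B (wild) homozygotes get the lowest values -> negative a
        spec, true, gmap = small_map
        q = simulate.QTLSpec("c1", 70.0, a=-1.0, d=0.0, residual_sd=0.5)
        y = simulate.simulate_f23_phenotypes(true, q, 35)["value"].to_numpy()
        curve = interval_mapping_scan(gmap, y)
        peak = curve.loc[curve["lod"].idxmax()]
        assert peak["add"] < 0

    def test_missing_phenotypes_dropped(self, small_map):
        _, _, gmap = small_map
        rng = np.random.default_rng(36)
        y = rng.normal(size=172)
        y[:30] = np.nan
        curve = interval_mapping_scan(gmap, y)
        assert np.isfinite(curve["lod"]).all()


class TestPermutationThreshold:
    def test_alpha_one_gives_zero_threshold(self, small_map):
        _, _, gmap = small_map
        y = np.random.default_rng(37).normal(size=172)
        assert permutation_threshold(gmap, y, 50, alpha=1.0, seed=1) == 0.0

    def test_null_threshold_in_expected_band(self, small_map):
        # a Gaussian null with n=172 on a dense map: genome-wise 5%
        # threshold characteristically falls between 3 and 5 LOD
        _, _, gmap = small_map
        y = np.random.default_rng(38).normal(size=172)
        t = permutation_threshold(gmap, y, 300, alpha=0.05, seed=2)
        assert 3.0 <= t <= 5.0

    def test_threshold_stable_under_more_permutations(self, small_map):
        _, _, gmap = small_map
        y = np.random.default_rng(39).normal(size=172)
        designs = build_scan_designs(gmap)
        t1 = permutation_threshold(gmap, y, 1000, seed=3, designs=designs)
        t2 = permutation_threshold(gmap, y, 2000, seed=3, designs=designs)
        assert abs(t1 - t2) < 0.2

    def test_seed_reproducible(self, small_map):
        _, _, gmap = small_map
        y = np.random.default_rng(40).normal(size=172)
        designs = build_scan_designs(gmap)
        assert permutation_threshold(gmap, y, 100, seed=5, designs=designs) == \
            permutation_threshold(gmap, y, 100, seed=5, designs=designs)


class TestPeaks:
    def test_flat_curve_below_threshold_empty(self, small_map):
        _, _, gmap = small_map
        curve = pd.DataFrame({"lg": "LG1", "cm": np.arange(0, 100.0),
                              "lod": 1.0, "add": 0.0, "dom": 0.0, "pve": 0.0})
        assert call_peaks(curve, gmap, tlod=4.0) == []

    def test_major_qtl_called_once_with_interval(self, small_map):
        spec, true, gmap = small_map
        q = simulate.QTLSpec("c2", 80.0, a=-1.5, d=0.1, residual_sd=1.0)
        y = simulate.simulate_f23_phenotypes(true, q, 41)["value"].to_numpy()
        designs = build_scan_designs(gmap)
        curve = interval_mapping_scan(gmap, y, designs=designs)
        peaks = call_peaks(curve, gmap, tlod=4.0, trait="t", season="1")
        on_lg2 = [p for p in peaks if p.lg == "LG2"]
        assert len(on_lg2) == 1
        p = on_lg2[0]
        assert p.cm_lo <= p.pos_cm <= p.cm_hi
        assert p.lod >= 4.0

    def test_interval_width_arithmetic(self):
        p = QTLPeak(trait="LVC", season="1", lg="LG10", pos_cm=63.0,
                    lod=41.06, tlod=4.03, add=-0.710, dom=0.089, pve=56.62,
                    bin_left="B10_240", bin_right="B10_249",
                    cm_lo=60.97, cm_hi=63.25,
                    phys_lo_kb=63_480, phys_hi_kb=65_160)
        assert p.width_cm == pytest.approx(2.28)
        assert p.width_mb == pytest.approx(1.68)


class TestCombineSeasons:
    def _peak(self, season, add, dom, pve):
        return QTLPeak(trait="t", season=season, lg="LG10", pos_cm=63.0,
                       lod=40.0, tlod=4.0, add=add, dom=dom, pve=pve,
                       bin_left="B10_240", bin_right="B10_249")

    def test_two_season_averages(self):
        combined = combine_seasons([self._peak("1", -0.710, 0.089, 56.62),
                                    self._peak("2", -0.746, 0.001, 72.64)])
        assert combined.pve == pytest.approx(64.63)
        assert combined.add == pytest.approx(-0.728)
        assert combined.season == "1+2"

    def test_additive_average_second_trait(self):
        combined = combine_seasons([self._peak("1", -1.134, 0.085, 51.72),
                                    self._peak("2", -1.226, 0.049, 58.94)])
        assert combined.add == pytest.approx(-1.180)
        assert combined.pve == pytest.approx(55.33)

    def test_single_season_identity(self):
        p = self._peak("1", -0.7, 0.1, 50.0)
        assert combine_seasons([p]) is p

    def test_mismatched_intervals_rejected(self):
        other = self._peak("2", -0.7, 0.1, 50.0)
        other.bin_left = "B10_100"
        with pytest.raises(ValueError):
            combine_seasons([self._peak("1", -0.7, 0.1, 50.0), other])


class TestAssociationScan:
    def _matrix(self, codes):
        table = pd.DataFrame({"chrom": "c1",
                              "pos": np.arange(1, len(codes) + 1)})
        return MarkerMatrix(table, np.asarray(codes, np.int8),
                            [f"F{i}" for i in range(codes.shape[1])])

    def test_perfectly_associated_marker_attains_min_p(self):
        codes = simulate.simulate_unlinked_f2_codes(50, 100, 42)
        y = codes[7].astype(float) - 1.0
        res = association_scan(self._matrix(codes), y)
        assert int(res["p"].idxmin()) == 7

    def test_association_colocates_with_interval_peak(self, small_map):
        spec, true, gmap = small_map
        q = simulate.QTLSpec("c1", 40.0, a=-1.2, d=0.0, residual_sd=0.8)
        y = simulate.simulate_f23_phenotypes(true, q, 43)["value"].to_numpy()
        on_c1 = (true.markers["chrom"] == "c1").to_numpy()
        table = true.markers.loc[on_c1, ["chrom", "pos"]].reset_index(drop=True)
        mm = MarkerMatrix(table, true.codes[on_c1],
                          [f"F{i}" for i in range(172)])
        res = association_scan(mm, y)
        top_pos = res.loc[res["p"].idxmin(), "pos"]
        curve = interval_mapping_scan(gmap, y)
        peaks = call_peaks(curve, gmap, tlod=4.0)
        best = max(peaks, key=lambda p: p.lod)
        assert best.lg == "LG1"
        assert best.phys_lo_kb * 1000 - 5e6 <= top_pos <= best.phys_hi_kb * 1000 + 5e6

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(44)
        passed = 0
        for rep in range(20):
            codes = simulate.simulate_unlinked_f2_codes(80, 120, 500 + rep)
            y = rng.normal(size=120)
            res = association_scan(self._matrix(codes), y)
            if stats.kstest(res["p"], "uniform").pvalue > 0.01:
                passed += 1
        assert passed >= 18

    def test_too_few_individuals_rejected(self):
        codes = simulate.simulate_unlinked_f2_codes(5, 10, 45)
        with pytest.raises(ValueError):
            association_scan(self._matrix(codes), np.zeros(10))


class TestCandidateFilter:
    def _variants(self):
        return pd.DataFrame([
            # pos, gt_a, gt_b, depth_a, depth_b
            ("c10", 64_566_331, "A", "G", "0/0", "1/1", 30, 25),
            ("c10", 64_600_000, "A", "G", "0/0", "1/1", 5, 25),   # low depth
            ("c10", 64_700_000, "G", "C", "0/0", "1/1", 20, 20),  # synonymous
            ("c10", 64_800_000, "T", "C", "1/1", "0/0", 20, 20),  # A not ref
            ("c10", 90_000_000, "A", "G", "0/0", "1/1", 30, 30),  # outside
        ], columns=["chrom", "pos", "ref", "alt", "gt_a", "gt_b",
                    "depth_a", "depth_b"])

    def _annotations(self):
        return pd.DataFrame([
            # AGT (Ser) in parent B's allele context -> GGT (Gly)
            ("c10", 64_566_331, "gene1", "AGT", "GGT"),
            ("c10", 64_600_000, "gene1", "AGT", "GGT"),
            ("c10", 64_700_000, "gene2", "GGT", "GGC"),  # both Glycine
            ("c10", 64_800_000, "gene3", "ACT", "GCT"),
        ], columns=["chrom", "pos", "gene_id", "codon_ref", "codon_alt"])

    def test_criteria_applied_jointly(self):
        res = candidate_variant_filter(self._variants(), self._annotations(),
                                       ("c10", 63_480_000, 65_160_000))
        assert len(res) == 4  # interval restriction
        by_pos = res.set_index("pos")
        assert bool(by_pos.loc[64_566_331, "candidate"])
        assert by_pos.loc[64_566_331, "aa_change"] == "S>G"
        assert not by_pos.loc[64_600_000, "pass_depth_hom"]   # depth 5 < 6
        assert not by_pos.loc[64_700_000, "pass_protein_change"]  # Gly>Gly
        assert not by_pos.loc[64_800_000, "pass_ref_concordance"]

    def test_missing_annotation_indeterminate_not_passed(self):
        v = self._variants().iloc[[0]]
        res = candidate_variant_filter(v, None, ("c10", 0, 70_000_000))
        assert bool(res["indeterminate"].iloc[0])
        assert not bool(res["candidate"].iloc[0])
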