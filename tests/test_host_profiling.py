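"""LexA/CSB detection, PSB survey, and threshold derivation by clustering."""

import numpy as np
import pytest
from scipy.stats import gaussian_kde

from sosdep.genome_io import CdsFeature, GenomeRecord
from sosdep.host_profiling import (
    STATUS_AMBIGUOUS,
    STATUS_NO_CSB,
    STATUS_NO_LEXA,
    STATUS_OK,
    build_host_profile,
    derive_thresholds,
    find_csb,
    find_lexa,
    load_lexa_references,
    survey_psbs,
)
from sosdep.synthetic_fixtures import (
    FixtureSpec,
    default_spec,
    design_sequence_for_hi,
    generate_fixture,
)


def kde_valley_split(values, bandwidth=None):
    """Brute-force 1-D oracle: split at the KDE density minimum between the
    two outermost modes."""
    values = np.sort(np.asarray(values, float))
    kde = gaussian_kde(values, bw_method=None if bandwidth is None else bandwidth)
    grid = np.linspace(values.min(), values.max(), 4000)
    dens = kde(grid)
    rising = np.where((dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]))[0] + 1
    assert len(rising) >= 2, "expected a bimodal density"
    lo_mode, hi_mode = grid[rising[0]], grid[rising[-1]]
    between = (grid > lo_mode) & (grid < hi_mode)
    valley = grid[between][np.argmin(dens[between])]
    return values[values <= valley], values[values > valley]


def mixture(rng, n=200, loc=(7, 22), scale=(1, 2)):
    half = n // 2
    return np.concatenate(
        [rng.normal(loc[0], scale[0], half), rng.normal(loc[1], scale[1], n - half)]
    )


class TestFindLexa:
    def test_planted_lexa_is_found(self, fixture_bundle):
        _, genome, _, truth = fixture_bundle
        locus = find_lexa(genome)
        assert locus is not None
        assert locus.feature_id == "lexA"
        assert (locus.start, locus.end) == tuple(truth.lexa_interval)

    def test_no_cds_means_absent(self):
        assert find_lexa(GenomeRecord("r", "ACGT" * 50)) is None

    def test_unrelated_cds_scores_below_threshold(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        g = GenomeRecord(
            "r", seq, [CdsFeature("x", 100, 700, "+", translation="M" + "AGSTV" * 40)]
        )
        assert find_lexa(g) is None

    def test_reference_set_is_usable(self):
        refs = load_lexa_references()
        assert refs and all(set(s) <= set("ACDEFGHIKLMNPQRSTVWY") for s in refs.values())


class TestFindCsb:
    def test_consensus_box_upstream_scores_zero(self, fixture_bundle, matrix):
        _, genome, _, truth = fixture_bundle
        lexa = find_lexa(genome)
        csb = find_csb(genome, lexa, matrix)
        assert csb is not None
        assert csb.hit.hi == pytest.approx(0.0)
        assert (csb.hit.start, csb.hit.end) == tuple(truth.csb_interval)
        assert 0 <= csb.distance_to_lexa_start <= 300

    def test_cutoff_separates_confirmable_from_weak_boxes(self, matrix):
        refs = load_lexa_references()
        prot = next(iter(refs.values()))
        for target, expected_found in [(10.0, True), (20.0, False)]:
            box = design_sequence_for_hi(matrix, target, 0.25, seed=5)
            seq = "A" * 400 + box + "A" * 80 + "ATG" + "A" * 603 + "TAA" + "A" * 100
            cds = CdsFeature("lexA", 500, 500 + 609, "+", translation=prot)
            genome = GenomeRecord("r", seq, [cds])
            lexa = find_lexa(genome)
            csb = find_csb(genome, lexa, matrix)
            assert (csb is not None) is expected_found

    def test_scrambled_upstream_yields_no_csb(self, matrix):
        spec = default_spec(3)
        spec = FixtureSpec(
            seed=spec.seed,
            low_hi_targets=spec.low_hi_targets,
            high_hi_targets=spec.high_hi_targets,
            prophages=spec.prophages,
            plant_csb=False,
        )
        genome, _, _, _ = generate_fixture(spec)
        lexa = find_lexa(genome)
        assert lexa is not None
        assert find_csb(genome, lexa, matrix) is None


class TestSurveyPsbs:
    def test_no_core_matches_gives_empty(self, matrix):
        assert survey_psbs(GenomeRecord("r", "A" * 2000), matrix) == []

    def test_planted_mixture_is_recovered_bimodal(self, fixture_bundle, matrix):
        spec, genome, _, truth = fixture_bundle
        hits = survey_psbs(genome, matrix)
        assert len(hits) == len(truth.psb_intervals) + 1  # + the CSB
        his = np.array([h.hi for h in hits])
        low = (his < 14).sum()
        high = (his >= 14).sum()
        assert low >= 15 and high >= 15

    def test_promoter_scope_is_subset_of_whole_genome(self, fixture_bundle, matrix):
        _, genome, _, _ = fixture_bundle
        whole = {(h.start, h.end) for h in survey_psbs(genome, matrix)}
        prom = {(h.start, h.end) for h in survey_psbs(genome, matrix, "promoters")}
        assert prom <= whole
        assert prom  # every planted box sits in a promoter window


class TestDeriveThresholds:
    @pytest.mark.parametrize("method", ["meanshift", "kmeans2", "otsu"])
    def test_two_component_mixture_recovers_partition(self, rng, method):
        values = mixture(rng)
        result = derive_thresholds(values, method=method)
        assert result.ok
        assert 8 <= result.hi_c1 <= 14
        assert result.hi_c1 < result.hi_c2
        assert all(v <= result.hi_c1 for v in result.low_cluster)
        assert max(result.low_cluster) == result.hi_c1
        assert min(result.high_cluster) == result.hi_c2

    def test_meanshift_matches_kde_valley_oracle_when_separated(self, rng):
        # well-separated: inter-mode gap 15 > 4x the within-component SD
        for seed in range(5):
            local = np.random.default_rng(seed)
            values = mixture(local, n=200, scale=(1.0, 2.0))
            result = derive_thresholds(values, method="meanshift")
            assert result.ok
            low_o, high_o = kde_valley_split(values)
            assert sorted(result.low_cluster) == pytest.approx(sorted(low_o))
            assert sorted(result.high_cluster) == pytest.approx(sorted(high_o))

    def test_identical_values_are_ambiguous(self):
        result = derive_thresholds([5.0] * 50)
        assert not result.ok

    def test_too_few_values_are_ambiguous(self):
        result = derive_thresholds([5.0, 25.0])
        assert not result.ok
        assert "2" in result.reason

    def test_order_invariance(self, rng):
        values = mixture(rng)
        a = derive_thresholds(values)
        b = derive_thresholds(values[::-1])
        c = derive_thresholds(rng.permutation(values))
        assert a.hi_c1 == b.hi_c1 == c.hi_c1
        assert a.hi_c2 == b.hi_c2 == c.hi_c2

    def test_adding_interior_value_preserves_order(self, rng):
        values = list(mixture(rng))
        base = derive_thresholds(values)
        inner = (min(values) + base.hi_c1) / 2
        grown = derive_thresholds(values + [inner])
        assert grown.ok
        assert grown.hi_c1 < grown.hi_c2


class TestBuildHostProfile:
    def test_full_fixture_is_ok_and_brackets_the_gap(self, fixture_bundle):
        spec, genome, _, _ = fixture_bundle
        profile = build_host_profile(genome)
        assert profile.status == STATUS_OK
        low_max = max(spec.low_hi_targets)
        high_min = min(spec.high_hi_targets)
        assert profile.hi_c1 <= low_max + 0.5
        assert profile.hi_c2 >= high_min - 0.5
        assert profile.hi_c1 < profile.hi_c2
        assert set(profile.low_cluster) <= set(profile.psb_his)
        assert set(profile.high_cluster) <= set(profile.psb_his)
        assert max(profile.low_cluster) < min(profile.high_cluster)

    def test_fixture_without_lexa_reports_no_lexa(self):
        spec = default_spec(4)
        spec = FixtureSpec(
            seed=spec.seed,
            low_hi_targets=spec.low_hi_targets,
            high_hi_targets=spec.high_hi_targets,
            plant_lexa=False,
        )
        genome, _, _, _ = generate_fixture(spec)
        assert build_host_profile(genome).status == STATUS_NO_LEXA

    def test_fixture_without_csb_reports_no_csb(self):
        spec = default_spec(5)
        spec = FixtureSpec(
            seed=spec.seed,
            low_hi_targets=spec.low_hi_targets,
            high_hi_targets=spec.high_hi_targets,
            plant_csb=False,
        )
        genome, _, _, _ = generate_fixture(spec)
        assert build_host_profile(genome).status == STATUS_NO_CSB

    def test_too_few_psbs_reports_ambiguous(self):
        spec = FixtureSpec(seed=6, low_hi_targets=(), high_hi_targets=())
        genome, _, _, _ = generate_fixture(spec)
        assert build_host_profile(genome).status == STATUS_AMBIGUOUS
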