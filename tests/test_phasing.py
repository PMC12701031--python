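"""Trio truth phasing and switch-error scoring."""

import numpy as np
import pytest

from recmap.hotspots import IntervalSet
from recmap.phasing import (
    GenotypeMatrix,
    PhasedSample,
    PhaseStatus,
    decompose_switch_runs,
    mendelian_phase,
    merge_sample_into_panel,
    rates_from_counts,
    score_switches,
    truth_sites_from_haplotypes,
)
from recmap.simulate import sim_phased_errors, sim_trio


def phase_site(child, mother, father):
    (site,) = mendelian_phase("chr1", [100],
                              np.array([child]), np.array([mother]),
                              np.array([father]))
    return site


class TestMendelianPhase:
    def test_homozygous_parents_force_phase(self):
        site = phase_site((0, 1), mother=(0, 0), father=(1, 1))
        assert site.status is PhaseStatus.RESOLVED
        assert (site.paternal, site.maternal) == (1, 0)

    def test_one_het_parent_still_forced(self):
        site = phase_site((0, 1), mother=(0, 0), father=(0, 1))
        assert site.status is PhaseStatus.RESOLVED
        assert (site.paternal, site.maternal) == (1, 0)

    def test_double_het_undetermined(self):
        site = phase_site((0, 1), mother=(0, 1), father=(0, 1))
        assert site.status is PhaseStatus.UNDETERMINED

    def test_non_mendelian_discarded(self):
        site = phase_site((0, 1), mother=(0, 0), father=(0, 0))
        assert site.status is PhaseStatus.DISCARDED

    def test_missing_data_discarded(self):
        site = phase_site((0, 1), mother=(-1, -1), father=(1, 1))
        assert site.status is PhaseStatus.DISCARDED

    def test_child_homozygote_carried_not_scored(self):
        site = phase_site((1, 1), mother=(0, 1), father=(1, 1))
        assert site.status is PhaseStatus.HOMOZYGOUS

    def test_inconsistent_homozygote_discarded(self):
        site = phase_site((1, 1), mother=(0, 0), father=(1, 1))
        assert site.status is PhaseStatus.DISCARDED


class TestRunDecomposition:
    @pytest.mark.parametrize("pattern,expected", [
        ([0, 0, 0], (0, 0, 0)),
        ([1, 0, 0], (1, 0, 0)),          # isolated single
        ([1, 1, 0], (0, 2, 1)),          # adjacent pair -> one double
        ([1, 1, 1], (1, 2, 1)),          # length 3: one double + one single
        ([1, 1, 1, 1], (0, 4, 2)),       # length 4: two doubles
        ([1, 0, 1, 1], (1, 2, 1)),       # single then double
    ])
    def test_patterns(self, pattern, expected):
        singles, paired, doubles, _ = decompose_switch_runs(np.array(pattern, bool))
        assert (singles, paired, doubles) == expected
        assert singles + paired == int(np.sum(pattern))

    def test_histogram(self):
        _, _, _, hist = decompose_switch_runs(
            np.array([1, 0, 1, 1, 0, 1, 1, 1], bool))
        assert hist == {1: 1, 2: 1, 3: 1}


def make_truth_and_test(orientations):
    """Truth het sites at 1 kb spacing; test sample with the given
    hap-labeling orientation (0 = agrees with truth) at each site."""
    n = len(orientations)
    positions = np.arange(1, n + 1) * 1000
    pat = np.tile([0, 1], n)[:n]  # alternate so every site is het
    mat = 1 - pat
    sites = truth_sites_from_haplotypes("chr1", positions, pat, mat)
    o = np.asarray(orientations)
    hap1 = np.where(o == 0, pat, mat)
    hap2 = np.where(o == 0, mat, pat)
    return sites, PhasedSample("chr1", positions, hap1, hap2)


class TestScoreSwitches:
    def test_perfect_phase(self):
        sites, test = make_truth_and_test([0] * 10)
        report = score_switches(sites, test)
        assert report.n_switch_errors == 0
        assert report.switch_error_rate == 0.0
        assert report.phase_error_rate == 0.0

    def test_single_crossover(self):
        sites, test = make_truth_and_test([0, 0, 0, 1, 1, 1])
        report = score_switches(sites, test)
        assert report.n_switch_errors == 1
        assert report.n_single_switches == 1
        assert report.n_double_switches == 0

    def test_isolated_flip_is_double_switch(self):
        # correct-flip-correct: two adjacent indicators, one phase error
        sites, test = make_truth_and_test([0, 0, 1, 0, 0])
        report = score_switches(sites, test)
        assert report.n_switch_errors == 2
        assert report.n_double_switches == 1
        assert report.n_single_switches == 0
        assert report.phase_error_rate == pytest.approx(1 / 5)

    def test_global_relabeling_changes_nothing(self):
        # swapping the two test haplotypes everywhere flips every orientation;
        # alignment at the first het absorbs it
        sites, test = make_truth_and_test([0, 1, 1, 0, 0, 1])
        swapped = PhasedSample("chr1", test.positions, test.hap2, test.hap1)
        a = score_switches(sites, test)
        b = score_switches(sites, swapped)
        assert a.n_switch_errors == b.n_switch_errors
        assert a.n_single_switches == b.n_single_switches
        assert a.n_double_switches == b.n_double_switches

    def test_switch_rate_at_least_phase_rate(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            o = (np.random.default_rng(seed).random(50) < 0.3).astype(int)
            sites, test = make_truth_and_test(o)
            r = score_switches(sites, test)
            assert r.switch_error_rate >= r.phase_error_rate

    def test_unscored_sites_do_not_affect_rates(self):
        sites, test = make_truth_and_test([0, 0, 1, 0])
        # add a homozygous truth site between hets: no effect
        extra = truth_sites_from_haplotypes(
            "chr1", [1500], np.array([1]), np.array([1]))
        report = score_switches(sites + extra, test)
        assert report.n_phased_hets == 4
        assert report.n_switch_errors == 2

    def test_truth_only_sites_counted(self):
        sites, test = make_truth_and_test([0, 0, 0, 0])
        extra = truth_sites_from_haplotypes(
            "chr1", [9999], np.array([0]), np.array([1]))
        report = score_switches(sites + extra, test)
        assert report.n_truth_only == 1
        assert report.n_phased_hets == 4

    def test_too_few_hets_rejected(self):
        sites, test = make_truth_and_test([0])
        with pytest.raises(ValueError, match="at least 2"):
            score_switches(sites, test)


class TestRatesFromCounts:
    @pytest.mark.parametrize("hets,switches,singles_doubles,ser,per", [
        (98_765, 2_205, 1_602, 0.0223, 0.0162),
        (98_765, 2_233, 1_650, 0.0226, 0.0167),
        (98_765, 2_241, 1_640, 0.0227, 0.0166),
        (98_765, 2_243, 1_649, 0.0227, 0.0167),
    ])
    def test_error_rates_from_summary_counts(self, hets, switches,
                                             singles_doubles, ser, per):
        """Switch-error and phase-error rates over the Mendelian-phased-het
        denominator, to 3 significant figures."""
        s, p = rates_from_counts(hets, switches, singles_doubles)
        assert round(s, 4) == ser
        assert round(p, 4) == per


class TestPlantedErrorRecovery:
    @pytest.mark.parametrize("seed", range(20))
    def test_exact_recovery(self, seed):
        """Planted singles and doubles, separated by enough correct hets, are
        recovered exactly, and the phase error rate is (s + d) / n."""
        trio, _ = sim_trio(3000, seed=seed)
        test, truth = sim_phased_errors(
            trio.positions, trio.child_paternal, trio.child_maternal,
            n_single=5, n_double=3, min_separation=3, seed=seed + 1000)
        sites = truth_sites_from_haplotypes(
            "chr1", trio.positions, trio.child_paternal, trio.child_maternal)
        report = score_switches(sites, test)
        assert report.n_single_switches == 5
        assert report.n_double_switches == 3
        assert report.phase_error_rate == pytest.approx(8 / report.n_phased_hets)
        assert report.n_switch_errors == 5 + 2 * 3


class TestPanelMerge:
    def make_matrix(self, positions, n_samples, prefix):
        rng = np.random.default_rng(len(positions))
        g = rng.integers(0, 2, size=(len(positions), n_samples, 2)).astype(np.int8)
        return GenotypeMatrix("chr1", np.asarray(positions),
                              [f"{prefix}{i}" for i in range(n_samples)], g)

    def test_empty_segdup_keeps_all_shared(self):
        sample = self.make_matrix([100, 200, 300], 1, "s")
        panel = self.make_matrix([100, 200, 300, 400], 5, "p")
        merged = merge_sample_into_panel(sample, panel)
        assert merged.n_sites == 3
        assert merged.genotypes.shape == (3, 6, 2)

    def test_segdup_site_removed(self):
        sample = self.make_matrix([100, 200, 300], 1, "s")
        panel = self.make_matrix([100, 200, 300], 2, "p")
        segdups = IntervalSet.from_records([("chr1", 150, 250)])
        merged = merge_sample_into_panel(sample, panel, segdups)
        np.testing.assert_array_equal(merged.positions, [100, 300])

    def test_boundary_semantics_half_open(self):
        # 1-based SNP at interval start is inside; at the end coordinate it
        # is outside
        sample = self.make_matrix([151, 251], 1, "s")
        panel = self.make_matrix([151, 251], 1, "p")
        segdups = IntervalSet.from_records([("chr1", 150, 250)])
        merged = merge_sample_into_panel(sample, panel, segdups)
        np.testing.assert_array_equal(merged.positions, [251])

    def test_no_shared_sites_rejected(self):
        sample = self.make_matrix([100], 1, "s")
        panel = self.make_matrix([999], 1, "p")
        with pytest.raises(ValueError, match="share no sites"):
            merge_sample_into_panel(sample, panel)
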