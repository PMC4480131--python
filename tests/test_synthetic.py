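import math

import numpy as np
import pytest
from scipy import stats

from hireschip import (
    GenomeInfo,
    MotifSite,
    SynthConfig,
    apply_size_selection,
    simulate_sonicated_chip,
    simulate_tf_chip,
    vplot,
)
from hireschip.synthetic import retention_probability

from conftest import make_fragset


@pytest.fixture
def sim_genome():
    return GenomeInfo({"chr1": 500_000})


@pytest.fixture
def sim_sites(sim_genome):
    return [MotifSite("chr1", s, s + 19, name=f"m{i}")
            for i, s in enumerate(range(2_000, 490_000, 2_000))]


class TestSimulateTfChip:
    def test_no_chewback_yields_exact_footprints(self, sim_genome, sim_sites):
        cfg = SynthConfig(seed=5, chew_p=1.0, fragments_per_site=10,
                          background_rate=0.0)
        fs, truth = simulate_tf_chip(sim_genome, sim_sites, cfg)
        assert len(fs) > 0
        assert (fs.lengths == 19).all()
        starts_by_site = {s.start for s in sim_sites}
        assert set(fs.df["start"]).issubset(starts_by_site)
        assert all(t.origin == "footprint" and t.overhang_left == 0
                   and t.overhang_right == 0 for t in truth)

    def test_same_seed_reproduces_exactly(self, sim_genome, sim_sites):
        cfg = SynthConfig(seed=11, fragments_per_site=15)
        fs1, t1 = simulate_tf_chip(sim_genome, sim_sites, cfg)
        fs2, t2 = simulate_tf_chip(sim_genome, sim_sites, cfg)
        assert fs1 == fs2
        assert t1 == t2

    def test_truth_overhangs_match_coordinates(self, sim_genome, sim_sites):
        cfg = SynthConfig(seed=2, chew_p=0.4, fragments_per_site=8)
        fs, truth = simulate_tf_chip(sim_genome, sim_sites, cfg)
        by_name = {s.name: s for s in sim_sites}
        for row, t in zip(fs.df.itertuples(index=False), truth):
            site = by_name[t.site_id]
            assert row.start == site.start - t.overhang_left
            assert row.end == site.end + t.overhang_right

    def test_background_fragments_emitted_with_labels(self, sim_genome, sim_sites):
        cfg = SynthConfig(seed=4, fragments_per_site=1, background_rate=1.0)
        fs, truth = simulate_tf_chip(sim_genome, sim_sites, cfg)
        origins = {t.origin for t in truth}
        assert {"footprint", "nucleosome", "background"} <= origins
        nuc_lens = [
            (t, row) for row, t in zip(fs.df.itertuples(index=False), truth)
            if t.origin == "nucleosome"
        ]
        lens = np.array([r.end - r.start for _, r in nuc_lens])
        assert 120 < lens.mean() < 175  # ~147 bp nucleosomal protection

    def test_site_outside_genome_rejected(self, sim_genome):
        bad = [MotifSite("chr1", 499_995, 500_014)]
        with pytest.raises(ValueError):
            simulate_tf_chip(sim_genome, bad, SynthConfig(seed=0))

    def test_poisson_dispersion_of_counts(self, sim_genome):
        """Per-site fragment counts across seeds have variance consistent
        with Poisson (chi-square dispersion test, alpha = 0.01)."""
        sites = [MotifSite("chr1", 10_000, 10_019)]
        counts = []
        for seed in range(200):
            cfg = SynthConfig(seed=seed, fragments_per_site=30.0)
            fs, _ = simulate_tf_chip(sim_genome, sites, cfg)
            counts.append(len(fs))
        counts = np.array(counts)
        disp = (len(counts) - 1) * counts.var(ddof=1) / counts.mean()
        lo = stats.chi2.ppf(0.005, len(counts) - 1)
        hi = stats.chi2.ppf(0.995, len(counts) - 1)
        assert lo < disp < hi

    @pytest.mark.parametrize("footprint", [15, 19, 25])
    def test_vplot_apex_recovers_footprint_length(self, sim_genome, footprint):
        sites = [MotifSite("chr1", s, s + footprint)
                 for s in range(2_000, 490_000, 2_000)]
        cfg = SynthConfig(seed=13, footprint_len=footprint, chew_p=0.5,
                          fragments_per_site=40)
        fs, _ = simulate_tf_chip(sim_genome, sites, cfg)
        vm = vplot(fs, sites, flank=50, len_min=1, len_max=150)
        assert vm.apex_length() == footprint

    def test_vplot_all_mass_at_apex_without_chewback(self, sim_genome, sim_sites):
        cfg = SynthConfig(seed=7, chew_p=1.0, fragments_per_site=10)
        fs, _ = simulate_tf_chip(sim_genome, sim_sites, cfg)
        vm = vplot(fs, sim_sites, flank=30, len_min=1, len_max=100)
        assert vm.matrix.sum() == len(fs)
        assert vm.matrix[19 - 1, 30] == len(fs)  # row L=19, offset 0


def count_ends_near(fragset, anchors, offset, halfwidth):
    ends = np.concatenate([fragset.df["start"].to_numpy(),
                           fragset.df["end"].to_numpy()])
    ends.sort()
    total = 0
    for a in anchors:
        c = a.center + offset
        total += int(
            np.searchsorted(ends, c + halfwidth, side="right")
            - np.searchsorted(ends, c - halfwidth, side="left")
        )
    return total


def anchor_bias_pvalue(fragset, anchors):
    """Two-sided binomial test of anchor-proximal vs matched distal
    fragment-end counts (100-bp half-width windows)."""
    prox = count_ends_near(fragset, anchors, 0, 100)
    dist = count_ends_near(fragset, anchors, 2_000, 100)
    res = stats.binomtest(prox, prox + dist, 0.5)
    return res.pvalue, prox, dist


class TestSimulateSonicatedChip:
    @pytest.fixture
    def big_genome(self):
        return GenomeInfo({"chr1": 10_000_000})

    @pytest.fixture
    def anchors(self):
        return [MotifSite("chr1", c, c + 19)
                for c in range(500_000, 9_500_000, 450_000)]

    def test_lengths_within_sonication_bounds(self, big_genome, anchors):
        cfg = SynthConfig(seed=1, n_sonicated_fragments=5_000)
        fs, truth = simulate_sonicated_chip(big_genome, anchors, cfg)
        assert (fs.lengths >= 200).all() and (fs.lengths <= 500).all()
        assert all(t.origin == "sonicated" for t in truth)

    def test_unbiased_breaks_look_uniform(self, big_genome, anchors):
        cfg = SynthConfig(seed=21, n_sonicated_fragments=50_000,
                          accessibility_bias_weight=0.0)
        fs, _ = simulate_sonicated_chip(big_genome, anchors, cfg)
        pvalue, _, _ = anchor_bias_pvalue(fs, anchors)
        assert pvalue > 0.01

    def test_biased_breaks_pile_up_at_anchors(self, big_genome, anchors):
        cfg = SynthConfig(seed=21, n_sonicated_fragments=50_000,
                          accessibility_bias_weight=5.0)
        fs, _ = simulate_sonicated_chip(big_genome, anchors, cfg)
        pvalue, prox, dist = anchor_bias_pvalue(fs, anchors)
        assert prox > dist
        assert pvalue < 0.01

    def test_deterministic_given_seed(self, big_genome, anchors):
        cfg = SynthConfig(seed=9, n_sonicated_fragments=2_000,
                          accessibility_bias_weight=2.0)
        fs1, _ = simulate_sonicated_chip(big_genome, anchors, cfg)
        fs2, _ = simulate_sonicated_chip(big_genome, anchors, cfg)
        assert fs1 == fs2


class TestSizeSelection:
    def test_hard_cutoff_retains_only_short(self):
        fs = make_fragset(
            [("chr1", 0, L) for L in (40, 100, 169, 170, 171, 400)]
        )
        cfg = SynthConfig(seed=0, selection_steepness=math.inf,
                          selection_midpoint_len=170)
        kept, _ = apply_size_selection(fs, cfg)
        assert sorted(kept.lengths.tolist()) == [40, 100, 169]

    def test_retention_probability_non_increasing(self):
        cfg = SynthConfig(seed=0, selection_steepness=0.05)
        grid = np.arange(1, 501)
        p = retention_probability(grid, cfg)
        assert (np.diff(p) <= 0).all()
        assert p[0] > 0.99 and p[-1] < 0.01

    def test_toy_mixture_fold_enrichment_100(self):
        """1 fragment of 40 bp among 99 of 150 bp, hard cutoff at 100:
        the sub-50 bp fraction goes 0.01 -> 1.0, a 100-fold enrichment."""
        fs = make_fragset(
            [("chr1", 0, 40)] + [("chr1", 10 * i, 10 * i + 150) for i in range(99)]
        )
        cfg = SynthConfig(seed=0, selection_steepness=math.inf,
                          selection_midpoint_len=100)
        kept, report = apply_size_selection(fs, cfg)
        assert report.fraction_below_before == pytest.approx(0.01)
        assert report.fraction_below_after == pytest.approx(1.0)
        assert report.fold_enrichment == pytest.approx(100.0)
        assert len(kept) == 1

    def test_selection_is_seed_reproducible(self):
        rng = np.random.default_rng(1)
        fs = make_fragset(
            [("chr1", int(s), int(s) + int(L))
             for s, L in zip(rng.integers(0, 10_000, 500),
                             rng.integers(20, 400, 500))]
        )
        cfg = SynthConfig(seed=33)
        k1, r1 = apply_size_selection(fs, cfg)
        k2, r2 = apply_size_selection(fs, cfg)
        assert k1 == k2
        assert r1.fraction_below_after == r2.fraction_below_after
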