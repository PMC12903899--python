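"""Generator tests: genomes, NGG target enumeration, planted activities, screens."""

import numpy as np
import pytest

import guidescreen as gs
from guidescreen.core import reverse_complement
from guidescreen.synthetic import ActivityModel, ScreenConfig


class TestGenerateGenome:
    def test_rejects_empty_genome(self):
        with pytest.raises(ValueError):
            gs.generate_genome(0, gc=0.5, seed=1)

    def test_deterministic_for_fixed_seed(self):
        a = gs.generate_genome(10_000, gc=0.5, seed=1)
        b = gs.generate_genome(10_000, gc=0.5, seed=1)
        assert a.sequence == b.sequence

    def test_gc_fraction_within_binomial_interval(self):
        n, gc = 100_000, 0.3
        g = gs.generate_genome(n, gc=gc, seed=7)
        observed = sum(1 for b in g.sequence if b in "GC")
        sd = np.sqrt(n * gc * (1 - gc))
        assert abs(observed - n * gc) < 3 * sd


def brute_force_sites(seq: str, max_flank: int) -> int:
    """Independent oracle: scan for GG on both strands with full spacer and flanks."""
    total = 0
    for s in (seq, reverse_complement(seq)):
        for i in range(len(s) - 2):
            if s[i + 1 : i + 3] == "GG" and i - 20 - max_flank >= 0 and i + 3 + max_flank <= len(s):
                total += 1
    return total


class TestEnumerateTargets:
    def test_single_constructed_pam(self):
        # one AGG at offsets 20-22, no other NGG on either strand
        seq = "A" * 20 + "AGG" + "AT"
        sites = gs.enumerate_targets(gs.Genome("c", seq), max_flank=0)
        assert len(sites) == 1
        (site,) = sites
        assert site.strand == "+" and site.spacer_start == 0
        assert site.spacer == "A" * 20 and site.pam == "AGG"

    def test_minus_strand_spacer_is_revcomp_of_reference(self, tiny_genome):
        sites = gs.enumerate_targets(tiny_genome, max_flank=0)
        minus = [s for s in sites if s.strand == "-"]
        assert minus, "random genome should contain minus-strand sites"
        L = len(tiny_genome.sequence)
        for site in minus[:50]:
            # spacer at [s, s+20) on the revcomp equals revcomp of the + slice
            start_plus = L - (site.spacer_start + 20)
            ref_slice = tiny_genome.sequence[start_plus : start_plus + 20]
            assert site.spacer == reverse_complement(ref_slice)
            # and it sits immediately 3' of a CC-containing PAM on the + strand
            pam_plus = tiny_genome.sequence[start_plus - 3 : start_plus]
            assert reverse_complement(pam_plus)[1:] == "GG"

    @pytest.mark.parametrize("max_flank", [0, 30])
    def test_count_matches_bruteforce_scan(self, max_flank):
        g = gs.generate_genome(10_000, gc=0.5, seed=13)
        sites = gs.enumerate_targets(g, max_flank=max_flank)
        assert len(sites) == brute_force_sites(g.sequence, max_flank)

    def test_all_sites_support_requested_flank(self, tiny_genome):
        for site in gs.enumerate_targets(tiny_genome, max_flank=25):
            w = gs.extract_window(tiny_genome, site, gs.WindowSpec(25, True, 22))
            assert len(w) == 25 + 20 + 3 + 22


class TestAssignTrueActivity:
    def test_null_model_gives_baseline(self, tiny_genome):
        sites = gs.enumerate_targets(tiny_genome, max_flank=5)[:50]
        model = ActivityModel(baseline=1.5, noise_sd=0.0)
        acts = gs.assign_true_activity(tiny_genome, sites, model)
        assert all(a == 1.5 for a in acts.values())

    def test_single_planted_weight_is_analytic(self, tiny_genome):
        sites = gs.enumerate_targets(tiny_genome, max_flank=5)[:200]
        w = 0.7
        model = ActivityModel(positional_weights={(-2, "TT"): w}, noise_sd=0.0)
        acts = gs.assign_true_activity(tiny_genome, sites, model)
        for site in sites:
            expected = w if site.spacer[18:20] == "TT" else 0.0
            assert acts[site.guide_id] == pytest.approx(expected)

    def test_noise_is_seed_deterministic(self, tiny_genome):
        sites = gs.enumerate_targets(tiny_genome, max_flank=5)[:50]
        model = ActivityModel(noise_sd=0.5, seed=9)
        a = gs.assign_true_activity(tiny_genome, sites, model)
        b = gs.assign_true_activity(tiny_genome, sites, model)
        assert a == b

    def test_weight_outside_flank_raises(self):
        seq = "A" * 20 + "AGG" + "AT"
        genome = gs.Genome("c", seq)
        sites = gs.enumerate_targets(genome, max_flank=0)
        model = ActivityModel(positional_weights={(40, "AA"): 1.0})
        with pytest.raises(ValueError, match="outside the contig"):
            gs.assign_true_activity(genome, sites, model)


@pytest.fixture(scope="module")
def library():
    g = gs.generate_genome(30_000, gc=0.5, seed=5)
    sites = gs.enumerate_targets(g, max_flank=5)[:400]
    return g, sites


class TestSimulateScreen:
    def test_column_sums_equal_depth(self, library):
        g, sites = library
        acts = {s.guide_id: 0.5 for s in sites}
        table = gs.simulate_screen(sites, acts, ScreenConfig(depth=50_000, seed=2))
        assert (table.counts.sum(axis=0) == 50_000).all()

    def test_null_selection_centers_scores_at_zero(self, library):
        g, sites = library
        rng = np.random.default_rng(4)
        acts = {s.guide_id: float(rng.normal()) for s in sites}
        cfg = ScreenConfig(n_control=3, n_experimental=3, depth=400_000,
                           selection_strength=0.0, seed=7)
        table = gs.simulate_screen(sites, acts, cfg)
        scores = gs.score_diffbtw(table)
        assert abs(scores["score"].mean()) < 0.05

    def test_two_guide_reweighting_matches_closed_form(self):
        g = gs.generate_genome(3000, gc=0.5, seed=6)
        sites = gs.enumerate_targets(g, max_flank=0)[:2]
        a = 2.0
        acts = {sites[0].guide_id: a, sites[1].guide_id: 0.0}
        cfg = ScreenConfig(n_control=1, n_experimental=1, depth=4_000_000,
                           abundance_dispersion=0.0, selection_strength=1.0,
                           direction="depletion", seed=3)
        table = gs.simulate_screen(sites, acts, cfg)
        exp = table.counts[table.samples_for("experimental")[0]]
        ratio = exp.iloc[0] / exp.iloc[1]
        assert ratio == pytest.approx(2.0 ** (-a), rel=0.02)

    def test_zero_depth_gives_all_zero_counts(self, library):
        g, sites = library
        acts = {s.guide_id: 0.0 for s in sites}
        table = gs.simulate_screen(sites, acts, ScreenConfig(depth=0, seed=1))
        assert (table.counts.to_numpy() == 0).all()

    def test_empty_site_list_rejected(self):
        with pytest.raises(ValueError):
            gs.simulate_screen([], {}, ScreenConfig())

    def test_deterministic_per_seed(self, library):
        g, sites = library
        acts = {s.guide_id: 0.1 for s in sites}
        t1 = gs.simulate_screen(sites, acts, ScreenConfig(depth=10_000, seed=8))
        t2 = gs.simulate_screen(sites, acts, ScreenConfig(depth=10_000, seed=8))
        assert t1.counts.equals(t2.counts)

    def test_score_rmse_decreases_with_depth(self, library):
        """Deeper sequencing brings point-estimate scores closer to k*activity."""
        g, sites = library
        rng = np.random.default_rng(10)
        acts = {s.guide_id: float(rng.normal(0, 1)) for s in sites}
        truth = np.array([acts[s.guide_id] for s in sites])
        rmses = []
        for depth in (4_000, 40_000, 400_000):
            cfg = ScreenConfig(n_control=2, n_experimental=2, depth=depth,
                               abundance_dispersion=0.5, selection_strength=1.0, seed=12)
            scores = gs.score_diffbtw(gs.simulate_screen(sites, acts, cfg))["score"].to_numpy()
            # compositional closure shifts the scale; compare centred values
            rmses.append(np.sqrt(np.mean(((scores - scores.mean()) - (truth - truth.mean())) ** 2)))
        assert rmses[0] > rmses[1] > rmses[2]
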