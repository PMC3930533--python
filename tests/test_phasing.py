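"""Bootstrap arithmetic, pair phase calls, chain extension and verdicts."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import matephase as mp
from matephase.association import UsageError
from matephase.phasing import cumulative_ci, nearest_rank

UP = mp.HetSite("chr1", 100, "G", "A")
DOWN = mp.HetSite("chr1", 2100, "A", "G")


def matrix(cells, up=UP, down=DOWN):
    """cells: {(up_base, down_base): count}"""
    counts = np.zeros((4, 4), dtype=np.int64)
    for (a, b), c in cells.items():
        counts[mp.BASE_INDEX[a], mp.BASE_INDEX[b]] = c
    return mp.AssociationMatrix(up, down, counts)


class TestBootstrapRow:
    def test_degenerate_row_without_error_mass(self):
        res = mp.bootstrap_row([100, 0, 0, 0], error_mass=0.0, seed=1)
        assert np.allclose(res.probs, [1, 0, 0, 0])
        assert res.ci_low[0] == res.ci_high[0] == 1.0
        assert (res.ci_low[1:] == 0).all() and (res.ci_high[1:] == 0).all()

    def test_error_mass_adjustment_is_exact(self):
        res = mp.bootstrap_row([100, 0, 0, 0], error_mass=0.01, seed=1)
        assert res.probs[0] == pytest.approx(0.9925, abs=1e-15)
        assert np.allclose(res.probs[1:], 0.0025, atol=1e-15)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 500), min_size=4, max_size=4)
           .filter(lambda c: sum(c) > 0),
           st.floats(0.0, 0.5))
    def test_adjusted_probabilities_normalize(self, counts, eps):
        res = mp.bootstrap_row(counts, error_mass=eps, n_iter=10, seed=0)
        assert abs(res.probs.sum() - 1.0) < 1e-12
        assert ((0 <= res.ci_low) & (res.ci_low <= res.ci_high)
                & (res.ci_high <= 1)).all()

    def test_mean_bootstrap_proportion_is_unbiased(self):
        # counts (50,50,0,0), eps=0.01: adjusted major probability 0.4975
        res = mp.bootstrap_row([50, 50, 0, 0], error_mass=0.01,
                               n_iter=4000, seed=7)
        se = np.sqrt(0.4975 * 0.5025 / 100)
        for b in (0, 1):
            assert abs(res.draws[:, b].mean() - 0.4975) < 3 * se

    def test_zero_row_signals_zero_coverage(self):
        with pytest.raises(mp.ZeroCoverageError):
            mp.bootstrap_row([0, 0, 0, 0], seed=0)

    def test_ci_width_shrinks_with_row_total(self):
        widths = []
        for n in (20, 200, 2000):
            res = mp.bootstrap_row([9 * n // 10, n // 10, 0, 0],
                                   error_mass=0.01, seed=5)
            widths.append(float(np.mean(res.ci_high - res.ci_low)))
        assert widths[0] > widths[1] > widths[2]


def test_nearest_rank_small_samples():
    v = np.array([0.1, 0.2, 0.3, 0.4])
    assert nearest_rank(v, 0.01) == 0.1
    assert nearest_rank(v, 0.5) == 0.2
    assert nearest_rank(v, 0.99) == 0.4


class TestPhasePair:
    def test_diagonal_matrix_is_cis_with_certainty(self):
        m = matrix({("G", "A"): 500, ("A", "G"): 500})  # ref-with-ref, alt-with-alt
        pp = mp.phase_pair(m, error_mass=0.0, seed=0)
        assert pp.call == "cis" and pp.confident
        assert pp.step_probabilities == (1.0, 1.0)

    def test_trans_specimen_with_recombinant_mass(self):
        # 7% of each row on the recombinant cell; adjusted selected
        # probability = 0.99*0.93 + 0.0025 = 0.9232 exactly
        m = matrix({("G", "G"): 93, ("G", "A"): 7,
                    ("A", "A"): 93, ("A", "G"): 7})
        pp = mp.phase_pair(m, error_mass=0.01, seed=0)
        assert pp.call == "trans" and pp.confident
        for p in pp.step_probabilities:
            assert p == pytest.approx(0.99 * 0.93 + 0.0025, abs=1e-12)

    def test_same_selection_in_both_rows_is_ambiguous(self):
        m = matrix({("G", "G"): 90, ("A", "G"): 90, ("A", "A"): 10})
        assert mp.phase_pair(m, seed=0).call == "ambiguous"

    def test_zero_allele_row_is_unphaseable(self):
        m = matrix({("G", "G"): 50})
        with pytest.raises(mp.ZeroCoverageError):
            mp.phase_pair(m, seed=0)

    def test_simulated_trans_specimen(self):
        sites = ((250, "G", "A"), (2250, "A", "G"))
        cfg = mp.SimulationConfig(seed=77, region_length=2500, het_sites=sites,
                                  hap1_bases=("G", "G"), n_fragments=60000)
        # hap1 = (ref, alt) -> the two mutants sit on opposite alleles
        fs = mp.simulate_fragments(cfg)
        m = mp.build_association_matrix(fs.to_linked_fragments(2), *cfg.sites)
        pp = mp.phase_pair(m, seed=1)
        assert pp.call == "trans" and pp.confident


def chain_matrices(step_probs, n=1000):
    """Connected matrices whose ref-row adjusted probs (eps=0) hit step_probs."""
    sites = [mp.HetSite("chr1", 100 * (i + 1), "G", "A")
             for i in range(len(step_probs) + 1)]
    out = []
    for i, p in enumerate(step_probs):
        k = int(round(p * n))
        cells = {("G", "G"): k, ("G", "A"): n - k,
                 ("A", "A"): k, ("A", "G"): n - k}
        out.append(matrix(cells, sites[i], sites[i + 1]))
    return out


class TestChainPhase:
    def test_single_matrix_cumulative_equals_step(self):
        (m,) = chain_matrices([0.9])
        c1, _ = mp.chain_phase([m], error_mass=0.0, seed=3)
        st_ = c1.steps[0]
        assert st_.cumulative_prob == st_.step_probability
        sel = mp.BASE_INDEX[st_.selected_base]
        assert st_.cumulative_ci_low == st_.row.ci_low[sel]
        assert st_.cumulative_ci_high == st_.row.ci_high[sel]

    def test_two_step_cumulative_is_product(self):
        c1, _ = mp.chain_phase(chain_matrices([0.9, 0.8]), error_mass=0.0, seed=3)
        assert c1.steps[0].step_probability == pytest.approx(0.9, abs=1e-12)
        assert c1.steps[1].step_probability == pytest.approx(0.8, abs=1e-12)
        assert c1.steps[1].cumulative_prob == pytest.approx(0.72, abs=1e-12)

    def test_cumulative_product_identity_and_monotonicity(self, chained_region):
        cfg, fs, frags = chained_region
        plan = mp.adjacent_pairs_matrices(frags, cfg.sites)
        c1, c2 = mp.chain_phase(plan.matrices, seed=11)
        for chain in (c1, c2):
            running = 1.0
            prev = 1.0
            for st_ in chain.steps:
                running *= st_.step_probability
                assert abs(st_.cumulative_prob - running) < 1e-12
                assert st_.cumulative_prob <= prev + 1e-15
                prev = st_.cumulative_prob

    def test_chains_are_complementary_on_simulated_data(self, chained_region):
        cfg, fs, frags = chained_region
        plan = mp.adjacent_pairs_matrices(frags, cfg.sites)
        c1, c2 = mp.chain_phase(plan.matrices, seed=11)
        assert mp.chains_complementary(c1, c2)
        calls1, calls2 = c1.calls(), c2.calls()
        for s in cfg.sites:
            assert {calls1[s.pos], calls2[s.pos]} == set(s.alleles)

    def test_disconnected_matrices_rejected(self):
        m1, m2 = chain_matrices([0.9, 0.9])
        m2.upstream = mp.HetSite("chr1", 150, "G", "A")
        with pytest.raises(UsageError):
            mp.chain_phase([m1, m2], seed=0)

    def test_zero_coverage_row_breaks_and_restarts(self):
        sites = [mp.HetSite("chr1", p, "G", "A") for p in (100, 200, 300)]
        m1 = matrix({("G", "G"): 100, ("A", "A"): 100}, sites[0], sites[1])
        # middle->right matrix has no G row: chain 1 (starting ref) breaks
        m2 = matrix({("A", "A"): 100}, sites[1], sites[2])
        c1, c2 = mp.chain_phase([m1, m2], error_mass=0.0, seed=5)
        assert c1.steps[1].break_before
        assert c1.steps[1].phase_set == 300
        assert c1.steps[0].phase_set == 100
        # chain 2 went A -> A -> A without a break
        assert not c2.steps[1].break_before

    def test_seeded_determinism_is_bitwise(self, chained_region):
        cfg, fs, frags = chained_region
        plan = mp.adjacent_pairs_matrices(frags, cfg.sites)
        a1, a2 = mp.chain_phase(plan.matrices, seed=42)
        b1, b2 = mp.chain_phase(plan.matrices, seed=42)
        for x, y in ((a1, b1), (a2, b2)):
            for sx, sy in zip(x.steps, y.steps):
                assert sx.selected_base == sy.selected_base
                assert sx.cumulative_prob == sy.cumulative_prob
                assert sx.cumulative_ci_low == sy.cumulative_ci_low
                assert np.array_equal(sx.row.draws, sy.row.draws)


class TestCumulativeCi:
    def test_single_step_equals_step_ci(self):
        draws = np.linspace(0.5, 1.0, 1000)
        (lo, hi), = cumulative_ci([draws])
        assert lo == nearest_rank(np.sort(draws), 0.01)
        assert hi == nearest_rank(np.sort(draws), 0.99)

    def test_all_ones_draws_give_unit_interval(self):
        ones = np.ones(500)
        out = cumulative_ci([ones, ones, ones])
        assert out == [(1.0, 1.0)] * 3

    def test_two_step_product_center(self):
        rng = np.random.default_rng(12)
        d1 = 0.93 + 0.01 * rng.standard_normal(20000)
        d2 = 0.93 + 0.01 * rng.standard_normal(20000)
        (_, _), (lo, hi) = cumulative_ci([d1, d2])
        prod = d1 * d2
        assert lo < prod.mean() < hi
        assert prod.mean() == pytest.approx(0.93 ** 2, abs=3e-4)

    def test_mismatched_iteration_counts_rejected(self):
        with pytest.raises(UsageError):
            cumulative_ci([np.ones(10), np.ones(20)])


class TestVerdicts:
    def test_perfect_data_all_confident(self):
        ms = chain_matrices([1.0, 1.0, 1.0])
        c1, c2 = mp.chain_phase(ms, error_mass=0.0, seed=2)
        assert c1.all_confident and c2.all_confident

    def test_low_coverage_junction_is_ambiguous(self):
        sites = [mp.HetSite("chr1", 100, "G", "A"), mp.HetSite("chr1", 200, "G", "A")]
        m = matrix({("G", "G"): 4, ("G", "A"): 1,
                    ("A", "A"): 4, ("A", "G"): 1}, *sites)
        c1, _ = mp.chain_phase([m], seed=9)
        assert c1.steps[0].verdict == "ambiguous"

    def test_confidence_verdict_matches_chain_flags(self, chained_region):
        cfg, fs, frags = chained_region
        plan = mp.adjacent_pairs_matrices(frags, cfg.sites)
        c1, _ = mp.chain_phase(plan.matrices, seed=11)
        assert mp.confidence_verdict(c1) == c1.verdicts

    def test_tied_argmax_is_flagged_ambiguous(self):
        m = matrix({("G", "G"): 50, ("G", "A"): 50, ("A", "A"): 100})
        c1, _ = mp.chain_phase([m], error_mass=0.0, seed=1)
        assert c1.steps[0].tie and c1.steps[0].verdict == "ambiguous"
        assert c1.steps[0].selected_base == "A"  # lowest base in A<C<G<T order


class TestPhaseRegion:
    def test_twelve_site_region_fully_phased(self, chained_region):
        cfg, fs, frags = chained_region
        res = mp.phase_region(frags, cfg.sites, seed=11)
        assert res.complementary
        assert res.n_phased == len(cfg.sites)
        assert len(set(c.phase_set for c in res.assignments.values())) == 1
        truth = cfg.truth_phase
        calls1 = res.chain1.calls()
        hap = 0 if calls1[cfg.sites[0].pos] == truth[cfg.sites[0].pos][0] else 1
        for s in cfg.sites:
            assert calls1[s.pos] == truth[s.pos][hap]

    def test_fewer_than_two_sites_rejected(self):
        with pytest.raises(UsageError):
            mp.phase_region([], [UP], seed=0)
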