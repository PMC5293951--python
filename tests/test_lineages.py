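import numpy as np
import pytest

import mutdiv as m
from mutdiv import ContactOutcomes, RegimeParameters, RICoupling


def params(**kwargs):
    defaults = dict(t_i=100.0, t_s=500.0, t_r=200.0, timing_mode="fixed",
                    total_time=350.0, max_lineages=64)
    defaults.update(kwargs)
    return RegimeParameters(**defaults)


class TestClassifyRegime:
    @pytest.mark.parametrize(
        "t_i,t_s,t_r,expected",
        [
            (100, 500, 200, "isolation_completes_ri"),
            (300, 50, 5000, "fusion_latest_split_only"),
            (30, 50, 5000, "chained_isolation"),
            (100, 80, 300, "partial_ri_contact"),
        ],
    )
    def test_textbook_regimes(self, t_i, t_s, t_r, expected):
        assert m.classify_regime(t_i, t_s, t_r) == expected

    def test_tie_goes_to_isolation(self):
        # t_s == t_r: RI completes by the time contact can occur
        assert m.classify_regime(100, 200, 200) == "isolation_completes_ri"

    def test_far_factor_boundary(self):
        assert m.classify_regime(10, 100, 999) == "partial_ri_contact"
        assert m.classify_regime(10, 100, 1000) == "chained_isolation"

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            m.classify_regime(0, 1, 1)


class TestSimulateHistory:
    def test_no_isolation_events_single_lineage(self):
        hist = m.simulate_history(params(t_i=1e9), seed=0)
        assert len(hist.events) == 0
        assert len(hist.lineages) == 1
        assert not hist.truncated

    def test_isolation_regime_completes_ri_without_fusion(self):
        hist = m.simulate_history(params(), seed=1)
        kinds = [e.type for e in hist.events]
        assert "fuse" not in kinds and "extinction" not in kinds
        # every split at least t_r before the end reached RI
        n_splits_old = sum(
            1 for e in hist.events if e.type == "isolation" and e.time <= 350 - 200
        )
        assert kinds.count("ri_complete") == n_splits_old

    def test_fixed_timing_doubles_lineages_every_t_i(self):
        hist = m.simulate_history(params(), seed=2)
        tree = m.reconstruct_tree(hist)
        assert len(tree.leaf_nodes()) == 2 ** int(350 // 100)

    def test_fusion_regime_keeps_only_latest_split(self):
        p = params(t_i=100, t_s=30, t_r=5000, total_time=500,
                   contact_outcomes=ContactOutcomes(0.0, 0.0, 0.0))
        hist = m.simulate_history(p, seed=3)
        kinds = [e.type for e in hist.events]
        # every isolation except the last is undone by a fusion
        assert kinds.count("fuse") == kinds.count("isolation") - 1
        tree = m.reconstruct_tree(hist)
        assert len(tree.leaf_nodes()) == 2
        last_split = max(e.time for e in hist.events if e.type == "isolation")
        # the only surviving split is the latest isolation event
        assert tree.seed_node.edge.length == pytest.approx(last_split)

    def test_event_times_non_decreasing_and_states_exclusive(self):
        p = params(t_i=50, t_s=60, t_r=150, timing_mode="exponential",
                   total_time=400, contact_outcomes=ContactOutcomes(0.3, 0.2, 0.1))
        for seed in range(10):
            hist = m.simulate_history(p, seed=seed)
            times = [e.time for e in hist.events]
            assert times == sorted(times)
            for lin in hist.lineages.values():
                if lin.death is not None:
                    assert lin.fate in ("fused", "extinct")
                    assert lin.death >= lin.birth
                else:
                    assert lin.fate is None
                if lin.parent is not None:
                    assert hist.lineages[lin.parent].birth <= lin.birth

    def test_truncation_flag_at_lineage_cap(self):
        hist = m.simulate_history(params(max_lineages=4, total_time=1000), seed=4)
        assert hist.truncated
        assert sum(1 for l in hist.lineages.values() if l.extant) == 4
        assert hist.end_time < 1000

    def test_reinforcement_completes_ri_and_both_survive(self):
        p = params(t_i=1000, t_s=50, t_r=5000, total_time=1500,
                   contact_outcomes=ContactOutcomes(1.0, 0.0, 0.0))
        hist = m.simulate_history(p, seed=5)
        kinds = [e.type for e in hist.events]
        assert "reinforce" in kinds and "fuse" not in kinds
        assert sum(1 for l in hist.lineages.values() if l.extant) == 2

    def test_extinction_of_both_leaves_empty_tree(self):
        p = params(t_i=10, t_s=1, t_r=5000, total_time=15,
                   contact_outcomes=ContactOutcomes(0.0, 0.0, 1.0))
        hist = m.simulate_history(p, seed=6)
        assert any(e.type == "extinction" for e in hist.events)
        with pytest.raises(m.EmptyTreeError):
            m.reconstruct_tree(hist)


class TestReconstruction:
    def test_single_lineage_tree(self):
        hist = m.simulate_history(params(t_i=1e9), seed=0)
        tree = m.reconstruct_tree(hist)
        assert len(tree.leaf_nodes()) == 1
        assert tree.seed_node.edge.length == pytest.approx(350.0)

    def test_trees_are_binary_positive_and_ultrametric(self):
        p = params(t_i=60, t_s=70, t_r=150, timing_mode="exponential", total_time=400)
        for seed in range(5):
            hist = m.simulate_history(p, seed=seed)
            try:
                tree = m.reconstruct_tree(hist)
            except m.EmptyTreeError:
                continue
            for node in tree.preorder_node_iter():
                assert node.edge.length >= 0
                assert len(node.child_nodes()) in (0, 2)
            # ultrametric at the reading time (truncated runs end early)
            depths = [leaf.distance_from_root() for leaf in tree.leaf_nodes()]
            assert np.allclose(depths, hist.end_time)

    def test_total_tree_length_matches_event_log_pure_birth(self):
        # with no fusion/extinction every population alive at the end is a
        # tip, so the sum of edge lengths must equal the integral of the
        # alive-lineage count over time, computed from the raw event record
        p = params(t_i=60, t_s=1e9, t_r=1.0, timing_mode="exponential",
                   total_time=400)
        for seed in range(10):
            hist = m.simulate_history(p, seed=seed)
            tree = m.reconstruct_tree(hist)
            births = sorted(l.birth for l in hist.lineages.values())
            integral = sum(hist.end_time - b for b in births)
            total = sum(nd.edge.length for nd in tree.preorder_node_iter())
            assert total == pytest.approx(integral, rel=1e-9)

    def test_pruned_tree_never_longer_than_true_genealogy(self):
        # fused and extinct branches are invisible to reconstruction
        p = params(t_i=60, t_s=80, t_r=120, timing_mode="exponential",
                   total_time=500, contact_outcomes=ContactOutcomes(0.4, 0.2, 0.05))
        for seed in range(10):
            hist = m.simulate_history(p, seed=seed)
            try:
                tree = m.reconstruct_tree(hist)
            except m.EmptyTreeError:
                continue
            true_length = sum(
                (l.death if l.death is not None else hist.end_time) - l.birth
                for l in hist.lineages.values()
            )
            total = sum(nd.edge.length for nd in tree.preorder_node_iter())
            assert total <= true_length + 1e-9

    def test_internode_summary_fixed_timing(self):
        hist = m.simulate_history(params(), seed=7)
        s = m.internode_summary(m.reconstruct_tree(hist))
        assert s.mean == pytest.approx(100.0)
        assert s.variance == pytest.approx(0.0)
        assert s.count == 2 ** int(350 // 100) - 1

    def test_internode_summary_needs_two_tips(self):
        hist = m.simulate_history(params(t_i=1e9), seed=0)
        with pytest.raises(ValueError):
            m.internode_summary(m.reconstruct_tree(hist))


class TestDiversification:
    def test_two_tip_formula(self):
        p = params(t_i=250, total_time=350, t_s=1e6, t_r=1.0)
        hist = m.simulate_history(p, seed=8)
        est = m.diversification_estimate(m.reconstruct_tree(hist))
        assert est.n_tips == 2
        assert est.crown_age == pytest.approx(100.0)
        assert est.lambda_hat == pytest.approx(np.log(2) / 100)

    def test_yule_consistency_against_direct_oracle(self):
        # independent oracle: simulate the Yule process directly (waits
        # Exp(t_i/k)) and compare mean crown-age estimates
        t_i, total, n_hist = 100.0, 500.0, 400
        rng = np.random.default_rng(9)
        oracle = []
        for _ in range(n_hist):
            t, k, first_split = 0.0, 1, None
            while True:
                t += rng.exponential(t_i / k)
                if t > total:
                    break
                if first_split is None:
                    first_split = t
                k += 1
            if k >= 2:
                oracle.append(np.log(k) / (total - first_split))
        p = params(t_i=t_i, t_s=1e9, t_r=1.0, timing_mode="exponential",
                   total_time=total, max_lineages=1000)
        sims = []
        for seed in range(n_hist):
            hist = m.simulate_history(p, seed=(10, seed))
            try:
                sims.append(m.diversification_estimate(m.reconstruct_tree(hist)).lambda_hat)
            except (m.EmptyTreeError, ValueError):
                pass
        sem = np.hypot(np.std(oracle) / np.sqrt(len(oracle)),
                       np.std(sims) / np.sqrt(len(sims)))
        assert abs(np.mean(sims) - np.mean(oracle)) < 3 * sem

    def test_fusion_regime_slower_diversification_than_isolation(self):
        # stem-age measure ln(n)/T: fusion prunes tips at matched t_i
        common = dict(t_i=100.0, timing_mode="exponential", total_time=500.0,
                      max_lineages=200)
        iso = RegimeParameters(t_s=1e9, t_r=1.0, **common)
        fus = RegimeParameters(t_s=20.0, t_r=1e9,
                               contact_outcomes=ContactOutcomes(0.0, 0.0, 0.0),
                               **common)
        def mean_stem(p, base):
            vals = []
            for seed in range(200):
                hist = m.simulate_history(p, seed=(base, seed))
                try:
                    n = len(m.reconstruct_tree(hist).leaf_nodes())
                except m.EmptyTreeError:
                    n = 1
                vals.append(np.log(n) / hist.end_time)
            return np.mean(vals)
        assert mean_stem(fus, 0) < mean_stem(iso, 1)


class TestMutationRateCoupling:
    def test_doubling_u_halves_expected_t_r(self):
        p1 = params(t_r=None, coupling=RICoupling(0.05, 1e-4))
        p2 = params(t_r=None, coupling=RICoupling(0.05, 2e-4))
        assert p1.expected_t_r == pytest.approx(2 * p2.expected_t_r)
        assert p1.expected_t_r == pytest.approx((1 / 0.05) / 1e-4)

    def test_sweep_reports_one_row_per_u(self):
        base = RegimeParameters(t_i=5e4, t_s=1e4, t_r=1.0, timing_mode="exponential",
                                total_time=1.5e5, max_lineages=50,
                                contact_outcomes=ContactOutcomes(0.0, 0.0, 0.0))
        df = m.sweep_mutation_rate([4e-4, 4e-3], 0.05, base, n_histories=50, seed=13)
        assert list(df["u"]) == [4e-4, 4e-3]
        assert (df["mean_lambda"] >= 0).all()

    def test_high_epsilon_approaches_pure_isolation(self):
        # epsilon near 1: the first substitution isolates, T_R ~ 1/u
        p = params(t_r=None, coupling=RICoupling(0.999, 1e-3))
        assert p.expected_t_r == pytest.approx(1 / 0.999 / 1e-3, rel=1e-6)


class TestValidation:
    def test_exactly_one_of_t_r_and_coupling(self):
        with pytest.raises(ValueError):
            params(t_r=None)
        with pytest.raises(ValueError):
            params(coupling=RICoupling(0.05, 1e-4))  # t_r also set by default

    @pytest.mark.parametrize(
        "kwargs",
        [dict(t_i=0), dict(t_s=-1), dict(t_r=0), dict(timing_mode="gamma"),
         dict(total_time=0), dict(max_lineages=1)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            params(**kwargs)

    def test_outcome_probabilities_validated(self):
        with pytest.raises(ValueError):
            ContactOutcomes(0.9, 0.2, 0.1)
        assert ContactOutcomes(0.5, 0.25, 0.05).p_fuse == pytest.approx(0.2)
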