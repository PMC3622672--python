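"""Control selection, leave-one-out driver, and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from diffprio import (
    CVConfig,
    GeneNetwork,
    GenePositions,
    parameter_sweep,
    pr_curve,
    roc_from_rank_ratios,
    run_loocv,
    select_controls_ali,
    select_controls_random,
)


class TestRandomControls:
    def test_forced_on_n_plus_one_genes(self, rng):
        net = GeneNetwork(edges=[(f"g{i:03d}", f"g{(i + 1) % 100:03d}")
                                 for i in range(100)])
        controls = select_controls_random("g000", net, 99, rng)
        assert controls == frozenset(net.nodes) - {"g000"}

    def test_seed_reproducibility_and_exclusion(self, small_bundle):
        net = small_bundle.network
        a = select_controls_random("g00005", net, 20,
                                   np.random.default_rng(5),
                                   exclude={"g00001"})
        b = select_controls_random("g00005", net, 20,
                                   np.random.default_rng(5),
                                   exclude={"g00001"})
        assert a == b
        assert "g00005" not in a and "g00001" not in a

    def test_too_few_genes(self, triangle_network, rng):
        with pytest.raises(ValueError, match="controls"):
            select_controls_random("a", triangle_network, 99, rng)


def positions_from(records):
    return GenePositions(records=records)


class TestAliControls:
    @pytest.fixture
    def five_gene_chrom(self):
        net = GeneNetwork(
            edges=[("g1", "g2"), ("g2", "g3"), ("g3", "g4"), ("g4", "g5")])
        pos = positions_from({
            "g1": ("chr1", 5, 15), "g2": ("chr1", 15, 25),
            "g3": ("chr1", 25, 35), "g4": ("chr1", 35, 45),
            "g5": ("chr1", 45, 55),
        })
        return net, pos

    def test_nearest_two(self, five_gene_chrom):
        net, pos = five_gene_chrom
        controls = select_controls_ali("g3", pos, net, 2)
        assert controls == {"g2", "g4"}

    def test_equidistant_tie_breaks_by_gene_id(self):
        net = GeneNetwork(edges=[("a", "b"), ("b", "c"), ("c", "t")])
        pos = positions_from({
            "t": ("chr1", 100, 100), "a": ("chr1", 90, 90),
            "b": ("chr1", 110, 110), "c": ("chr1", 120, 120),
        })
        controls = select_controls_ali("t", pos, net, 1)
        assert controls == {"a"}  # |90-100| == |110-100|; 'a' < 'b'

    def test_short_chromosome_random_fill(self, rng):
        net = GeneNetwork(edges=[(f"x{i}", f"x{i + 1}") for i in range(9)])
        pos = positions_from(
            {f"x{i}": ("chr1" if i < 4 else "chr2", i * 100, i * 100 + 10)
             for i in range(10)})
        controls = select_controls_ali("x0", pos, net, 6, rng)
        assert len(controls) == 6
        assert {"x1", "x2", "x3"} <= controls  # all same-chromosome genes

    def test_missing_position_raises_key_error(self, five_gene_chrom):
        net, pos = five_gene_chrom
        with pytest.raises(KeyError, match="position"):
            select_controls_ali("nowhere", pos, net, 2)


class TestRocFromRankRatios:
    def test_all_top_ranked(self):
        # every held-out gene at rank 1 of 100: sensitivity 1 from the
        # first grid step on, AUC essentially 1
        test_rr = [0.01] * 5
        control_rr = [r / 100 for r in range(2, 101)] * 5
        roc, auc = roc_from_rank_ratios(test_rr, control_rr)
        assert roc.loc[roc.threshold == 0.01, "sensitivity"].item() == 1.0
        assert auc >= 0.99

    def test_single_case_step(self):
        roc, _ = roc_from_rank_ratios([0.5], [])
        sens = roc.sensitivity.to_numpy()
        assert sens[49] == 0.0  # threshold 0.49
        assert sens[50] == 1.0  # threshold 0.50
        assert len(roc) == 101

    def test_uniform_ranks_give_half_auc(self, rng):
        # 500 simulated cases with uniformly random ranks of 100
        ranks = rng.integers(1, 101, size=500)
        test_rr = ranks / 100
        control_rr = np.concatenate(
            [np.delete(np.arange(1, 101), r - 1) / 100 for r in ranks])
        _, auc = roc_from_rank_ratios(test_rr, control_rr)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_curve_is_monotone(self, rng):
        test_rr = rng.uniform(0.01, 1, 50)
        control_rr = rng.uniform(0.01, 1, 500)
        roc, auc = roc_from_rank_ratios(test_rr, control_rr)
        assert roc.sensitivity.is_monotonic_increasing
        assert (1 - roc.specificity).is_monotonic_increasing
        assert 0.0 <= auc <= 1.0


class TestPrCurve:
    def test_hand_enumerated_three_points(self):
        # scores 0.9(+), 0.8(-), 0.7(+): precision at full recall is 2/3
        curve = pr_curve([0.9, 0.8, 0.7], [1, 0, 1])
        assert curve.precision.tolist() == pytest.approx([1.0, 0.5, 2 / 3])
        assert curve.recall.tolist() == pytest.approx([0.5, 0.5, 1.0])

    def test_perfect_separation(self):
        # every recall level is attainable at precision 1 when positives
        # strictly outscore negatives
        curve = pr_curve([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        envelope = curve.groupby("recall")["precision"].max()
        assert (envelope == 1.0).all()

    def test_matches_sklearn_on_random_scores(self, rng):
        from sklearn.metrics import precision_recall_curve

        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0] = 1
        labels[1] = 0
        ours = pr_curve(scores, labels)
        precision, recall, thresholds = precision_recall_curve(labels, scores)
        ref = {(round(r, 12), round(t, 12)): p
               for p, r, t in zip(precision, recall, thresholds)}
        for row in ours.itertuples():
            key = (round(row.recall, 12), round(row.threshold, 12))
            if key in ref:
                assert row.precision == pytest.approx(ref[key])

    def test_constant_scores_give_prevalence(self):
        curve = pr_curve([0.5, 0.5, 0.5, 0.5], [1, 0, 0, 0])
        assert len(curve) == 1
        assert curve.precision.item() == 0.25
        assert curve.recall.item() == 1.0

    def test_requires_both_classes(self):
        with pytest.raises(ValueError, match="positive"):
            pr_curve([0.1, 0.2], [0, 0])


class TestRunLoocv:
    def test_perfect_and_definitions(self, small_bundle):
        # with strong planted modules most held-out genes rank near the
        # top; check the bookkeeping identities rather than the score level
        result = run_loocv(small_bundle.associations,
                           small_bundle.similarities,
                           small_bundle.network,
                           CVConfig(method="rwr", n_controls=20, seed=3))
        assert result.pre_count == sum(c.rank == 1 for c in result.cases)
        assert result.pre_proportion == result.pre_count / result.n_cases
        for case in result.cases:
            assert 0 < case.rank_ratio <= 1
            assert case.n_candidates == 21
            assert case.rank_ratio == case.rank / case.n_candidates
        assert 0.0 <= result.auc <= 1.0

    def test_determinism(self, small_bundle):
        config = CVConfig(method="dp_lcc", n_controls=15, seed=11)
        a = run_loocv(small_bundle.associations, small_bundle.similarities,
                      small_bundle.network, config)
        b = run_loocv(small_bundle.associations, small_bundle.similarities,
                      small_bundle.network, config)
        pd.testing.assert_frame_equal(a.cases_frame(), b.cases_frame())
        assert a.auc == b.auc and a.pre_count == b.pre_count

    def test_forced_controls_make_result_seed_invariant(self):
        # 100-gene network, 99 controls: the control set is forced, so any
        # two seeds agree (co-causal exclusion off, else the pool is short)
        net = GeneNetwork(edges=[(f"g{i:03d}", f"g{(i + 1) % 100:03d}")
                                 for i in range(100)])
        amap = {"D1": frozenset({"g000", "g050"}),
                "D2": frozenset({"g010", "g011"})}
        results = [
            run_loocv(amap, None, net,
                      CVConfig(method="rwr", n_controls=99, seed=seed,
                               exclude_cocausal_controls=False))
            for seed in (0, 99)
        ]
        assert [c.rank for c in results[0].cases] == \
            [c.rank for c in results[1].cases]

    def test_requires_multi_gene_disease(self, triangle_network):
        with pytest.raises(ValueError, match="2 in-network"):
            run_loocv({"D": frozenset({"a"})}, None, triangle_network,
                      CVConfig(method="rwr", n_controls=1))

    def test_ali_mode(self, small_bundle):
        result = run_loocv(small_bundle.associations,
                           small_bundle.similarities,
                           small_bundle.network,
                           CVConfig(method="rwr", control_mode="ali",
                                    n_controls=10, seed=1),
                           positions=small_bundle.positions)
        assert result.n_cases > 0
        assert all(c.n_candidates == 11 for c in result.cases)

    def test_strict_holdout_runs_and_differs_in_config(self, small_bundle):
        strict = run_loocv(small_bundle.associations,
                           small_bundle.similarities, small_bundle.network,
                           CVConfig(method="dp_lcc", n_controls=10, seed=2,
                                    strict_holdout=True))
        assert strict.config.strict_holdout
        assert strict.n_cases > 0


class TestParameterSweep:
    def test_grid_shape_and_determinism(self, small_bundle):
        kwargs = dict(
            gammas=[0.25, 0.7], lams=[0.0, 0.5],
            methods=["dp_lcc", "rwr"],
            base_config=CVConfig(n_controls=10, seed=4),
        )
        table = parameter_sweep(small_bundle.associations,
                                small_bundle.similarities,
                                small_bundle.network, **kwargs)
        assert len(table) == 8
        assert set(table.method) == {"dp_lcc", "rwr"}
        again = parameter_sweep(small_bundle.associations,
                                small_bundle.similarities,
                                small_bundle.network, **kwargs)
        pd.testing.assert_frame_equal(table, again)

    def test_lambda_zero_rwr_rows_constant_in_lambda(self, small_bundle):
        # the component-score baseline ignores lambda entirely
        table = parameter_sweep(small_bundle.associations,
                                small_bundle.similarities,
                                small_bundle.network,
                                gammas=[0.25], lams=[0.0, 0.5],
                                methods=["rwr"],
                                base_config=CVConfig(n_controls=10, seed=4))
        assert table.auc.nunique() == 1 and table.pre_count.nunique() == 1
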