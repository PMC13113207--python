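"""Variance-of-Gradients scoring, normalisation, ranking and analysis."""

import math

import numpy as np
import pandas as pd
import pytest

from mortexplain import model as mdl
from mortexplain import vog as vg


def naive_vog(grads):
    """Per-cell double loop oracle for the gradient-stack variance."""
    K, n, d = grads.shape
    total = 0.0
    for i in range(n):
        for j in range(d):
            cells = [grads[k, i, j] for k in range(K)]
            mean = sum(cells) / K
            total += sum((c - mean) ** 2 for c in cells) / K
    return total / (n * d)


def make_records(raws, classes, codes=None):
    return [
        vg.VoGRecord(
            cert_id=f"r{i}", class_index=c, raw_vog=r, n_tokens=5,
            n_conditions=2, n_lines=1,
            stated_codes=tuple(codes[i]) if codes else ("A00",),
        )
        for i, (r, c) in enumerate(zip(raws, classes))
    ]


class TestGradientStackArithmetic:
    def test_single_cell_hand_example(self):
        grads = np.array([1.0, 3.0]).reshape(2, 1, 1)
        assert vg.vog_from_gradient_stack(grads) == pytest.approx(1.0)

    def test_two_token_mean_of_variances(self):
        # per-token variances 1 and 3 -> mean 2
        grads = np.array([[[1.0], [1.0]], [[3.0], [2.0 + math.sqrt(3)]]])
        grads[0, 1, 0] = 2.0 - math.sqrt(3)
        assert vg.vog_from_gradient_stack(grads) == pytest.approx(2.0)

    def test_matches_naive_loop_on_random_stacks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            grads = rng.normal(size=(int(rng.integers(2, 6)),
                                     int(rng.integers(1, 7)),
                                     int(rng.integers(1, 5))))
            assert vg.vog_from_gradient_stack(grads) == pytest.approx(
                naive_vog(grads), abs=1e-12
            )

    def test_scale_property(self):
        rng = np.random.default_rng(1)
        grads = rng.normal(size=(4, 3, 2))
        base = vg.vog_from_gradient_stack(grads)
        for c in (0.5, 3.0):
            assert vg.vog_from_gradient_stack(c * grads) == pytest.approx(c**2 * base)

    def test_token_permutation_invariance(self):
        rng = np.random.default_rng(2)
        grads = rng.normal(size=(3, 6, 4))
        perm = rng.permutation(6)
        assert vg.vog_from_gradient_stack(grads[:, perm]) == pytest.approx(
            vg.vog_from_gradient_stack(grads)
        )

    def test_single_snapshot_rejected(self):
        with pytest.raises(ValueError):
            vg.vog_from_gradient_stack(np.zeros((1, 2, 2)))


class TestInstanceVoG:
    def test_oracle_equivalence_on_trained_model(self, trained20):
        cks = trained20["checkpoints"]
        rng = np.random.default_rng(3)
        for record in rng.choice(trained20["test"], size=100, replace=False):
            p = int(rng.integers(cks.final.k))
            grads = np.stack(
                [mdl.token_gradients(ck.model, record, p) * record.n_tokens for ck in cks]
            )
            assert vg.instance_vog(cks, record, p) == pytest.approx(
                naive_vog(grads), abs=1e-10
            )

    def test_identical_checkpoints_give_zero(self, trained20):
        final = trained20["checkpoints"].checkpoints[-1]
        twice = mdl.CheckpointSet(
            [mdl.Checkpoint(epoch=1, model=final.model),
             mdl.Checkpoint(epoch=2, model=final.model, is_final=True)]
        )
        assert vg.instance_vog(twice, trained20["test"][0], 0) == pytest.approx(0.0)

    def test_single_checkpoint_rejected(self, trained20):
        one = mdl.CheckpointSet([mdl.Checkpoint(
            epoch=1, model=trained20["model"], is_final=True)])
        with pytest.raises(ValueError):
            vg.instance_vog(one, trained20["test"][0], 0)

    def test_final_mode_uses_component_variance(self, trained20):
        record = trained20["test"][0]
        S = mdl.token_gradients(trained20["model"], record, 0) * record.n_tokens
        expected = S.var(axis=1, ddof=0).mean()
        got = vg.instance_vog(trained20["checkpoints"], record, 0, mode="final")
        assert got == pytest.approx(expected)


class TestNormalization:
    def test_class_centering_hand_example(self):
        records = vg.normalize_vog(make_records([0.0, 2.0], [0, 0]))
        assert [r.class_norm_vog for r in records] == [-1.0, 1.0]

    def test_two_class_z_scores_and_clipping(self):
        records = vg.normalize_vog(make_records([0.0, 2.0, 5.0, 5.0], [0, 0, 1, 1]))
        centred = np.array([-1.0, 1.0, 0.0, 0.0])
        z = centred / centred.std()
        expected = np.clip(z, -1, 1)
        assert [r.global_norm_vog for r in records] == pytest.approx(list(expected))
        assert [r.global_norm_unclipped for r in records] == pytest.approx(list(z))

    def test_extreme_outlier_clipped_to_one(self):
        raws = [0.0] * 50 + [100.0]
        records = vg.normalize_vog(make_records(raws, [0] * 51))
        assert records[-1].global_norm_vog == 1.0
        assert records[-1].global_norm_unclipped > 1.0

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            vg.normalize_vog(make_records([1.0, 1.0, 1.0], [0, 0, 1]))

    def test_class_means_centre_to_zero(self, trained20):
        recs = vg.score_records(trained20["checkpoints"], trained20["test"][:200])
        recs = vg.normalize_vog(recs)
        df = pd.DataFrame({"c": [r.class_index for r in recs],
                           "v": [r.class_norm_vog for r in recs]})
        assert df.groupby("c")["v"].mean().abs().max() < 1e-9


class TestRankAndFlag:
    def test_unseen_code_flagged(self):
        records = vg.normalize_vog(
            make_records([1.0, 2.0, 3.0], [0, 0, 0],
                         codes=[("A00",), ("A00",), ("Q99",)])
        )
        flagged = vg.rank_and_flag(records, {"A00": 50}, flag_quantile=0.99)
        by_id = {r.cert_id: r for r in flagged}
        assert by_id["r2"].ood_flag  # states Q99, absent from training

    def test_quantile_flag_count(self):
        rng = np.random.default_rng(4)
        records = vg.normalize_vog(make_records(rng.normal(10, 1, 1000), [0] * 1000))
        flagged = vg.rank_and_flag(records, {"A00": 5}, flag_quantile=0.95)
        n_flagged = sum(r.ood_flag for r in flagged)
        assert 40 <= n_flagged <= 60

    def test_sorting_is_a_permutation(self):
        rng = np.random.default_rng(5)
        records = vg.normalize_vog(make_records(rng.normal(10, 1, 100), [0] * 100))
        flagged = vg.rank_and_flag(records, {"A00": 5})
        assert sorted(r.cert_id for r in flagged) == sorted(r.cert_id for r in records)
        scores = [r.global_norm_vog for r in flagged]
        assert scores == sorted(scores, reverse=True)

    def test_unnormalized_records_rejected(self):
        with pytest.raises(ValueError):
            vg.rank_and_flag(make_records([1.0], [0]), {})


class TestFrequencyAnalysis:
    def test_row_counts_conserve_records(self):
        rng = np.random.default_rng(6)
        codes = [("A00",) if u < 0.5 else ("B20",) for u in rng.random(200)]
        records = vg.normalize_vog(
            make_records(rng.normal(10, 1, 200), [0] * 200, codes=codes)
        )
        table, trend = vg.vog_frequency_analysis(records, {"A00": 1, "B20": 5000})
        assert table["count"].sum() == 200
        assert trend["count"].sum() == 200

    def test_single_range_population(self):
        records = vg.normalize_vog(make_records([1.0, 2.0], [0, 0]))
        table, _ = vg.vog_frequency_analysis(records, {"A00": 10_000})
        assert (table["count"] > 0).sum() == 1

    def test_overlapping_ranges_rejected(self):
        records = vg.normalize_vog(make_records([1.0, 2.0], [0, 0]))
        with pytest.raises(ValueError):
            vg.vog_frequency_analysis(records, {"A00": 1},
                                      ranges=[(0, 5), (3, math.inf)])

    def test_gapped_ranges_rejected(self):
        records = vg.normalize_vog(make_records([1.0, 2.0], [0, 0]))
        with pytest.raises(ValueError):
            vg.vog_frequency_analysis(records, {"A00": 1},
                                      ranges=[(0, 5), (10, math.inf)])


class TestCorrelations:
    def test_perfect_monotone(self):
        v = np.arange(10.0)
        out = vg.difficulty_correlations(v, v, v + 3)
        assert out["pearson_conditions"] == pytest.approx(1.0)
        assert out["kendall_conditions"] == pytest.approx(1.0)

    def test_anti_monotone(self):
        v = np.arange(10.0)
        out = vg.difficulty_correlations(v, -v, -2 * v)
        assert out["kendall_conditions"] == pytest.approx(-1.0)
        assert out["pearson_lines"] == pytest.approx(-1.0)

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(7)
        out = vg.difficulty_correlations(
            rng.normal(size=10_000), rng.normal(size=10_000), rng.normal(size=10_000)
        )
        assert abs(out["pearson_conditions"]) < 0.03
        assert abs(out["kendall_conditions"]) < 0.03

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            vg.difficulty_correlations([1, 1, 1], [1, 2, 3], [1, 2, 3])

    def test_too_few_classes_rejected(self):
        with pytest.raises(ValueError):
            vg.difficulty_correlations([1, 2], [1, 2], [1, 2])
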