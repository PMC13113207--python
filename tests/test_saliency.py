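"""Integrated Gradients attribution, word aggregation and reporting."""

import numpy as np
import pytest

from mortexplain import model as mdl
from mortexplain import saliency as sal


class TestIntegratedGradients:
    @pytest.mark.parametrize("steps", [1, 4, 50])
    def test_linear_model_exact_at_any_step_count(self, trained_linear, steps):
        model = trained_linear["model"]
        record = trained_linear["test"][0]
        attrs, gap = sal.integrated_gradients(model, record, 0, steps=steps)
        X = mdl.embed_record(model, record)
        B = np.tile(model.params["E"][0], (X.shape[0], 1))
        expected = (X - B) * model.params["W"][0] / X.shape[0]
        assert np.allclose(attrs, expected, atol=1e-12)
        assert gap < 1e-10

    def test_baseline_equal_to_input_gives_zero(self, trained20):
        model = trained20["model"]
        record = trained20["test"][0]
        X = mdl.embed_record(model, record)
        attrs, gap = sal.integrated_gradients(model, record, 0, baseline=X)
        assert np.allclose(attrs, 0.0) and gap == pytest.approx(0.0)

    def test_completeness_against_dense_riemann_oracle(self, trained20):
        model = trained20["model"]
        rng = np.random.default_rng(0)
        for record in rng.choice(trained20["test"], size=5, replace=False):
            p = int(rng.integers(model.k))
            oracle, _ = sal.integrated_gradients(
                model, record, p, steps=4096, method="riemann_left"
            )
            attrs, gap = sal.integrated_gradients(model, record, p, steps=128)
            assert gap <= 1e-3
            assert np.allclose(attrs, oracle, atol=1e-3)

    def test_gap_non_increasing_in_steps(self, trained20):
        model = trained20["model"]
        rng = np.random.default_rng(1)
        for record in rng.choice(trained20["test"], size=20, replace=False):
            gaps = [
                sal.integrated_gradients(model, record, 0, steps=s)[1]
                for s in (8, 32, 128)
            ]
            assert gaps[2] <= gaps[0] + 1e-12
            assert gaps[1] <= gaps[0] + 1e-12

    def test_invalid_arguments_rejected(self, trained20):
        record = trained20["test"][0]
        with pytest.raises(ValueError):
            sal.integrated_gradients(trained20["model"], record, 0, steps=0)
        with pytest.raises(ValueError):
            sal.integrated_gradients(
                trained20["model"], record, 0, baseline=np.zeros((1, 1))
            )

    def test_symmetric_tokens_get_equal_attributions(self, trained20):
        model = trained20["model"]
        base = trained20["test"][0]
        tid = base.token_ids[1]
        record = type(base)(
            cert_id="sym", text="x x", tokens=(base.tokens[1],) * 2,
            token_ids=(tid, tid), token_offsets=((0, 1), (2, 3)),
            word_map=((0, 1), (1, 2)), label="", label_index=0,
        )
        attrs, _ = sal.integrated_gradients(model, record, 0)
        assert np.allclose(attrs[0], attrs[1], atol=1e-12)


class TestWordAggregation:
    def test_hand_sum(self):
        token_scalars, words, display = sal.aggregate_to_words(
            np.array([0.2, 0.3, -0.1]), [(0, 2), (2, 3)]
        )
        assert words == pytest.approx([0.5, -0.1])
        assert display == pytest.approx([1.0, -0.2])

    def test_component_matrix_is_summed_per_token(self):
        attrs = np.array([[0.1, 0.2], [0.3, -0.1]])
        token_scalars, words, _ = sal.aggregate_to_words(attrs, [(0, 1), (1, 2)])
        assert token_scalars == pytest.approx([0.3, 0.2])
        assert words.sum() == pytest.approx(token_scalars.sum())

    def test_all_zero_skips_display_normalisation(self):
        _, words, display = sal.aggregate_to_words(np.zeros(3), [(0, 3)])
        assert words == pytest.approx([0.0]) and display == pytest.approx([0.0])

    def test_uncovered_token_rejected(self):
        with pytest.raises(ValueError):
            sal.aggregate_to_words(np.array([0.1, 0.2]), [(0, 1)])

    def test_conservation_under_aggregation(self, trained20):
        record = trained20["test"][0]
        attrs, _ = sal.integrated_gradients(trained20["model"], record, 0)
        token_scalars, words, _ = sal.aggregate_to_words(attrs, record.word_map)
        assert words.sum() == pytest.approx(token_scalars.sum())
        assert words.sum() == pytest.approx(attrs.sum())


class TestReport:
    @pytest.fixture
    def attribution_records(self, trained_hard):
        model = trained_hard["model"]
        probs = mdl.predict_proba_batch(model, trained_hard["test"])
        pred = probs.argmax(axis=1)
        labels = np.array([r.label_index for r in trained_hard["test"]])
        correct = np.flatnonzero(pred == labels)[:3]
        wrong = np.flatnonzero(pred != labels)[:3]
        return [
            sal.attribute_record(
                model, trained_hard["test"][i], trained_hard["codebook"],
                trained_hard["classes"],
            )
            for i in np.concatenate([correct, wrong])
        ]

    def test_row_per_record_with_correctness(self, attribution_records, tmp_path):
        page, table = sal.render_saliency_report(
            attribution_records,
            html_path=tmp_path / "r.html",
            tsv_path=tmp_path / "r.tsv",
        )
        assert len(table) == 6
        assert table["correct"].tolist() == [True] * 3 + [False] * 3
        assert (tmp_path / "r.html").exists() and (tmp_path / "r.tsv").exists()

    def test_attribution_score_is_word_sum(self, attribution_records):
        for r in attribution_records:
            assert r.attribution_score == pytest.approx(r.word_attributions.sum())
            assert r.completeness_gap >= 0

    def test_failure_rows_render_both_titles(self, attribution_records):
        page, _ = sal.render_saliency_report(attribution_records)
        failure = [r for r in attribution_records if not r.correct][0]
        assert failure.true_title in page and failure.target_title in page
        assert failure.true_title != failure.target_title


class TestDirectionalAttribution:
    def test_external_cause_words_dominate_when_rule_fires(self):
        """On certificates decided by external-cause precedence, the
        external-cause words should usually carry the top positive word
        attribution in correctly classified cases (pooled over 5 seeds)."""
        from conftest import build_text_dataset

        hits = total = 0
        for seed in range(5):
            data = build_text_dataset(
                seed=100 + seed, n_codes=30, n_certs=1500, mean_conditions=2.5
            )
            model, _ = mdl.train_with_checkpoints(
                data["train"], mdl.ModelConfig(seed=seed, epochs=15, K=2),
                vocab_size=len(data["vocab"]), n_classes=len(data["classes"]),
            )
            cb = data["codebook"]
            certs = {c.cert_id: c for c in data["certs"]}
            probs = mdl.predict_proba_batch(model, data["test"])
            pred = probs.argmax(axis=1)
            for i, record in enumerate(data["test"]):
                cert = certs[record.cert_id]
                if not cb[cert.true_ucod].is_external_cause or cert.n_conditions < 2:
                    continue
                if pred[i] != record.label_index:
                    continue
                rec = sal.attribute_record(model, record, cb, data["classes"])
                ext_words = {
                    w.lower()
                    for w in cb[cert.true_ucod].title.replace(",", " ").split()
                }
                order = np.argsort(-rec.word_attributions)
                top_words = {rec.words[j].lower() for j in order[:3]}
                total += 1
                hits += bool(ext_words & top_words)
        assert total >= 20
        assert hits / total > 0.5
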