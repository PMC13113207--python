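"""Generator: codebook, rule cascade, certificates, splits, synthetic logits."""

import numpy as np
import pytest

from mortexplain import calibration as cal
from mortexplain import synthetic as syn
from mortexplain.reporting import map_code_to_chapter

from conftest import cert


def gini(counts):
    x = np.sort(np.asarray(list(counts), dtype=float))
    n = x.size
    return float((2 * np.arange(1, n + 1) - n - 1) @ x / (n * x.sum()))


class TestCodebook:
    def test_seeded_determinism(self):
        config = syn.GeneratorConfig(seed=7, n_codes=200)
        assert syn.build_codebook(config) == syn.build_codebook(config)

    def test_flag_chapter_consistency(self, generated):
        _, codebook, _ = generated
        for code, e in codebook.entries.items():
            assert e.chapter == map_code_to_chapter(code)
            assert e.is_external_cause == (e.chapter == "XX")
            assert e.is_injury == (e.chapter == "XIX")
            assert e.is_ill_defined == (e.chapter == "XVIII")
            if e.is_injury:
                assert not e.selectable_as_ucod

    def test_titles_unique_by_default(self, generated):
        _, codebook, _ = generated
        titles = [e.title for e in codebook.entries.values()]
        assert len(set(titles)) == len(titles)

    def test_title_collision_mode(self):
        config = syn.GeneratorConfig(seed=7, n_codes=200, title_collision=True)
        codebook = syn.build_codebook(config)
        titles = [e.title for e in codebook.entries.values()]
        assert len(set(titles)) < len(titles)

    def test_too_few_codes_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.build_codebook(syn.GeneratorConfig(seed=0, n_codes=5))

    def test_bad_chapter_weights_rejected(self):
        with pytest.raises(syn.ConfigurationError):
            syn.GeneratorConfig(chapter_weights={"IX": 0.5})

    def test_json_round_trip(self, generated, tmp_path):
        _, codebook, _ = generated
        codebook.to_json(tmp_path / "cb.json")
        assert syn.CodeBook.from_json(tmp_path / "cb.json") == codebook


class TestUcodSelection:
    def test_originating_condition_fallback(self, rule_codebook):
        c = cert([["I21.9"], ["I10"], ["N19"]])
        assert syn.select_true_ucod(c, rule_codebook) == "N19"

    def test_external_cause_precedence_over_injury(self, rule_codebook):
        c = cert([["S02.1"], ["V03.1"]])
        assert syn.select_true_ucod(c, rule_codebook) == "V03.1"

    def test_external_cause_in_part2_still_selected(self, rule_codebook):
        c = cert([["S02.1"]], part2=["V03.1"])
        assert syn.select_true_ucod(c, rule_codebook) == "V03.1"

    def test_ill_defined_originating_skipped(self, rule_codebook):
        c = cert([["I10"], ["R99"]])
        assert syn.select_true_ucod(c, rule_codebook) == "I10"

    def test_all_excluded_returns_originating(self, rule_codebook):
        c = cert([["R99"]])
        assert syn.select_true_ucod(c, rule_codebook) == "R99"

    def test_part2_never_selected_without_external(self, rule_codebook):
        c = cert([["I10"]], part2=["N19"])
        assert syn.select_true_ucod(c, rule_codebook) == "I10"

    def test_empty_certificate_rejected(self, rule_codebook):
        with pytest.raises(ValueError):
            syn.select_true_ucod(cert([]), rule_codebook)

    def test_unknown_code_rejected(self, rule_codebook):
        with pytest.raises(KeyError, match="Z99"):
            syn.select_true_ucod(cert([["Z99"]]), rule_codebook)


class TestGenerateCertificates:
    def test_seeded_determinism(self, generated):
        config, codebook, certs = generated
        assert syn.generate_certificates(codebook, 1000, config) == certs

    def test_condition_count_bounds(self, generated):
        _, _, certs = generated
        assert all(1 <= c.n_conditions <= 15 for c in certs)

    def test_generator_self_consistency(self, generated):
        _, codebook, certs = generated
        assert all(syn.select_true_ucod(c, codebook) == c.true_ucod for c in certs)

    def test_external_cause_dominance(self, generated):
        _, codebook, certs = generated
        seen = 0
        for c in certs:
            if any(codebook[x].is_external_cause for x in c.stated_codes()):
                seen += 1
                assert codebook[c.true_ucod].chapter == "XX"
        assert seen > 0

    def test_injury_never_selected(self, generated):
        _, codebook, certs = generated
        assert not any(codebook[c.true_ucod].is_injury for c in certs)

    def test_target_diversity_below_stated_diversity(self, generated):
        _, _, certs = generated
        assert len(syn.target_frequencies(certs)) < len(syn.code_frequencies(certs))

    def test_imbalance_raises_gini(self):
        counts = {}
        for exponent in (0.0, 2.0):
            config = syn.GeneratorConfig(seed=5, n_codes=150, imbalance_exponent=exponent)
            certs = syn.generate_certificates(syn.build_codebook(config), 3000, config)
            freq = syn.code_frequencies(certs)
            counts[exponent] = list(freq.values()) + [0] * (150 - len(freq))
        assert gini(counts[2.0]) > gini(counts[0.0])

    def test_invalid_n_rejected(self, generated):
        config, codebook, _ = generated
        with pytest.raises(ValueError):
            syn.generate_certificates(codebook, 0, config)

    def test_csv_round_trip(self, generated, tmp_path):
        _, _, certs = generated
        syn.write_certificates_csv(tmp_path / "c.csv", certs)
        assert syn.read_certificates_csv(tmp_path / "c.csv") == certs


class TestSplitDataset:
    def test_exact_split_sizes(self, generated):
        _, _, certs = generated
        splits = syn.split_dataset(certs, {"train": 0.8, "test": 0.1, "validation": 0.1}, seed=3)
        assert [len(splits[s]) for s in ("train", "test", "validation")] == [800, 100, 100]
        ids = [c.cert_id for s in splits.values() for c in s]
        assert len(ids) == len(set(ids)) == 1000

    def test_stratification_within_one_member(self, generated):
        _, _, certs = generated
        splits = syn.split_dataset(certs, {"train": 0.8, "test": 0.1, "validation": 0.1}, seed=3)
        targets = syn.target_frequencies(certs)
        train_targets = syn.target_frequencies(splits["train"])
        for code, total in targets.items():
            if total >= 10:
                assert abs(train_targets.get(code, 0) - 0.8 * total) <= 1.0

    def test_ood_holdout_removed_from_train_only(self, generated):
        _, _, certs = generated
        code = syn.code_frequencies(certs).most_common(30)[-1][0]
        splits = syn.split_dataset(
            certs, {"train": 0.8, "test": 0.2}, seed=3, ood_holdout=frozenset([code])
        )
        assert code not in syn.code_frequencies(splits["train"])
        assert code in syn.code_frequencies(splits["test"])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            syn.split_dataset([], {"train": 0.8}, seed=0)

    def test_bad_fractions_rejected(self, generated):
        _, _, certs = generated
        with pytest.raises(ValueError):
            syn.split_dataset(certs, {"train": 0.9, "test": 0.3}, seed=0)


class TestCalibratedLogits:
    def test_seeded_determinism(self):
        a = syn.generate_calibrated_logits(200, 5, 2.0, seed=4)
        b = syn.generate_calibrated_logits(200, 5, 2.0, seed=4)
        assert a.provenance == b.provenance
        assert all(
            np.array_equal(x.logits, y.logits) and x.label == y.label
            for x, y in zip(a.records, b.records)
        )

    def test_unit_temperature_labels_are_calibrated(self):
        ps = syn.generate_calibrated_logits(100_000, 10, 1.0, seed=0)
        report = cal.calibration_errors(cal.bin_predictions(ps.records, 10))
        assert report.ece < 1.0  # percent scale

    def test_argmax_labels_give_perfect_accuracy(self):
        ps = syn.generate_calibrated_logits(500, 7, 1.0, seed=1, labels_from_argmax=True)
        assert all(r.correct for r in ps.records)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_calibrated_logits(10, 3, 0.0, seed=0)
        with pytest.raises(ValueError):
            syn.generate_calibrated_logits(0, 3, 1.0, seed=0)
        with pytest.raises(ValueError):
            syn.generate_calibrated_logits(10, 1, 1.0, seed=0)
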