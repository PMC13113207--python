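import numpy as np
import pytest

from mortexplain import model as mdl
from mortexplain import reverse_coding as rc
from mortexplain import synthetic as syn


def entry(title, chapter, ext=False, inj=False, ill=False, sel=True):
    return syn.CodeBookEntry(
        title=title,
        chapter=chapter,
        is_external_cause=ext,
        is_injury=inj,
        is_ill_defined=ill,
        selectable_as_ucod=sel,
    )


@pytest.fixture(scope="session")
def rule_codebook():
    """Hand-built codebook with real ICD-10 codes/titles for rule tests."""
    return syn.CodeBook(
        {
            "I21.9": entry("Acute myocardial infarction", "IX"),
            "I10": entry("Hypertension", "IX"),
            "N19": entry("Unspecified kidney failure", "XIV"),
            "C50.9": entry(
                "Malignant neoplasm of breast, unspecified or malignant "
                "neoplasm, without specification of site",
                "II",
            ),
            "A41.9": entry("Sepsis, unspecified", "I"),
            "M72.6": entry("Necrotizing fasciitis", "XIII"),
            "S02.1": entry("Fracture of base of skull", "XIX", inj=True, sel=False),
            "V03.1": entry("Pedestrian injured in collision with car", "XX", ext=True),
            "R99": entry(
                "Other ill-defined and unspecified causes of mortality",
                "XVIII",
                ill=True,
            ),
        }
    )


def cert(part1, part2=(), sex="female", age=55, ucod="", cid="c0"):
    return syn.CodedCertificate(
        cert_id=cid,
        sex=sex,
        age=age,
        part1_lines=tuple(tuple(line) for line in part1),
        part2=tuple(part2),
        true_ucod=ucod,
    )


@pytest.fixture(scope="session")
def generated():
    """A moderately sized generated dataset shared across tests."""
    config = syn.GeneratorConfig(seed=7, n_codes=200)
    codebook = syn.build_codebook(config)
    certs = syn.generate_certificates(codebook, 1000, config)
    return config, codebook, certs


def build_text_dataset(seed, n_codes, n_certs, mean_conditions, part2_probability=0.0):
    """Generate, render and tokenize a train/test text dataset."""
    gcfg = syn.GeneratorConfig(
        seed=seed,
        n_codes=n_codes,
        mean_conditions=mean_conditions,
        part2_probability=part2_probability,
    )
    cb = syn.build_codebook(gcfg)
    certs = syn.generate_certificates(cb, n_certs, gcfg)
    splits = syn.split_dataset(certs, {"train": 0.8, "test": 0.2}, seed=seed)
    texts = {
        name: [(c.cert_id, rc.render_sentence(c, cb), c.true_ucod) for c in cs]
        for name, cs in splits.items()
    }
    vocab = rc.Vocabulary.from_texts(t for _, t, _ in texts["train"])
    classes = sorted({c.true_ucod for c in certs})
    index = {c: i for i, c in enumerate(classes)}
    tok = lambda rows: [rc.tokenize(cid, t, vocab, l, index[l]) for cid, t, l in rows]
    return {
        "codebook": cb,
        "certs": certs,
        "vocab": vocab,
        "classes": classes,
        "train": tok(texts["train"]),
        "test": tok(texts["test"]),
    }


@pytest.fixture(scope="session")
def trained20():
    """Well-separated 20-class benchmark: single-condition certificates.

    21 codes yield 20 underlying-cause classes (the injury code is never a
    target because the external cause accompanying it takes precedence).
    """
    data = build_text_dataset(seed=11, n_codes=21, n_certs=2000, mean_conditions=1.0)
    model, checkpoints = mdl.train_with_checkpoints(
        data["train"],
        mdl.ModelConfig(seed=11),
        vocab_size=len(data["vocab"]),
        n_classes=len(data["classes"]),
    )
    return {**data, "model": model, "checkpoints": checkpoints}


@pytest.fixture(scope="session")
def trained_hard():
    """Imbalanced multi-condition dataset where the classifier makes errors."""
    data = build_text_dataset(
        seed=21, n_codes=60, n_certs=1500, mean_conditions=3.0, part2_probability=0.3
    )
    model, checkpoints = mdl.train_with_checkpoints(
        data["train"],
        mdl.ModelConfig(seed=21, epochs=15, K=3),
        vocab_size=len(data["vocab"]),
        n_classes=len(data["classes"]),
    )
    return {**data, "model": model, "checkpoints": checkpoints}


@pytest.fixture(scope="session")
def trained_linear():
    """Linear-head twin of the benchmark model (closed-form oracles)."""
    data = build_text_dataset(seed=11, n_codes=20, n_certs=600, mean_conditions=1.0)
    model, checkpoints = mdl.train_with_checkpoints(
        data["train"],
        mdl.ModelConfig(seed=11, arch="linear", epochs=10, K=2),
        vocab_size=len(data["vocab"]),
        n_classes=len(data["classes"]),
    )
    return {**data, "model": model, "checkpoints": checkpoints}
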