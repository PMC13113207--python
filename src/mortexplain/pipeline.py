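"""End-to-end orchestration: generate -> reverse-code -> train -> calibrate
-> difficulty -> saliency -> stratified reports.

Every stage reads its inputs from, and writes its outputs to, a run
directory, so stages are individually re-runnable from serialized
intermediates. A run manifest records the configuration (and its hash), the
status of every stage, the flag decisions in force, and a SHA-256 of every
output file; under a fixed seed two runs produce identical manifests.

The default configuration is desk scale: 5,000 certificates over a 60-code
codebook (about 50 distinct underlying-cause classes), split
0.784/0.196/0.02 into train/test/validation (the 40:10:1 proportions of the
national-scale study design), a 5-checkpoint mlp classifier, 10 calibration
bins, and desk-scale difficulty frequency ranges.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import model as mdl
from . import reporting as rep
from . import reverse_coding as rc
from . import synthetic as syn
from . import vog as vg
from . import saliency as sal

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class CalibrationSettings:
    bins: int = 10
    objective: str = "nll"


@dataclass(frozen=True)
class VoGSettings:
    mode: str = "checkpoint"
    token_scale: str = "contribution"
    class_of: str = "true"
    flag_quantile: float = 0.95
    ranges: str = "desk"        # "desk" | "full"


@dataclass(frozen=True)
class SaliencySettings:
    steps: int = 50
    method: str = "gausslegendre"
    baseline: str = "pad"
    target: str = "predicted"
    n_correct: int = 3
    n_incorrect: int = 3


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_certificates: int = 5000
    n_codes: int = 60
    imbalance_exponent: float = 2.0
    mean_conditions: float = 3.0
    part2_probability: float = 0.3
    title_collision: bool = False
    n_ood_holdout: int = 3
    fractions: dict = field(
        default_factory=lambda: {"train": 0.784, "test": 0.196, "validation": 0.02}
    )
    model: mdl.ModelConfig = field(default_factory=mdl.ModelConfig)
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)
    vog: VoGSettings = field(default_factory=VoGSettings)
    saliency: SaliencySettings = field(default_factory=SaliencySettings)
    top_k: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "model" in kwargs:
            kwargs["model"] = mdl.ModelConfig(**kwargs["model"])
        if "calibration" in kwargs:
            kwargs["calibration"] = CalibrationSettings(**kwargs["calibration"])
        if "vog" in kwargs:
            kwargs["vog"] = VoGSettings(**kwargs["vog"])
        if "saliency" in kwargs:
            kwargs["saliency"] = SaliencySettings(**kwargs["saliency"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def generator_config(self, ood_holdout=frozenset()) -> syn.GeneratorConfig:
        return syn.GeneratorConfig(
            n_codes=self.n_codes,
            imbalance_exponent=self.imbalance_exponent,
            mean_conditions=self.mean_conditions,
            part2_probability=self.part2_probability,
            title_collision=self.title_collision,
            ood_holdout=frozenset(ood_holdout),
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_json(path: Path):
    with open(path) as fh:
        return json.load(fh)


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=float)


def _label_indexer(classes: Sequence[str]):
    index = {c: i for i, c in enumerate(classes)}
    return lambda code: index[code]


def _load_sentences(out: Path, split: str) -> list[rc.SentenceRecord]:
    vocab = rc.Vocabulary.from_json(out / "vocab.json")
    classes = _read_json(out / "classes.json")
    return rc.read_sentences_tsv(
        out / "sentences" / f"{split}.tsv", vocab, _label_indexer(classes)
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_generate(cfg: RunConfig, out: Path) -> None:
    """Codebook, certificates, held-out code choice and stratified splits."""
    base = cfg.generator_config()
    codebook = syn.build_codebook(base)
    certs = syn.generate_certificates(codebook, cfg.n_certificates, base)

    # Held-out codes: rare stated codes (at most ~0.5% of certificates each,
    # so the train->test reassignment stays marginal), preferring codes that
    # are never targets so the label space keeps its training support.
    holdout: list[str] = []
    if cfg.n_ood_holdout > 0:
        stated = syn.code_frequencies(certs)
        targets = set(syn.target_frequencies(certs))
        cap = max(10, round(0.005 * len(certs)))
        ranked = [c for c, n in sorted(stated.items(), key=lambda kv: (kv[1], kv[0]))]
        rare = [c for c in ranked if stated[c] <= cap]
        pool = [c for c in rare if c not in targets] + [c for c in rare if c in targets]
        holdout = (pool or ranked)[: cfg.n_ood_holdout]

    codebook.to_json(out / "codebook.json")
    syn.write_certificates_csv(out / "certificates.csv", certs)
    _write_json(out / "ood_holdout.json", sorted(holdout))

    splits = syn.split_dataset(certs, cfg.fractions, cfg.seed,
                               ood_holdout=frozenset(holdout))
    (out / "splits").mkdir(exist_ok=True)
    for name, subset in splits.items():
        syn.write_certificates_csv(out / "splits" / f"{name}.csv", subset)

    classes = sorted({c.true_ucod for c in certs})
    _write_json(out / "classes.json", classes)


def stage_reverse_code(cfg: RunConfig, out: Path) -> None:
    """Render sentences per split; build the vocabulary on the training split."""
    codebook = syn.CodeBook.from_json(out / "codebook.json")
    splits = {
        name: syn.read_certificates_csv(out / "splits" / f"{name}.csv")
        for name in cfg.fractions
    }
    texts = {
        name: [(c.cert_id, rc.render_sentence(c, codebook), c.true_ucod) for c in cs]
        for name, cs in splits.items()
    }
    vocab = rc.Vocabulary.from_texts(t for _, t, _ in texts["train"])
    vocab.to_json(out / "vocab.json")
    classes = _read_json(out / "classes.json")
    indexer = _label_indexer(classes)
    (out / "sentences").mkdir(exist_ok=True)
    for name, rows in texts.items():
        records = [rc.tokenize(cid, t, vocab, label, indexer(label)) for cid, t, label in rows]
        rc.write_sentences_tsv(out / "sentences" / f"{name}.tsv", records)


def stage_train(cfg: RunConfig, out: Path) -> None:
    """Train with checkpoint capture; score test and validation splits."""
    vocab = rc.Vocabulary.from_json(out / "vocab.json")
    classes = _read_json(out / "classes.json")
    train = _load_sentences(out, "train")
    model_cfg = dataclasses.replace(cfg.model, seed=cfg.seed)
    model, checkpoints = mdl.train_with_checkpoints(
        train, model_cfg, vocab_size=len(vocab), n_classes=len(classes)
    )
    mdl.save_checkpoints(out / "model", checkpoints)

    (out / "predictions").mkdir(exist_ok=True)
    for split in ("test", "validation"):
        records = _load_sentences(out, split)
        ids, mask, labels = mdl._batchify(records)
        logits = model.forward(ids, mask)
        preds = [
            cal.PredictionRecord.from_logits(r.cert_id, logits[i], r.label_index)
            for i, r in enumerate(records)
        ]
        cal.write_predictions_jsonl(
            out / "predictions" / f"{split}.jsonl",
            preds,
            provenance={"source": "model", "seed": cfg.seed, "split": split},
        )


def stage_calibrate(cfg: RunConfig, out: Path) -> None:
    """ECE/MCE before/after temperature scaling; reliability plot table."""
    test, _ = cal.read_predictions_jsonl(out / "predictions" / "test.jsonl")
    val, _ = cal.read_predictions_jsonl(out / "predictions" / "validation.jsonl")
    M = cfg.calibration.bins
    before = cal.bin_predictions(test, M)
    report_before = cal.calibration_errors(before)
    temp = cal.fit_temperature(val, objective=cfg.calibration.objective, bins=M)
    rescaled = cal.rescale_predictions(test, temp.T)
    after = cal.bin_predictions(rescaled, M)
    report_after = cal.calibration_errors(after)

    (out / "calibration").mkdir(exist_ok=True)
    cal.reliability_data(before, after).to_csv(
        out / "calibration" / "reliability.csv", index=False
    )
    _write_json(
        out / "calibration" / "report.json",
        {
            "bins": M,
            "objective": cfg.calibration.objective,
            "temperature": temp.T,
            "bound_hit": temp.bound_hit,
            "accuracy": float(np.mean([p.correct for p in test])),
            "ece_before": report_before.ece,
            "mce_before": report_before.mce,
            "ece_after": report_after.ece,
            "mce_after": report_after.mce,
            "scale": "percent",
        },
    )


def stage_vog(cfg: RunConfig, out: Path) -> None:
    """Difficulty scores, OOD flags, frequency stratification, correlations."""
    checkpoints = mdl.load_checkpoints(out / "model")
    test = _load_sentences(out, "test")
    certs = {c.cert_id: c for c in syn.read_certificates_csv(out / "certificates.csv")}
    train_counts = syn.code_frequencies(
        syn.read_certificates_csv(out / "splits" / "train.csv")
    )
    records = vg.score_records(
        checkpoints, test, certs, class_of=cfg.vog.class_of,
        mode=cfg.vog.mode, token_scale=cfg.vog.token_scale,
    )
    records = vg.normalize_vog(records)
    records = vg.rank_and_flag(records, train_counts, cfg.vog.flag_quantile)
    ranges = (
        vg.DESK_SCALE_FREQUENCY_RANGES if cfg.vog.ranges == "desk"
        else vg.DEFAULT_FREQUENCY_RANGES
    )
    freq_table, trend = vg.vog_frequency_analysis(records, train_counts, ranges)
    per_class = vg.class_level_table(records)
    usable = per_class[per_class["n"] > 0]
    correlations = vg.difficulty_correlations(
        usable["mean_vog"], usable["mean_conditions"], usable["mean_lines"]
    )

    (out / "vog").mkdir(exist_ok=True)
    vg.records_to_frame(records).to_csv(out / "vog" / "records.csv", index=False)
    freq_table.to_csv(out / "vog" / "frequency_table.csv", index=False)
    trend.to_csv(out / "vog" / "log2_trend.csv", index=False)
    per_class.to_csv(out / "vog" / "per_class.csv", index=False)
    _write_json(
        out / "vog" / "analysis.json",
        {
            "mode": cfg.vog.mode,
            "class_of": cfg.vog.class_of,
            "flag_quantile": cfg.vog.flag_quantile,
            "n_flagged": int(sum(r.ood_flag for r in records)),
            "correlations": correlations,
            "frequency_means": {
                row["range"]: row["mean_global_norm_vog"]
                for _, row in freq_table.iterrows()
            },
        },
    )


def stage_saliency(cfg: RunConfig, out: Path) -> None:
    """Integrated-gradients report for correct and failure cases."""
    checkpoints = mdl.load_checkpoints(out / "model")
    model = checkpoints.final
    test = _load_sentences(out, "test")
    codebook = syn.CodeBook.from_json(out / "codebook.json")
    classes = _read_json(out / "classes.json")

    probs = mdl.predict_proba_batch(model, test)
    pred = probs.argmax(axis=1)
    correct_idx = [i for i, r in enumerate(test) if pred[i] == r.label_index]
    wrong_idx = [i for i, r in enumerate(test) if pred[i] != r.label_index]
    chosen = correct_idx[: cfg.saliency.n_correct] + wrong_idx[: cfg.saliency.n_incorrect]
    records = [
        sal.attribute_record(
            model, test[i], codebook, classes,
            target=cfg.saliency.target, baseline=cfg.saliency.baseline,
            steps=cfg.saliency.steps, method=cfg.saliency.method,
        )
        for i in chosen
    ]
    (out / "saliency").mkdir(exist_ok=True)
    sal.render_saliency_report(
        records,
        html_path=out / "saliency" / "report.html",
        tsv_path=out / "saliency" / "report.tsv",
    )


def stage_report(cfg: RunConfig, out: Path) -> None:
    """Chapter table, top-k frequency tables, per-group confidence stats."""
    codebook = syn.CodeBook.from_json(out / "codebook.json")
    classes = _read_json(out / "classes.json")
    test_certs = syn.read_certificates_csv(out / "splits" / "test.csv")
    train_certs = syn.read_certificates_csv(out / "splits" / "train.csv")
    preds, _ = cal.read_predictions_jsonl(out / "predictions" / "test.jsonl")
    calrep = _read_json(out / "calibration" / "report.json")
    scaled = cal.rescale_predictions(preds, calrep["temperature"])

    pred_codes = {p.id: classes[p.predicted] for p in scaled}
    chapter_table = rep.chapter_accuracy_table(pred_codes, test_certs, codebook)

    all_certs = syn.read_certificates_csv(out / "certificates.csv")
    top_ucod = rep.top_k_frequency_table(
        syn.target_frequencies(all_certs), cfg.top_k, codebook
    )
    top_stated = rep.top_k_frequency_table(
        syn.code_frequencies(all_certs), cfg.top_k, codebook
    )

    cert_index = {c.cert_id: c for c in test_certs}
    frame = pd.DataFrame(
        {
            "cert_id": [p.id for p in scaled],
            "confidence": [p.confidence for p in scaled],
            "correct": [p.correct for p in scaled],
            "class": [cert_index[p.id].true_ucod for p in scaled],
            "chapter": [
                rep.map_code_to_chapter(cert_index[p.id].true_ucod) for p in scaled
            ],
        }
    )
    train_class_counts = syn.target_frequencies(train_certs)
    train_chapter_counts: dict[str, int] = {}
    for code, n in train_class_counts.items():
        ch = rep.map_code_to_chapter(code)
        train_chapter_counts[ch] = train_chapter_counts.get(ch, 0) + n
    by_chapter = rep.confidence_group_stats(frame, "chapter", train_chapter_counts)
    by_class = rep.confidence_group_stats(frame, "class", train_class_counts)

    rdir = out / "report"
    rdir.mkdir(exist_ok=True)
    chapter_table.to_csv(rdir / "chapter_table.csv", index=False)
    top_ucod.to_csv(rdir / "top_ucod.csv", index=False)
    top_stated.to_csv(rdir / "top_conditions.csv", index=False)
    by_chapter.to_csv(rdir / "confidence_by_chapter.csv", index=False)
    by_class.to_csv(rdir / "confidence_by_class.csv", index=False)


STAGES = (
    ("generate", stage_generate),
    ("reverse_code", stage_reverse_code),
    ("train", stage_train),
    ("calibrate", stage_calibrate),
    ("vog", stage_vog),
    ("saliency", stage_saliency),
    ("report", stage_report),
)


def run_pipeline(config: RunConfig, out_dir, stages: Sequence[str] | None = None) -> Path:
    """Run the full pipeline (or selected stages) into ``out_dir``.

    Writes ``manifest.json`` on success; on a stage failure, partial outputs
    are retained next to a ``FAILED`` marker naming the stage, and a
    :class:`PipelineStageError` is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True, default=float).encode()
    ).hexdigest()

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setLevel(logging.DEBUG)
    root = logging.getLogger("mortexplain")
    root.addHandler(handler)

    selected = [(n, f) for n, f in STAGES if stages is None or n in stages]
    statuses: list[dict] = []
    try:
        for name, fn in selected:
            t0 = time.perf_counter()
            try:
                fn(config, out)
            except Exception as exc:
                statuses.append({"stage": name, "status": "failed"})
                (out / "FAILED").write_text(f"{name}: {exc}\n")
                raise PipelineStageError(name, exc) from exc
            logger.debug("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            statuses.append({"stage": name, "status": "ok"})
    finally:
        root.removeHandler(handler)
        handler.close()

    outputs = {
        str(p.relative_to(out)): _sha256(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name not in ("manifest.json", "run.log", "FAILED")
    }
    manifest = {
        "config": config_dict,
        "config_sha256": config_hash,
        "seed": config.seed,
        "stages": statuses,
        "flags": {
            "calibration_objective": config.calibration.objective,
            "calibration_bins": config.calibration.bins,
            "vog_mode": config.vog.mode,
            "vog_class_of": config.vog.class_of,
            "vog_ranges": config.vog.ranges,
            "saliency_baseline": config.saliency.baseline,
            "saliency_method": config.saliency.method,
            "saliency_target": config.saliency.target,
        },
        "outputs": outputs,
    }
    _write_json(out / "manifest.json", manifest)
    if (out / "FAILED").exists():
        (out / "FAILED").unlink()
    return out
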