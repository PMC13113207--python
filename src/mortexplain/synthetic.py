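"""Synthetic coded death certificates with rule-derived ground truth.

The generator plays the role of the ground-truth joint distribution pi(x, y)
over certificates and underlying causes of death (UCOD). It produces:

* a codebook of ICD-10-style codes (letter + two digits + optional decimal)
  with pseudo-medical titles and chapter-derived flags,
* certificates with 1-15 stated conditions spread over up to four Part 1
  lines and an optional Part 2, with long-tailed (power-law) code
  frequencies and chapter imbalance mirroring US multiple-cause mortality
  data,
* the true UCOD via a simplified WHO-style rule cascade (external-cause
  precedence, injury exclusion, ill-defined exclusion, originating-condition
  fallback),
* stratified train/test/validation splits with optional held-out
  ("never seen in training") codes, and
* synthetic logit/label sets with a known miscalibration temperature for
  exercising the calibration stack.

The full WHO selection and modification rule tables are intentionally out
of scope; the simplified cascade keeps the ground truth unambiguous and
machine-checkable.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import softmax

from .calibration import PredictionRecord
from .reporting import ROMAN_CHAPTERS, map_code_to_chapter, CHAPTER_RANGES

__all__ = [
    "CodeBookEntry",
    "CodeBook",
    "GeneratorConfig",
    "CodedCertificate",
    "PredictionSet",
    "build_codebook",
    "select_true_ucod",
    "generate_certificates",
    "split_dataset",
    "generate_calibrated_logits",
    "code_frequencies",
    "target_frequencies",
    "write_certificates_csv",
    "read_certificates_csv",
]

logger = logging.getLogger(__name__)

CODE_RE = re.compile(r"^[A-Z]\d{2}(\.\d)?$")

#: Relative chapter weights for stated conditions, following the chapter
#: imbalance observed in US multiple-cause-of-death files (circulatory and
#: neoplasm chapters dominate; eye/ear chapters are near-absent; the
#: administrative chapter XXI and provisional chapter XXII never occur).
DEFAULT_CHAPTER_WEIGHTS: dict[str, float] = {
    "I": 2.521, "II": 22.118, "III": 0.857, "IV": 5.857, "V": 7.892,
    "VI": 3.908, "VII": 0.030, "VIII": 0.009, "IX": 31.116, "X": 11.735,
    "XI": 3.271, "XII": 0.289, "XIII": 0.835, "XIV": 4.472, "XV": 0.044,
    "XVI": 0.378, "XVII": 0.212, "XVIII": 6.238, "XIX": 5.935, "XX": 3.579,
    "XXI": 0.0, "XXII": 0.0,
}
_total = sum(DEFAULT_CHAPTER_WEIGHTS.values())
DEFAULT_CHAPTER_WEIGHTS = {k: v / _total for k, v in DEFAULT_CHAPTER_WEIGHTS.items()}


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class CodeBookEntry:
    title: str
    chapter: str
    is_external_cause: bool
    is_injury: bool
    is_ill_defined: bool
    selectable_as_ucod: bool


class CodeBook:
    """Ordered map code -> :class:`CodeBookEntry`."""

    def __init__(self, entries: Mapping[str, CodeBookEntry]):
        self.entries: dict[str, CodeBookEntry] = dict(entries)
        for code, entry in self.entries.items():
            if not CODE_RE.match(code):
                raise ConfigurationError(f"malformed code: {code!r}")
            if entry.is_external_cause and entry.chapter != "XX":
                raise ConfigurationError(f"{code}: external cause outside chapter XX")
            if entry.is_injury and entry.chapter != "XIX":
                raise ConfigurationError(f"{code}: injury flag outside chapter XIX")
            if entry.is_ill_defined and entry.chapter != "XVIII":
                raise ConfigurationError(f"{code}: ill-defined flag outside chapter XVIII")
            if entry.is_injury and entry.selectable_as_ucod:
                raise ConfigurationError(f"{code}: injuries are never selectable as UCOD")

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __getitem__(self, code: str) -> CodeBookEntry:
        return self.entries[code]

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, CodeBook) and self.entries == other.entries

    @property
    def codes(self) -> list[str]:
        return list(self.entries)

    def title(self, code: str) -> str:
        try:
            return self.entries[code].title
        except KeyError:
            raise KeyError(f"code not in codebook: {code!r}") from None

    def to_json(self, path) -> None:
        obj = {
            code: {
                "title": e.title,
                "chapter": e.chapter,
                "is_external_cause": e.is_external_cause,
                "is_injury": e.is_injury,
                "is_ill_defined": e.is_ill_defined,
                "selectable_as_ucod": e.selectable_as_ucod,
            }
            for code, e in self.entries.items()
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CodeBook":
        with open(path) as fh:
            obj = json.load(fh)
        return cls({code: CodeBookEntry(**spec) for code, spec in obj.items()})


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic ground-truth distribution.

    ``chapter_weights`` set the marginal chapter mix of stated conditions;
    ``imbalance_exponent`` is the within-chapter power-law (Zipf) exponent of
    code frequencies (0 = uniform); ``mean_conditions`` is the expected
    number of stated conditions per certificate (bounded to [1, 15]);
    ``part2_probability`` is the chance that a certificate carries
    contributing conditions in Part 2; ``ood_holdout`` codes are kept out of
    the training split so they are never seen in training.
    """

    n_codes: int = 200
    chapter_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHAPTER_WEIGHTS)
    )
    imbalance_exponent: float = 2.0
    ood_holdout: frozenset[str] = frozenset()
    title_collision: bool = False
    mean_conditions: float = 3.0
    part2_probability: float = 0.3
    seed: int = 0

    def __post_init__(self):
        w = np.array([self.chapter_weights.get(ch, 0.0) for ch in ROMAN_CHAPTERS])
        if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-6):
            raise ConfigurationError("chapter weights must be non-negative and sum to 1")
        if self.imbalance_exponent < 0:
            raise ConfigurationError("imbalance_exponent must be >= 0")
        if not 1.0 <= self.mean_conditions <= 15.0:
            raise ConfigurationError("mean_conditions must lie in [1, 15]")


@dataclass(frozen=True)
class CodedCertificate:
    """A structured multi-line cause-of-death record.

    ``part1_lines`` is the causal chain: up to four ordered lines, read
    top-to-bottom, the last code of the last used line being the
    originating condition. ``part2`` holds contributing conditions that are
    never selected as the underlying cause.
    """

    cert_id: str
    sex: str
    age: int
    part1_lines: tuple[tuple[str, ...], ...]
    part2: tuple[str, ...]
    true_ucod: str

    def stated_codes(self) -> list[str]:
        """All stated codes in reading order (Part 1 lines, then Part 2)."""
        out = [c for line in self.part1_lines for c in line]
        out.extend(self.part2)
        return out

    @property
    def n_conditions(self) -> int:
        return len(self.stated_codes())

    @property
    def n_lines(self) -> int:
        return len(self.part1_lines)


@dataclass(frozen=True)
class PredictionSet:
    records: list[PredictionRecord]
    provenance: dict

    def __post_init__(self):
        ks = {r.k for r in self.records}
        if len(ks) > 1:
            raise ValueError(f"records disagree on class count: {sorted(ks)}")


# ---------------------------------------------------------------------------
# Codebook generation
# ---------------------------------------------------------------------------

_TITLE_ADJ = (
    "Acute", "Chronic", "Unspecified", "Malignant", "Benign", "Congenital",
    "Secondary", "Recurrent", "Degenerative", "Obstructive", "Ischemic",
    "Hemorrhagic", "Infectious", "Toxic", "Necrotizing", "Atypical",
)
_TITLE_SITE = (
    "heart", "lung", "kidney", "liver", "brain", "stomach", "pancreas",
    "bladder", "spleen", "colon", "esophagus", "larynx", "skin", "bone",
    "artery", "vein", "thyroid", "prostate", "breast", "bronchus",
)
# Disease-noun morphemes: real ICD concept titles carry distinctive medical
# terms that rarely recur across categories, which is what makes the
# reverse-coded text of a never-seen code genuinely novel to a model. Titles
# therefore build their disease noun from medical morphemes (~2,600
# combinations), so most codes carry a near-unique content word.
_MORPH_ROOT = (
    "cardi", "nephr", "hepat", "neur", "gastr", "oste", "derm", "angi",
    "pneum", "enter", "myel", "arthr", "cephal", "cyst", "hem", "bronch",
    "col", "phleb", "splen", "thyr",
)
_MORPH_MID = ("o", "io", "ato", "ulo", "ero", "ano", "oto", "ido", "omo", "avo", "ovo", "eno", "imo")
_MORPH_SUFFIX = (
    "itis", "osis", "oma", "opathy", "algia", "ectasia", "emia", "plasia",
    "sclerosis", "megaly",
)
_EXTERNAL_TEMPLATES = (
    "Accidental exposure to {noun} hazard",
    "Transport accident involving {noun} vehicle occupant",
    "Accidental fall from {noun} level",
    "Intentional self-harm by {noun} means",
    "Assault by {noun} object",
    "Accidental poisoning by {noun} agent",
)


def _morpheme_noun(rng: np.random.Generator) -> str:
    return (
        str(rng.choice(_MORPH_ROOT))
        + str(rng.choice(_MORPH_MID))
        + str(rng.choice(_MORPH_SUFFIX))
    )


def _chapter_letter_slots(chapter: str) -> list[str]:
    """All three-character stems (letter + two digits) of a chapter range."""
    for first, last, ch in CHAPTER_RANGES:
        if ch != chapter:
            continue
        slots = []
        for letter in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[
            ord(first[0]) - 65 : ord(last[0]) - 65 + 1
        ]:
            lo = int(first[1:]) if letter == first[0] else 0
            hi = int(last[1:]) if letter == last[0] else 99
            slots.extend(f"{letter}{i:02d}" for i in range(lo, hi + 1))
        return slots
    raise ConfigurationError(f"unknown chapter: {chapter!r}")


def _apportion(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` items over weights."""
    target = weights / weights.sum() * total
    base = np.floor(target).astype(int)
    # Every positively weighted bucket gets at least one item.
    base = np.maximum(base, (weights > 0).astype(int))
    while base.sum() > total:  # the >=1 floor may overshoot
        i = int(np.argmax(base - target))
        base[i] -= 1
    rem = target - base
    order = np.argsort(-rem)
    for i in order[: total - base.sum()]:
        base[i] += 1
    return base


def _make_title(rng: np.random.Generator, chapter: str, used: set[str]) -> str:
    # Two morpheme terms per title (plus an optional subtype qualifier):
    # ICD concept titles are term-dense, so the reverse-coded sentence of a
    # never-seen code contributes several genuinely novel words.
    for _ in range(1000):
        noun = f"{_morpheme_noun(rng)} {_morpheme_noun(rng)}"
        if chapter == "XX":
            t = str(rng.choice(_EXTERNAL_TEMPLATES)).format(noun=noun)
        elif chapter == "XIX":
            t = f"Injury of {rng.choice(_TITLE_SITE)} with {noun}"
        elif chapter == "XVIII":
            t = f"Abnormal {noun} findings, not elsewhere classified"
        else:
            t = f"{rng.choice(_TITLE_ADJ)} {noun} of {rng.choice(_TITLE_SITE)}"
        if rng.random() < 0.5:
            t += f", {_morpheme_noun(rng)} type"
        if t not in used:
            return t
    raise ConfigurationError("could not generate a unique title; reduce n_codes")


def build_codebook(config: GeneratorConfig) -> CodeBook:
    """Deterministically generate a codebook from the generator config."""
    rng = np.random.default_rng([config.seed, 0])
    weights = np.array([config.chapter_weights.get(ch, 0.0) for ch in ROMAN_CHAPTERS])
    positive = int((weights > 0).sum())
    if config.n_codes < positive:
        raise ConfigurationError(
            f"n_codes={config.n_codes} below the {positive} positively weighted chapters"
        )
    per_chapter = _apportion(weights, config.n_codes)

    entries: dict[str, CodeBookEntry] = {}
    used_titles: set[str] = set()
    for chapter, n_ch in zip(ROMAN_CHAPTERS, per_chapter):
        if n_ch == 0:
            continue
        slots = _chapter_letter_slots(chapter)
        stems = rng.choice(len(slots), size=min(n_ch, len(slots)), replace=False)
        for si in np.sort(stems):
            stem = slots[int(si)]
            code = stem if rng.random() < 0.5 else f"{stem}.{rng.integers(0, 10)}"
            title = _make_title(rng, chapter, used_titles)
            used_titles.add(title)
            entries[code] = CodeBookEntry(
                title=title,
                chapter=chapter,
                is_external_cause=chapter == "XX",
                is_injury=chapter == "XIX",
                is_ill_defined=chapter == "XVIII",
                selectable_as_ucod=chapter != "XIX",
            )
    if config.title_collision and len(entries) >= 2:
        # Emulate the duplicate-title failure mode: two distinct codes with
        # one textual representation.
        codes = sorted(entries)
        a, b = rng.choice(len(codes), size=2, replace=False)
        donor, receiver = codes[int(a)], codes[int(b)]
        entries[receiver] = replace(entries[receiver], title=entries[donor].title)
    return CodeBook(entries)


# ---------------------------------------------------------------------------
# UCOD selection (simplified WHO-style cascade)
# ---------------------------------------------------------------------------

def select_true_ucod(cert: CodedCertificate, codebook: CodeBook) -> str:
    """Rule cascade selecting the underlying cause of death.

    R1: an external cause (chapter XX), if stated anywhere, takes
    precedence — the first one in reading order is selected.
    R2: otherwise, starting from the originating condition (the last code
    of the last used Part 1 line) and walking backwards through the Part 1
    chain, the first code that is selectable and neither ill-defined nor an
    injury is selected.
    R3: if every candidate is excluded, the originating condition is
    returned regardless of flags. Part 2 codes are never selected.
    """
    stated = cert.stated_codes()
    if not stated:
        raise ValueError(f"certificate {cert.cert_id} states no conditions")
    for code in stated:
        if code not in codebook:
            raise KeyError(f"code not in codebook: {code!r}")
    for code in stated:  # R1
        if codebook[code].is_external_cause:
            return code
    chain = [c for line in cert.part1_lines for c in line]
    if not chain:
        raise ValueError(f"certificate {cert.cert_id} has an empty Part 1")
    for code in reversed(chain):  # R2
        e = codebook[code]
        if e.selectable_as_ucod and not e.is_ill_defined and not e.is_injury:
            return code
    return chain[-1]  # R3


# ---------------------------------------------------------------------------
# Certificate generation
# ---------------------------------------------------------------------------

def _code_weights(codebook: CodeBook, config: GeneratorConfig, rng) -> np.ndarray:
    """Per-code sampling weights: chapter marginals x within-chapter Zipf."""
    codes = codebook.codes
    weights = np.zeros(len(codes))
    by_chapter: dict[str, list[int]] = {}
    for i, c in enumerate(codes):
        by_chapter.setdefault(codebook[c].chapter, []).append(i)
    for chapter, idx in by_chapter.items():
        w_ch = config.chapter_weights.get(chapter, 0.0)
        ranks = rng.permutation(len(idx)) + 1.0
        zipf = ranks ** (-config.imbalance_exponent)
        weights[idx] = w_ch * zipf / zipf.sum()
    return weights / weights.sum()


def generate_certificates(
    codebook: CodeBook, n: int, config: GeneratorConfig
) -> list[CodedCertificate]:
    """Generate ``n`` certificates; deterministic given ``config.seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([config.seed, 1])
    codes = np.array(codebook.codes)
    weights = _code_weights(codebook, config, rng)

    certs: list[CodedCertificate] = []
    for i in range(n):
        n_cond = int(np.clip(1 + rng.poisson(max(config.mean_conditions - 1.0, 0.0)), 1, 15))
        k = min(n_cond, len(codes))
        picked = list(rng.choice(codes, size=k, replace=False, p=weights))
        # A certificate stating an injury virtually always states the external
        # cause that produced it; guarantee one so injuries are never forced
        # into the underlying-cause slot by the fallback rule.
        if any(codebook[c].is_injury for c in picked) and not any(
            codebook[c].is_external_cause for c in picked
        ):
            external = [c for c in codes if codebook[c].is_external_cause]
            if external:
                chosen = str(rng.choice(external))
                if len(picked) < 15:
                    picked.insert(int(rng.integers(0, len(picked) + 1)), chosen)
                else:  # respect the 15-condition cap
                    non_injury = [i for i, c in enumerate(picked)
                                  if not codebook[c].is_injury]
                    picked[non_injury[0] if non_injury else 0] = chosen
        part2: tuple[str, ...] = ()
        if len(picked) >= 2 and rng.random() < config.part2_probability:
            n2 = int(rng.integers(1, min(3, len(picked))))
            part2 = tuple(picked[-n2:])
            picked = picked[:-n2]
        n_lines = int(rng.integers(1, min(4, len(picked)) + 1))
        cuts = np.sort(rng.choice(np.arange(1, len(picked)), size=n_lines - 1, replace=False)) if n_lines > 1 else np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), len(picked)]
        lines = tuple(
            tuple(picked[bounds[j] : bounds[j + 1]]) for j in range(n_lines)
        )
        sex = "female" if rng.random() < 0.5 else "male"
        age = int(np.clip(round(rng.normal(70.0, 15.0)), 0, 105))
        cert = CodedCertificate(
            cert_id=f"cert{i:06d}",
            sex=sex,
            age=age,
            part1_lines=lines,
            part2=part2,
            true_ucod="",
        )
        cert = replace(cert, true_ucod=select_true_ucod(cert, codebook))
        certs.append(cert)
    return certs


def code_frequencies(certs: Iterable[CodedCertificate]) -> Counter:
    """Counts of stated conditions over a certificate collection."""
    counts: Counter = Counter()
    for cert in certs:
        counts.update(cert.stated_codes())
    return counts


def target_frequencies(certs: Iterable[CodedCertificate]) -> Counter:
    """Counts of true underlying causes over a certificate collection."""
    return Counter(c.true_ucod for c in certs)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_dataset(
    certs: Sequence[CodedCertificate],
    fractions: Mapping[str, float],
    seed: int,
    ood_holdout: frozenset[str] | None = None,
) -> dict[str, list[CodedCertificate]]:
    """Stratified train/test/validation split.

    Splits are stratified by true UCOD using a largest-remainder
    transportation rounding: each class contributes within one member of
    its proportional share to every split while global split sizes are hit
    exactly. Classes too small to stratify are covered by the same
    remainder mechanism (effectively random assignment; a warning reports
    how many). Certificates stating a held-out code are moved out of the
    training split into the test split afterwards, so held-out codes are
    never seen in training.
    """
    if not certs:
        raise ValueError("no certificates to split")
    names = list(fractions)
    fr = np.array([fractions[s] for s in names], dtype=float)
    if (fr <= 0).any() or fr.sum() > 1 + 1e-9:
        raise ValueError("fractions must be positive and sum to at most 1")
    rng = np.random.default_rng([seed, 2])

    n = len(certs)
    split_sizes = np.floor(fr * n).astype(int)
    rem = fr * n - split_sizes
    for i in np.argsort(-rem)[: int(round(fr.sum() * n)) - split_sizes.sum()]:
        split_sizes[i] += 1

    by_class: dict[str, list[int]] = {}
    for i, c in enumerate(certs):
        by_class.setdefault(c.true_ucod, []).append(i)
    classes = sorted(by_class)
    for c in classes:
        rng.shuffle(by_class[c])

    # Fractional allocation matrix (class x split), rounded so that both the
    # per-class totals (<= class size) and the global split sizes hold.
    norm = fr / fr.sum()
    alloc = np.zeros((len(classes), len(names)), dtype=int)
    frac = np.zeros_like(alloc, dtype=float)
    assigned_frac = fr.sum()
    for ci, c in enumerate(classes):
        m = len(by_class[c]) * assigned_frac  # items this class contributes
        target = norm * m
        alloc[ci] = np.floor(target).astype(int)
        frac[ci] = target - alloc[ci]
    n_small = sum(1 for c in classes if len(by_class[c]) < len(names))
    if n_small:
        logger.warning(
            "%d classes have fewer members than splits; assigned by remainder", n_small
        )
    remaining = split_sizes - alloc.sum(axis=0)
    order = np.dstack(np.unravel_index(np.argsort(-(frac + rng.random(frac.shape) * 1e-9), axis=None), frac.shape))[0]
    class_room = np.array([len(by_class[c]) for c in classes]) - alloc.sum(axis=1)
    for ci, si in order:
        if remaining[si] > 0 and class_room[ci] > 0:
            alloc[ci, si] += 1
            remaining[si] -= 1
            class_room[ci] -= 1
    # Safety net: grant leftovers wherever a class still has unassigned items.
    for si in range(len(names)):
        while remaining[si] > 0:
            ci = int(np.argmax(class_room))
            if class_room[ci] <= 0:
                break
            alloc[ci, si] += 1
            remaining[si] -= 1
            class_room[ci] -= 1

    splits: dict[str, list[CodedCertificate]] = {s: [] for s in names}
    for ci, c in enumerate(classes):
        pos = 0
        for si, s in enumerate(names):
            for idx in by_class[c][pos : pos + alloc[ci, si]]:
                splits[s].append(certs[idx])
            pos += alloc[ci, si]

    if ood_holdout:
        holdout = set(ood_holdout)
        kept, moved = [], []
        for cert in splits.get("train", []):
            (moved if holdout & set(cert.stated_codes()) else kept).append(cert)
        if moved:
            logger.info("moved %d certificates stating held-out codes to test", len(moved))
            splits["train"] = kept
            splits.setdefault("test", []).extend(moved)
    for s in splits:
        splits[s].sort(key=lambda c: c.cert_id)
    return splits


# ---------------------------------------------------------------------------
# Synthetic miscalibrated predictions
# ---------------------------------------------------------------------------

def generate_calibrated_logits(
    n: int,
    k: int,
    true_temperature: float,
    seed: int,
    scale: float = 2.0,
    labels_from_argmax: bool = False,
) -> PredictionSet:
    """Logit/label pairs whose labels are sampled at a known temperature.

    Logits have i.i.d. normal components (sd ``scale``, chosen so that raw
    confidences spread across all bins). Labels are drawn from the
    categorical distribution softmax(z / true_temperature), so dividing the
    logits by the true temperature yields perfectly calibrated
    probabilities in expectation. With ``labels_from_argmax`` the labels
    equal argmax(z) instead (accuracy 1 by construction).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 2:
        raise ValueError("k must be >= 2")
    if true_temperature <= 0:
        raise ValueError("true_temperature must be positive")
    rng = np.random.default_rng([seed, 3])
    z = rng.normal(0.0, scale, size=(n, k))
    if labels_from_argmax:
        labels = z.argmax(axis=1)
    else:
        p = softmax(z / true_temperature, axis=1)
        u = rng.random(n)
        labels = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
        labels = np.minimum(labels, k - 1)
    records = [
        PredictionRecord.from_logits(f"synth{i:06d}", z[i], int(labels[i]))
        for i in range(n)
    ]
    return PredictionSet(
        records=records,
        provenance={
            "source": "synthetic",
            "true_temperature": float(true_temperature),
            "seed": int(seed),
            "scale": float(scale),
            "labels_from_argmax": bool(labels_from_argmax),
        },
    )


# ---------------------------------------------------------------------------
# Certificate CSV serialization (multiple-cause layout at toy scale)
# ---------------------------------------------------------------------------

_CSV_FIELDS = [
    "cert_id", "sex", "age",
    "part1_line1", "part1_line2", "part1_line3", "part1_line4",
    "part2", "true_ucod",
]


def write_certificates_csv(path, certs: Iterable[CodedCertificate]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        w.writeheader()
        for c in certs:
            row = {
                "cert_id": c.cert_id,
                "sex": c.sex,
                "age": c.age,
                "part2": ";".join(c.part2),
                "true_ucod": c.true_ucod,
            }
            for j in range(4):
                row[f"part1_line{j + 1}"] = (
                    ";".join(c.part1_lines[j]) if j < len(c.part1_lines) else ""
                )
            w.writerow(row)


def read_certificates_csv(path) -> list[CodedCertificate]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lines = tuple(
                tuple(row[f"part1_line{j + 1}"].split(";"))
                for j in range(4)
                if row[f"part1_line{j + 1}"]
            )
            part2 = tuple(row["part2"].split(";")) if row["part2"] else ()
            out.append(
                CodedCertificate(
                    cert_id=row["cert_id"],
                    sex=row["sex"],
                    age=int(row["age"]),
                    part1_lines=lines,
                    part2=part2,
                    true_ucod=row["true_ucod"],
                )
            )
    return out
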