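"""ICD-10 chapter mapping and stratified summary tables.

Provides the letter-range chapter lookup (ICD-10 2016 chapter boundaries),
chapter-level accuracy/frequency tables, top-k frequency tables with
cumulative coverage, and per-group confidence summaries (quartiles, error
rate, training-sample counts) used to stratify calibration and difficulty
results by chapter or by underlying-cause class.
"""

from __future__ import annotations

import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CHAPTER_RANGES",
    "ROMAN_CHAPTERS",
    "map_code_to_chapter",
    "chapter_accuracy_table",
    "top_k_frequency_table",
    "confidence_group_stats",
]


class MappingError(ValueError):
    """Raised for malformed or out-of-range ICD-style codes."""


# ICD-10 (2016) chapter boundaries: (first code, last code, chapter id).
# A code belongs to a chapter when first <= (letter, number) <= last.
CHAPTER_RANGES: tuple[tuple[str, str, str], ...] = (
    ("A00", "B99", "I"),
    ("C00", "D48", "II"),
    ("D50", "D89", "III"),
    ("E00", "E90", "IV"),
    ("F00", "F99", "V"),
    ("G00", "G99", "VI"),
    ("H00", "H59", "VII"),
    ("H60", "H95", "VIII"),
    ("I00", "I99", "IX"),
    ("J00", "J99", "X"),
    ("K00", "K93", "XI"),
    ("L00", "L99", "XII"),
    ("M00", "M99", "XIII"),
    ("N00", "N99", "XIV"),
    ("O00", "O99", "XV"),
    ("P00", "P96", "XVI"),
    ("Q00", "Q99", "XVII"),
    ("R00", "R99", "XVIII"),
    ("S00", "T98", "XIX"),
    ("V01", "Y98", "XX"),
    ("Z00", "Z99", "XXI"),
    ("U00", "U99", "XXII"),
)

#: All 22 chapter ids in classification order.
ROMAN_CHAPTERS: tuple[str, ...] = tuple(ch for _, _, ch in CHAPTER_RANGES)

_CODE_RE = re.compile(r"^([A-Z])(\d{2})(?:\.(\d))?$")


def _code_key(code: str) -> tuple[str, int]:
    m = _CODE_RE.match(code)
    if m is None:
        raise MappingError(f"malformed code: {code!r}")
    return m.group(1), int(m.group(2))


def map_code_to_chapter(code: str) -> str:
    """Map an ICD-10-style code (e.g. ``I21.9``) to its roman chapter id.

    Raises :class:`MappingError` for codes that are malformed or fall in a
    gap of the chapter table (e.g. ``D49``, ``V00``).
    """
    key = _code_key(code)
    for first, last, chapter in CHAPTER_RANGES:
        if _key_of(first) <= key <= _key_of(last):
            return chapter
    raise MappingError(f"code outside all chapter ranges: {code!r}")


def _key_of(bound: str) -> tuple[str, int]:
    return bound[0], int(bound[1:])


def chapter_accuracy_table(
    predictions: Mapping[str, str],
    certificates: Sequence,
    codebook=None,
) -> pd.DataFrame:
    """Chapter-level input/target frequencies and top-1 accuracy.

    ``predictions`` maps cert_id -> predicted code. ``certificates`` are
    :class:`~mortexplain.synthetic.CodedCertificate` objects carrying the
    stated conditions and the true underlying cause. Input frequency counts
    every stated condition by chapter; target frequency counts true
    underlying causes; accuracy is the fraction of correct predictions among
    certificates whose true cause falls in the chapter (NaN where a chapter
    never occurs as a target).
    """
    cert_index = {c.cert_id: c for c in certificates}
    missing = [cid for cid in predictions if cid not in cert_index]
    if missing:
        raise ValueError(f"predictions reference unknown certificates: {missing[:5]}")

    input_counts: dict[str, int] = {ch: 0 for ch in ROMAN_CHAPTERS}
    target_counts: dict[str, int] = {ch: 0 for ch in ROMAN_CHAPTERS}
    correct: dict[str, int] = {ch: 0 for ch in ROMAN_CHAPTERS}
    scored: dict[str, int] = {ch: 0 for ch in ROMAN_CHAPTERS}

    for cert in certificates:
        for code in cert.stated_codes():
            input_counts[map_code_to_chapter(code)] += 1
        target_counts[map_code_to_chapter(cert.true_ucod)] += 1

    for cid, pred_code in predictions.items():
        cert = cert_index[cid]
        ch = map_code_to_chapter(cert.true_ucod)
        scored[ch] += 1
        if pred_code == cert.true_ucod:
            correct[ch] += 1

    n_input = sum(input_counts.values())
    n_target = sum(target_counts.values())
    rows = []
    for ch in ROMAN_CHAPTERS:
        acc = correct[ch] / scored[ch] if scored[ch] > 0 else np.nan
        rows.append(
            {
                "chapter": ch,
                "input_count": input_counts[ch],
                "input_pct": 100.0 * input_counts[ch] / n_input if n_input else 0.0,
                "target_count": target_counts[ch],
                "target_pct": 100.0 * target_counts[ch] / n_target if n_target else 0.0,
                "accuracy": acc,
            }
        )
    return pd.DataFrame(rows)


def top_k_frequency_table(
    counts: Mapping[str, int],
    k: int,
    codebook=None,
    total: int | None = None,
) -> pd.DataFrame:
    """Top-k most frequent codes with percent and cumulative coverage.

    ``total`` defaults to the sum of all supplied counts; pass it explicitly
    when ``counts`` holds only the head of a larger frequency table. Percent
    values are exact; round to 3 decimals at presentation time.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not counts:
        raise ValueError("empty counts")
    if total is None:
        total = int(sum(counts.values()))
    if total <= 0:
        raise ValueError("total must be positive")
    # Stable ordering: count descending, code ascending for ties.
    top = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    rows = []
    cum = 0.0
    for code, count in top:
        pct = 100.0 * count / total
        cum += pct
        title = ""
        if codebook is not None and code in codebook:
            title = codebook[code].title
        rows.append(
            {
                "code": code,
                "title": title,
                "count": int(count),
                "percent": pct,
                "cumulative_percent": cum,
            }
        )
    return pd.DataFrame(rows)


def confidence_group_stats(
    records: pd.DataFrame,
    grouping: str,
    train_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-group confidence five-number summary with error rate.

    ``records`` needs columns ``confidence`` (float), ``correct`` (bool) and
    the grouping column (``chapter`` or ``class``). Quartiles use linear
    interpolation. ``train_counts`` optionally maps group key -> number of
    training samples (emitted for confidence-vs-training-size scatters).
    """
    if grouping not in ("chapter", "class"):
        raise ValueError(f"unknown grouping: {grouping!r}")
    if grouping not in records.columns:
        raise ValueError(f"records lack a {grouping!r} column")
    rows = []
    for key, grp in records.groupby(grouping, sort=True):
        conf = grp["confidence"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(conf, [25, 50, 75])
        rows.append(
            {
                grouping: key,
                "n": len(grp),
                "min": conf.min(),
                "q1": q1,
                "median": med,
                "q3": q3,
                "max": conf.max(),
                "mean_confidence": conf.mean(),
                "error_rate": 1.0 - grp["correct"].mean(),
                "train_count": (train_counts or {}).get(key, np.nan),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["quartile_method"] = "linear interpolation"
    return out
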