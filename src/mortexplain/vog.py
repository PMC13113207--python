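"""Variance-of-Gradients instance difficulty over training checkpoints.

For each instance, the gradient S of the class-p logit with respect to each
token embedding is computed at every training checkpoint. The raw VoG score
is the mean, over all (token, embedding component) cells, of the population
variance of that cell across the K checkpoints:

    raw_vog = mean_{i,j} Var_k S_k[i, j]      (denominator K)

By default S holds the gradient with respect to each token's *pooled
contribution* (e_i / n): under mean pooling the raw embedding gradient is
attenuated by 1/n, which would conflate certificate length with difficulty;
the contribution gradient makes scores length-comparable
(``token_scale="embedding"`` restores the raw embedding gradient).

High scores mark instances whose gradients keep changing through training —
difficult or atypical inputs. Scores are then class-centred (subtract the
class mean, to remove class-frequency effects) and globally standardised
(z-score of the centred score, clipped to [-1, 1] for reporting). The
module also ranks records, flags OOD-like ones (stating codes never seen in
training, or scores above a quantile), stratifies mean difficulty by
training-frequency ranges, and correlates class-level difficulty with the
mean number of stated conditions and of used certificate lines.

A ``mode="final"`` variant computes, at the final checkpoint only, the
per-token variance across embedding components (sensitivity analysis for
the single-snapshot reading of token-level VoG).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, pearsonr

from .model import CheckpointSet, token_gradients
from .reverse_coding import SentenceRecord

__all__ = [
    "VoGRecord",
    "VoGAnalysis",
    "DEFAULT_FREQUENCY_RANGES",
    "vog_from_gradient_stack",
    "instance_vog",
    "score_records",
    "normalize_vog",
    "rank_and_flag",
    "vog_frequency_analysis",
    "difficulty_correlations",
    "class_level_table",
]

#: Minimum-training-occurrence ranges used for frequency stratification at
#: full national-data scale ({0}, {1-2}, {3-1000}, {1001-5000},
#: {5001-20000}, {>20000}).
DEFAULT_FREQUENCY_RANGES: tuple[tuple[int, float], ...] = (
    (0, 0), (1, 2), (3, 1000), (1001, 5000), (5001, 20000), (20001, math.inf),
)

#: The same stratification compressed to desk-scale datasets (thousands of
#: certificates rather than hundreds of thousands).
DESK_SCALE_FREQUENCY_RANGES: tuple[tuple[int, float], ...] = (
    (0, 0), (1, 2), (3, 10), (11, 50), (51, 200), (201, math.inf),
)


@dataclass(frozen=True)
class VoGRecord:
    """Per-instance difficulty score with its normalisations."""

    cert_id: str
    class_index: int            # class p whose logit gradient was used
    raw_vog: float
    n_tokens: int
    n_conditions: int
    n_lines: int
    stated_codes: tuple[str, ...]
    class_norm_vog: float = math.nan
    global_norm_vog: float = math.nan   # clipped to [-1, 1]
    global_norm_unclipped: float = math.nan
    ood_flag: bool = False


@dataclass(frozen=True)
class VoGAnalysis:
    per_class: pd.DataFrame          # class -> mean vog / conditions / lines
    frequency_table: pd.DataFrame    # occurrence range -> mean vog, count
    log2_trend: pd.DataFrame         # log2(min occurrence + 1) binned means
    correlations: dict[str, float]


def vog_from_gradient_stack(grads: np.ndarray) -> float:
    """VoG of a (K, n_tokens, d) gradient stack.

    Population variance (denominator K) of every (token, component) cell
    across the K checkpoints, averaged over all cells.
    """
    grads = np.asarray(grads, dtype=float)
    if grads.ndim != 3 or grads.shape[0] < 2:
        raise ValueError("need a (K >= 2, n_tokens, d) gradient stack")
    return float(grads.var(axis=0, ddof=0).mean())


def _scaled_gradients(model, record: SentenceRecord, p: int, token_scale: str) -> np.ndarray:
    S = token_gradients(model, record, p)
    if token_scale == "contribution":
        # Gradient w.r.t. each token's pooled contribution (e_i / n). Under
        # mean pooling the raw embedding gradient carries a structural 1/n
        # factor, which would make short certificates look uniformly harder;
        # the contribution gradient removes that attenuation so scores are
        # comparable across certificate lengths.
        return S * S.shape[0]
    if token_scale == "embedding":
        return S
    raise ValueError(f"unknown token_scale: {token_scale!r}")


def instance_vog(
    checkpoints: CheckpointSet,
    record: SentenceRecord,
    p: int,
    mode: str = "checkpoint",
    token_scale: str = "contribution",
) -> float:
    """Raw VoG of one record for class ``p``.

    ``mode="checkpoint"`` (default): per-(token, component) population
    variance across the K >= 2 checkpoints, averaged over all cells.
    ``mode="final"``: per-token variance across embedding components at the
    final checkpoint only, averaged over tokens (single-snapshot reading).

    ``token_scale`` picks the gradient each cell holds: ``"contribution"``
    (default) differentiates with respect to the token's share of the
    pooled representation, ``"embedding"`` with respect to the raw token
    embedding (the two differ by the token count under mean pooling).
    """
    if mode == "checkpoint":
        if len(checkpoints) < 2:
            raise ValueError("variance across checkpoints needs K >= 2 snapshots")
        grads = np.stack(
            [_scaled_gradients(ck.model, record, p, token_scale) for ck in checkpoints]
        )  # (K, n_tokens, d)
        return vog_from_gradient_stack(grads)
    if mode == "final":
        S = _scaled_gradients(checkpoints.final, record, p, token_scale)
        return float(S.var(axis=1, ddof=0).mean())
    raise ValueError(f"unknown mode: {mode!r}")


def score_records(
    checkpoints: CheckpointSet,
    records: Sequence[SentenceRecord],
    certificates: Mapping[str, object] | None = None,
    class_of: str = "true",
    mode: str = "checkpoint",
    token_scale: str = "contribution",
) -> list[VoGRecord]:
    """Raw VoG for a collection of records.

    ``class_of="true"`` takes gradients of the true-label logit (labeled
    analysis); ``class_of="predicted"`` uses the final model's prediction
    (unlabeled scoring).
    """
    from .model import predict_logits  # local to avoid cycle in docs builds

    out = []
    for r in records:
        if class_of == "true":
            p = r.label_index
        elif class_of == "predicted":
            p = int(np.argmax(predict_logits(checkpoints.final, r)))
        else:
            raise ValueError(f"unknown class_of: {class_of!r}")
        cert = certificates.get(r.cert_id) if certificates else None
        stated = tuple(cert.stated_codes()) if cert is not None else ()
        out.append(
            VoGRecord(
                cert_id=r.cert_id,
                class_index=p,
                raw_vog=instance_vog(checkpoints, r, p, mode=mode, token_scale=token_scale),
                n_tokens=r.n_tokens,
                n_conditions=cert.n_conditions if cert is not None else -1,
                n_lines=cert.n_lines if cert is not None else -1,
                stated_codes=stated,
            )
        )
    return out


def normalize_vog(records: Sequence[VoGRecord]) -> list[VoGRecord]:
    """Class-centre raw scores, then globally standardise and clip.

    class_norm = raw - mean(raw of the record's class);
    global_norm = z-score of class_norm over all records, clipped to
    [-1, 1] (the unclipped value is retained alongside).
    """
    if not records:
        raise ValueError("no records to normalize")
    raw = np.array([r.raw_vog for r in records])
    classes = np.array([r.class_index for r in records])
    class_mean = {c: raw[classes == c].mean() for c in np.unique(classes)}
    centred = raw - np.array([class_mean[c] for c in classes])
    sd = centred.std(ddof=0)
    if sd == 0:
        raise ValueError("zero global standard deviation: all scores identical")
    z = (centred - centred.mean()) / sd
    return [
        replace(
            r,
            class_norm_vog=float(centred[i]),
            global_norm_vog=float(np.clip(z[i], -1.0, 1.0)),
            global_norm_unclipped=float(z[i]),
        )
        for i, r in enumerate(records)
    ]


def rank_and_flag(
    records: Sequence[VoGRecord],
    train_code_counts: Mapping[str, int],
    flag_quantile: float = 0.95,
) -> list[VoGRecord]:
    """Sort descending by global-normalised VoG and flag OOD-like records.

    A record is flagged when (a) it states any code with zero training
    occurrences, or (b) its global-normalised score exceeds the
    ``flag_quantile`` quantile of the score distribution. Ranking and the
    quantile rule use the unclipped z-scores: clipping (a reporting device)
    piles the upper tail onto exactly 1.0, which would make "exceeds the
    quantile" vacuous there.
    """
    if not records:
        return []
    if any(math.isnan(r.global_norm_unclipped) for r in records):
        raise ValueError("records must be normalized before ranking")
    scores = np.array([r.global_norm_unclipped for r in records])
    threshold = float(np.quantile(scores, flag_quantile))
    flagged = []
    for r in records:
        unseen = any(train_code_counts.get(c, 0) == 0 for c in r.stated_codes)
        flagged.append(
            replace(r, ood_flag=bool(unseen or r.global_norm_unclipped > threshold))
        )
    flagged.sort(key=lambda r: (-r.global_norm_unclipped, r.cert_id))
    return flagged


def _min_occurrence(r: VoGRecord, counts: Mapping[str, int]) -> int:
    if not r.stated_codes:
        raise ValueError(f"record {r.cert_id} carries no stated codes")
    return min(counts.get(c, 0) for c in r.stated_codes)


def vog_frequency_analysis(
    records: Sequence[VoGRecord],
    train_code_counts: Mapping[str, int],
    ranges: Sequence[tuple[int, float]] = DEFAULT_FREQUENCY_RANGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean difficulty by minimum training occurrence of the stated codes.

    Each record is assigned by the *minimum* training occurrence among its
    stated codes. Returns (range table, log2 trend table); the latter bins
    log2(min occurrence + 1) at unit width.
    """
    rs = sorted(ranges)
    for (lo1, hi1), (lo2, _) in zip(rs, rs[1:]):
        if hi1 >= lo2:
            raise ValueError("occurrence ranges overlap")
    if rs[0][0] != 0 or not math.isinf(rs[-1][1]) or any(
        lo2 != hi1 + 1 for (_, hi1), (lo2, _) in zip(rs, rs[1:])
    ):
        raise ValueError("occurrence ranges must partition [0, inf)")

    mins = np.array([_min_occurrence(r, train_code_counts) for r in records])
    scores = np.array([r.global_norm_vog for r in records])

    rows = []
    for lo, hi in rs:
        sel = (mins >= lo) & (mins <= hi)
        label = f"{lo}" if lo == hi else (f">{lo - 1}" if math.isinf(hi) else f"{lo}-{hi:g}")
        rows.append(
            {
                "range": label,
                "min_occurrence": lo,
                "count": int(sel.sum()),
                "mean_global_norm_vog": float(scores[sel].mean()) if sel.any() else math.nan,
            }
        )
    freq_table = pd.DataFrame(rows)

    lb = np.floor(np.log2(mins + 1.0)).astype(int)
    trend = (
        pd.DataFrame({"log2_bin": lb, "vog": scores})
        .groupby("log2_bin", as_index=False)
        .agg(count=("vog", "size"), mean_global_norm_vog=("vog", "mean"))
    )
    return freq_table, trend


def class_level_table(records: Sequence[VoGRecord]) -> pd.DataFrame:
    """Per-class mean VoG, mean stated conditions and mean used lines."""
    df = pd.DataFrame(
        {
            "class_index": [r.class_index for r in records],
            "vog": [r.global_norm_vog for r in records],
            "conditions": [r.n_conditions for r in records],
            "lines": [r.n_lines for r in records],
        }
    )
    return df.groupby("class_index", as_index=False).agg(
        n=("vog", "size"),
        mean_vog=("vog", "mean"),
        mean_conditions=("conditions", "mean"),
        mean_lines=("lines", "mean"),
    )


def difficulty_correlations(
    mean_vog: Sequence[float],
    mean_conditions: Sequence[float],
    mean_lines: Sequence[float],
) -> dict[str, float]:
    """Pearson and Kendall correlations of class difficulty with size proxies."""
    v = np.asarray(mean_vog, dtype=float)
    c = np.asarray(mean_conditions, dtype=float)
    l = np.asarray(mean_lines, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 classes")
    for name, arr in (("vog", v), ("conditions", c), ("lines", l)):
        if np.ptp(arr) == 0:
            raise ValueError(f"zero variance in {name}; correlation undefined")
    return {
        "pearson_conditions": float(pearsonr(v, c).statistic),
        "pearson_lines": float(pearsonr(v, l).statistic),
        "kendall_conditions": float(kendalltau(v, c).statistic),
        "kendall_lines": float(kendalltau(v, l).statistic),
    }


def records_to_frame(records: Sequence[VoGRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cert_id": [r.cert_id for r in records],
            "class_index": [r.class_index for r in records],
            "raw_vog": [r.raw_vog for r in records],
            "class_norm_vog": [r.class_norm_vog for r in records],
            "global_norm_vog": [r.global_norm_vog for r in records],
            "global_norm_unclipped": [r.global_norm_unclipped for r in records],
            "n_tokens": [r.n_tokens for r in records],
            "n_conditions": [r.n_conditions for r in records],
            "n_lines": [r.n_lines for r in records],
            "ood_flag": [r.ood_flag for r in records],
        }
    )
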