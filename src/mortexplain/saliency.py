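"""Integrated Gradients word attribution with completeness checks.

Integrated Gradients attributes a model output F (here the pre-softmax
logit of a target class) to each input component by accumulating gradients
along the straight-line path from a baseline x' to the input x:

    IG_i(x) = (x_i - x'_i) * integral_0^1 dF(x' + a (x - x')) / dx_i da

The integral is approximated by Gauss-Legendre quadrature (default) or a
left Riemann sum. Completeness — sum_i IG_i = F(x) - F(x') — is verified
per record and the residual reported as ``completeness_gap``.

Token attributions (per embedding component) are scalarised by component
sum (sign preserved) and aggregated to words via the tokenizer's word map;
display values are scaled by the record's maximum absolute word attribution
for the red/white/green rendering of the HTML report.
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    TextClassifier,
    embed_record,
    gradient_from_embeddings,
    logit_from_embeddings,
    predict_logits,
)
from .reverse_coding import PAD_ID, SentenceRecord

__all__ = [
    "AttributionRecord",
    "integrated_gradients",
    "aggregate_to_words",
    "attribute_record",
    "render_saliency_report",
]


@dataclass(frozen=True)
class AttributionRecord:
    """Word-level Integrated Gradients attribution for one certificate."""

    cert_id: str
    text: str
    words: tuple[str, ...]
    target_class: int
    target_code: str
    target_title: str
    true_class: int
    true_code: str
    true_title: str
    token_attributions: np.ndarray     # per-token scalars
    word_attributions: np.ndarray      # per-word scalars
    word_display: np.ndarray           # max-abs scaled, sign preserved
    attribution_score: float           # sum of word attributions
    completeness_gap: float
    steps: int
    method: str

    @property
    def correct(self) -> bool:
        return self.target_class == self.true_class


def _quadrature(steps: int, method: str) -> tuple[np.ndarray, np.ndarray]:
    if steps < 1:
        raise ValueError("steps must be >= 1")
    if method == "gausslegendre":
        nodes, weights = np.polynomial.legendre.leggauss(steps)
        return (nodes + 1.0) / 2.0, weights / 2.0
    if method == "riemann_left":
        return np.arange(steps) / steps, np.full(steps, 1.0 / steps)
    raise ValueError(f"unknown quadrature method: {method!r}")


def integrated_gradients(
    model: TextClassifier,
    record: SentenceRecord,
    target: int,
    baseline: str | np.ndarray = "pad",
    steps: int = 50,
    method: str = "gausslegendre",
) -> tuple[np.ndarray, float]:
    """Per-token, per-component attributions and the completeness gap.

    ``baseline`` is ``"pad"`` (padding-token embedding repeated to input
    length, the default neutral reference), ``"zero"``, or an explicit
    (n_tokens, d) array.
    """
    X = embed_record(model, record)
    if isinstance(baseline, str):
        if baseline == "pad":
            B = np.tile(model.params["E"][PAD_ID], (X.shape[0], 1))
        elif baseline == "zero":
            B = np.zeros_like(X)
        else:
            raise ValueError(f"unknown baseline: {baseline!r}")
    else:
        B = np.asarray(baseline, dtype=float)
        if B.shape != X.shape:
            raise ValueError(f"baseline shape {B.shape} != input shape {X.shape}")

    alphas, weights = _quadrature(steps, method)
    avg_grad = np.zeros_like(X)
    for a, w in zip(alphas, weights):
        avg_grad += w * gradient_from_embeddings(model, B + a * (X - B), target)
    attributions = (X - B) * avg_grad
    gap = abs(
        attributions.sum()
        - (logit_from_embeddings(model, X, target) - logit_from_embeddings(model, B, target))
    )
    return attributions, float(gap)


def aggregate_to_words(
    token_attributions: np.ndarray,
    word_map: Sequence[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate component attributions to token and word scalars.

    Returns (token_scalars, word_attributions, word_display). Token scalars
    are component sums (sign preserved); a word's attribution is the sum
    over its tokens; display values are scaled by the maximum absolute word
    attribution (skipped when all attributions are zero).
    """
    token_attributions = np.asarray(token_attributions)
    token_scalars = (
        token_attributions.sum(axis=1)
        if token_attributions.ndim == 2
        else token_attributions.astype(float)
    )
    n = token_scalars.shape[0]
    covered = np.zeros(n, dtype=int)
    for a, b in word_map:
        covered[a:b] += 1
    if (covered != 1).any():
        raise ValueError("word map must cover every token exactly once")
    words = np.array([token_scalars[a:b].sum() for a, b in word_map])
    peak = np.abs(words).max()
    display = words / peak if peak > 0 else words.copy()
    return token_scalars, words, display


def attribute_record(
    model: TextClassifier,
    record: SentenceRecord,
    codebook,
    classes: Sequence[str],
    target: str = "predicted",
    baseline: str | np.ndarray = "pad",
    steps: int = 50,
    method: str = "gausslegendre",
) -> AttributionRecord:
    """Full attribution for one record (target = predicted or true label)."""
    if target == "predicted":
        p = int(np.argmax(predict_logits(model, record)))
    elif target == "true":
        p = record.label_index
    else:
        raise ValueError(f"unknown target: {target!r}")
    attrs, gap = integrated_gradients(model, record, p, baseline, steps, method)
    token_scalars, word_attr, display = aggregate_to_words(attrs, record.word_map)
    target_code = classes[p]
    true_code = record.label
    return AttributionRecord(
        cert_id=record.cert_id,
        text=record.text,
        words=tuple(record.words()),
        target_class=p,
        target_code=target_code,
        target_title=codebook.title(target_code),
        true_class=record.label_index,
        true_code=true_code,
        true_title=codebook.title(true_code),
        token_attributions=token_scalars,
        word_attributions=word_attr,
        word_display=display,
        attribution_score=float(word_attr.sum()),
        completeness_gap=gap,
        steps=steps,
        method=method,
    )


# ---------------------------------------------------------------------------
# Report rendering (HTML + TSV twin)
# ---------------------------------------------------------------------------

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Word attribution report</title>
<style>
 body {{ font-family: sans-serif; margin: 2em; }}
 table {{ border-collapse: collapse; }}
 td, th {{ border: 1px solid #999; padding: 6px 10px; vertical-align: top; }}
 .word {{ padding: 1px 3px; border-radius: 3px; }}
 .score {{ text-align: right; }}
</style></head>
<body>
<h1>Word importance (Integrated Gradients)</h1>
<p>Green marks positive attribution toward the predicted underlying cause,
red negative, white neutral. The attribution score is the sum of all
word-level attributions.</p>
<table>
<tr><th>True label (UCOD)</th><th>True title</th><th>Predicted label (UCOD)</th>
<th>Predicted title</th><th>Correct</th><th>Word importance</th>
<th>Attribution score</th></tr>
{rows}
</table></body></html>
"""


def _word_span(word: str, value: float) -> str:
    alpha = min(abs(float(value)), 1.0)
    color = f"rgba(0,160,0,{alpha:.2f})" if value >= 0 else f"rgba(220,0,0,{alpha:.2f})"
    return f'<span class="word" style="background-color:{color}">{html.escape(word)}</span>'


def render_saliency_report(
    records: Sequence[AttributionRecord],
    html_path=None,
    tsv_path=None,
) -> tuple[str, pd.DataFrame]:
    """Render attribution records as an HTML page and a numeric TSV twin."""
    rows_html = []
    rows_tsv = []
    for r in records:
        spans = " ".join(_word_span(w, v) for w, v in zip(r.words, r.word_display))
        rows_html.append(
            "<tr>"
            f"<td>{html.escape(r.true_code)}</td><td>{html.escape(r.true_title)}</td>"
            f"<td>{html.escape(r.target_code)}</td><td>{html.escape(r.target_title)}</td>"
            f"<td>{'yes' if r.correct else 'no'}</td>"
            f"<td>{spans}</td>"
            f'<td class="score">{r.attribution_score:.3f}</td>'
            "</tr>"
        )
        rows_tsv.append(
            {
                "cert_id": r.cert_id,
                "true_code": r.true_code,
                "true_title": r.true_title,
                "pred_code": r.target_code,
                "pred_title": r.target_title,
                "correct": r.correct,
                "attribution_score": r.attribution_score,
                "completeness_gap": r.completeness_gap,
                "word_attributions": " ".join(
                    f"{w}:{v:.6g}" for w, v in zip(r.words, r.word_attributions)
                ),
            }
        )
    page = _PAGE.format(rows="\n".join(rows_html))
    table = pd.DataFrame(rows_tsv)
    if html_path is not None:
        with open(html_path, "w") as fh:
            fh.write(page)
    if tsv_path is not None:
        table.to_csv(tsv_path, sep="\t", index=False)
    return page, table
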