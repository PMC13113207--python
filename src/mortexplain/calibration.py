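"""Binned confidence calibration (ECE/MCE) and temperature scaling.

A multiclass classifier is *calibrated* when, among predictions made with
confidence p, a fraction p is correct. Calibration is estimated empirically
by grouping predictions into M equal-width confidence bins ((m-1)/M, m/M]
and comparing each bin's accuracy acc(B_m) with its mean confidence
conf(B_m):

    ECE = sum_m |B_m|/n * |acc(B_m) - conf(B_m)|      (count-weighted mean)
    MCE = max over non-empty bins of |acc - conf|      (worst case)

Both are reported on the percent scale (x100). Temperature scaling is the
standard post-hoc recalibration: a single scalar T > 0 divides the logits
before the softmax, fitted on held-out data by minimising the negative log
likelihood (optionally the ECE itself); it never changes the argmax, so
accuracy is preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import log_softmax, softmax

__all__ = [
    "PredictionRecord",
    "CalibrationBins",
    "CalibrationReport",
    "TemperatureModel",
    "bin_predictions",
    "calibration_errors",
    "fit_temperature",
    "apply_temperature",
    "reliability_data",
    "write_predictions_jsonl",
    "read_predictions_jsonl",
]

T_BOUNDS = (0.05, 20.0)
T_XATOL = 1e-4


@dataclass(frozen=True)
class PredictionRecord:
    """One scored prediction: logits, true label and derived quantities.

    ``probabilities`` is softmax of the (possibly temperature-scaled)
    logits; ``predicted`` is the argmax (ties broken toward the lowest
    class index, as numpy's argmax does); ``confidence`` is the maximum
    probability and always lies in [1/k, 1].
    """

    id: str
    logits: np.ndarray
    label: int
    probabilities: np.ndarray
    predicted: int
    confidence: float

    @classmethod
    def from_logits(
        cls, id: str, logits: Sequence[float], label: int, temperature: float = 1.0
    ) -> "PredictionRecord":
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        z = np.asarray(logits, dtype=float)
        if z.ndim != 1 or z.size < 2:
            raise ValueError("logits must be a 1-d vector with k >= 2")
        p = softmax(z / temperature)
        pred = int(np.argmax(p))
        return cls(
            id=str(id),
            logits=z,
            label=int(label),
            probabilities=p,
            predicted=pred,
            confidence=float(p[pred]),
        )

    @property
    def correct(self) -> bool:
        return self.predicted == self.label

    @property
    def k(self) -> int:
        return int(self.logits.size)


@dataclass
class CalibrationBins:
    """Equal-width confidence bins with per-bin membership and statistics."""

    M: int
    n: int
    counts: np.ndarray          # (M,) int
    acc: np.ndarray             # (M,) float, NaN for empty bins
    conf: np.ndarray            # (M,) float, NaN for empty bins
    member_ids: list[list[str]] = field(repr=False, default_factory=list)

    @property
    def midpoints(self) -> np.ndarray:
        return (np.arange(self.M) + 0.5) / self.M


@dataclass(frozen=True)
class CalibrationReport:
    """ECE/MCE on the percent scale plus the per-bin gap table."""

    ece: float
    mce: float
    per_bin: pd.DataFrame
    scale: str = "percent"


@dataclass(frozen=True)
class TemperatureModel:
    """Fitted temperature with optimisation diagnostics."""

    T: float
    objective: str
    objective_value: float
    iterations: int
    bound_hit: bool


def _bin_index(confidence: np.ndarray, M: int) -> np.ndarray:
    """Bin m covers ((m-1)/M, m/M]; confidence 0 goes to the first bin."""
    idx = np.ceil(np.asarray(confidence) * M).astype(int) - 1
    return np.clip(idx, 0, M - 1)


def bin_predictions(preds: Sequence[PredictionRecord], M: int = 10) -> CalibrationBins:
    """Group predictions into M equal-width half-open confidence bins."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if not preds:
        raise ValueError("no predictions to bin")
    conf = np.array([p.confidence for p in preds])
    correct = np.array([p.correct for p in preds], dtype=float)
    idx = _bin_index(conf, M)
    counts = np.bincount(idx, minlength=M)
    sums_conf = np.bincount(idx, weights=conf, minlength=M)
    sums_acc = np.bincount(idx, weights=correct, minlength=M)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(counts > 0, sums_acc / np.maximum(counts, 1), np.nan)
        mean_conf = np.where(counts > 0, sums_conf / np.maximum(counts, 1), np.nan)
    members: list[list[str]] = [[] for _ in range(M)]
    for p, m in zip(preds, idx):
        members[m].append(p.id)
    return CalibrationBins(
        M=M, n=len(preds), counts=counts, acc=acc, conf=mean_conf, member_ids=members
    )


def calibration_errors(bins: CalibrationBins) -> CalibrationReport:
    """ECE and MCE (percent scale) from a set of calibration bins.

    Empty bins contribute zero weight to the ECE and are excluded from the
    MCE maximum.
    """
    nonempty = bins.counts > 0
    if not nonempty.any():
        raise ValueError("all bins empty")
    gap = np.abs(bins.acc[nonempty] - bins.conf[nonempty])
    weights = bins.counts[nonempty] / bins.n
    ece = float(np.sum(weights * gap) * 100.0)
    mce = float(np.max(gap) * 100.0)
    table = pd.DataFrame(
        {
            "bin": np.arange(1, bins.M + 1),
            "midpoint": bins.midpoints,
            "count": bins.counts,
            "accuracy": bins.acc,
            "confidence": bins.conf,
            "gap": np.abs(bins.acc - bins.conf),
        }
    )
    return CalibrationReport(ece=ece, mce=mce, per_bin=table)


def _logits_labels(preds: Sequence[PredictionRecord]) -> tuple[np.ndarray, np.ndarray]:
    z = np.stack([p.logits for p in preds])
    y = np.array([p.label for p in preds])
    return z, y


def _nll(z: np.ndarray, y: np.ndarray, T: float) -> float:
    logp = log_softmax(z / T, axis=1)
    return float(-logp[np.arange(len(y)), y].mean())


def _ece_at(z: np.ndarray, y: np.ndarray, T: float, M: int) -> float:
    p = softmax(z / T, axis=1)
    pred = p.argmax(axis=1)
    conf = p[np.arange(len(y)), pred]
    idx = _bin_index(conf, M)
    counts = np.bincount(idx, minlength=M)
    sums_conf = np.bincount(idx, weights=conf, minlength=M)
    sums_acc = np.bincount(idx, weights=(pred == y).astype(float), minlength=M)
    nz = counts > 0
    gap = np.abs(sums_acc[nz] / counts[nz] - sums_conf[nz] / counts[nz])
    return float(np.sum(counts[nz] / len(y) * gap))


def fit_temperature(
    validation: Sequence[PredictionRecord],
    objective: str = "nll",
    bins: int = 10,
) -> TemperatureModel:
    """Fit the scalar temperature on held-out predictions.

    The default objective is the mean negative log likelihood of the true
    labels under softmax(z/T), minimised by bounded scalar search on
    T in [0.05, 20] to an absolute tolerance of 1e-4. ``objective="ece"``
    instead minimises the binned ECE over a dense grid (the ECE is
    piecewise-constant in T, so smooth search is inappropriate). A fit that
    lands on a search bound is flagged (degenerate likelihoods, e.g. an
    all-correct validation set, push T to a boundary).
    """
    if not validation:
        raise ValueError("empty validation set")
    z, y = _logits_labels(validation)
    if np.unique(y).size < 2:
        # Degenerate: NLL can be improved without bound by sharpening.
        pass  # still fit; the bound-hit flag reports the degeneracy
    if objective == "nll":
        res = minimize_scalar(
            lambda t: _nll(z, y, t),
            bounds=T_BOUNDS,
            method="bounded",
            options={"xatol": T_XATOL},
        )
        T, value, nit = float(res.x), float(res.fun), int(res.nfev)
    elif objective == "ece":
        grid = np.geomspace(T_BOUNDS[0], T_BOUNDS[1], 600)
        vals = np.array([_ece_at(z, y, t, bins) for t in grid])
        i = int(vals.argmin())
        T, value, nit = float(grid[i]), float(vals[i]), len(grid)
    else:
        raise ValueError(f"unknown objective: {objective!r}")
    bound_hit = T <= T_BOUNDS[0] * 1.01 or T >= T_BOUNDS[1] * 0.99
    return TemperatureModel(
        T=T, objective=objective, objective_value=value, iterations=nit, bound_hit=bound_hit
    )


def apply_temperature(logits: np.ndarray, T: float) -> np.ndarray:
    """softmax(z / T); preserves the argmax for any T > 0."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    z = np.asarray(logits, dtype=float)
    return softmax(z / T, axis=-1)


def rescale_predictions(
    preds: Sequence[PredictionRecord], T: float
) -> list[PredictionRecord]:
    """Re-derive prediction records with temperature-scaled probabilities."""
    return [
        PredictionRecord.from_logits(p.id, p.logits, p.label, temperature=T)
        for p in preds
    ]


def reliability_data(before: CalibrationBins, after: CalibrationBins) -> pd.DataFrame:
    """Plot-ready reliability-diagram table for raw and rescaled bins.

    One row per bin: midpoint, then count/accuracy/confidence/gap for the
    raw ("before") and temperature-scaled ("after") predictions. The
    identity line of the reliability diagram is the ``midpoint`` column.
    """
    if before.M != after.M:
        raise ValueError("bin counts differ between the two binnings")
    out = pd.DataFrame({"bin": np.arange(1, before.M + 1), "midpoint": before.midpoints})
    for tag, bins in (("before", before), ("after", after)):
        out[f"count_{tag}"] = bins.counts
        out[f"accuracy_{tag}"] = bins.acc
        out[f"confidence_{tag}"] = bins.conf
        out[f"gap_{tag}"] = np.abs(bins.acc - bins.conf)
    return out


# ---------------------------------------------------------------------------
# JSONL serialization (one record per line, optional provenance header)
# ---------------------------------------------------------------------------

def write_predictions_jsonl(path, preds: Iterable[PredictionRecord], provenance=None):
    with open(path, "w") as fh:
        if provenance is not None:
            fh.write(json.dumps({"provenance": provenance}) + "\n")
        for p in preds:
            fh.write(
                json.dumps(
                    {"id": p.id, "logits": [float(v) for v in p.logits], "label": p.label}
                )
                + "\n"
            )


def read_predictions_jsonl(path) -> tuple[list[PredictionRecord], dict | None]:
    preds: list[PredictionRecord] = []
    provenance = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            if "provenance" in obj:
                provenance = obj["provenance"]
                continue
            preds.append(
                PredictionRecord.from_logits(obj["id"], obj["logits"], obj["label"])
            )
    return preds, provenance
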