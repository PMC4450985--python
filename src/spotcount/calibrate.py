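"""Probability calibration: sigmoid mapping from ensemble to empirical scale.

Leaf-proportion averages out of a bagged ensemble track the true signal
frequency only loosely. To fix that, curated examples are binned by their
preliminary probability (11 bins centered at 0.0, 0.1, ..., 1.0) and the
observed fraction of true spots per bin is fit with the two-parameter Platt
family  g(p) = 1 / (1 + exp(a*p + b)),  weighted by bin occupancy. The
fitted curve converts any preliminary probability into an empirical
probability; the hard call is signal iff the calibrated probability exceeds
0.5 (strictly).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .stacks import ValidationError

__all__ = [
    "CalibrationCurve",
    "build_calibration",
    "apply_calibration",
    "decide",
    "save_calibration",
    "load_calibration",
]

BIN_CENTERS = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 1)


def _sigmoid(p: np.ndarray, a: float, b: float) -> np.ndarray:
    # Clip the exponent so extreme fitted slopes cannot overflow.
    return 1.0 / (1.0 + np.exp(np.clip(a * p + b, -500, 500)))


@dataclass
class CalibrationCurve:
    """Fitted mapping preliminary probability -> empirical probability.

    ``method`` is "sigmoid" for the Platt fit; "monotone_bins" flags the
    fallback used when the least-squares fit came out decreasing (a > 0),
    in which case a nondecreasing clamp of the bin proportions is
    interpolated instead.
    """

    a: float
    b: float
    bin_centers: np.ndarray
    bin_proportions: np.ndarray  # NaN where the bin was empty
    bin_counts: np.ndarray
    residual: float
    method: str = "sigmoid"
    monotone_values: np.ndarray | None = field(default=None)

    def __call__(self, p_hat):
        return apply_calibration(self, p_hat)


def bin_corpus(p_hat: np.ndarray, labels: np.ndarray):
    """Assign scores to the 11 calibration bins (edges at midpoints)."""
    p_hat = np.asarray(p_hat, dtype=np.float64)
    labels = np.asarray(labels)
    if np.any((p_hat < 0) | (p_hat > 1)):
        raise ValidationError("preliminary probabilities must lie in [0, 1]")
    idx = np.clip(np.round(p_hat * 10).astype(int), 0, 10)
    counts = np.bincount(idx, minlength=11).astype(float)
    sums = np.bincount(idx, weights=labels.astype(float), minlength=11)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = sums / counts
    return counts, props


def build_calibration(p_hat: np.ndarray, labels: np.ndarray) -> CalibrationCurve:
    """Fit the calibration sigmoid to a curated (p_hat, label) corpus.

    Empty bins are dropped; occupied bins are weighted by their example
    count in the least-squares fit. A fit with a > 0 (a decreasing curve)
    is rejected and replaced by a flagged monotone clamp of the raw bin
    proportions.
    """
    labels = np.asarray(labels)
    if len(set(np.unique(labels)) & {0, 1}) < 2:
        raise ValidationError("calibration corpus must contain both labels")
    counts, props = bin_corpus(p_hat, labels)
    occupied = counts > 0
    if occupied.sum() < 2:
        raise ValidationError("need >= 2 non-empty calibration bins")

    x = BIN_CENTERS[occupied]
    yv = props[occupied]
    w = counts[occupied]

    a, b = np.nan, np.nan
    ok = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda p, a, b: _sigmoid(p, a, b),
                x,
                yv,
                p0=(-8.0, 4.0),
                sigma=1.0 / np.sqrt(w),
                absolute_sigma=False,
                maxfev=5000,
            )
        a, b = float(popt[0]), float(popt[1])
        ok = np.isfinite(a) and np.isfinite(b) and a <= 0
    except Exception:  # noqa: BLE001 - fall through to the monotone clamp
        ok = False

    if ok:
        resid = float(np.sqrt(np.average((_sigmoid(x, a, b) - yv) ** 2, weights=w)))
        return CalibrationCurve(
            a=a,
            b=b,
            bin_centers=BIN_CENTERS.copy(),
            bin_proportions=props,
            bin_counts=counts,
            residual=resid,
            method="sigmoid",
        )

    # Fallback: nondecreasing clamp (running max) of observed proportions.
    mono = np.fmax.accumulate(np.where(occupied, props, -np.inf))
    mono = np.clip(mono, 0.0, 1.0)
    first = np.argmax(occupied)
    mono[: first + 1] = np.clip(props[first], 0, 1)
    resid = float(np.sqrt(np.average((mono[occupied] - yv) ** 2, weights=w)))
    return CalibrationCurve(
        a=np.nan,
        b=np.nan,
        bin_centers=BIN_CENTERS.copy(),
        bin_proportions=props,
        bin_counts=counts,
        residual=resid,
        method="monotone_bins",
        monotone_values=mono,
    )


def apply_calibration(curve: CalibrationCurve, p_hat):
    """Calibrated probability g(p_hat), clipped to [0, 1]."""
    p = np.asarray(p_hat, dtype=np.float64)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("preliminary probability outside [0, 1]")
    if curve.method == "sigmoid":
        out = _sigmoid(p, curve.a, curve.b)
    else:
        out = np.interp(p, curve.bin_centers, curve.monotone_values)
    out = np.clip(out, 0.0, 1.0)
    return float(out[0]) if scalar else out


def decide(p) -> np.ndarray:
    """Hard classification: signal iff calibrated probability > 0.5 (strict)."""
    p = np.asarray(p, dtype=np.float64)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("probability outside [0, 1]")
    lab = (p > 0.5).astype(np.intp)
    return int(lab[0]) if scalar else lab


def save_calibration(curve: CalibrationCurve, path) -> None:
    doc = {
        "a": None if np.isnan(curve.a) else curve.a,
        "b": None if np.isnan(curve.b) else curve.b,
        "bin_centers": curve.bin_centers.tolist(),
        "bin_proportions": [
            None if np.isnan(v) else v for v in curve.bin_proportions
        ],
        "bin_counts": curve.bin_counts.tolist(),
        "residual": curve.residual,
        "method": curve.method,
        "monotone_values": (
            curve.monotone_values.tolist() if curve.monotone_values is not None else None
        ),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_calibration(path) -> CalibrationCurve:
    with open(path) as fh:
        doc = json.load(fh)
    props = np.array(
        [np.nan if v is None else v for v in doc["bin_proportions"]], dtype=np.float64
    )
    mono = doc.get("monotone_values")
    return CalibrationCurve(
        a=np.nan if doc["a"] is None else float(doc["a"]),
        b=np.nan if doc["b"] is None else float(doc["b"]),
        bin_centers=np.asarray(doc["bin_centers"], dtype=np.float64),
        bin_proportions=props,
        bin_counts=np.asarray(doc["bin_counts"], dtype=np.float64),
        residual=float(doc["residual"]),
        method=doc["method"],
        monotone_values=np.asarray(mono, dtype=np.float64) if mono is not None else None,
    )
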