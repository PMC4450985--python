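"""Molecule-count point estimate and Poisson-trials confidence interval.

Each tested local maximum k carries a calibrated probability p_k of being a
real emitter. The total count of true spots is then a sum of independent
Bernoulli trials with heterogeneous probabilities (Poisson trials):

    T = sum_k X_k,   P{X_k = 1} = p_k.

Simulating this sum many times (default 1000 replicates) and taking
empirical quantiles yields a confidence interval whose width directly
reflects image quality: crisp images have p_k near 0 or 1 and tight
intervals, murky ones have many mid-range p_k and wide intervals. The exact
Poisson-binomial distribution (iterative convolution, O(n^2)) is kept
alongside as an oracle and is reported whenever n is small enough.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stacks import ValidationError

__all__ = [
    "CountEstimate",
    "simulate_count",
    "confidence_interval",
    "exact_poisson_binomial",
    "exact_quantiles",
    "count_report",
    "save_count",
]


@dataclass
class CountEstimate:
    """Point count plus Monte-Carlo confidence interval for one stack."""

    n: int
    point_count: int
    p_list: np.ndarray
    ci_low: int
    ci_high: int
    level: float
    n_reps: int
    seed: int
    exact_ci: tuple[int, int] | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "point_count": self.point_count,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "exact_ci": list(self.exact_ci) if self.exact_ci is not None else None,
        }


def _check_probs(p_list) -> np.ndarray:
    p = np.asarray(p_list, dtype=np.float64)
    if p.ndim != 1:
        raise ValidationError("p_list must be 1D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("probabilities must lie in [0, 1]")
    return p


def simulate_count(p_list, n_reps: int, seed: int = 0) -> np.ndarray:
    """Draw ``n_reps`` independent realizations of T = sum_k Bernoulli(p_k)."""
    p = _check_probs(p_list)
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(p)
    if n == 0:
        return np.zeros(n_reps, dtype=np.int64)
    # Chunk replicates so n_reps=1e5 at large n stays within memory.
    out = np.empty(n_reps, dtype=np.int64)
    chunk = max(1, int(2e7) // max(n, 1))
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        out[done : done + m] = (rng.random((m, n)) < p).sum(axis=1)
        done += m
    return out


def confidence_interval(T_samples, level: float = 0.95) -> tuple[int, int]:
    """Nearest-rank percentile interval of the simulated totals.

    With N sorted samples the bounds are ``sorted[floor(q_lo*N)]`` and
    ``sorted[min(ceil(q_hi*N), N-1)]`` for q_lo = (1-level)/2 and
    q_hi = 1 - q_lo, so the interval leans slightly outward and is always
    integer-valued.
    """
    samples = np.sort(np.asarray(T_samples))
    if len(samples) < 2:
        raise ValidationError("need >= 2 samples for an interval")
    if not (0 < level < 1):
        raise ValidationError("level must be in (0, 1)")
    n = len(samples)
    q_lo = (1.0 - level) / 2.0
    q_hi = 1.0 - q_lo
    lo = samples[min(int(np.floor(q_lo * n)), n - 1)]
    hi = samples[min(int(np.ceil(q_hi * n)), n - 1)]
    return int(lo), int(hi)


def exact_poisson_binomial(p_list) -> np.ndarray:
    """Exact pmf of T over {0, ..., n} by iterative convolution.

    Starts from [1] and convolves with [1-p_k, p_k] for each trial; the
    result sums to 1 to within accumulation error (< 1e-12 for n in the
    thousands). An empty list gives the point mass at 0.
    """
    p = _check_probs(p_list)
    pmf = np.array([1.0])
    for pk in p:
        pmf = np.convolve(pmf, [1.0 - pk, pk])
    return pmf


def exact_quantiles(pmf: np.ndarray, level: float = 0.95) -> tuple[int, int]:
    """Central quantiles of an exact pmf (smallest k with cdf >= q)."""
    cdf = np.cumsum(pmf)
    q_lo = (1.0 - level) / 2.0
    q_hi = 1.0 - q_lo
    lo = int(np.searchsorted(cdf, q_lo))
    hi = int(np.searchsorted(cdf, q_hi))
    return lo, hi


EXACT_MAX_N = 5000


def count_report(
    spots: pd.DataFrame,
    level: float = 0.95,
    n_reps: int = 1000,
    seed: int = 0,
    prob_column: str = "p_calibrated",
) -> CountEstimate:
    """Assemble the count estimate for a classified spot table.

    ``n`` is the number of local maxima actually tested (candidates removed
    by the detection truncation never enter). The exact Poisson-binomial
    interval is attached whenever n <= 5000.
    """
    if len(spots) == 0:
        return CountEstimate(
            n=0,
            point_count=0,
            p_list=np.empty(0),
            ci_low=0,
            ci_high=0,
            level=level,
            n_reps=n_reps,
            seed=seed,
            exact_ci=(0, 0),
        )
    if prob_column not in spots.columns:
        raise ValidationError(f"spot table lacks column {prob_column!r}")
    p = _check_probs(spots[prob_column].to_numpy())
    point = int((p > 0.5).sum())
    samples = simulate_count(p, n_reps=n_reps, seed=seed)
    lo, hi = confidence_interval(samples, level=level)
    exact = None
    if len(p) <= EXACT_MAX_N:
        exact = exact_quantiles(exact_poisson_binomial(p), level=level)
    return CountEstimate(
        n=len(p),
        point_count=point,
        p_list=p,
        ci_low=lo,
        ci_high=hi,
        level=level,
        n_reps=n_reps,
        seed=seed,
        exact_ci=exact,
    )


def save_count(estimate: CountEstimate, path, metadata: dict | None = None) -> None:
    doc = estimate.to_dict()
    if metadata:
        doc.update(metadata)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
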