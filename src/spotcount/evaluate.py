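"""Scoring against ground truth: detection matching, AUROC, quality sweep.

Two distinct questions are kept separate on purpose: *detection* (did a
truth source get a candidate at all — measured by greedy matching into
TP/FP/FN) and *classification* (among retained candidates, do real emitters
score above noise — measured by AUROC over the candidates' probabilities).
The quality-sweep harness degrades synthetic image quality on a grid and
reports both, always training the classifier on stacks from one simulated
background and testing on stacks from held-out backgrounds so the score
reflects transfer, not memorized background structure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import simulate as sim
from .calibrate import apply_calibration, build_calibration
from .classify import oob_probabilities, train_forest
from .count import count_report
from .detect import DetectionConfig
from .pipeline import detect_and_featurize, score_candidates
from .features import label_candidates
from .stacks import ValidationError

__all__ = ["EvalResult", "match_detections", "roc_auc", "quality_sweep"]

DEFAULT_MATCH_TOLERANCE = 2.0  # voxels, about one PSF sigma_xy


@dataclass
class EvalResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    auroc: float
    signal_intensity: float
    spot_density: float
    seed: int


def match_detections(
    spots: pd.DataFrame,
    truth: pd.DataFrame,
    tolerance: float = DEFAULT_MATCH_TOLERANCE,
) -> tuple[int, int, int]:
    """Greedy nearest-first matching of signal calls to truth sources.

    Candidate/source pairs within ``tolerance`` voxels are matched in order
    of increasing distance, each side used at most once. Unmatched signal
    calls are false positives; unmatched sources are false negatives.
    ``spots`` should already be restricted to signal-classified rows (a
    ``label`` column, when present, is applied here).
    """
    if "label" in spots.columns:
        spots = spots[spots["label"] == 1]
    src = (
        truth[["z", "y", "x"]].to_numpy(dtype=float)
        if len(truth)
        else np.empty((0, 3))
    )
    if len(spots) == 0:
        return 0, 0, len(src)
    cand = spots[["z", "y", "x"]].to_numpy(dtype=float)
    if len(cand) == 0:
        return 0, 0, len(src)
    if len(src) == 0:
        return 0, len(cand), 0
    d = np.sqrt(((cand[:, None, :] - src[None, :, :]) ** 2).sum(axis=2))
    pairs = np.argwhere(d <= tolerance)
    order = np.argsort(d[pairs[:, 0], pairs[:, 1]], kind="stable")
    used_c = np.zeros(len(cand), dtype=bool)
    used_s = np.zeros(len(src), dtype=bool)
    tp = 0
    for ci, si in pairs[order]:
        if not used_c[ci] and not used_s[si]:
            used_c[ci] = True
            used_s[si] = True
            tp += 1
    fp = int((~used_c).sum())
    fn = int((~used_s).sum())
    return tp, fp, fn


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (rank / Mann-Whitney statistic, tie-aware)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def quality_sweep(
    magnitudes,
    base_config: sim.SimulationConfig,
    background_seeds=(1, 2, 3),
    detection: DetectionConfig | None = None,
    n_trees: int = 200,
    match_tolerance: float = DEFAULT_MATCH_TOLERANCE,
    seed: int = 0,
    n_reps: int = 1000,
) -> pd.DataFrame:
    """Degrade image quality over a magnitude grid and score the pipeline.

    For every magnitude level one stack is simulated per background seed.
    Candidates are auto-labeled against truth; the forest and calibration
    are built from the first background's stacks only (all levels pooled)
    and scored on the held-out backgrounds. One long-format row per
    (magnitude level, test background): detection counts, AUROC of the
    calibrated probabilities, count-interval width, and the realized
    signal-intensity / spot-density metrics. Infeasible cells are flagged
    in the ``status`` column and skipped.
    """
    if len(background_seeds) < 2:
        raise ValidationError("need >= 2 background seeds (train + test)")
    detection = detection or DetectionConfig()

    cells = {}  # (mag, bg) -> dict with labeled table + metrics
    rows = []
    for mag in magnitudes:
        for bi, bg_seed in enumerate(background_seeds):
            if mag <= 0:
                rows.append(
                    {"magnitude": mag, "background": bi + 1, "status": "rejected"}
                )
                continue
            cfg = replace(
                base_config,
                magnitude_mean=float(mag),
                seed=int(seed * 10_000 + round(mag * 10) * 10 + bi),
                stack_id=f"m{mag:g}_b{bi + 1}",
            )
            background = sim.generate_background(
                cfg.shape, cfg.background_params, seed=bg_seed
            )
            try:
                stack, truth = sim.simulate_stack(cfg, background=background)
            except sim.DensityInfeasibleError:
                rows.append(
                    {"magnitude": mag, "background": bi + 1, "status": "infeasible"}
                )
                continue
            table, _ = detect_and_featurize(stack, detection)
            truth_df = pd.DataFrame(
                [
                    {"stack_id": truth.stack_id, "z": z, "y": y, "x": x}
                    for z, y, x, _ in truth.sources
                ]
            )
            labeled = label_candidates(table, truth_df, tolerance=match_tolerance)
            cells[(mag, bi)] = {
                "labeled": labeled,
                "truth_df": truth_df,
                "signal_intensity": sim.signal_intensity_metric(stack, truth),
                "spot_density": sim.spot_density_metric(stack, truth),
            }

    train_parts = [
        c["labeled"] for (mag, bi), c in cells.items() if bi == 0
    ]
    if not train_parts:
        raise ValidationError("no feasible training cells")
    training = pd.concat(train_parts, ignore_index=True)
    model = train_forest(training, n_trees=n_trees, seed=seed + 17)
    p_oob, y_oob, _ = oob_probabilities(model, training)
    curve = build_calibration(p_oob, y_oob)

    for (mag, bi), cell in sorted(cells.items()):
        if bi == 0:
            continue
        scored = score_candidates(cell["labeled"], model, curve)
        try:
            auc = roc_auc(scored["p_calibrated"], scored["label"])
        except ValidationError:
            auc = np.nan
        tp, fp, fn = match_detections(
            scored.assign(label=scored["decision"]),
            cell["truth_df"],
            tolerance=match_tolerance,
        )
        est = count_report(scored, n_reps=n_reps, seed=seed + bi)
        rows.append(
            {
                "magnitude": mag,
                "background": bi + 1,
                "status": "ok",
                "signal_intensity": cell["signal_intensity"],
                "spot_density": cell["spot_density"],
                "n_candidates": len(scored),
                "auroc": auc,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "ci_width": est.ci_high - est.ci_low,
                "point_count": est.point_count,
                "n_true": len(cell["truth_df"]),
            }
        )
    return pd.DataFrame(rows)
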