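"""End-to-end drivers tying detection, features, classification and counting.

``detect_and_featurize`` turns a stack into a candidate feature table;
``score_candidates`` adds preliminary/calibrated probabilities and the hard
decision; ``run_pipeline`` is the file-to-file version used by the CLI.
"""

from __future__ import annotations

import hashlib
import json
import logging

import numpy as np
import pandas as pd

from .calibrate import CalibrationCurve, apply_calibration, decide
from .classify import ForestModel, preliminary_probability
from .count import CountEstimate, count_report, save_count
from .detect import CandidateSpot, DetectionConfig, detect_candidates
from .features import FEATURE_NAMES, SCHEMA_VERSION, candidates_to_table
from .stacks import ImageStack, ValidationError

__all__ = [
    "detect_and_featurize",
    "score_candidates",
    "run_pipeline",
    "SPOT_COLUMNS",
]

logger = logging.getLogger("spotcount")

SPOT_COLUMNS = (
    ["stack_id", "rank", "z", "y", "x"]
    + FEATURE_NAMES
    + ["p_raw", "p_calibrated", "decision"]
)


def detect_and_featurize(
    stack: ImageStack, detection: DetectionConfig | None = None
) -> tuple[pd.DataFrame, list[CandidateSpot]]:
    """Detect candidates in a stack and compute their feature table."""
    detection = detection or DetectionConfig()
    candidates = detect_candidates(stack, detection)
    logger.info("%s: %d candidates retained", stack.stack_id, len(candidates))
    table = candidates_to_table(candidates, stack)
    return table, candidates


def score_candidates(
    table: pd.DataFrame, model: ForestModel, curve: CalibrationCurve
) -> pd.DataFrame:
    """Attach preliminary and calibrated probabilities plus the hard call."""
    if model.schema_version != SCHEMA_VERSION:
        raise ValidationError(
            f"model feature schema v{model.schema_version} does not match "
            f"extractor v{SCHEMA_VERSION}; refusing to score"
        )
    out = table.copy()
    if len(out) == 0:
        out["p_raw"] = np.empty(0)
        out["p_calibrated"] = np.empty(0)
        out["decision"] = np.empty(0, dtype=int)
        return out
    X = out[FEATURE_NAMES].to_numpy(dtype=np.float64)
    p_raw = preliminary_probability(model, X)
    p_cal = apply_calibration(curve, p_raw)
    out["p_raw"] = p_raw
    out["p_calibrated"] = p_cal
    out["decision"] = decide(p_cal)
    return out


def _config_hash(detection: DetectionConfig, model: ForestModel) -> str:
    doc = json.dumps(
        {
            "patch_side": detection.patch_side,
            "mse_cutoff": detection.mse_cutoff,
            "cutoff_multiplier": detection.cutoff_multiplier,
            "persistence_window": detection.persistence_window,
            "model_seed": model.seed,
            "n_trees": model.n_trees,
            "schema": model.schema_version,
        },
        sort_keys=True,
    )
    return hashlib.sha256(doc.encode()).hexdigest()[:12]


def run_pipeline(
    stack: ImageStack,
    model: ForestModel,
    curve: CalibrationCurve,
    detection: DetectionConfig | None = None,
    spots_path=None,
    count_path=None,
    level: float = 0.95,
    n_reps: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, CountEstimate]:
    """Full pass over one stack: detect -> featurize -> score -> count.

    When output paths are given, the spot table is written as CSV with a
    provenance comment line (stack_id, config hash, seed) and the count
    estimate as JSON carrying the same fields, so a run can be reproduced
    exactly from its outputs.
    """
    detection = detection or DetectionConfig()
    table, _ = detect_and_featurize(stack, detection)
    scored = score_candidates(table, model, curve)
    logger.info(
        "%s: %d candidates scored, %d classified signal",
        stack.stack_id,
        len(scored),
        int(scored["decision"].sum()) if len(scored) else 0,
    )
    estimate = count_report(scored, level=level, n_reps=n_reps, seed=seed)
    cfg_hash = _config_hash(detection, model)
    if spots_path is not None:
        with open(spots_path, "w") as fh:
            fh.write(
                f"# stack_id={stack.stack_id} config={cfg_hash} seed={seed} "
                "coords=0-based (z=page, y=row, x=col)\n"
            )
            scored.to_csv(fh, index=False, float_format="%.17g")
    if count_path is not None:
        save_count(
            estimate,
            count_path,
            metadata={"stack_id": stack.stack_id, "config": cfg_hash},
        )
    return scored, estimate
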