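"""Per-candidate feature vectors and training-set assembly.

The classifier sees each candidate as a fixed 13-component vector covering
the attribute families a curator inspects when deciding whether a local
maximum is a real emitter: raw and background-corrected brightness, the
fitted Gaussian's shape parameters and fit quality (absolute and
scale-free), local signal-to-noise, spot footprint, and focal-plane
prominence relative to the neighboring z-planes. The schema is versioned so
a trained model refuses to score vectors produced by a different extractor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .detect import CandidateSpot, GaussianFit
from .stacks import ImageStack, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "SCHEMA_VERSION",
    "compute_features",
    "candidates_to_table",
    "label_candidates",
    "TRAINING_COLUMNS",
]

SCHEMA_VERSION = 1

FEATURE_NAMES = [
    "center_intensity",        # f1 raw center-pixel intensity
    "corrected_intensity",     # f2 center minus border-ring median
    "fit_amplitude",           # f3 fitted Gaussian amplitude A
    "fit_sigma",               # f4 fitted Gaussian width (pixels)
    "fit_offset",              # f5 fitted baseline c
    "fit_mse",                 # f6 mean squared fit residual
    "fit_mse_rel",             # f7 mse / patch variance (scale-free fit quality)
    "local_snr",               # f8 A / border-ring sd
    "center_shift",            # f9 fitted-center distance from patch center
    "mass_above_border",       # f10 patch total above the border median
    "halfmax_area_frac",       # f11 fraction of pixels above border median + A/2
    "z_prominence",            # f12 center minus mean of (y,x) in planes z+-1
    "fit_ok",                  # f13 1 if the Gaussian fit converged
]

TRAINING_COLUMNS = (
    ["stack_id", "rank", "z", "y", "x"] + FEATURE_NAMES + ["label", "curator_id"]
)


def compute_features(
    candidate: CandidateSpot, fit: GaussianFit | None = None, stack: ImageStack | None = None
) -> np.ndarray:
    """13-component feature vector for one candidate. Deterministic.

    ``fit`` defaults to the candidate's attached fit. ``stack`` supplies the
    z-context feature; without it the focal-prominence feature is 0 (used
    only in degenerate single-plane situations).
    """
    fit = fit if fit is not None else candidate.fit
    if fit is None:
        raise ValidationError("candidate has no Gaussian fit")
    patch = np.asarray(candidate.patch, dtype=np.float64)
    side = patch.shape[0]
    half = side // 2
    center = float(patch[half, half])
    border = np.concatenate(
        [patch[0, :], patch[-1, :], patch[1:-1, 0], patch[1:-1, -1]]
    )
    border_med = float(np.median(border))
    border_sd = float(border.std())
    patch_var = float(patch.var())

    corrected = center - border_med
    mse_rel = fit.mse / patch_var if patch_var > 0 else 0.0
    local_snr = fit.amplitude / border_sd if border_sd > 0 else 0.0
    center_shift = float(np.hypot(fit.center_dy, fit.center_dx))
    mass_above = float(np.clip(patch - border_med, 0.0, None).sum())
    half_level = border_med + fit.amplitude / 2.0
    halfmax_frac = float(np.mean(patch > half_level))

    z_prom = 0.0
    if stack is not None:
        nz = stack.shape[0]
        z, y, x = candidate.z, candidate.y, candidate.x
        neigh = [stack.voxels[zz, y, x] for zz in (z - 1, z + 1) if 0 <= zz < nz]
        if neigh:
            z_prom = center - float(np.mean(neigh))

    vec = np.array(
        [
            center,
            corrected,
            fit.amplitude,
            fit.sigma,
            fit.offset,
            fit.mse,
            mse_rel,
            local_snr,
            center_shift,
            mass_above,
            halfmax_frac,
            z_prom,
            1.0 if fit.ok else 0.0,
        ],
        dtype=np.float64,
    )
    if not np.all(np.isfinite(vec)):
        bad = FEATURE_NAMES[int(np.argmin(np.isfinite(vec)))]
        raise ValidationError(f"non-finite feature: {bad}")
    return vec


def candidates_to_table(
    candidates: list[CandidateSpot], stack: ImageStack
) -> pd.DataFrame:
    """Feature table for a retained candidate list (one row per candidate)."""
    rows = []
    for cand in candidates:
        vec = compute_features(cand, stack=stack)
        row = {
            "stack_id": cand.stack_id,
            "rank": cand.rank,
            "z": cand.z,
            "y": cand.y,
            "x": cand.x,
        }
        row.update(dict(zip(FEATURE_NAMES, vec)))
        rows.append(row)
    cols = ["stack_id", "rank", "z", "y", "x"] + FEATURE_NAMES
    return pd.DataFrame(rows, columns=cols)


def label_candidates(
    candidates: pd.DataFrame,
    truth: pd.DataFrame,
    tolerance: float = 2.0,
    curator_id: str = "auto",
) -> pd.DataFrame:
    """Auto-curate candidates against ground truth.

    A candidate is labeled signal (1) iff it lies within ``tolerance`` voxels
    (Euclidean) of a not-yet-matched truth source; matching is greedy in rank
    order and each source is used at most once. Everything else is noise (0).
    Replaces interactive curation for synthetic data, and defines the
    file-based curation format for real data.
    """
    required = {"stack_id", "rank", "z", "y", "x"}
    if not required <= set(candidates.columns):
        raise ValidationError(f"candidates table needs columns {sorted(required)}")
    out = candidates.copy()
    out["label"] = 0
    out["curator_id"] = curator_id

    for sid, grp in candidates.groupby("stack_id", sort=False):
        coords = grp[["z", "y", "x"]].to_numpy(dtype=float)
        if len(coords) != len(np.unique(coords, axis=0)):
            raise ValidationError(f"duplicate candidate coordinates in stack {sid}")
        tgrp = truth[truth["stack_id"].astype(str) == str(sid)]
        if tgrp.empty:
            continue
        src = tgrp[["z", "y", "x"]].to_numpy(dtype=float)
        used = np.zeros(len(src), dtype=bool)
        order = grp.sort_values("rank").index
        for idx in order:
            c = candidates.loc[idx, ["z", "y", "x"]].to_numpy(dtype=float)
            d = np.sqrt(((src - c) ** 2).sum(axis=1))
            d[used] = np.inf
            j = int(np.argmin(d))
            if d[j] <= tolerance:
                used[j] = True
                out.loc[idx, "label"] = 1
    return out
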