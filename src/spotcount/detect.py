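"""Candidate-spot detection: 3D local maxima, ranking, 2D Gaussian fits.

The candidate generator of the pipeline. Every voxel strictly brighter than
all of its 26-connected neighbors is a candidate; candidates are ranked by
background-corrected intensity and then fit, in rank order, to an isotropic
2D Gaussian in the candidate's own z-plane. A persistence rule on the fit
mean-squared error truncates the ranked list once it has descended into
maxima that are never true emitters, which keeps the downstream classifier
from having to score tens of thousands of noise maxima.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .stacks import ImageStack, ValidationError

__all__ = [
    "CandidateSpot",
    "GaussianFit",
    "DetectionConfig",
    "find_local_maxima",
    "extract_patch",
    "background_corrected_intensity",
    "rank_candidates",
    "fit_gaussian_2d",
    "truncate_candidates",
    "detect_candidates",
]

DEFAULT_PATCH_SIDE = 7
DEFAULT_PERSISTENCE_WINDOW = 30
DEFAULT_CUTOFF_MULTIPLIER = 1.5
FIT_CHUNK = 4096


@dataclass(frozen=True)
class GaussianFit:
    """Isotropic 2D Gaussian + constant offset fitted over a patch.

    ``center_dy``/``center_dx`` are the fitted center's offset from the patch
    center in pixels. ``ok`` is False when the optimizer failed and the
    returned parameters are the initialization evaluated as-is.
    """

    amplitude: float
    center_dy: float
    center_dx: float
    sigma: float
    offset: float
    mse: float
    ok: bool = True


@dataclass(frozen=True)
class CandidateSpot:
    """A ranked local intensity maximum with its fitting patch."""

    stack_id: str
    z: int
    y: int
    x: int
    patch: np.ndarray
    rank: int
    corrected_intensity: float
    fit: GaussianFit | None = None


@dataclass
class DetectionConfig:
    """Detection knobs.

    ``mse_cutoff`` fixes the truncation cutoff explicitly; when None it is
    calibrated per stack as ``cutoff_multiplier`` x the median fit MSE of a
    sample of the dimmest decile of candidates (maxima that are essentially
    never real emitters, so their fit error estimates the noise floor).
    """

    patch_side: int = DEFAULT_PATCH_SIDE
    mse_cutoff: float | None = None
    cutoff_multiplier: float = DEFAULT_CUTOFF_MULTIPLIER
    persistence_window: int = DEFAULT_PERSISTENCE_WINDOW
    cutoff_sample_size: int = 120
    min_retained: int = 150
    seed: int = 0

    def validate(self) -> None:
        if self.patch_side < 3 or self.patch_side % 2 == 0:
            raise ValidationError("patch_side must be odd and >= 3")
        if self.persistence_window < 1:
            raise ValidationError("persistence_window must be >= 1")
        if self.mse_cutoff is not None and self.mse_cutoff < 0:
            raise ValidationError("mse_cutoff must be >= 0")
        if self.cutoff_multiplier <= 0:
            raise ValidationError("cutoff_multiplier must be > 0")
        if self.min_retained < 0:
            raise ValidationError("min_retained must be >= 0")


def find_local_maxima(stack: ImageStack) -> list[tuple[int, int, int, float]]:
    """All voxels strictly greater than every existing 26-connected neighbor.

    Border voxels compare against their in-bounds neighbors only. Plateaus
    (ties with a neighbor) produce no maximum.
    """
    from scipy import ndimage

    v = stack.voxels
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neighbor_max = ndimage.maximum_filter(
        v, footprint=footprint, mode="constant", cval=-np.inf
    )
    zz, yy, xx = np.nonzero(v > neighbor_max)
    return [
        (int(z), int(y), int(x), float(v[z, y, x])) for z, y, x in zip(zz, yy, xx)
    ]


def _padded_plane(stack: ImageStack, z: int, half: int) -> np.ndarray:
    return np.pad(stack.voxels[z], half, mode="reflect")


def extract_patch(stack: ImageStack, z: int, y: int, x: int, side: int) -> np.ndarray:
    """Odd-sided 2D window from plane ``z`` centered at ``(y, x)``.

    Borders are mirror-padded so every candidate gets a full-sized patch with
    scale-consistent statistics.
    """
    if side % 2 == 0:
        raise ValidationError("patch side must be odd")
    half = side // 2
    plane = _padded_plane(stack, z, half)
    return plane[y : y + side, x : x + side].copy()


def background_corrected_intensity(patch: np.ndarray) -> float:
    """Center-pixel intensity minus the median of the patch's border ring."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or patch.shape[0] != patch.shape[1] or patch.shape[0] % 2 == 0:
        raise ValidationError("patch must be square with odd side")
    side = patch.shape[0]
    center = patch[side // 2, side // 2]
    border = np.concatenate(
        [patch[0, :], patch[-1, :], patch[1:-1, 0], patch[1:-1, -1]]
    )
    return float(center - np.median(border))


def rank_candidates(
    maxima: list[tuple[int, int, int, float]],
    stack: ImageStack,
    patch_side: int = DEFAULT_PATCH_SIDE,
) -> list[CandidateSpot]:
    """Order maxima by descending background-corrected intensity.

    Ties break by (z, y, x) lexicographic order so ranking is deterministic
    on quantized data.
    """
    if not maxima:
        return []
    half = patch_side // 2
    coords = np.array([(z, y, x) for z, y, x, _ in maxima], dtype=np.intp)
    patches = np.empty((len(coords), patch_side, patch_side))
    offs = np.arange(patch_side)
    # Pad each needed plane once and gather all patches of that plane in one
    # fancy-indexing shot; the per-candidate loop would dominate runtime on
    # stacks with tens of thousands of maxima.
    for z in np.unique(coords[:, 0]):
        sel = np.nonzero(coords[:, 0] == z)[0]
        plane = _padded_plane(stack, int(z), half)
        ys = coords[sel, 1]
        xs = coords[sel, 2]
        patches[sel] = plane[
            (ys[:, None, None] + offs[None, :, None]),
            (xs[:, None, None] + offs[None, None, :]),
        ]
    border = np.concatenate(
        [
            patches[:, 0, :],
            patches[:, -1, :],
            patches[:, 1:-1, 0],
            patches[:, 1:-1, -1],
        ],
        axis=1,
    )
    corr = patches[:, half, half] - np.median(border, axis=1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], -corr))
    return [
        CandidateSpot(
            stack_id=stack.stack_id,
            z=int(coords[i, 0]),
            y=int(coords[i, 1]),
            x=int(coords[i, 2]),
            patch=patches[i],
            rank=r + 1,
            corrected_intensity=float(corr[i]),
        )
        for r, i in enumerate(order)
    ]


def _model_batch(theta: np.ndarray, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    """Evaluate A*exp(-r^2/(2 sigma^2)) + c for a (n, 5) parameter batch."""
    a = theta[:, 0, None]
    dy = theta[:, 1, None]
    dx = theta[:, 2, None]
    sigma = theta[:, 3, None]
    c = theta[:, 4, None]
    r2 = (yy[None, :] - dy) ** 2 + (xx[None, :] - dx) ** 2
    return a * np.exp(-r2 / (2.0 * sigma**2)) + c


def fit_gaussian_2d_batch(
    patches: np.ndarray, max_iter: int = 60
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``A*exp(-r^2/(2*sigma^2)) + c`` to a batch of odd square patches.

    Vectorized Levenberg-Marquardt with an analytic Jacobian: all patches
    advance together, each carrying its own damping factor, so fitting tens
    of thousands of candidate windows costs seconds rather than minutes.
    Initialization per patch: A = center - min, center offsets 0,
    sigma = side/6, c = patch min.

    Returns ``(theta, mse, ok)`` where theta is (n, 5) as
    (amplitude, dy, dx, sigma, offset); patches whose optimization failed
    (non-finite or no cost improvement) keep the evaluated initialization
    and get ``ok=False``.
    """
    patches = np.asarray(patches, dtype=np.float64)
    if patches.ndim == 2:
        patches = patches[None]
    n, s1, s2 = patches.shape
    if s1 != s2 or s1 % 2 == 0:
        raise ValidationError("patches must be square with odd side")
    side = s1
    half = side // 2
    npx = side * side
    yy, xx = np.meshgrid(
        np.arange(-half, half + 1, dtype=np.float64),
        np.arange(-half, half + 1, dtype=np.float64),
        indexing="ij",
    )
    yy = yy.ravel()
    xx = xx.ravel()
    Y = patches.reshape(n, npx)

    pmin = Y.min(axis=1)
    center = patches[:, half, half]
    theta0 = np.column_stack(
        [center - pmin, np.zeros(n), np.zeros(n), np.full(n, side / 6.0), pmin]
    )
    theta = theta0.copy()
    sigma_lo, sigma_hi = 0.05, 4.0 * side

    def cost_of(th):
        r = _model_batch(th, yy, xx) - Y
        return np.einsum("ij,ij->i", r, r)

    cost = cost_of(theta)
    cost0 = cost.copy()
    lam = np.full(n, 1e-3)
    eye = np.eye(5)
    stalls = 0

    for _ in range(max_iter):
        a = theta[:, 0, None]
        dy = theta[:, 1, None]
        dx = theta[:, 2, None]
        sg = theta[:, 3, None]
        c = theta[:, 4, None]
        uy = yy[None, :] - dy
        ux = xx[None, :] - dx
        r2 = uy**2 + ux**2
        E = np.exp(-r2 / (2.0 * sg**2))
        f = a * E + c
        r = f - Y
        J = np.empty((n, npx, 5))
        J[:, :, 0] = E
        J[:, :, 1] = a * E * uy / sg**2
        J[:, :, 2] = a * E * ux / sg**2
        J[:, :, 3] = a * E * r2 / sg**3
        J[:, :, 4] = 1.0
        g = np.einsum("npk,np->nk", J, r)
        H = np.einsum("npk,npl->nkl", J, J)
        diag = np.einsum("nkk->nk", H)
        A_mat = H + lam[:, None, None] * (diag[:, None, :] * eye[None]) + 1e-12 * eye[None]
        try:
            delta = np.linalg.solve(A_mat, -g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            A_mat = A_mat + 1e-6 * eye[None]
            delta = np.linalg.solve(A_mat, -g[:, :, None])[:, :, 0]
        trial = theta + delta
        trial[:, 3] = np.clip(np.abs(trial[:, 3]), sigma_lo, sigma_hi)
        trial_cost = cost_of(trial)
        improved = np.isfinite(trial_cost) & (trial_cost < cost)
        rel_step = np.max(np.abs(delta[improved]) / (1.0 + np.abs(theta[improved]))) if np.any(improved) else 0.0
        theta[improved] = trial[improved]
        cost[improved] = trial_cost[improved]
        lam = np.where(improved, lam / 3.0, np.minimum(lam * 4.0, 1e9))
        stalls = stalls + 1 if (not np.any(improved) or rel_step < 1e-12) else 0
        if stalls >= 4:
            break

    finite = np.all(np.isfinite(theta), axis=1) & np.isfinite(cost)
    ok = finite & (cost <= cost0 + 1e-9 * (1.0 + cost0))
    theta[~finite] = theta0[~finite]
    cost[~finite] = cost0[~finite]
    theta[:, 3] = np.abs(theta[:, 3])
    mse = cost / npx
    return theta, mse, ok


def fit_gaussian_2d(patch: np.ndarray) -> GaussianFit:
    """Least-squares fit of an isotropic 2D Gaussian + offset over one patch.

    Thin wrapper over :func:`fit_gaussian_2d_batch` for a single window.
    A failed optimization returns the initialization evaluated as-is,
    flagged ``ok=False``.
    """
    theta, mse, ok = fit_gaussian_2d_batch(np.asarray(patch, dtype=np.float64))
    a, dy, dx, sigma, c = theta[0]
    return GaussianFit(
        amplitude=float(a),
        center_dy=float(dy),
        center_dx=float(dx),
        sigma=float(sigma),
        offset=float(c),
        mse=float(mse[0]),
        ok=bool(ok[0]),
    )


def truncate_candidates(
    candidates: list[CandidateSpot],
    mse_cutoff: float,
    persistence_window: int = DEFAULT_PERSISTENCE_WINDOW,
) -> list[CandidateSpot]:
    """Cut the ranked list at the first run of persistently sub-cutoff fits.

    Scans in rank order counting consecutive fits with mse < cutoff; upon
    reaching ``persistence_window`` consecutive sub-cutoff fits, returns all
    candidates ranked strictly before the first member of that run. Never
    triggered means everything is kept. Output is always a prefix of the
    input.
    """
    if persistence_window < 1:
        raise ValidationError("persistence_window must be >= 1")
    run = 0
    for i, cand in enumerate(candidates):
        if cand.fit is None:
            raise ValidationError("truncate_candidates requires fitted candidates")
        if cand.fit.mse < mse_cutoff:
            run += 1
            if run >= persistence_window:
                return list(candidates[: i - persistence_window + 1])
        else:
            run = 0
    return list(candidates)


def _calibrate_cutoff(
    ranked: list[CandidateSpot], config: DetectionConfig
) -> float:
    """Estimate the noise-floor MSE from the dimmest decile of candidates."""
    n = len(ranked)
    decile = ranked[int(np.floor(0.9 * n)) :] or ranked[-1:]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    if len(decile) > config.cutoff_sample_size:
        idx = rng.choice(len(decile), size=config.cutoff_sample_size, replace=False)
        sample = [decile[i] for i in sorted(idx)]
    else:
        sample = decile
    _, mses, _ = fit_gaussian_2d_batch(np.stack([c.patch for c in sample]))
    return config.cutoff_multiplier * float(np.median(mses))


def detect_candidates(
    stack: ImageStack, config: DetectionConfig | None = None
) -> list[CandidateSpot]:
    """Full detection pass: maxima -> rank -> sequential fit -> truncate.

    Fits are performed lazily in rank order and stop as soon as the
    persistence rule fires, so the cost scales with the number of retained
    candidates rather than with the raw count of local maxima.
    """
    config = config or DetectionConfig()
    config.validate()
    maxima = find_local_maxima(stack)
    ranked = rank_candidates(maxima, stack, patch_side=config.patch_side)
    if not ranked:
        return []

    cutoff = config.mse_cutoff
    adaptive = cutoff is None
    if adaptive:
        cutoff = _calibrate_cutoff(ranked, config)

    # Fit in rank order, chunked so the batch fitter stays hot while the
    # persistence rule can still stop the scan early. In adaptive mode a
    # retention floor keeps at least ``min_retained`` candidates even if the
    # persistence rule fires earlier: downstream training and calibration
    # need a pool of noise candidates to learn from, and on clean stacks the
    # rule can otherwise fire immediately after the last real spot.
    floor = min(config.min_retained, len(ranked)) if adaptive else 0
    run = 0
    w = config.persistence_window
    cut_at: int | None = None
    fitted: list[CandidateSpot] = []
    for start in range(0, len(ranked), FIT_CHUNK):
        chunk = ranked[start : start + FIT_CHUNK]
        theta, mses, oks = fit_gaussian_2d_batch(np.stack([c.patch for c in chunk]))
        for cand, th, mse, ok in zip(chunk, theta, mses, oks):
            fit = GaussianFit(
                amplitude=float(th[0]),
                center_dy=float(th[1]),
                center_dx=float(th[2]),
                sigma=float(th[3]),
                offset=float(th[4]),
                mse=float(mse),
                ok=bool(ok),
            )
            fitted.append(replace(cand, fit=fit))
            if cut_at is None:
                if fit.mse < cutoff:
                    run += 1
                    if run >= w:
                        cut_at = max(len(fitted) - w, floor)
                else:
                    run = 0
            if cut_at is not None and len(fitted) >= cut_at:
                return fitted[:cut_at]
    return fitted if cut_at is None else fitted[:cut_at]
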