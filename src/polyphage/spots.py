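"""smRNA-FISH spot detection and 3D Gaussian fitting.

The pipeline mirrors the standard single-molecule FISH quantification chain:
the stack is convolved with a Gaussian to remove noise, spots are detected as
local maxima above a threshold derived from a negative-control image, and each
spot is fitted with a 3D Gaussian

    I(x, y, z) = B + A * exp(-((x-x0)^2/(2*sx^2) + (y-y0)^2/(2*sy^2)
                              + (z-z0)^2/(2*sz^2)))

whose integrated, background-subtracted intensity is the analytic volume
``A * (2*pi)**1.5 * sx * sy * sz``.  Spots in close proximity are fitted
jointly as a sum of Gaussians over one shared background.

Conventions: voxel arrays are indexed ``(z, y, x)``; public coordinate and
sigma tuples are ordered ``(x, y, z)``.  Candidate voxels are strictly greater
than all 26-connected neighbours (plateaus contribute their lowest-index
voxel) and strictly greater than the threshold, so running detection on the
negative control itself yields no spots under the default threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

__all__ = [
    "ImageStack",
    "SpotFit",
    "SpotFitConfig",
    "DetectionConfig",
    "gaussian_denoise",
    "threshold_from_negative_control",
    "detect_local_maxima",
    "fit_spot",
    "fit_multi_spot",
    "group_candidates",
    "detect_spots",
]

_TWO_PI_32 = (2.0 * math.pi) ** 1.5


@dataclass
class ImageStack:
    """A single-channel 3D stack, voxels indexed (z, y, x)."""

    voxels: np.ndarray
    channel: str = ""
    voxel_size_xy: float = 0.11  # micrometres per pixel
    z_step: float = 1.0  # micrometres per plane

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ValueError(f"voxels must be a 3D array, got shape {v.shape}")
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise ValueError("intensities must be finite and non-negative")
        self.voxels = v

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class SpotFit:
    """A fitted 3D Gaussian spot (coordinates and sigmas ordered x, y, z)."""

    center: tuple[float, float, float]
    sigma: tuple[float, float, float]
    amplitude: float
    background: float
    integrated_intensity: float
    residual: float
    multi: bool = False
    converged: bool = True
    channel: str = ""


@dataclass(frozen=True)
class SpotFitConfig:
    """Fit-window geometry, initial widths and bounds (x, y, z order)."""

    window_radius: tuple[int, int, int] = (4, 4, 3)
    init_sigma: tuple[float, float, float] = (1.4, 1.4, 1.2)
    sigma_min: float = 0.3
    # spots wider than ~2x the nominal PSF are background structure, not
    # diffraction-limited transcripts; fits pinned at this bound are rejected
    sigma_max: float = 3.0
    max_group: int = 5  # larger unresolved groups are excluded
    proximity_radius: float | None = None  # extra centre-distance grouping rule


@dataclass(frozen=True)
class DetectionConfig:
    """End-to-end detection settings for :func:`detect_spots`."""

    denoise_sigma: tuple[float, float, float] | None = None  # (x, y, z); None = default
    threshold_method: str = "max_maxima"
    threshold_quantile: float = 0.999
    min_separation_vox: float = 2.0
    fit: SpotFitConfig = field(default_factory=SpotFitConfig)


def default_denoise_sigma(stack: ImageStack) -> tuple[float, float, float]:
    """(1, 1, voxel_xy / z_step) voxels — isotropic in physical units."""
    return (1.0, 1.0, stack.voxel_size_xy / stack.z_step)


def gaussian_denoise(
    stack: ImageStack, sigma_vox: tuple[float, float, float]
) -> ImageStack:
    """Convolve with a normalized 3D Gaussian kernel (reflective boundaries).

    ``sigma_vox`` is ordered (x, y, z); a zero sigma on every axis returns the
    input unchanged.  Total intensity is conserved away from the boundary.
    """
    sx, sy, sz = sigma_vox
    if min(sx, sy, sz) < 0:
        raise ValueError("denoise sigmas must be non-negative")
    if sx == sy == sz == 0:
        return stack
    out = ndimage.gaussian_filter(stack.voxels, sigma=(sz, sy, sx), mode="reflect")
    return replace(stack, voxels=np.clip(out, 0, None))


def _regional_maxima(voxels: np.ndarray, threshold: float) -> list[tuple[int, int, int]]:
    """Voxels strictly greater than all 26-neighbours and the threshold.

    A constant plateau that is a regional maximum contributes its lowest
    (z, y, x) voxel.
    """
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    neigh_max = ndimage.maximum_filter(
        voxels, footprint=footprint, mode="constant", cval=-np.inf
    )
    above = voxels > threshold
    strict = (voxels > neigh_max) & above
    cands = list(zip(*np.nonzero(strict)))
    plateau = (voxels == neigh_max) & above
    if plateau.any():
        labels, n = ndimage.label(plateau, structure=np.ones((3, 3, 3), dtype=bool))
        for lab in range(1, n + 1):
            idx = np.argwhere(labels == lab)
            # all component voxels share one value and no neighbour exceeds it
            zyx = idx[np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))][0]
            cands.append(tuple(int(c) for c in zyx))
    return sorted(cands)


def threshold_from_negative_control(
    neg: ImageStack, method: str = "max_maxima", q: float = 0.999
) -> float:
    """Detection threshold from a (denoised) negative-control stack.

    ``max_maxima`` returns the maximum intensity among the control's local
    maxima; ``quantile`` returns the ``q``-quantile of those intensities.
    With the strict ``>`` comparison used by detection, the ``max_maxima``
    threshold guarantees zero detections on the control itself.
    """
    v = neg.voxels
    if v.size == 0:
        raise ValueError("negative control has no voxels")
    maxima = _regional_maxima(v, -np.inf)
    intensities = np.array([v[c] for c in maxima]) if maxima else v.ravel()
    if method == "max_maxima":
        return float(intensities.max())
    if method == "quantile":
        return float(np.quantile(intensities, q))
    raise ValueError(f"unknown threshold method {method!r}")


def detect_local_maxima(
    stack: ImageStack, threshold: float, min_separation_vox: float = 2.0
) -> list[tuple[int, int, int]]:
    """Candidate spot voxels (z, y, x) above ``threshold``.

    Candidates closer than ``min_separation_vox`` (Euclidean, in voxels) are
    merged keeping the brighter one.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    cands = _regional_maxima(stack.voxels, threshold)
    if min_separation_vox <= 0 or len(cands) < 2:
        return cands
    v = stack.voxels
    order = sorted(cands, key=lambda c: (-v[c], c))
    kept: list[tuple[int, int, int]] = []
    arr = np.empty((0, 3))
    for c in order:
        if arr.size and np.min(np.linalg.norm(arr - np.array(c), axis=1)) < min_separation_vox:
            continue
        kept.append(c)
        arr = np.vstack([arr, c])
    return sorted(kept)


def _window_slices(
    shape: tuple[int, int, int],
    candidate: tuple[int, int, int],
    radius_xyz: tuple[int, int, int],
) -> tuple[slice, slice, slice]:
    rx, ry, rz = radius_xyz
    rzyx = (rz, ry, rx)
    return tuple(
        slice(max(0, c - r), min(n, c + r + 1))
        for c, r, n in zip(candidate, rzyx, shape)
    )


def _grids(slices: tuple[slice, slice, slice]) -> tuple[np.ndarray, ...]:
    zz, yy, xx = np.meshgrid(
        *(np.arange(s.start, s.stop, dtype=float) for s in slices), indexing="ij"
    )
    return zz.ravel(), yy.ravel(), xx.ravel()


def _model_and_jac(p: np.ndarray, zz, yy, xx, k: int):
    """Sum of k Gaussians + shared background; returns (model, jacobian)."""
    n = zz.size
    model = np.full(n, p[0])
    jac = np.zeros((n, 1 + 7 * k))
    jac[:, 0] = 1.0
    for i in range(k):
        A, z0, y0, x0, sz, sy, sx = p[1 + 7 * i : 8 + 7 * i]
        dz, dy, dx = zz - z0, yy - y0, xx - x0
        g = np.exp(-(dz**2 / (2 * sz**2) + dy**2 / (2 * sy**2) + dx**2 / (2 * sx**2)))
        model += A * g
        base = 1 + 7 * i
        jac[:, base] = g
        jac[:, base + 1] = A * g * dz / sz**2
        jac[:, base + 2] = A * g * dy / sy**2
        jac[:, base + 3] = A * g * dx / sx**2
        jac[:, base + 4] = A * g * dz**2 / sz**3
        jac[:, base + 5] = A * g * dy**2 / sy**3
        jac[:, base + 6] = A * g * dx**2 / sx**3
    return model, jac


def _joint_fit(
    stack: ImageStack,
    candidates: Sequence[tuple[int, int, int]],
    config: SpotFitConfig,
    multi: bool,
) -> list[SpotFit]:
    v = stack.voxels
    k = len(candidates)
    boxes = [_window_slices(v.shape, c, config.window_radius) for c in candidates]
    union = tuple(
        slice(min(b[d].start for b in boxes), max(b[d].stop for b in boxes))
        for d in range(3)
    )
    zz, yy, xx = _grids(union)
    data = v[union].ravel()
    n_params = 1 + 7 * k
    if data.size < n_params:
        return [
            SpotFit(
                center=(float(c[2]), float(c[1]), float(c[0])),
                sigma=config.init_sigma,
                amplitude=0.0,
                background=0.0,
                integrated_intensity=0.0,
                residual=float("nan"),
                multi=multi,
                converged=False,
                channel=stack.channel,
            )
            for c in candidates
        ]
    bg0 = float(data.min())
    sx0, sy0, sz0 = config.init_sigma
    p0 = [bg0]
    lo = [0.0]
    hi = [np.inf]
    for c in candidates:
        a0 = max(float(v[c]) - bg0, 1e-6)
        p0 += [a0, float(c[0]), float(c[1]), float(c[2]), sz0, sy0, sx0]
        lo += [0.0, union[0].start - 1.0, union[1].start - 1.0, union[2].start - 1.0]
        lo += [config.sigma_min] * 3
        hi += [np.inf, union[0].stop, union[1].stop, union[2].stop]
        hi += [config.sigma_max] * 3
    p0 = np.clip(np.asarray(p0, dtype=float), lo, hi)

    def resid(p):
        model, _ = _model_and_jac(p, zz, yy, xx, k)
        return model - data

    def jac(p):
        _, j = _model_and_jac(p, zz, yy, xx, k)
        return j

    sol = least_squares(resid, p0, jac=jac, bounds=(lo, hi), method="trf", xtol=1e-10)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    fits = []
    for i in range(k):
        A, z0, y0, x0, sz, sy, sx = sol.x[1 + 7 * i : 8 + 7 * i]
        # a width pinned at the upper bound is a runaway fit of background
        # structure, not a diffraction-limited spot
        widths_ok = max(sx, sy, sz) < 0.99 * config.sigma_max
        fits.append(
            SpotFit(
                center=(float(x0), float(y0), float(z0)),
                sigma=(float(sx), float(sy), float(sz)),
                amplitude=float(A),
                background=float(sol.x[0]),
                integrated_intensity=float(A * _TWO_PI_32 * sx * sy * sz),
                residual=rms,
                multi=multi,
                converged=bool(sol.success) and widths_ok,
                channel=stack.channel,
            )
        )
    return fits


def fit_spot(
    stack: ImageStack,
    candidate: tuple[int, int, int],
    config: SpotFitConfig = SpotFitConfig(),
) -> SpotFit:
    """Least-squares single-Gaussian fit in a window around ``candidate`` (z, y, x).

    Initialized with ``A = peak - window minimum``, ``B = window minimum`` and
    the configured sigmas.  A degenerate window (fewer voxels than parameters)
    returns a fit flagged ``converged=False``.
    """
    return _joint_fit(stack, [candidate], config, multi=False)[0]


def fit_multi_spot(
    stack: ImageStack,
    candidate_group: Sequence[tuple[int, int, int]],
    config: SpotFitConfig = SpotFitConfig(),
) -> list[SpotFit]:
    """Joint fit of a group of nearby candidates as a sum of Gaussians.

    A single-candidate group falls back to :func:`fit_spot`.  Groups larger
    than ``config.max_group`` are unresolved: an empty list is returned and
    the group is excluded downstream.
    """
    if len(candidate_group) == 0:
        return []
    if len(candidate_group) == 1:
        return [fit_spot(stack, candidate_group[0], config)]
    if len(candidate_group) > config.max_group:
        return []
    return _joint_fit(stack, list(candidate_group), config, multi=True)


def group_candidates(
    candidates: Sequence[tuple[int, int, int]],
    config: SpotFitConfig = SpotFitConfig(),
) -> list[list[tuple[int, int, int]]]:
    """Partition candidates into proximity groups for joint fitting.

    Two candidates are connected when their fit windows overlap (per-axis
    centre distance <= 2 * radius) or, if ``config.proximity_radius`` is set,
    when their Euclidean distance is below it; groups are the connected
    components.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    rx, ry, rz = config.window_radius
    lim = np.array([2 * rz, 2 * ry, 2 * rx])
    pts = np.asarray(candidates, dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = np.abs(pts[i] - pts[j])
            near = np.all(d <= lim)
            if not near and config.proximity_radius is not None:
                near = float(np.linalg.norm(d)) < config.proximity_radius
            if near:
                parent[find(i)] = find(j)
    groups: dict[int, list[tuple[int, int, int]]] = {}
    for i, c in enumerate(candidates):
        groups.setdefault(find(i), []).append(c)
    return [sorted(g) for g in sorted(groups.values(), key=lambda g: min(g))]


def detect_spots(
    stack: ImageStack,
    negative_control: ImageStack,
    config: DetectionConfig = DetectionConfig(),
) -> tuple[list[SpotFit], dict]:
    """Full chain: denoise -> control threshold -> maxima -> (multi-)Gaussian fits.

    Returns the converged fits plus a report dict with the threshold, the
    counts at each stage and the number of unresolved (oversize) groups.
    """
    sigma = config.denoise_sigma or default_denoise_sigma(stack)
    sm = gaussian_denoise(stack, sigma)
    neg = gaussian_denoise(negative_control, sigma)
    threshold = threshold_from_negative_control(
        neg, config.threshold_method, config.threshold_quantile
    )
    cands = detect_local_maxima(sm, threshold, config.min_separation_vox)
    groups = group_candidates(cands, config.fit)
    fits: list[SpotFit] = []
    n_unresolved = 0
    for g in groups:
        res = fit_multi_spot(sm, g, config.fit)
        if not res and len(g) > config.fit.max_group:
            n_unresolved += 1
        fits.extend(f for f in res if f.converged)
    report = {
        "threshold": threshold,
        "threshold_method": config.threshold_method,
        "denoise_sigma": tuple(sigma),
        "n_candidates": len(cands),
        "n_groups": len(groups),
        "n_unresolved_groups": n_unresolved,
        "n_spots": len(fits),
    }
    return fits, report
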