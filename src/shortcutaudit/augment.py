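"""Stochastic geometric distortions for shortcut-robust training and TTA.

Four operators — rotation, shear, scaling and fisheye distortion — implemented
for 2D images and 3D volumes, with modality presets:

========  =================  ==================  ============  =====
modality  rotation (deg)     shear (radians)     scale         k
========  =================  ==================  ============  =====
CXR 2D    [-90, 90]          [-pi/4, pi/4]       [0.4, 1]      0.4
MRI 3D    [-10, 10]          [-pi/6, pi/6]       [0.8, 1]      0.4
========  =================  ==================  ============  =====

All operators preserve the input shape, anchor at the image centre, fill
out-of-bounds regions with ``fill_value`` and clip the result back to [0, 1].
A train-time policy defaults to ``composition_mode='compose_all'``, chaining
all four operators in the fixed order rotate -> shear -> scale -> fisheye with
independently drawn parameters: a corner marker survives any single scale,
shear or fisheye draw (all three are quadrant-preserving), so only the chained
family reliably destroys corner-located shortcuts.  ``'single_random'`` (one
operator per image, drawn uniformly) is available for ablations; the test-time
ensemble always draws per-method.

The fisheye warp is a normalised barrel model: with radii measured from the
chosen centre and normalised so the farthest image corner is at radius 1, the
output location at radius ``r`` samples the input at
``r * (1 + k*r**2) / (1 + k)``.  It is the identity at ``k = 0``, fixes the
centre point for every ``k``, never folds (the radial map is strictly
increasing), and its displacement grows with the distance from the centre over
the central field, returning to zero at the rim so corners map to corners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "AugmentationPolicy",
    "AugSpec",
    "preset_policy",
    "rotate",
    "shear",
    "scale",
    "fisheye",
    "apply_policy",
    "apply_augspec",
    "make_tta_ensemble",
    "METHODS",
]

METHODS = ("rotate", "shear", "scale", "fisheye")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Parameter ranges for the four distortions plus sampling behaviour."""

    rotation_range: tuple[float, float] = (-90.0, 90.0)   # degrees
    shear_range: tuple[float, float] = (-math.pi / 4, math.pi / 4)  # radians
    scale_range: tuple[float, float] = (0.4, 1.0)          # unitless, subset of (0, 1]
    fisheye_k: float = 0.4
    composition_mode: str = "compose_all"                  # or "single_random"
    interpolation_order: int = 1
    fill_value: float = 0.0

    def validate(self) -> None:
        for name, (lo, hi) in (
            ("rotation_range", self.rotation_range),
            ("shear_range", self.shear_range),
            ("scale_range", self.scale_range),
        ):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"{name} must be a finite non-empty interval, got {(lo, hi)}")
        lo, hi = self.scale_range
        if not (0.0 < lo and hi <= 1.0):
            raise ValueError(f"scale_range must be within (0, 1], got {self.scale_range}")
        if self.fisheye_k < 0:
            raise ValueError(f"fisheye_k must be >= 0, got {self.fisheye_k}")
        if self.composition_mode not in ("single_random", "compose_all"):
            raise ValueError(f"unknown composition_mode {self.composition_mode!r}")


@dataclass(frozen=True)
class AugSpec:
    """One concrete sampled transform (or chain), replayable on another array."""

    method: str                                # rotate|shear|scale|fisheye|identity|compose
    params: tuple = ()
    center: tuple | None = None
    chain: tuple = ()                          # for method == "compose"

    def to_dict(self) -> dict:
        return asdict(self)


def preset_policy(modality: str) -> AugmentationPolicy:
    """Modality presets: ``'cxr'``/``'CXR_2D'`` or ``'mri'``/``'MRI_3D'``."""
    key = modality.lower()
    if key in ("cxr", "cxr_2d", "2d"):
        return AugmentationPolicy(
            rotation_range=(-90.0, 90.0),
            shear_range=(-math.pi / 4, math.pi / 4),
            scale_range=(0.4, 1.0),
            fisheye_k=0.4,
        )
    if key in ("mri", "mri_3d", "3d"):
        return AugmentationPolicy(
            rotation_range=(-10.0, 10.0),
            shear_range=(-math.pi / 6, math.pi / 6),
            scale_range=(0.8, 1.0),
            fisheye_k=0.4,
        )
    raise ValueError(f"unknown modality {modality!r}; expected 'cxr' or 'mri'")


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValueError(f"expected a 2D or 3D array, got ndim={image.ndim}")
    return image


def _affine(image: np.ndarray, matrix: np.ndarray, order: int, fill: float) -> np.ndarray:
    """Centre-anchored affine warp; `matrix` maps output -> input coordinates."""
    center = (np.array(image.shape, dtype=float) - 1.0) / 2.0
    # snap float noise (cos(pi/2) ~ 6e-17) so exact quarter-turns map grid->grid
    near = np.abs(matrix - np.round(matrix)) < 1e-12
    matrix = np.where(near, np.round(matrix), matrix)
    offset = center - matrix @ center
    near = np.abs(offset - np.round(offset)) < 1e-9
    offset = np.where(near, np.round(offset), offset)
    out = ndimage.affine_transform(
        image.astype(np.float64), matrix, offset=offset, order=order,
        mode="constant", cval=fill, prefilter=(order > 1),
    )
    return _restore(out, image)


def _restore(out: np.ndarray, image: np.ndarray) -> np.ndarray:
    if image.dtype == bool:
        return out > 0.5
    np.clip(out, 0.0, 1.0, out=out)
    return out.astype(image.dtype, copy=False)


def rotate(image: np.ndarray, angle: float, *, order: int = 1, fill: float = 0.0) -> np.ndarray:
    """Rotate counter-clockwise by ``angle`` degrees about the image centre.

    3D volumes rotate in-plane (about the first axis), matching the small-angle
    axial convention of the MRI preset.
    """
    image = _check_image(image)
    if not np.isfinite(angle):
        raise ValueError(f"rotation angle must be finite, got {angle}")
    if angle == 0:
        return image.copy()
    t = math.radians(angle)
    # output->input rotation in the trailing (row, col) plane; positive angle
    # turns image content counter-clockwise in the usual array display.
    r = np.array([[math.cos(t), math.sin(t)], [-math.sin(t), math.cos(t)]])
    if image.ndim == 2:
        m = r
    else:
        m = np.eye(3)
        m[1:, 1:] = r
    return _affine(image, m, order, fill)


def shear(image: np.ndarray, radian: float, *, order: int = 1, fill: float = 0.0) -> np.ndarray:
    """Centre-anchored horizontal shear by angle ``radian``.

    Columns are displaced proportionally to the (signed) row distance from the
    centre with slope ``tan(radian)``; the centre row is fixed.
    """
    image = _check_image(image)
    if not np.isfinite(radian) or abs(radian) >= math.pi / 2:
        raise ValueError(f"shear radian must satisfy |r| < pi/2, got {radian}")
    if radian == 0:
        return image.copy()
    t = math.tan(radian)
    # forward map displaces the last axis proportionally to the second-to-last;
    # affine_transform wants the inverse (output -> input) matrix.
    f = np.eye(image.ndim)
    f[-1, -2] = t
    return _affine(image, np.linalg.inv(f), order, fill)


def scale(image: np.ndarray, factor: float, *, order: int = 1, fill: float = 0.0) -> np.ndarray:
    """Shrink content about the centre by ``factor`` in (0, 1], padding with fill."""
    image = _check_image(image)
    if not (0.0 < factor <= 1.0):
        raise ValueError(f"scale factor must be in (0, 1], got {factor}")
    if factor == 1.0:
        return image.copy()
    m = np.eye(image.ndim) / factor  # output->input: sample farther out
    return _affine(image, m, order, fill)


def fisheye(
    image: np.ndarray,
    k: float,
    center: Sequence[float],
    *,
    order: int = 1,
    fill: float = 0.0,
) -> np.ndarray:
    """Radial barrel warp about ``center`` (array coordinates, (row, col[, ...]))."""
    image = _check_image(image)
    if k < 0:
        raise ValueError(f"fisheye coefficient must be >= 0, got {k}")
    center = np.asarray(center, dtype=float)
    if center.shape != (image.ndim,):
        raise ValueError(f"center must have {image.ndim} coordinates, got {center}")
    if np.any(center < 0) or np.any(center > np.array(image.shape) - 1):
        raise ValueError(f"center {tuple(center)} lies outside image bounds {image.shape}")
    if k == 0:
        return image.copy()

    shape = image.shape
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    delta = [g - c for g, c in zip(grids, center)]
    r = np.sqrt(sum(d * d for d in delta))
    # farthest corner from the centre defines the normalisation radius
    corners = np.array(np.meshgrid(*[(0.0, n - 1.0) for n in shape], indexing="ij"))
    corners = corners.reshape(image.ndim, -1).T
    r_max = float(np.max(np.linalg.norm(corners - center, axis=1)))
    r_out = r / r_max
    gain = (1.0 + k * r_out**2) / (1.0 + k)  # r_in = r_out * gain, <= r_out
    coords = [c + d * gain for c, d in zip(center, delta)]
    out = ndimage.map_coordinates(
        image.astype(np.float64), np.stack(coords), order=order,
        mode="constant", cval=fill, prefilter=(order > 1),
    )
    return _restore(out, image)


_OPERATORS = {"rotate": rotate, "shear": shear, "scale": scale, "fisheye": fisheye}


# ---------------------------------------------------------------------------
# fused composition: one resampling pass for a whole transform chain
# ---------------------------------------------------------------------------

def _op_matrix(spec: AugSpec, ndim: int) -> np.ndarray:
    """Output->input matrix of an affine member of the family."""
    if spec.method == "rotate":
        t = math.radians(spec.params[0])
        r = np.array([[math.cos(t), math.sin(t)], [-math.sin(t), math.cos(t)]])
        m = np.eye(ndim)
        m[-2:, -2:] = r
        return m
    if spec.method == "shear":
        f = np.eye(ndim)
        f[-1, -2] = math.tan(spec.params[0])
        return np.linalg.inv(f)
    if spec.method == "scale":
        return np.eye(ndim) / spec.params[0]
    raise ValueError(spec.method)


def _chain_coords(shape: tuple[int, ...], chain) -> np.ndarray:
    """Output->input coordinate field of a transform chain, built by walking the
    chain in reverse application order (each member maps output to input)."""
    ndim = len(shape)
    center = (np.array(shape, dtype=np.float64) - 1.0) / 2.0
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    coords = np.stack(grids)                        # (d, *shape)
    flat = coords.reshape(ndim, -1)
    for spec in reversed(chain):
        if spec.method == "identity":
            continue
        if spec.method == "fisheye":
            k = spec.params[0]
            if k == 0:
                continue
            c = np.asarray(spec.center, dtype=np.float64)
            corners = np.array(np.meshgrid(*[(0.0, n - 1.0) for n in shape],
                                           indexing="ij")).reshape(ndim, -1).T
            r_max = float(np.max(np.linalg.norm(corners - c, axis=1)))
            delta = flat - c[:, None]
            r_out = np.sqrt((delta**2).sum(axis=0)) / r_max
            gain = (1.0 + k * r_out**2) / (1.0 + k)
            flat = c[:, None] + delta * gain
        else:
            m = _op_matrix(spec, ndim)
            flat = m @ (flat - center[:, None]) + center[:, None]
    return flat.reshape((ndim,) + shape)


def _apply_chain(image: np.ndarray, chain, *, order: int, fill: float) -> np.ndarray:
    """Apply a whole chain through a single interpolation pass."""
    coords = _chain_coords(image.shape, chain)
    out = ndimage.map_coordinates(image.astype(np.float64), coords, order=order,
                                  mode="constant", cval=fill, prefilter=(order > 1))
    return _restore(out, image)


# ---------------------------------------------------------------------------
# policy sampling
# ---------------------------------------------------------------------------

def _sample_spec(image_shape, policy: AugmentationPolicy, method: str, rng) -> AugSpec:
    if method == "rotate":
        return AugSpec("rotate", (float(rng.uniform(*policy.rotation_range)),))
    if method == "shear":
        return AugSpec("shear", (float(rng.uniform(*policy.shear_range)),))
    if method == "scale":
        return AugSpec("scale", (float(rng.uniform(*policy.scale_range)),))
    if method == "fisheye":
        center = tuple(float(rng.uniform(0, n - 1)) for n in image_shape)
        return AugSpec("fisheye", (policy.fisheye_k,), center=center)
    raise ValueError(method)


def apply_augspec(image: np.ndarray, spec: AugSpec, *, order: int = 1, fill: float = 0.0) -> np.ndarray:
    """Replay a sampled transform on another array (e.g. a mask with order=0)."""
    if spec.method == "identity":
        return np.asarray(image).copy()
    if spec.method == "compose":
        # fused: the chain resolves to one coordinate field and one resampling
        # pass (no accumulation of interpolation blur across the four warps)
        return _apply_chain(_check_image(image), spec.chain, order=order, fill=fill)
    op = _OPERATORS[spec.method]
    kwargs = {"order": order, "fill": fill}
    if spec.method == "fisheye":
        return op(image, spec.params[0], spec.center, **kwargs)
    return op(image, spec.params[0], **kwargs)


def apply_policy(
    image: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> tuple[np.ndarray, AugSpec]:
    """Draw one transform from the policy and apply it.

    ``single_random`` draws exactly one of the four operators uniformly;
    ``compose_all`` chains all four with independently drawn parameters.
    """
    policy.validate()
    image = _check_image(image)
    if policy.composition_mode == "single_random":
        method = METHODS[int(rng.integers(len(METHODS)))]
        spec = _sample_spec(image.shape, policy, method, rng)
    else:
        chain = tuple(_sample_spec(image.shape, policy, m, rng) for m in METHODS)
        spec = AugSpec("compose", chain=chain)
    out = apply_augspec(image, spec, order=policy.interpolation_order, fill=policy.fill_value)
    return out, spec


def make_tta_ensemble(
    image: np.ndarray,
    policy: AugmentationPolicy,
    reps_per_method: int = 3,
    rng: np.random.Generator | None = None,
    return_specs: bool = False,
):
    """Test-time augmentation ensemble: ``reps_per_method`` draws of each of the
    four operators (12 images at the default of 3), grouped by method."""
    if reps_per_method < 1:
        raise ValueError(f"reps_per_method must be >= 1, got {reps_per_method}")
    policy.validate()
    image = _check_image(image)
    rng = np.random.default_rng() if rng is None else rng
    images, specs = [], []
    for method in METHODS:
        for _ in range(reps_per_method):
            spec = _sample_spec(image.shape, policy, method, rng)
            images.append(apply_augspec(image, spec, order=policy.interpolation_order,
                                        fill=policy.fill_value))
            specs.append(spec)
    return (images, specs) if return_specs else images
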