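"""Synthetic subject-grouped image cohorts with planted demographic shortcuts.

The generator emulates the statistical structure of chest-radiograph and brain-MRI
cohorts used in shortcut-learning audits: every image belongs to a subject, every
subject to one demographic group, binary "finding" labels are drawn with
group-dependent prevalence, and an incidental image feature correlated with the
group (e.g. a technician's corner marker) can be planted with controllable
strength and leak rate.

Intensities are floating point in [0, 1] with a flat background of 0.3,
mimicking histogram-equalised, normalised grayscale images.  The "disease"
signal is a set of concentric, centred shapes (one band per label) so that it is
invariant under rotation and survives the geometric augmentation family, while
the planted shortcut (corner token / border marker / global offset) is not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ShortcutSpec",
    "SignalSpec",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "render_sample",
    "split_by_subject",
]

BACKGROUND = 0.3

_SHORTCUT_KINDS = ("corner_token", "border_marker", "global_offset")


@dataclass(frozen=True)
class ShortcutSpec:
    """A demographic-correlated incidental image feature.

    kind
        ``corner_token``: a bright square (2D) or cube (3D) whose corner is a
        deterministic function of the group; ``border_marker``: a bright stripe
        along one border/face chosen by group; ``global_offset``: a per-group
        additive intensity offset.
    strength
        Contrast amplitude added on top of the background, intensity units.
    token_size / margin
        Token edge length in pixels and its distance from the image border.
    leak_rate
        Probability that a subject carries its group's shortcut (1 =
        deterministic shortcut).
    """

    kind: str = "corner_token"
    strength: float = 0.4
    token_size: int = 7
    margin: int = 2
    leak_rate: float = 1.0

    def validate(self, image_shape: tuple[int, ...]) -> None:
        if self.kind not in _SHORTCUT_KINDS:
            raise ValueError(f"shortcut.kind must be one of {_SHORTCUT_KINDS}, got {self.kind!r}")
        if not (0.0 <= self.leak_rate <= 1.0):
            raise ValueError(f"shortcut.leak_rate must be in [0, 1], got {self.leak_rate}")
        if self.strength < 0:
            raise ValueError(f"shortcut.strength must be >= 0, got {self.strength}")
        if self.kind in ("corner_token", "border_marker"):
            if self.token_size < 1:
                raise ValueError(f"shortcut.token_size must be >= 1, got {self.token_size}")
            if any(self.token_size + self.margin > n for n in image_shape):
                raise ValueError(
                    "shortcut.token_size + margin does not fit inside the image "
                    f"(token {self.token_size} + margin {self.margin} vs shape {image_shape})"
                )


@dataclass(frozen=True)
class SignalSpec:
    """The geometry-robust 'disease' signal: concentric centred bands.

    Label ``l`` is rendered as the radial band
    ``[base + l*step, base + l*step + width]`` (fractions of the smallest image
    half-extent); label 0 is therefore a filled central disk, later labels are
    annuli around it.  All bands are centred, so the signal is rotation
    invariant by construction.

    Two noise mechanisms are available.  ``visibility`` is the probability that
    a positive label's band is rendered at all, emulating the noise of
    report-derived (NLP-extracted) labels: an invisible positive is
    indistinguishable from a negative, so a group-revealing shortcut carries
    usable prior information and the detection ceiling sits below 1 for every
    model equally.  Optionally, band intensity can follow a severity continuum:
    positives draw ``max(0, N(contrast, contrast_sd))`` and negatives a faint
    mimic ``max(0, N(mimic_contrast, contrast_sd))``, making marginal cases
    ambiguous.  Defaults: visibility 0.8, fixed contrast (sd 0), no mimics.
    """

    contrast: float = 0.3
    contrast_sd: float = 0.0
    mimic_contrast: float = 0.0
    visibility: float = 0.8
    base_radius: float = 0.28
    band_width: float = 0.14
    band_step: float = 0.26
    placement: str = "center"
    rotation_invariant: bool = True

    def validate(self, n_labels: int, any_prevalence: bool) -> None:
        if any_prevalence and self.contrast <= 0:
            raise ValueError("disease_signal.contrast must be > 0 when any label prevalence is > 0")
        if self.contrast_sd < 0 or self.mimic_contrast < 0:
            raise ValueError("disease_signal.contrast_sd and mimic_contrast must be >= 0")
        if self.mimic_contrast >= self.contrast:
            raise ValueError("disease_signal.mimic_contrast must be below contrast")
        if not (0.0 < self.visibility <= 1.0):
            raise ValueError("disease_signal.visibility must be in (0, 1]")
        outer = self.base_radius + (n_labels - 1) * self.band_step + self.band_width
        if outer > 1.0 + 1e-9:
            raise ValueError(
                f"disease_signal bands for {n_labels} labels exceed the image half-extent "
                f"(outer radius fraction {outer:.2f} > 1)"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a subject-grouped, multi-label image cohort."""

    n_subjects: int = 600
    images_per_subject: int | tuple[int, int] = 3
    image_shape: tuple[int, ...] = (64, 64)
    group_names: tuple[str, ...] = ("groupA", "groupB", "groupC")
    group_proportions: tuple[float, ...] = (0.2, 0.3, 0.5)
    # one group-dependent finding plus one designed-null finding (uniform
    # prevalence): the null has no irreducible group disparity, so any
    # per-group error spread on it is attributable to the model
    label_names: tuple[str, ...] = ("focal_opacity", "ring_pattern")
    # prevalence_per_group[g][l] = P(label l = 1 | group g)
    prevalence_per_group: tuple[tuple[float, ...], ...] = (
        (0.25, 0.5),
        (0.50, 0.5),
        (0.75, 0.5),
    )
    shortcut: ShortcutSpec = field(default_factory=ShortcutSpec)
    disease_signal: SignalSpec = field(default_factory=SignalSpec)
    noise_sigma: float = 0.05
    seed: int = 2021

    def __post_init__(self):
        object.__setattr__(self, "image_shape", tuple(int(n) for n in self.image_shape))
        object.__setattr__(self, "group_names", tuple(self.group_names))
        object.__setattr__(self, "label_names", tuple(self.label_names))
        object.__setattr__(self, "group_proportions", tuple(float(p) for p in self.group_proportions))
        object.__setattr__(
            self,
            "prevalence_per_group",
            tuple(tuple(float(p) for p in row) for row in self.prevalence_per_group),
        )

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        ips = self.images_per_subject
        if isinstance(ips, tuple):
            if len(ips) != 2 or ips[0] < 1 or ips[1] < ips[0]:
                raise ValueError(f"images_per_subject range invalid: {ips}")
        elif int(ips) < 1:
            raise ValueError(f"images_per_subject must be positive, got {ips}")
        if len(self.image_shape) not in (2, 3):
            raise ValueError(f"image_shape must be 2D or 3D, got {self.image_shape}")
        if any(n < 16 for n in self.image_shape):
            raise ValueError(f"image_shape extents must be >= 16 per axis, got {self.image_shape}")
        if len(self.group_names) != len(self.group_proportions):
            raise ValueError("group_names and group_proportions lengths differ")
        if abs(sum(self.group_proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"group_proportions must sum to 1 +- 1e-9, got sum {sum(self.group_proportions)}"
            )
        if any(p < 0 for p in self.group_proportions):
            raise ValueError("group_proportions must be non-negative")
        prev = np.asarray(self.prevalence_per_group, dtype=float)
        if prev.shape != (len(self.group_names), len(self.label_names)):
            raise ValueError(
                "prevalence_per_group must have shape (n_groups, n_labels) = "
                f"{(len(self.group_names), len(self.label_names))}, got {prev.shape}"
            )
        if np.any(prev < 0) or np.any(prev > 1):
            raise ValueError("prevalence_per_group entries must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        self.shortcut.validate(self.image_shape)
        self.disease_signal.validate(len(self.label_names), bool(np.any(prev > 0)))

    @property
    def ndim(self) -> int:
        return len(self.image_shape)

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "shortcut" in d and isinstance(d["shortcut"], dict):
            d["shortcut"] = ShortcutSpec(**d["shortcut"])
        if "disease_signal" in d and isinstance(d["disease_signal"], dict):
            d["disease_signal"] = SignalSpec(**d["disease_signal"])
        for key in ("image_shape", "group_names", "group_proportions", "label_names"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "prevalence_per_group" in d:
            d["prevalence_per_group"] = tuple(tuple(r) for r in d["prevalence_per_group"])
        if isinstance(d.get("images_per_subject"), list):
            d["images_per_subject"] = tuple(d["images_per_subject"])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "CohortSpec":
        return cls.from_dict(json.loads(s))


@dataclass
class SyntheticCohort:
    """A realised cohort: image stack plus per-sample annotations and truth masks."""

    images: np.ndarray          # (N, *image_shape) float32 in [0, 1]
    subject_id: np.ndarray      # (N,) int
    group: np.ndarray           # (N,) str, values from spec.group_names
    labels: np.ndarray          # (N, n_labels) int8 in {0, 1}
    shortcut_masks: np.ndarray  # (N, *image_shape) bool
    disease_masks: np.ndarray   # (N, *image_shape) bool
    spec: CohortSpec
    sample_id: np.ndarray = None  # (N,) int; assigned if missing

    def __post_init__(self):
        if self.sample_id is None:
            self.sample_id = np.arange(len(self.images))
        self._check()

    def _check(self):
        n = len(self.images)
        for name in ("subject_id", "group", "sample_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of images")
        if self.labels.shape != (n, len(self.spec.label_names)):
            raise ValueError("labels shape mismatch")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        # each subject maps to exactly one group
        for sid in np.unique(self.subject_id):
            g = np.unique(self.group[self.subject_id == sid])
            if len(g) != 1:
                raise ValueError(f"subject {sid} has multiple groups: {g}")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def group_codes(self) -> np.ndarray:
        """Integer group codes in spec.group_names order."""
        lut = {g: i for i, g in enumerate(self.spec.group_names)}
        return np.array([lut[g] for g in self.group], dtype=np.int64)

    def subset(self, idx: np.ndarray) -> "SyntheticCohort":
        idx = np.asarray(idx)
        return SyntheticCohort(
            images=self.images[idx],
            subject_id=self.subject_id[idx],
            group=self.group[idx],
            labels=self.labels[idx],
            shortcut_masks=self.shortcut_masks[idx],
            disease_masks=self.disease_masks[idx],
            spec=self.spec,
            sample_id=self.sample_id[idx],
        )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _radial_distance(shape: tuple[int, ...]) -> np.ndarray:
    """Distance of every pixel from the image centre, in pixels."""
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    center = [(n - 1) / 2.0 for n in shape]
    return np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))


def _label_band_mask(spec: CohortSpec, label_index: int) -> np.ndarray:
    sig = spec.disease_signal
    half = min(spec.image_shape) / 2.0
    r = _radial_distance(spec.image_shape)
    if label_index == 0:
        lo, hi = 0.0, sig.base_radius * half
    else:
        lo = (sig.base_radius + label_index * sig.band_step - sig.band_width) * half
        hi = (sig.base_radius + label_index * sig.band_step) * half
    return (r >= lo) & (r <= hi)


def _shortcut_mask(spec: CohortSpec, group_index: int) -> np.ndarray:
    sc = spec.shortcut
    shape = spec.image_shape
    mask = np.zeros(shape, dtype=bool)
    d = len(shape)
    if sc.kind == "corner_token":
        n_corners = 2 ** d
        corner = group_index % n_corners
        slices = []
        for ax in range(d):
            lo = (corner >> ax) & 1
            if lo == 0:
                slices.append(slice(sc.margin, sc.margin + sc.token_size))
            else:
                slices.append(slice(shape[ax] - sc.margin - sc.token_size, shape[ax] - sc.margin))
        mask[tuple(slices)] = True
    elif sc.kind == "border_marker":
        n_sides = 2 * d
        side = group_index % n_sides
        ax, hi = side % d, side // d
        slices = [slice(None)] * d
        if hi == 0:
            slices[ax] = slice(0, sc.token_size)
        else:
            slices[ax] = slice(shape[ax] - sc.token_size, shape[ax])
        mask[tuple(slices)] = True
    else:  # global_offset
        mask[...] = True
    return mask


def render_sample(
    spec: CohortSpec,
    group,
    labels: Sequence[int],
    rng: np.random.Generator,
    *,
    shortcut_on: bool | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one sample: background + label bands + (maybe) shortcut + noise.

    Returns ``(image, disease_mask, shortcut_mask)``.  ``shortcut_on`` overrides
    the Bernoulli(leak_rate) draw; cohort generation uses it to share one
    realisation across a subject's images.
    """
    spec.validate()
    if isinstance(group, str):
        group_index = spec.group_names.index(group)
    else:
        group_index = int(group)
        if not (0 <= group_index < len(spec.group_names)):
            raise ValueError(f"group index {group_index} out of range")
    labels = np.asarray(labels, dtype=np.int8)
    if labels.shape != (len(spec.label_names),):
        raise ValueError("labels inconsistent with spec.label_names")

    img = np.full(spec.image_shape, BACKGROUND, dtype=np.float64)
    disease_mask = np.zeros(spec.image_shape, dtype=bool)
    sig = spec.disease_signal
    for l, on in enumerate(labels):
        if on and sig.visibility < 1.0 and rng.random() >= sig.visibility:
            continue  # invisible positive: report-label noise
        mu = sig.contrast if on else sig.mimic_contrast
        severity = mu if sig.contrast_sd == 0 else max(0.0, rng.normal(mu, sig.contrast_sd))
        if severity > 0:
            band = _label_band_mask(spec, l)
            img[band] += severity
            if on:
                disease_mask |= band

    if shortcut_on is None:
        shortcut_on = bool(rng.random() < spec.shortcut.leak_rate)
    if shortcut_on and spec.shortcut.strength > 0:
        sc_mask = _shortcut_mask(spec, group_index)
        if spec.shortcut.kind == "global_offset":
            n_groups = len(spec.group_names)
            img += spec.shortcut.strength * (group_index + 1) / n_groups
        else:
            img[sc_mask] += spec.shortcut.strength
    else:
        sc_mask = np.zeros(spec.image_shape, dtype=bool)

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=spec.image_shape)
    np.clip(img, 0.0, 1.0, out=img)
    return img.astype(np.float32), disease_mask, sc_mask


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Realise a cohort from its spec.  Deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_groups = len(spec.group_names)
    prev = np.asarray(spec.prevalence_per_group, dtype=float)

    subj_group = rng.choice(n_groups, size=spec.n_subjects, p=spec.group_proportions)
    ips = spec.images_per_subject
    if isinstance(ips, tuple):
        subj_n_images = rng.integers(ips[0], ips[1] + 1, size=spec.n_subjects)
    else:
        subj_n_images = np.full(spec.n_subjects, int(ips))

    images, subject_ids, groups, labels = [], [], [], []
    sc_masks, dz_masks = [], []
    for sid in range(spec.n_subjects):
        g = int(subj_group[sid])
        subj_labels = (rng.random(len(spec.label_names)) < prev[g]).astype(np.int8)
        carries = bool(rng.random() < spec.shortcut.leak_rate)
        for _ in range(int(subj_n_images[sid])):
            img, dz, sc = render_sample(spec, g, subj_labels, rng, shortcut_on=carries)
            images.append(img)
            subject_ids.append(sid)
            groups.append(spec.group_names[g])
            labels.append(subj_labels)
            sc_masks.append(sc)
            dz_masks.append(dz)

    return SyntheticCohort(
        images=np.stack(images),
        subject_id=np.asarray(subject_ids, dtype=np.int64),
        group=np.asarray(groups, dtype=object),
        labels=np.stack(labels),
        shortcut_masks=np.stack(sc_masks),
        disease_masks=np.stack(dz_masks),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_by_subject(
    cohort: SyntheticCohort,
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
    seed: int = 0,
) -> tuple[SyntheticCohort, SyntheticCohort, SyntheticCohort]:
    """Partition a cohort into train/val/test with no subject crossing splits.

    Subject counts follow largest-remainder rounding of ``fractions``, so they
    are within one subject of the exact targets (and exact when the targets are
    integral).
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 +- 1e-9, got {sum(fractions)}")
    subjects = np.unique(cohort.subject_id)
    n = len(subjects)
    if n < len(fractions):
        raise ValueError(f"cohort has {n} subjects, fewer than {len(fractions)} splits")

    rng = np.random.default_rng(seed)
    order = rng.permutation(subjects)
    targets = np.array(fractions) * n
    counts = np.floor(targets).astype(int)
    remainder = n - counts.sum()
    frac_part = targets - np.floor(targets)
    for i in np.argsort(-frac_part)[:remainder]:
        counts[i] += 1
    # guard against an empty split after rounding
    while (counts == 0).any():
        counts[np.argmin(counts)] += 1
        counts[np.argmax(counts)] -= 1

    bounds = np.cumsum(counts)[:-1]
    parts = np.split(order, bounds)
    out = []
    for part in parts:
        member = np.isin(cohort.subject_id, part)
        out.append(cohort.subset(np.where(member)[0]))
    return tuple(out)
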