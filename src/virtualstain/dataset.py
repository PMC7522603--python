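"""Training/validation/test set construction for paired image regression.

Covers random paired patch cropping, paired geometric augmentation,
whole-image train/validation splitting, and construction of
defocused-input / focused-target pairs from z-stacks for the autofocusing
task.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np

from .image_io import ChannelImage, read_image


@dataclass
class PairedSample:
    """k >= 1 co-registered input channels plus one target channel.

    All images must share an identical shape: the pipeline assumes channels
    are co-registered and never attempts registration itself.
    """

    inputs: list[ChannelImage]
    target: ChannelImage

    def __post_init__(self) -> None:
        if len(self.inputs) < 1:
            raise ValueError("a PairedSample needs at least one input channel")
        shapes = {im.shape for im in self.inputs} | {self.target.shape}
        if len(shapes) != 1:
            raise ValueError(f"input/target shapes differ (co-registration broken): {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.target.shape


@dataclass
class PatchSpec:
    """Random-crop plan: square patches of ``patch_size`` pixels, ``count`` per image."""

    patch_size: int
    count: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be positive")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class ZStack:
    """Ordered fluorescence slices at uniformly spaced axial positions."""

    slices: list[ChannelImage]
    z_positions: list[float]
    focus_index: int

    def __post_init__(self) -> None:
        if len(self.slices) != len(self.z_positions):
            raise ValueError("slices and z_positions length mismatch")
        z = np.asarray(self.z_positions, dtype=float)
        if len(z) > 1:
            dz = np.diff(z)
            if not (dz > 0).all():
                raise ValueError("z_positions must be strictly increasing")
            if not np.allclose(dz, dz[0]):
                raise ValueError("z_positions must be uniformly spaced")
        if not (0 <= self.focus_index < len(self.slices)):
            raise ValueError(f"focus_index {self.focus_index} out of range")


def _subimage(im: ChannelImage, r: int, c: int, size: int) -> ChannelImage:
    return ChannelImage(im.pixels[r:r + size, c:c + size].copy(), im.bit_depth,
                        im.channel_label, im.pixel_size)


def crop_patch_pairs(sample: PairedSample, spec: PatchSpec) -> list[PairedSample]:
    """Randomly crop co-located square patches from every channel of a pair.

    Offsets are drawn uniformly with replacement from the set of positions at
    which the patch fits entirely inside the image (border patches are
    rejected rather than padded).  Reproducible given ``spec.seed``.
    """
    h, w = sample.shape
    p = spec.patch_size
    if p > h or p > w:
        raise ValueError(f"patch_size {p} exceeds image shape {(h, w)}")
    rng = np.random.default_rng(spec.seed)
    rows = rng.integers(0, h - p + 1, size=spec.count)
    cols = rng.integers(0, w - p + 1, size=spec.count)
    out = []
    for r, c in zip(rows, cols):
        out.append(PairedSample([_subimage(im, r, c, p) for im in sample.inputs],
                                _subimage(sample.target, r, c, p)))
    return out


AUGMENT_OPS = ("identity", "rot90", "rot180", "rot270", "flip_h", "flip_v")


def _apply_op(a: np.ndarray, op: str) -> np.ndarray:
    if op == "identity":
        return a.copy()
    if op == "rot90":
        return np.rot90(a, 1).copy()
    if op == "rot180":
        return np.rot90(a, 2).copy()
    if op == "rot270":
        return np.rot90(a, 3).copy()
    if op == "flip_h":
        return a[:, ::-1].copy()
    if op == "flip_v":
        return a[::-1, :].copy()
    raise ValueError(f"unknown augmentation op {op!r}; expected one of {AUGMENT_OPS}")


def augment_pair(patch: PairedSample, op: str) -> PairedSample:
    """Apply one dihedral-group transform identically to all channels of a pair."""
    h, w = patch.shape
    if op in ("rot90", "rot270") and h != w:
        raise ValueError(f"90-degree rotation requires a square patch, got {(h, w)}")
    def t(im: ChannelImage) -> ChannelImage:
        return ChannelImage(_apply_op(im.pixels, op), im.bit_depth, im.channel_label, im.pixel_size)
    return PairedSample([t(im) for im in patch.inputs], t(patch.target))


def split_train_val(samples: list[PairedSample], val_fraction: float,
                    seed: int) -> tuple[list[PairedSample], list[PairedSample]]:
    """Disjoint, exhaustive whole-sample split; |val| = round(val_fraction * n).

    Splitting happens at the whole-image level so overlapping patches can
    never leak between train and validation.
    """
    if not 0 < val_fraction < 1:
        raise ValueError("val_fraction must be in (0, 1)")
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_val = int(round(val_fraction * n))
    n_val = min(max(n_val, 0), n)
    order = np.random.default_rng(seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [samples[i] for i in range(n) if i not in val_idx]
    val = [samples[i] for i in range(n) if i in val_idx]
    return train, val


def make_defocus_pairs(stack: ZStack, min_abs_z: float, max_abs_z: float) -> list[PairedSample]:
    """Pair each defocused slice with the in-focus slice of its stack.

    A slice at axial offset dz = z - z_focus is used as input when
    ``min_abs_z < |dz| <= max_abs_z`` (the band is exclusive at the lower
    edge and inclusive at the upper edge, so a [2, 10] um band on a 2-um
    stack yields the offsets {+-4, +-6, +-8, +-10}: 8 defocused planes).
    The focus slice is repeated as the target of every pair.
    """
    if min_abs_z > max_abs_z:
        raise ValueError("min_abs_z must be <= max_abs_z")
    z_focus = stack.z_positions[stack.focus_index]
    focus = stack.slices[stack.focus_index]
    pairs = []
    for im, z in zip(stack.slices, stack.z_positions):
        dz = abs(z - z_focus)
        if min_abs_z < dz <= max_abs_z:
            pairs.append(PairedSample([im], focus))
    if not pairs:
        warnings.warn(f"no slices in the ({min_abs_z}, {max_abs_z}] um defocus band", stacklevel=2)
    return pairs


# ---------------------------------------------------------------------------
# Dataset manifests: JSON listings of (input paths..., target path, role).


def write_manifest(path: str | os.PathLike, entries: list[dict]) -> None:
    """Write a dataset manifest: a JSON list of
    ``{"inputs": [paths...], "target": path, "role": "train"|"val"|"test"}``."""
    with open(path, "w") as fh:
        json.dump({"samples": entries}, fh, indent=2)


def load_manifest(path: str | os.PathLike) -> list[PairedSample]:
    """Load every sample listed in a manifest written by :func:`write_manifest`."""
    base = os.path.dirname(os.fspath(path))
    with open(path) as fh:
        doc = json.load(fh)
    if "samples" not in doc:
        raise ValueError(f"manifest {path} missing required field 'samples'")
    out = []
    for ent in doc["samples"]:
        for key in ("inputs", "target"):
            if key not in ent:
                raise ValueError(f"manifest entry missing required field {key!r}")
        inputs = [read_image(os.path.join(base, p)) for p in ent["inputs"]]
        target = read_image(os.path.join(base, ent["target"]))
        out.append(PairedSample(inputs, target))
    return out
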