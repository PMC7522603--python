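"""Full-field prediction: tiling, overlapped prediction, alpha-blend stitching.

Full fields of view are cut into overlapping square tiles, each tile is
predicted independently, and tile outputs are recombined with per-pixel
alpha weights that sum to one everywhere (a partition of unity), then
inversely normalized to the source bit range.  The per-tile weight ramps
linearly from (near) zero at the tile edge to one at half the overlap into
the tile and is constant inside; pixelwise renormalization makes the
partition exact, including at image borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import PairedSample
from .image_io import ChannelImage, NormalizedImage, denormalize, normalize

_W_EPS = 1e-3  # floor so border pixels covered by a single tile keep weight


@dataclass
class TileGrid:
    """Tiling plan: tile origins plus per-pixel blend weights.

    ``blend_weights[i]`` is the (renormalized) weight map of tile ``i``; over
    all tiles covering a pixel the weights sum to exactly 1.
    """

    image_shape: tuple[int, int]
    tile_size: int
    overlap: int
    tile_origins: list[tuple[int, int]]
    blend_weights: list[np.ndarray] = field(repr=False, default_factory=list)


def _origins_1d(size: int, tile: int, overlap: int) -> list[int]:
    stride = tile - overlap
    out = list(range(0, size - tile + 1, stride))
    if out[-1] != size - tile:  # snap the last tile to the border
        out.append(size - tile)
    return out


def _ramp_1d(tile: int, overlap: int) -> np.ndarray:
    w = np.ones(tile)
    half = overlap // 2
    for d in range(half):
        v = max((d + 1) / (half + 1), _W_EPS)
        w[d] = min(w[d], v)
        w[tile - 1 - d] = min(w[tile - 1 - d], v)
    return np.maximum(w, _W_EPS)


def plan_tiles(image_shape: tuple[int, int], tile_size: int, overlap: int) -> TileGrid:
    """Plan a full-coverage tiling with deterministic origins.

    Origins advance by ``tile_size - overlap``; the last tile in each axis is
    snapped to the image border.  Raw tile weights (edge feathering) are
    renormalized pixelwise so that at every output pixel the weights of the
    covering tiles sum to 1.
    """
    h, w = image_shape
    if tile_size > h or tile_size > w:
        raise ValueError(f"tile_size {tile_size} exceeds image shape {image_shape}")
    if not 0 <= overlap < tile_size:
        raise ValueError(f"overlap must satisfy 0 <= overlap < tile_size, got {overlap}")
    origins = [(r, c) for r in _origins_1d(h, tile_size, overlap)
               for c in _origins_1d(w, tile_size, overlap)]
    ramp = _ramp_1d(tile_size, overlap)
    raw = np.outer(ramp, ramp)
    total = np.zeros(image_shape)
    for r, c in origins:
        total[r:r + tile_size, c:c + tile_size] += raw
    weights = [raw / total[r:r + tile_size, c:c + tile_size] for r, c in origins]
    return TileGrid(image_shape, tile_size, overlap, origins, weights)


def stitch_tiles(tiles: list[np.ndarray], grid: TileGrid) -> np.ndarray:
    """Alpha-blend per-tile arrays back into one full-size array."""
    out = np.zeros(grid.image_shape, dtype=np.float64)
    for tile, (r, c), w in zip(tiles, grid.tile_origins, grid.blend_weights):
        out[r:r + grid.tile_size, c:c + grid.tile_size] += tile * w
    return out


def predict_full(inputs: list[ChannelImage], predictor, grid: TileGrid,
                 out_bit_depth: int | None = None) -> ChannelImage:
    """Predict a full field of view by overlapped tiling and stitching.

    ``predictor`` maps a normalized (k, tile, tile) stack to a predicted
    (tile, tile) array in [-1, 1]; a :class:`~virtualstain.cgan_core.TrainState`
    or a generator with a ``predict`` method is accepted directly.  The
    stitched result is inversely normalized to ``out_bit_depth`` (default:
    the bit depth of the first input channel).
    """
    if hasattr(predictor, "generator"):
        predictor = predictor.generator
    if hasattr(predictor, "predict"):
        model = predictor

        def predictor(stack):  # noqa: F811 - wrap network object
            out = model.predict(stack)
            return out[0] if out.ndim == 3 else out

    shapes = {im.shape for im in inputs}
    if len(shapes) != 1:
        raise ValueError(f"input channels have differing shapes: {shapes}")
    if next(iter(shapes)) != grid.image_shape:
        raise ValueError("grid was planned for a different image shape")
    stack = np.stack([normalize(im).pixels for im in inputs])
    t = grid.tile_size
    tiles = []
    for r, c in grid.tile_origins:
        pred = np.asarray(predictor(stack[:, r:r + t, c:c + t]), dtype=np.float64)
        if pred.shape != (t, t):
            raise ValueError(f"predictor returned shape {pred.shape}, expected {(t, t)}")
        tiles.append(pred)
    blended = np.clip(stitch_tiles(tiles, grid), -1.0, 1.0)
    depth = out_bit_depth or inputs[0].bit_depth
    return denormalize(NormalizedImage(blended, depth, "prediction"))
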