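"""Model interpretation: region-level significance maps and latent export.

The significance map partitions the FCGR image into a coarse grid of
regions (default 9x9) and estimates each region's additive contribution to
the probability of a target class by seeded random-subset masking: many
random region subsets are blanked to zero intensity (the FCGR meaning of
"no such k-mers"), the model is re-queried, and a linear surrogate
p(kept-regions) is fit whose coefficients are the attributions
(Kernel-SHAP-style). A positive score means masking the region tends to
lower the target-class probability.

A pure occlusion mode (one region at a time) is provided as a cheap
independent estimate; the two agree in sign for strongly attributed
regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .pipeline import TrainedModel
from .sequences import RnaWindow

DEFAULT_ATTRIBUTION_GRID = 9


def _band_sizes(n_pixels: int, n_bands: int) -> list[int]:
    """Near-equal contiguous bands; remainders go to the trailing bands.

    64 pixels over 9 bands gives (7, 7, 7, 7, 7, 7, 7, 7, 8).
    """
    base, rem = divmod(n_pixels, n_bands)
    return [base] * (n_bands - rem) + [base + 1] * rem


def region_slices(
    image_shape: tuple[int, int], grid: int
) -> list[list[tuple[slice, slice]]]:
    """(row-band, col-band) pixel slices of the grid x grid tiling."""
    h_sizes = _band_sizes(image_shape[0], grid)
    w_sizes = _band_sizes(image_shape[1], grid)
    h_edges = np.concatenate([[0], np.cumsum(h_sizes)])
    w_edges = np.concatenate([[0], np.cumsum(w_sizes)])
    return [
        [
            (slice(h_edges[r], h_edges[r + 1]), slice(w_edges[c], w_edges[c + 1]))
            for c in range(grid)
        ]
        for r in range(grid)
    ]


@dataclass
class SignificanceMap:
    """Region attribution scores for one image and one target class."""

    grid: np.ndarray  # (G, G) attribution scores
    upsampled: np.ndarray  # (H, W) piecewise-constant expansion
    target_class: int
    baseline_probability: float  # p(target | fully-masked image)


def _apply_mask(
    image: np.ndarray, keep: np.ndarray, slices, grid: int
) -> np.ndarray:
    out = image.copy()
    for r in range(grid):
        for c in range(grid):
            if not keep[r * grid + c]:
                rs, cs = slices[r][c]
                out[rs, cs] = 0.0
    return out


def _batched_proba(trained: TrainedModel, images: np.ndarray, batch: int = 64):
    out = [
        trained.model.predict_proba(images[i : i + batch])
        for i in range(0, len(images), batch)
    ]
    return np.concatenate(out)


def significance_map(
    trained: TrainedModel,
    image: np.ndarray,
    target_class: int = 1,
    grid: int = DEFAULT_ATTRIBUTION_GRID,
    n_samples: int = 256,
    seed: int = 0,
) -> SignificanceMap:
    """Random-subset-masking attribution over a grid x grid region tiling.

    Fits p(target) ~ intercept + sum_k phi_k * keep_k by least squares over
    ``n_samples`` seeded random keep-patterns (plus the all-kept and
    all-masked patterns); phi_k is region k's attribution.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != trained.config.image_shape:
        raise ValueError(
            f"image shape {image.shape} does not match model input "
            f"{trained.config.image_shape}"
        )
    rng = np.random.default_rng(seed)
    n_regions = grid * grid
    slices = region_slices(image.shape, grid)
    keep_patterns = rng.integers(0, 2, size=(n_samples, n_regions)).astype(bool)
    keep_patterns = np.vstack(
        [np.ones(n_regions, bool), np.zeros(n_regions, bool), keep_patterns]
    )
    masked = np.stack(
        [_apply_mask(image, keep, slices, grid) for keep in keep_patterns]
    )
    probs = _batched_proba(trained, masked)[:, target_class]
    design = np.column_stack([np.ones(len(keep_patterns)), keep_patterns.astype(float)])
    coef, *_ = np.linalg.lstsq(design, probs, rcond=None)
    scores = coef[1:].reshape(grid, grid)
    upsampled = np.zeros(image.shape)
    for r in range(grid):
        for c in range(grid):
            rs, cs = slices[r][c]
            upsampled[rs, cs] = scores[r, c]
    return SignificanceMap(
        grid=scores,
        upsampled=upsampled,
        target_class=target_class,
        baseline_probability=float(probs[1]),  # all-masked pattern
    )


def occlusion_map(
    trained: TrainedModel,
    image: np.ndarray,
    target_class: int = 1,
    grid: int = DEFAULT_ATTRIBUTION_GRID,
) -> SignificanceMap:
    """One-region-at-a-time occlusion: score_k = p(full) - p(region k masked)."""
    image = np.asarray(image, dtype=np.float64)
    n_regions = grid * grid
    slices = region_slices(image.shape, grid)
    keep_patterns = ~np.eye(n_regions, dtype=bool)
    stack = np.stack(
        [image]
        + [_apply_mask(image, keep, slices, grid) for keep in keep_patterns]
        + [np.zeros_like(image)]
    )
    probs = _batched_proba(trained, stack)[:, target_class]
    scores = (probs[0] - probs[1:-1]).reshape(grid, grid)
    upsampled = np.zeros(image.shape)
    for r in range(grid):
        for c in range(grid):
            rs, cs = slices[r][c]
            upsampled[rs, cs] = scores[r, c]
    return SignificanceMap(
        grid=scores,
        upsampled=upsampled,
        target_class=target_class,
        baseline_probability=float(probs[-1]),
    )


def motif_region_mask(
    motifs: Sequence[str], grid_size: int, grid: int = DEFAULT_ATTRIBUTION_GRID
) -> np.ndarray:
    """Boolean (grid, grid) mask of regions containing motif-suffix FCGR cells.

    A cell is motif-associated when its k-mer (k = log2 grid_size) ends
    with one of ``motifs``; a region is motif-associated when it contains
    at least one such cell. Used to compare attribution over planted-motif
    regions against the rest.
    """
    import itertools

    from .cgr import kmer_cell
    from .sequences import RNA_ALPHABET

    k = int(np.log2(grid_size))
    cells = set()
    for motif in motifs:
        if len(motif) > k:
            continue
        for prefix in itertools.product(RNA_ALPHABET, repeat=k - len(motif)):
            cells.add(kmer_cell("".join(prefix) + motif, grid_size))
    slices = region_slices((grid_size, grid_size), grid)
    mask = np.zeros((grid, grid), dtype=bool)
    for r in range(grid):
        for c in range(grid):
            rs, cs = slices[r][c]
            if any(rs.start <= cr < rs.stop and cs.start <= cc < cs.stop
                   for cr, cc in cells):
                mask[r, c] = True
    return mask


def export_latent_features(
    trained: TrainedModel,
    windows: Sequence[RnaWindow],
    layer: str = "digit",
    batch_size: int = 64,
) -> pd.DataFrame:
    """Flattened capsule vectors per window, as a labeled DataFrame.

    ``layer="digit"`` gives J x D values per window (2 x 32 = 64 with the
    full-scale configuration); ``layer="primary"`` gives L x m values.
    Intended for external clustering / t-SNE.
    """
    if layer not in ("digit", "primary"):
        raise ValueError("layer must be 'digit' or 'primary'")
    model = trained.model
    if not hasattr(model, "primary_capsules"):
        raise ValueError("latent export requires a capsule model")
    images = trained.encode(windows)
    feats = []
    for i in range(0, len(images), batch_size):
        out = model.forward(images[i : i + batch_size])
        if layer == "digit":
            feats.append(out.digit_vectors.data.reshape(len(out.chosen_class), -1))
        else:
            feats.append(out.primary.reshape(len(out.chosen_class), -1))
    mat = np.concatenate(feats)
    df = pd.DataFrame(mat, columns=[f"f{j:05d}" for j in range(mat.shape[1])])
    df.insert(0, "id", [w.id for w in windows])
    df.insert(1, "label", [w.label for w in windows])
    return df
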