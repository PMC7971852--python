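"""Proximity-ligation-assay spot counting.

Pipeline per image: grayscale conversion (luminance weighting for RGB
input), Gaussian smoothing, adaptive mean thresholding (a pixel is
foreground when it exceeds its local-window mean by a fixed offset),
8-connected component labeling, and a minimum component size to suppress
single-pixel noise. The neighborhood window is a batch parameter so it stays
constant between control and experimental images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import filters, measure
from skimage.color import rgb2gray


@dataclass
class SpotCountParams:
    gaussian_sigma: float = 1.5
    adaptive_window: int = 31   # odd local-mean window, px
    adaptive_offset: float = 8.0  # intensity above local mean for foreground
    min_component_px: int = 2

    def validate(self, shape=None) -> None:
        if self.adaptive_window <= 1 or self.adaptive_window % 2 == 0:
            raise ValueError("adaptive_window must be odd and > 1")
        if shape is not None and self.adaptive_window >= min(shape):
            raise ValueError("adaptive_window must be smaller than the image")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")


@dataclass
class SpotCountResult:
    image_id: str
    n_components: int
    n_cells: int
    dots_per_cell: float
    parameters: SpotCountParams


def _to_grayscale(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3 and image.shape[2] in (3, 4):
        # cast first: rgb2gray preserves the intensity scale of float input
        return rgb2gray(image[..., :3].astype(float))
    if image.ndim == 2:
        return image.astype(float)
    raise ValueError(f"expected 2-D or 3-channel image, got shape {image.shape}")


def count_spots(image: np.ndarray,
                params: SpotCountParams | None = None,
                image_id: str = "image",
                n_cells: int = 0) -> SpotCountResult:
    """Count fluorescent spots in one image.

    Returns a :class:`SpotCountResult`; ``dots_per_cell`` is NaN when
    ``n_cells`` is 0 (cell counts are an input, not inferred).
    """
    params = params or SpotCountParams()
    if image is None or np.size(image) == 0:
        raise ValueError("empty image")
    gray = _to_grayscale(np.asarray(image))
    params.validate(gray.shape)
    smoothed = filters.gaussian(gray, sigma=params.gaussian_sigma,
                                preserve_range=True)
    # threshold_local returns local_mean - offset; foreground must exceed the
    # local mean by +adaptive_offset, hence the sign flip
    thresh = filters.threshold_local(smoothed, block_size=params.adaptive_window,
                                     method="mean",
                                     offset=-params.adaptive_offset)
    binary = smoothed > thresh
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        n_components = 0
    else:
        sizes = np.bincount(labels.ravel())[1:]
        n_components = int((sizes >= params.min_component_px).sum())
    dpc = n_components / n_cells if n_cells > 0 else float("nan")
    return SpotCountResult(image_id=image_id, n_components=n_components,
                           n_cells=n_cells, dots_per_cell=dpc,
                           parameters=params)


def dots_per_cell(result: SpotCountResult, n_cells: int) -> float:
    """Average number of nascent-protein dots per cell."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    return result.n_components / n_cells


def count_spots_batch(images: dict[str, np.ndarray],
                      params: SpotCountParams | None = None,
                      cells: dict[str, int] | None = None) -> pd.DataFrame:
    """Run the counter over a batch with one shared parameter set.

    Sharing ``params`` across the batch enforces the constant-neighborhood
    constraint between control and experimental images.
    """
    params = params or SpotCountParams()
    cells = cells or {}
    rows = []
    for image_id, img in images.items():
        res = count_spots(img, params=params, image_id=image_id,
                          n_cells=cells.get(image_id, 0))
        rows.append({
            "image_id": res.image_id,
            "n_components": res.n_components,
            "n_cells": res.n_cells,
            "dots_per_cell": res.dots_per_cell,
            "gaussian_sigma": params.gaussian_sigma,
            "adaptive_window": params.adaptive_window,
            "adaptive_offset": params.adaptive_offset,
            "min_component_px": params.min_component_px,
        })
    return pd.DataFrame(rows)
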