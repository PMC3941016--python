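"""Hilbert-curve raster rendering of per-marker comparison categories.

Markers of one chromosome, in position order, are laid along a Hilbert
space-filling curve over a 2^k x 2^k pixel grid, one marker per pixel.  The
curve preserves locality, so runs of a category along the chromosome appear
as compact colored patches.  Pixels are colored by comparison category:
match light blue, half-match dark blue, conflict red, marker missing from
one individual grey; unused trailing cells stay white.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image

from .pairwise_similarity import ComparisonCategory

PALETTE: dict[ComparisonCategory, tuple[int, int, int]] = {
    ComparisonCategory.MATCH: (0xAD, 0xD8, 0xE6),       # light blue
    ComparisonCategory.HALF_MATCH: (0x00, 0x00, 0x8B),  # dark blue
    ComparisonCategory.CONFLICT: (0xFF, 0x00, 0x00),    # red
    ComparisonCategory.NO_DATA: (0x80, 0x80, 0x80),     # grey
}
BACKGROUND = (0xFF, 0xFF, 0xFF)


def hilbert_rank_to_xy(d: int, order: int) -> tuple[int, int]:
    """Map curve rank d in [0, 4^order) to grid cell (x, y); d=0 -> (0, 0).

    Standard iterative construction: at each scale the quadrant is read from
    two bits of d and the partial coordinates are rotated/reflected into it.
    """
    if not 0 <= d < 4 ** order:
        raise ValueError(f"rank {d} out of range for order {order}")
    x = y = 0
    t = d
    s = 1
    while s < 2 ** order:
        rx = 1 & (t // 2)
        ry = 1 & (t ^ rx)
        if ry == 0:  # rotate quadrant
            if rx == 1:
                x, y = s - 1 - x, s - 1 - y
            x, y = y, x
        x += s * rx
        y += s * ry
        t //= 4
        s *= 2
    return x, y


@dataclass(frozen=True)
class HilbertLayout:
    """Bijection between linear marker ranks and cells of a 2^k x 2^k grid."""

    order: int

    @property
    def side(self) -> int:
        return 2 ** self.order

    @property
    def n_cells(self) -> int:
        return 4 ** self.order

    def rank_to_xy(self, d: int) -> tuple[int, int]:
        return hilbert_rank_to_xy(d, self.order)

    def coordinates(self, n: int | None = None) -> np.ndarray:
        """(n, 2) array of (x, y) cells for ranks 0..n-1."""
        n = self.n_cells if n is None else n
        return np.array([hilbert_rank_to_xy(d, self.order) for d in range(n)])

    @classmethod
    def fitting(cls, n_markers: int) -> "HilbertLayout":
        """Smallest layout with at least ``n_markers`` cells."""
        if n_markers < 1:
            raise ValueError("need at least one marker")
        order = 0
        while 4 ** order < n_markers:
            order += 1
        return cls(order)


def render_comparison(categories: Sequence[ComparisonCategory], out_path=None,
                      scale: int = 1) -> Image.Image:
    """Paint position-sorted per-marker categories along the Hilbert curve.

    The smallest order whose grid holds all markers is used; the PNG is
    written to ``out_path`` when given and the image returned either way.
    ``scale`` upscales by integer pixel replication for viewing.
    """
    cats = list(categories)
    if not cats:
        raise ValueError("no markers to render")
    layout = HilbertLayout.fitting(len(cats))
    grid = np.full((layout.side, layout.side, 3), BACKGROUND, dtype=np.uint8)
    xy = layout.coordinates(len(cats))
    colors = np.array([PALETTE[c] for c in cats], dtype=np.uint8)
    grid[xy[:, 1], xy[:, 0]] = colors
    img = Image.fromarray(grid, mode="RGB")
    if scale > 1:
        img = img.resize((layout.side * scale,) * 2, Image.NEAREST)
    if out_path is not None:
        img.save(out_path, format="PNG")
    return img


def color_histogram(img: Image.Image) -> dict[ComparisonCategory, int]:
    """Count rendered pixels per category (background excluded); the counts
    equal the category counts of the underlying comparison."""
    arr = np.asarray(img.convert("RGB")).reshape(-1, 3)
    out = {}
    for cat, rgb in PALETTE.items():
        out[cat] = int((arr == np.array(rgb)).all(axis=1).sum())
    return out
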