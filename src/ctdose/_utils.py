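"""Shared helpers: deterministic sub-seed derivation and coordinate grids."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master: int, *keys) -> int:
    """Derive a reproducible 31-bit sub-seed from a master seed and context keys.

    Every stochastic stage of a pipeline (study, dose level, phase, slice)
    draws its own generator from ``derive_seed(master, ...)`` so that one
    master seed fixes the entire run while stages stay independent.
    """
    payload = repr((int(master),) + tuple(keys)).encode()
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def pixel_centers_mm(matrix: int, spacing_mm: float) -> np.ndarray:
    """1-D physical coordinates of pixel centers, origin at the grid center."""
    return (np.arange(matrix) - (matrix - 1) / 2.0) * spacing_mm


def center_grids_mm(matrix: int, spacing_mm: float):
    """(x, y) mm coordinate grids for a square image, origin at center.

    Row index is y, column index is x (image convention).
    """
    c = pixel_centers_mm(matrix, spacing_mm)
    xx, yy = np.meshgrid(c, c)
    return xx, yy
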