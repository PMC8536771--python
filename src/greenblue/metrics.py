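"""Small spatial comparison utilities."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["jaccard", "tolerant_jaccard"]


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Jaccard index |A∩B| / |A∪B| of two boolean masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def tolerant_jaccard(a: np.ndarray, b: np.ndarray, tolerance_cells: int = 2) -> float:
    """Jaccard overlap of two thin rasterized line masks with positional slack.

    Two one-cell-wide lines that trace the same feature but sit a cell or
    two apart would score near zero under the plain index. Dilating both
    masks by ``tolerance_cells`` before intersecting, while keeping the
    union un-dilated, gives

        J_t = |dil(A,t) ∩ dil(B,t) ∩ (A∪B)| / |A∪B|

    which reduces to the plain Jaccard at t = 0, is symmetric, and still
    penalizes feature cells of either mask that have no counterpart within
    the tolerance.
    """
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if tolerance_cells < 0:
        raise ValueError("tolerance must be >= 0")
    union = a | b
    if union.sum() == 0:
        return 1.0
    if tolerance_cells == 0:
        return jaccard(a, b)
    st = np.ones((3, 3), dtype=bool)
    da = ndimage.binary_dilation(a, structure=st, iterations=tolerance_cells)
    db = ndimage.binary_dilation(b, structure=st, iterations=tolerance_cells)
    return float((da & db & union).sum() / union.sum())
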