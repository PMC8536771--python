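"""Patch importance by the probability of connectivity (PC / dPC).

PC = (Σ_i Σ_j p_ij a_i a_j) / A² over **all** ordered patch pairs including
i = j (p_ii = 1), where p_ij is the maximum product of step dispersal
probabilities over all patch sequences joining i and j, a_i is patch area
and A the study-area total. dPC_k = (PC − PC_remove)/PC × 100 is the
percentage loss of connectivity when patch k is deleted (its matrix rows,
columns and area removed; A stays fixed).

The step kernel is the negative exponential calibrated through a reference
distance/probability pair — by default p(2000 m) = 0.5, the Conefor-style
probabilistic-index settings this pipeline inherits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .patches import PatchSet

__all__ = [
    "dispersal_kernel",
    "make_kernel",
    "pairwise_pij",
    "pc_value",
    "compute_PC",
    "compute_dPC",
    "compute_dPC_all",
    "normalize_scores",
    "select_gpas",
]

D_REF_DEFAULT = 2000.0  # metres
P_REF_DEFAULT = 0.5


def dispersal_kernel(d, d_ref: float = D_REF_DEFAULT, p_ref: float = P_REF_DEFAULT):
    """Probability of a direct dispersal step across distance ``d`` (m).

    ``p(d) = p_ref ** (d / d_ref)`` — a negative exponential with
    ``p(0) = 1`` and ``p(d_ref) = p_ref`` exactly.
    """
    if not 0 < p_ref < 1:
        raise ValueError("p_ref must lie strictly between 0 and 1")
    if not d_ref > 0:
        raise ValueError("d_ref must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = p_ref ** (d / d_ref)
    return float(out) if out.ndim == 0 else out


def make_kernel(d_ref: float = D_REF_DEFAULT, p_ref: float = P_REF_DEFAULT):
    """A one-argument kernel closed over the calibration pair."""
    dispersal_kernel(0.0, d_ref, p_ref)  # validate parameters
    return lambda d: dispersal_kernel(d, d_ref, p_ref)


def pairwise_pij(
    patches: PatchSet,
    kernel=None,
    distances: np.ndarray | None = None,
) -> np.ndarray:
    """Maximum path-product dispersal probability between every patch pair.

    The direct step probability is the kernel applied to the minimum
    edge-to-edge distance; routing through stepping-stone patches is allowed,
    and the maximum product over patch sequences is found as a minimal-sum
    path on −log probabilities. The result is symmetric with unit diagonal.
    """
    if kernel is None:
        kernel = make_kernel()
    if len(patches) == 0:
        raise ValueError("empty patch set")
    if distances is None:
        distances = patches.distance_matrix()
    direct = np.asarray(kernel(distances), dtype=float)
    np.fill_diagonal(direct, 1.0)
    with np.errstate(divide="ignore"):
        w = -np.log(direct)
    np.fill_diagonal(w, 0.0)
    dist = shortest_path(w, method="D", directed=False)
    pij = np.exp(-dist)
    np.fill_diagonal(pij, 1.0)
    return pij


def pc_value(areas, total_area: float, pij: np.ndarray) -> float:
    """PC from raw areas, study-area total and a p_ij matrix.

    The double sum runs over all ordered pairs including i = j, so a single
    patch filling the study area gives PC = 1.
    """
    a = np.asarray(areas, dtype=float)
    if pij.shape != (a.size, a.size):
        raise ValueError("p_ij matrix does not match the areas vector")
    if not total_area > 0:
        raise ValueError("study area A must be positive")
    return float(a @ pij @ a) / (total_area * total_area)


def compute_PC(patches: PatchSet, pij: np.ndarray) -> float:
    """Probability of connectivity: (a' P a) / A², in [0, 1]."""
    return pc_value(patches.areas(), patches.total_area, pij)


def compute_dPC(patches: PatchSet, pij: np.ndarray, patch_id: int) -> float:
    """Importance of one patch: % drop in PC when it is removed.

    The patch's rows/columns and area leave the sums; A is kept at the full
    study area. Computed incrementally from the pair-sum rather than by
    rebuilding the matrix.
    """
    a = patches.areas()
    ids = patches.ids
    if patch_id not in ids:
        raise KeyError(f"no patch with id {patch_id}")
    k = ids.index(patch_id)
    A2 = patches.total_area**2
    S = float(a @ pij @ a)
    if S == 0:
        raise ValueError("PC is zero; dPC undefined")
    row_k = float(pij[k] @ a)  # includes the diagonal term a_k
    S_remove = S - 2.0 * a[k] * row_k + pij[k, k] * a[k] * a[k]
    return (S - S_remove) / S * 100.0


def compute_dPC_all(patches: PatchSet, pij: np.ndarray) -> dict[int, float]:
    return {pid: compute_dPC(patches, pij, pid) for pid in patches.ids}


def normalize_scores(values) -> np.ndarray:
    """Scale a non-negative score vector so its maximum is exactly 100."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot normalize an empty score vector")
    if np.any(v < 0):
        raise ValueError("scores must be non-negative")
    m = v.max()
    if m <= 0:
        raise ValueError("cannot normalize an all-zero score vector")
    return v / m * 100.0  # x/x == 1 exactly in IEEE, so the max is exactly 100


def select_gpas(patches: PatchSet, normalized_dpc: dict[int, float], threshold: float = 10.0) -> PatchSet:
    """Patches whose normalized dPC is **strictly** above the threshold."""
    keep = [pid for pid in patches.ids if normalized_dpc[pid] > threshold]
    return patches.subset(keep)


def export_conefor(patches: PatchSet, distances: np.ndarray, prefix: str | Path) -> None:
    """Write Conefor-style node and connection text files for cross-checks."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".nodes.txt"), "w") as fh:
        for p in patches:
            fh.write(f"{p.id} {p.area!r}\n")
    ids = patches.ids
    with open(prefix.with_suffix(".connections.txt"), "w") as fh:
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                fh.write(f"{ids[i]} {ids[j]} {distances[i, j]!r}\n")
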