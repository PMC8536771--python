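"""Corridor interaction scoring by the improved gravity model.

The interaction force between patches a and b joined by a least-cost
corridor is

    G_ab = L_max² · ln(S_a S_b) / (L_ab² · P_a · P_b)

with S the patch areas, P the patch resistance values, L_ab the corridor's
accumulated resistance and L_max the maximum over all corridors. Larger,
lower-resistance patches joined by cheaper corridors interact more strongly.
Areas enter in hectares by default so the log argument stays above 1 even
for sub-km² patches.

Corridors are kept as ecological-candidate links when their normalized G_ab
(scaled so the maximum is 100) strictly exceeds a threshold (default 2) and
both endpoints are selected GPAs.
"""

from __future__ import annotations

import math

import pandas as pd

from .connectivity import normalize_scores
from .mcr import CorridorSet
from .patches import PatchSet

__all__ = ["gravity_force", "score_corridors", "filter_candidate_corridors"]

_AREA_SCALE = {"m2": 1.0, "km2": 1e-6, "ha": 1e-4}


def gravity_force(S_a: float, S_b: float, P_a: float, P_b: float, L_ab: float, L_max: float) -> float:
    """Interaction force between two patches; see module docstring."""
    if L_ab <= 0:
        raise ValueError("corridor resistance L_ab must be positive")
    if L_max < L_ab:
        raise ValueError("L_max must be >= L_ab")
    if P_a <= 0 or P_b <= 0:
        raise ValueError("patch resistances must be positive")
    if S_a * S_b <= 1:
        raise ValueError(
            "S_a*S_b must exceed 1 for a positive log; check the area unit "
            "(hectare areas of real patches satisfy this)"
        )
    return (L_max**2) * math.log(S_a * S_b) / (L_ab**2 * P_a * P_b)


def score_corridors(
    corridors: CorridorSet,
    patches: PatchSet,
    area_unit: str = "ha",
) -> pd.DataFrame:
    """G_ab for every corridor, raw and normalized to a maximum of 100.

    Requires patch resistances P (``PatchSet.attach_resistance``). Returns a
    table with columns a, b, L_ab, G_raw, G_norm sorted by (a, b).
    """
    scale = _AREA_SCALE[area_unit]
    L_max = corridors.L_max
    rows = []
    for key in sorted(corridors.corridors):
        cor = corridors.corridors[key]
        pa, pb = patches[cor.a], patches[cor.b]
        if pa.resistance is None or pb.resistance is None:
            raise ValueError("patch resistances missing; call attach_resistance first")
        g = gravity_force(
            pa.area * scale, pb.area * scale, pa.resistance, pb.resistance, cor.cost, L_max
        )
        rows.append({"a": cor.a, "b": cor.b, "L_ab": cor.cost, "G_raw": g})
    df = pd.DataFrame(rows)
    df["G_norm"] = normalize_scores(df["G_raw"].to_numpy())
    return df


def filter_candidate_corridors(
    scores: pd.DataFrame,
    corridors: CorridorSet,
    selected_ids,
    threshold: float = 2.0,
) -> tuple[CorridorSet, pd.DataFrame]:
    """Corridors with normalized G_ab strictly above threshold and both
    endpoints among the selected GPAs.

    Returns the surviving CorridorSet and the score table with a
    ``selected`` column added.
    """
    selected_ids = set(selected_ids)
    scores = scores.copy()
    keep_mask = (
        (scores["G_norm"] > threshold)
        & scores["a"].isin(selected_ids)
        & scores["b"].isin(selected_ids)
    )
    scores["selected"] = keep_mask
    kept = {
        (int(r.a), int(r.b)): corridors.corridors[(int(r.a), int(r.b))]
        for r in scores[keep_mask].itertuples()
    }
    return CorridorSet(kept, list(corridors.missing)), scores
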