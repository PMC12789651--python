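"""Egg-shaped background sampling and feature-table assembly.

For each scene, one of the three eggs is chosen at random as a template and
27 copies of its mask are translated (never rotated — sample orientation
follows the template egg) to random positions on the background.  Valid
positions keep the whole template inside the image and off the exclusion
zone (eggs, nest scrape margin, ruler, colour chart); samples may overlap
one another, since with 27 egg-areas on a bounded scene mutual exclusion can
be infeasible.  Placement is uniform over the valid offset set, implemented
by rejection sampling from the bounding rectangle with a hard draw budget.

Each scene then contributes 30 rows to the feature table — 3 eggs and 27
background samples — giving a fixed 0.1 prior probability that a randomly
chosen sample is an egg.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REJECTION_BUDGET = 100_000
N_BACKGROUND_SAMPLES = 27


class InfeasibleSceneError(RuntimeError):
    """Scene cannot host the requested number of background samples."""


class IncompleteSceneError(ValueError):
    """A scene is missing features for one or more regions."""


@dataclass
class SamplePlan:
    scene_id: str
    template_egg_index: int
    template_bbox: tuple[int, int, int, int]   # r0, c0, h, w (half-open)
    placements: list[tuple[int, int]]          # top-left offsets of the template box
    seed: int

    def to_dict(self) -> dict:
        return {
            "scene_id": self.scene_id,
            "template_egg_index": int(self.template_egg_index),
            "template_bbox": [int(v) for v in self.template_bbox],
            "placements": [[int(r), int(c)] for r, c in self.placements],
            "seed": int(self.seed),
        }


def scene_seed(global_seed: int, nest_id: str) -> int:
    """Deterministic per-scene seed from the global seed and the nest id."""
    return (int(global_seed) ^ zlib.crc32(nest_id.encode())) % (2 ** 31 - 1)


def _bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    return r0, c0, r1 - r0, c1 - c0


def plan_background_samples(scene, n: int = N_BACKGROUND_SAMPLES,
                            seed: int = 0) -> SamplePlan:
    """Plan ``n`` egg-shaped background sample placements for one scene.

    ``scene`` needs ``masks`` (a MaskSet) and ``nest_id``.  The template egg
    is chosen uniformly at random; offsets are drawn by rejection until
    ``n`` placements fully avoid the exclusion mask, or the draw budget is
    exhausted.
    """
    rng = np.random.default_rng(seed)
    masks = scene.masks
    rows, cols = masks.shape
    template_idx = int(rng.integers(len(masks.egg_masks)))
    egg_mask = masks.egg_masks[template_idx]
    r0, c0, h, w = _bbox(egg_mask)
    template = egg_mask[r0:r0 + h, c0:c0 + w]
    egg_area = int(template.sum())
    background_area = rows * cols - int(masks.exclusion_mask.sum())
    # feasibility heuristic at the design scale; samples may overlap each
    # other, so large n does not demand proportionally more free area
    needed = min(n, N_BACKGROUND_SAMPLES) * egg_area
    if n > 0 and background_area < needed:
        raise InfeasibleSceneError(
            f"background area {background_area} px^2 cannot host "
            f"{n} samples of {egg_area} px^2")
    placements: list[tuple[int, int]] = []
    exclusion = masks.exclusion_mask
    draws = 0
    while len(placements) < n:
        if draws >= REJECTION_BUDGET:
            raise InfeasibleSceneError(
                f"rejection budget {REJECTION_BUDGET} exhausted after "
                f"{len(placements)} placements")
        draws += 1
        rr = int(rng.integers(0, rows - h + 1))
        cc = int(rng.integers(0, cols - w + 1))
        if (exclusion[rr:rr + h, cc:cc + w] & template).any():
            continue
        placements.append((rr, cc))
    return SamplePlan(scene_id=scene.nest_id, template_egg_index=template_idx,
                      template_bbox=(r0, c0, h, w), placements=placements, seed=seed)


def region_masks(scene, plan: SamplePlan) -> list[tuple[str, int, np.ndarray]]:
    """The 30 region masks of a scene: (object_type, sample_index, mask).

    Egg regions use the true egg masks (sample_index 0-2); background
    regions are the planned template translations (sample_index 0-26).
    """
    masks = scene.masks
    r0, c0, h, w = plan.template_bbox
    template = masks.egg_masks[plan.template_egg_index][r0:r0 + h, c0:c0 + w]
    out = []
    for i, egg in enumerate(masks.egg_masks):
        out.append(("egg", i, egg))
    for i, (rr, cc) in enumerate(plan.placements):
        m = np.zeros(masks.shape, dtype=bool)
        m[rr:rr + h, cc:cc + w] = template
        out.append(("background", i, m))
    return out


def build_feature_table(colour_rows: pd.DataFrame,
                        texture_rows: pd.DataFrame) -> pd.DataFrame:
    """Merge per-region colour and texture rows into the analysis table.

    Both inputs carry (nest_id, habitat, object_type, sample_index) keys.
    Validates the 30-rows-per-scene design (3 eggs : 27 backgrounds) and
    that no region is missing features.
    """
    keys = ["nest_id", "habitat", "object_type", "sample_index"]
    merged = colour_rows.merge(texture_rows, on=keys, how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", keys].iloc[0].to_dict()
        raise IncompleteSceneError(f"missing colour or texture features for {bad}")
    merged = merged.drop(columns="_merge")
    for nest_id, grp in merged.groupby("nest_id"):
        counts = grp["object_type"].value_counts()
        if counts.get("egg", 0) != 3 or counts.get("background", 0) != N_BACKGROUND_SAMPLES:
            raise IncompleteSceneError(
                f"scene {nest_id} has {counts.to_dict()} regions; expected 3 eggs "
                f"and {N_BACKGROUND_SAMPLES} background samples")
    return merged.sort_values(keys).reset_index(drop=True)
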