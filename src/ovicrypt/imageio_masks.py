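"""Image and colour-keyed mask I/O.

A scene on disk is a pair of rasters plus a JSON sidecar: a 16-bit PNG (or
TIFF) holding the linearised photograph, and an 8-bit indexed PNG holding the
hand-painted (or generated) masks.  The mask palette is fixed: the three eggs
are cyan, magenta and yellow (in that order), a 40 mm ruler segment is green,
the 20 %-reflectance grey square of the colour chart is red, and an optional
blue key marks an explicit exclusion zone (e.g. the nest scrape).  Decoding
is by exact 8-bit palette match; anti-aliased masks are rejected as
malformed.

Coordinate convention, used across the whole package: 0-based, row-major,
origin at the top-left; rectangles are half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from PIL import Image
from scipy import ndimage

EGG_COLOURS = (("cyan", (0, 255, 255)),
               ("magenta", (255, 0, 255)),
               ("yellow", (255, 255, 0)))
RULER_COLOUR = ("green", (0, 255, 0))
GREY_COLOUR = ("red", (255, 0, 0))
EXCLUSION_COLOUR = ("blue", (0, 0, 255))
BACKGROUND_COLOUR = ("black", (0, 0, 0))

_KNOWN_RGB = {rgb for _, rgb in
              (*EGG_COLOURS, RULER_COLOUR, GREY_COLOUR, EXCLUSION_COLOUR, BACKGROUND_COLOUR)}

#: margin (px) by which egg/ruler/grey masks are dilated to form the default
#: exclusion zone when no explicit zone is painted
DEFAULT_EXCLUSION_MARGIN = 5


class MalformedMaskError(ValueError):
    """Mask raster does not decode to the expected palette regions."""


class EmptyRegionError(ValueError):
    """An operation was asked for a region with no pixels."""


@dataclass
class MaskSet:
    """Named boolean rasters for the regions of one scene."""

    egg_masks: list[np.ndarray]
    ruler_mask: np.ndarray
    grey_mask: np.ndarray
    exclusion_mask: np.ndarray
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.shape = tuple(self.shape)
        for m in (*self.egg_masks, self.ruler_mask, self.grey_mask, self.exclusion_mask):
            if m.shape != tuple(self.shape):
                raise MalformedMaskError("all masks must share one shape")
        for i in range(len(self.egg_masks)):
            for j in range(i + 1, len(self.egg_masks)):
                if (self.egg_masks[i] & self.egg_masks[j]).any():
                    raise MalformedMaskError(f"egg masks {i} and {j} overlap")
        core = self.ruler_mask | self.grey_mask
        for m in self.egg_masks:
            core = core | m
        if (core & ~self.exclusion_mask).any():
            raise MalformedMaskError("egg/ruler/grey masks must lie inside the exclusion mask")

    @classmethod
    def with_default_exclusion(
        cls,
        egg_masks: list[np.ndarray],
        ruler_mask: np.ndarray,
        grey_mask: np.ndarray,
        extra_exclusion: np.ndarray | None = None,
        margin: int = DEFAULT_EXCLUSION_MARGIN,
    ) -> "MaskSet":
        """Build a mask set whose exclusion zone is the union of all labelled
        regions dilated by ``margin`` pixels, plus any explicit extra zone."""
        union = ruler_mask | grey_mask
        for m in egg_masks:
            union = union | m
        exclusion = ndimage.binary_dilation(union, iterations=margin)
        if extra_exclusion is not None:
            exclusion = exclusion | extra_exclusion
        return cls(egg_masks=list(egg_masks), ruler_mask=ruler_mask,
                   grey_mask=grey_mask, exclusion_mask=exclusion,
                   shape=ruler_mask.shape)


@dataclass
class RawScene:
    """A scene as read from disk: linear image plus decoded masks."""

    image: np.ndarray
    masks: MaskSet
    nest_id: str
    habitat_label: str
    gains: np.ndarray | None = None   # set by grey calibration


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _mask_to_indexed(masks: MaskSet) -> Image.Image:
    """Encode a MaskSet as an indexed PNG with the fixed palette."""
    names_colours = [BACKGROUND_COLOUR, *EGG_COLOURS, RULER_COLOUR, GREY_COLOUR, EXCLUSION_COLOUR]
    index = np.zeros(masks.shape, dtype=np.uint8)
    # paint exclusion first so the specific labels take priority over it
    labelled = masks.ruler_mask | masks.grey_mask
    for m in masks.egg_masks:
        labelled = labelled | m
    index[masks.exclusion_mask & ~labelled] = 6
    for i, m in enumerate(masks.egg_masks):
        index[m] = 1 + i
    index[masks.ruler_mask] = 4
    index[masks.grey_mask] = 5
    img = Image.fromarray(index, mode="P")
    palette = []
    for _, rgb in names_colours:
        palette.extend(rgb)
    img.putpalette(palette)
    return img


def write_scene(scene, out_dir: str | Path, stem: str | None = None) -> dict:
    """Write a scene as 16-bit image PNG + indexed mask PNG + JSON sidecar.

    Accepts any object with ``image``, ``masks``, ``nest_id`` and
    ``habitat_label`` attributes (synthetic scenes additionally carry their
    ``ground_truth``, which is stored in the sidecar).  Returns the paths
    written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or scene.nest_id
    # 16-bit linear image as TIFF (the available PNG encoders cannot write
    # 16-bit RGB); masks stay 8-bit indexed PNG
    image_path = out_dir / f"{stem}_image.tiff"
    mask_path = out_dir / f"{stem}_mask.png"
    meta_path = out_dir / f"{stem}_meta.json"
    img16 = np.round(np.clip(scene.image, 0.0, 1.0) * 65535.0).astype(np.uint16)
    iio.imwrite(image_path, img16)
    _mask_to_indexed(scene.masks).save(mask_path)
    meta = {
        "nest_id": scene.nest_id,
        "habitat": scene.habitat_label,
        "ground_truth": getattr(scene, "ground_truth", None),
    }
    meta_path.write_text(json.dumps(meta, indent=1, default=_json_default))
    return {"image": image_path, "mask": mask_path, "meta": meta_path}


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _load_linear_image(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if np.issubdtype(arr.dtype, np.floating):
        return np.asarray(arr, dtype=float)
    raise MalformedMaskError(f"unsupported image dtype {arr.dtype} in {path}")


def decode_mask_image(rgb: np.ndarray) -> MaskSet:
    """Decode an H x W x 3 uint8 raster into a MaskSet by exact palette match."""
    if rgb.ndim != 3 or rgb.shape[-1] < 3:
        raise MalformedMaskError("mask raster must be RGB")
    rgb = rgb[..., :3]
    packed = (rgb[..., 0].astype(np.int64) << 16) | (rgb[..., 1].astype(np.int64) << 8) \
        | rgb[..., 2].astype(np.int64)
    known = {(r << 16) | (g << 8) | b for (r, g, b) in _KNOWN_RGB}
    present = set(np.unique(packed).tolist())
    unknown = present - known
    if unknown:
        v = unknown.pop()
        raise MalformedMaskError(
            f"unknown mask colour #{v:06X}; masks must use the exact palette "
            "(anti-aliased masks are rejected)")

    def plane(rgb_key):
        r, g, b = rgb_key
        return packed == ((r << 16) | (g << 8) | b)

    egg_masks = []
    for name, key in EGG_COLOURS:
        m = plane(key)
        if not m.any():
            raise MalformedMaskError(f"missing egg mask colour: {name}")
        egg_masks.append(m)
    ruler = plane(RULER_COLOUR[1])
    if not ruler.any():
        raise MalformedMaskError("missing ruler mask colour: green")
    grey = plane(GREY_COLOUR[1])
    if not grey.any():
        raise MalformedMaskError("missing grey-standard mask colour: red")
    explicit_exclusion = plane(EXCLUSION_COLOUR[1])
    return MaskSet.with_default_exclusion(
        egg_masks, ruler, grey,
        extra_exclusion=explicit_exclusion if explicit_exclusion.any() else None)


def read_scene(image_path: str | Path, mask_path: str | Path,
               metadata: dict | None = None) -> RawScene:
    """Read an image/mask pair from disk into a RawScene.

    Integer samples are mapped to [0, 1] by division by the format maximum;
    mask colours are decoded by exact palette match.  If no metadata dict is
    given, the sidecar JSON next to the image is used when present.
    """
    image = _load_linear_image(image_path)
    mask_rgb = np.asarray(Image.open(mask_path).convert("RGB"))
    if mask_rgb.shape[:2] != image.shape[:2]:
        raise MalformedMaskError(
            f"image {image.shape[:2]} and mask {mask_rgb.shape[:2]} dimensions differ")
    masks = decode_mask_image(mask_rgb)
    if metadata is None:
        p = Path(image_path)
        side = p.with_name(p.stem.replace("_image", "_meta") + ".json")
        metadata = json.loads(side.read_text()) if side.exists() else {}
    return RawScene(image=image, masks=masks,
                    nest_id=str(metadata.get("nest_id", Path(image_path).stem)),
                    habitat_label=str(metadata.get("habitat", "unknown")))


def region_pixels(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Return the N x 3 pixels where ``mask`` is true, in row-major order."""
    if not mask.any():
        raise EmptyRegionError("mask selects no pixels")
    return image[mask]


def read_manifest(manifest_path: str | Path) -> list[RawScene]:
    """Read scenes listed in a CSV manifest (nest_id, habitat, image_path, mask_path)."""
    import pandas as pd

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    required = {"nest_id", "habitat", "image_path", "mask_path"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    scenes = []
    for _, row in df.iterrows():
        image_path = manifest_path.parent / row["image_path"]
        mask_path = manifest_path.parent / row["mask_path"]
        scenes.append(read_scene(image_path, mask_path,
                                 {"nest_id": row["nest_id"], "habitat": row["habitat"]}))
    return scenes
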