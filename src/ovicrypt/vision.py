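"""Colour metrics per visual system.

'Colour' is collapsed to three variables per system: luminance (achromatic
brightness), a red-green opponent value and a yellow-blue opponent value.

* Avian (VS tetrachromat, violet cone omitted): luminance is the
  double-cone catch D; rg = (L - M) / (L + M); yb compares the pooled
  long/medium catch with the short-wave catch, ((L+M)/2 - S) / ((L+M)/2 + S).
* Carnivore (dichromat, ferret-like): luminance is the L-cone catch (the
  long-wave mechanism dominates achromatic vision in dichromats);
  yb = (L - S) / (L + S); no red-green channel exists.
* Human: CIE L*a*b* (L* = luminance, a* = red-green, b* = yellow-blue),
  computed from linear sRGB via XYZ under D65.

The Michelson-style contrast form (A - B) / (A + B) is intensity-invariant
and bounded in [-1, 1]; it is isolated in :func:`opponent_contrast` so an
alternative opponency could be swapped in.  Region colour is computed
mean-then-transform: receptor catches are pooled over the region first and
the opponent transform applied to the means, matching the spatial pooling
that precedes opponency when a patch is viewed at a distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import xyz2lab

from .imageio_masks import EmptyRegionError


class UndefinedChromaticityError(ValueError):
    """Opponent value undefined (zero denominator)."""


@dataclass
class ConeCatchImage:
    """Per-pixel quantum catches for one visual system."""

    system_name: str
    planes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) > 1:
            raise ValueError("cone planes must share one shape")
        for name, p in self.planes.items():
            if np.any(p < 0):
                raise ValueError(f"negative catches in plane {name}")


@dataclass(frozen=True)
class ColourTriplet:
    """(luminance, rg, yb) for avian/carnivore; (L*, a*, b*) for human."""

    luminance: float
    rg: float | None
    yb: float
    system: str = ""


def opponent_contrast(a: float, b: float) -> float:
    """Michelson contrast (a - b) / (a + b)."""
    denom = a + b
    if denom <= 0:
        raise UndefinedChromaticityError("opponent denominator is zero")
    return (a - b) / denom


def avian_channels(d: float, l: float, m: float, s: float,
                   contrast=opponent_contrast) -> ColourTriplet:
    """Avian colour triplet from double-cone and L/M/S single-cone catches.

    The opponency is the Michelson contrast by default; ``contrast`` accepts
    any (a, b) -> float alternative, since the exact opponent form is a
    modelling assumption rather than a measured quantity.
    """
    if min(d, l, m, s) < 0:
        raise ValueError("catches must be non-negative")
    rg = contrast(l, m)
    yb = contrast(0.5 * (l + m), s)
    return ColourTriplet(luminance=float(d), rg=float(rg), yb=float(yb), system="avian")


def carnivore_channels(l: float, s: float,
                       contrast=opponent_contrast) -> ColourTriplet:
    """Dichromat colour pair: L-cone luminance and a yellow-blue opponent."""
    if min(l, s) < 0:
        raise ValueError("catches must be non-negative")
    yb = contrast(l, s)
    return ColourTriplet(luminance=float(l), rg=None, yb=float(yb), system="carnivore")


# linear sRGB -> XYZ (D65, 2 degree observer)
_RGB_TO_XYZ = np.array([
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
])


def linear_rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """Linear sRGB (in [0, 1]) to CIE XYZ with white Y = 1."""
    rgb = np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0)
    return rgb @ _RGB_TO_XYZ.T


def human_lab(rgb: tuple[float, float, float]) -> ColourTriplet:
    """CIE L*a*b* of a linear-sRGB triplet (clipped into gamut first)."""
    xyz = linear_rgb_to_xyz(np.asarray(rgb, dtype=float).reshape(1, 1, 3))
    lab = xyz2lab(xyz)[0, 0]
    return ColourTriplet(luminance=float(lab[0]), rg=float(lab[1]),
                         yb=float(lab[2]), system="human")


def luminance_plane_y(rgb_image: np.ndarray) -> np.ndarray:
    """CIE Y luminance plane of a linear-RGB image.

    One shared luminance plane serves the texture analysis for all modelled
    visual systems; across regions the avian double-cone, carnivore L and
    CIE Y luminances are very highly correlated, so a single plane loses
    essentially nothing.
    """
    return rgb_image @ _RGB_TO_XYZ[1]


def human_xyz_image(rgb_image: np.ndarray) -> ConeCatchImage:
    """Represent human vision as an XYZ catch image (Y is the luminance plane)."""
    xyz = linear_rgb_to_xyz(rgb_image)
    return ConeCatchImage(system_name="human",
                          planes={"X": xyz[..., 0], "Y": xyz[..., 1], "Z": xyz[..., 2]})


def region_colour(catch_image: ConeCatchImage, mask: np.ndarray) -> ColourTriplet:
    """Colour triplet of a region: mean catch per plane, then opponency."""
    if not mask.any():
        raise EmptyRegionError("region mask selects no pixels")
    means = {name: float(plane[mask].mean()) for name, plane in catch_image.planes.items()}
    sys_name = catch_image.system_name
    if sys_name == "avian":
        return avian_channels(means["D"], means["L"], means["M"], means["S"])
    if sys_name == "carnivore":
        return carnivore_channels(means["L"], means["S"])
    if sys_name == "human":
        xyz = np.array([[[means["X"], means["Y"], means["Z"]]]])
        lab = xyz2lab(xyz)[0, 0]
        return ColourTriplet(luminance=float(lab[0]), rg=float(lab[1]),
                             yb=float(lab[2]), system="human")
    raise KeyError(f"unknown visual system '{sys_name}'")
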