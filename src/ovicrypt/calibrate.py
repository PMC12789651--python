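"""Calibration: grey-standard gains, ruler-based rescaling, cone-catch mapping.

Three steps turn a linearised photograph into predator-eye inputs:

1. **Grey calibration** — per-channel gains force the 20 %-reflectance grey
   square to read 0.20 in R, G and B, normalising exposure and white point
   in one move.
2. **Rescaling** — the 40 mm ruler segment fixes the spatial scale; images
   and masks are resampled (nearest-neighbour, to preserve the sharp
   maculation edges) to the standard 12 px/mm.
3. **Cone-catch mapping** — a quadratic polynomial in the calibrated R, G, B
   values predicts the quantum catches of each receptor of each modelled
   visual system (avian VS tetrachromat reduced to D/L/M/S without the
   violet cone, dichromatic carnivore L/S, trichromatic human L/M/S).  The
   polynomial is fitted by least squares on the responses of camera and
   cones to a bank of smooth synthetic reflectance spectra under D65, with
   a held-out split reporting per-cone R^2.

Spectral sensitivities are built from the Govardovskii A1 visual-pigment
nomogram parameterised by lambda-max, with avian oil-droplet filtering
approximated by a per-cone long-pass cutoff.  All curves live on a common
400-700 nm grid (5 nm step) and are normalised to unit peak; quantum catches
are normalised so a perfect (unit) reflector yields a catch of 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .imageio_masks import MaskSet, RawScene
from .vision import ConeCatchImage

STANDARD_RES_PX_PER_MM = 12.0
DEFAULT_GREY_TARGET = 0.20


class SaturationError(ValueError):
    """Grey patch unusable (saturated or underexposed)."""


class FiducialError(ValueError):
    """Ruler mask degenerate or implied resolution implausible."""


class SpectralGridError(ValueError):
    """Spectra defined on incompatible wavelength grids."""


class CollinearityError(ValueError):
    """Polynomial design matrix is rank deficient."""


# ---------------------------------------------------------------------------
# grey calibration
# ---------------------------------------------------------------------------

def grey_calibrate(scene: RawScene, grey_target: float = DEFAULT_GREY_TARGET) -> RawScene:
    """Apply per-channel gains so the grey patch means equal ``grey_target``.

    Gain_c = grey_target / mean(grey pixels, channel c); the whole image is
    multiplied by the gains.  Idempotent: a second application finds the
    patch already at target and applies unit gains.
    """
    if not scene.masks.grey_mask.any():
        raise SaturationError("grey mask is empty")
    means = scene.image[scene.masks.grey_mask].mean(axis=0)
    if np.any(means < 1e-6):
        raise SaturationError(f"grey patch channel mean(s) near zero: {means}")
    gains = grey_target / means
    image = np.clip(scene.image * gains[None, None, :], 0.0, None)
    return RawScene(image=image, masks=scene.masks, nest_id=scene.nest_id,
                    habitat_label=scene.habitat_label, gains=gains)


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

@dataclass
class CalibratedScene:
    """Colour- and size-standardised scene at 12 px/mm."""

    image: np.ndarray
    masks: MaskSet
    nest_id: str
    habitat_label: str
    scale_px_per_mm: float = STANDARD_RES_PX_PER_MM
    calibration_gains: np.ndarray | None = None


def ruler_extent_px(ruler_mask: np.ndarray) -> float:
    """Longer side of the ruler mask's bounding box, in pixels."""
    rows = np.any(ruler_mask, axis=1)
    cols = np.any(ruler_mask, axis=0)
    if not rows.any():
        raise FiducialError("ruler mask is empty")
    h = int(np.flatnonzero(rows).max() - np.flatnonzero(rows).min() + 1)
    w = int(np.flatnonzero(cols).max() - np.flatnonzero(cols).min() + 1)
    return float(max(h, w))


def rescale_to_standard(
    scene: RawScene | CalibratedScene,
    ruler_length_mm: float = 40.0,
    target_res: float = STANDARD_RES_PX_PER_MM,
    allow_upscale: bool = False,
) -> CalibratedScene:
    """Resample the scene so the ruler spans ``ruler_length_mm * target_res`` px.

    Nearest-neighbour interpolation keeps the sharp dark-light maculation
    edges and keeps masks boolean and disjoint.  In normal operation only
    downscaling occurs (photographs are standardised to the lowest working
    resolution); upscaling requires ``allow_upscale=True``.
    """
    extent = ruler_extent_px(scene.masks.ruler_mask)
    if extent < 10:
        raise FiducialError(f"degenerate ruler mask extent {extent} px")
    current_res = extent / ruler_length_mm
    factor = target_res / current_res
    if not (0.8 <= factor <= 1.2):
        raise FiducialError(
            f"implied resolution {current_res:.2f} px/mm outside +-20% of target {target_res}")
    if factor > 1.0 + 1e-9 and not allow_upscale:
        raise FiducialError("upscaling required but not enabled (allow_upscale=False)")
    gains = getattr(scene, "gains", None)
    if gains is None:
        gains = getattr(scene, "calibration_gains", None)
    if abs(factor - 1.0) < 1e-9:
        return CalibratedScene(image=scene.image, masks=scene.masks,
                               nest_id=scene.nest_id, habitat_label=scene.habitat_label,
                               scale_px_per_mm=target_res, calibration_gains=gains)
    rows, cols = scene.masks.shape
    out_shape = (max(1, round(rows * factor)), max(1, round(cols * factor)))

    def nn(arr):
        return resize(arr, out_shape, order=0, preserve_range=True,
                      anti_aliasing=False)

    image = nn(scene.image)
    masks = MaskSet(
        egg_masks=[nn(m).astype(bool) for m in scene.masks.egg_masks],
        ruler_mask=nn(scene.masks.ruler_mask).astype(bool),
        grey_mask=nn(scene.masks.grey_mask).astype(bool),
        exclusion_mask=nn(scene.masks.exclusion_mask).astype(bool),
        shape=out_shape,
    )
    return CalibratedScene(image=image, masks=masks, nest_id=scene.nest_id,
                           habitat_label=scene.habitat_label,
                           scale_px_per_mm=target_res, calibration_gains=gains)


# ---------------------------------------------------------------------------
# spectral machinery
# ---------------------------------------------------------------------------

# CIE standard illuminant D65 relative spectral power, 400-700 nm at 10 nm
_D65_10NM = np.array([
    82.75, 91.49, 93.43, 86.68, 104.86, 117.01, 117.81, 114.86, 115.92,
    108.81, 109.35, 107.80, 104.79, 107.69, 104.41, 104.05, 100.00, 96.33,
    95.79, 88.69, 90.01, 89.60, 87.70, 83.29, 83.70, 80.03, 80.21, 82.28,
    78.28, 69.72, 71.61,
])


def d65_illuminant(wavelengths: np.ndarray) -> np.ndarray:
    """CIE D65 relative irradiance interpolated onto ``wavelengths``."""
    grid10 = np.arange(400, 701, 10)
    return np.interp(wavelengths, grid10, _D65_10NM)


def pigment_nomogram(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """Govardovskii et al. A1 visual-pigment alpha-band template, unit peak."""
    x = lambda_max / np.asarray(wavelengths, dtype=float)
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    s = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
               + np.exp(-14.9 * (1.104 - x)) + 0.674)
    return s / s.max()


def _longpass(wavelengths: np.ndarray, cutoff_nm: float, slope_nm: float = 8.0) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(wavelengths - cutoff_nm) / slope_nm))


@dataclass
class SpectralSystem:
    """Wavelength grid, illuminant, camera sensors and per-species cone sets."""

    wavelengths_nm: np.ndarray
    illuminant: np.ndarray
    sensor_sensitivities: dict[str, np.ndarray]   # camera R, G, B
    cone_sets: dict[str, dict[str, np.ndarray]]   # system -> cone -> curve

    def __post_init__(self) -> None:
        n = len(self.wavelengths_nm)
        curves = list(self.sensor_sensitivities.values())
        for cones in self.cone_sets.values():
            curves.extend(cones.values())
        for c in (self.illuminant, *curves):
            if len(c) != n:
                raise SpectralGridError("all curves must live on the wavelength grid")
            if np.any(np.asarray(c) < 0):
                raise ValueError("sensitivity/illuminant curves must be non-negative")


#: default lambda-max (nm) per receptor; the avian set follows the peafowl
#: VS-type arrangement (double cone plus L/M/S singles, no violet cone),
#: carnivore the ferret dichromat, human the CIE-like trichromat.
DEFAULT_LAMBDA_MAX = {
    "camera": {"R": 600.0, "G": 540.0, "B": 460.0},
    "avian": {"D": 570.0, "L": 605.0, "M": 537.0, "S": 477.0},
    "carnivore": {"L": 558.0, "S": 430.0},
    "human": {"L": 566.0, "M": 541.0, "S": 441.0},
}

#: avian oil-droplet long-pass cutoffs (nm); None disables filtering
DEFAULT_OIL_DROPLET_CUTOFF = {"D": 460.0, "L": 560.0, "M": 505.0, "S": 445.0}


def make_default_system(
    step_nm: float = 5.0,
    lambda_max: dict | None = None,
    oil_droplet_cutoff: dict | None = None,
) -> SpectralSystem:
    """Build the default spectral system on a 400-700 nm grid."""
    lm = lambda_max or DEFAULT_LAMBDA_MAX
    oil = DEFAULT_OIL_DROPLET_CUTOFF if oil_droplet_cutoff is None else oil_droplet_cutoff
    wl = np.arange(400.0, 700.0 + step_nm / 2, step_nm)
    sensors = {name: pigment_nomogram(wl, peak) for name, peak in lm["camera"].items()}
    cone_sets: dict[str, dict[str, np.ndarray]] = {}
    for system in ("avian", "carnivore", "human"):
        cones = {}
        for name, peak in lm[system].items():
            curve = pigment_nomogram(wl, peak)
            if system == "avian" and oil.get(name) is not None:
                curve = curve * _longpass(wl, oil[name])
                curve = curve / curve.max()
            cones[name] = curve
        cone_sets[system] = cones
    return SpectralSystem(wavelengths_nm=wl, illuminant=d65_illuminant(wl),
                          sensor_sensitivities=sensors, cone_sets=cone_sets)


def quantum_catch(reflectance: np.ndarray, sensitivity: np.ndarray,
                  illuminant: np.ndarray) -> float:
    """Illuminant-weighted catch, normalised so a unit reflector catches 1."""
    reflectance = np.asarray(reflectance, dtype=float)
    if reflectance.shape[-1] != len(sensitivity) or len(sensitivity) != len(illuminant):
        raise SpectralGridError("reflectance, sensitivity and illuminant grids differ")
    weight = np.asarray(sensitivity) * np.asarray(illuminant)
    return (reflectance * weight).sum(axis=-1) / weight.sum()


def synthetic_spectra_bank(n: int = 200, seed: int = 1,
                           wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Smooth synthetic reflectance spectra: linear ramp + 1-3 broad Gaussians.

    Natural reflectance spectra are strongly band-limited (their variation
    across 300 nm is captured by a handful of smooth basis functions), so
    the bank uses Gaussian features of 70-220 nm width over a sloped base;
    values are clipped to [0, 1].  Returns an (n, n_wavelengths) array.
    """
    wl = np.arange(400.0, 700.0 + 2.5, 5.0) if wavelengths is None else np.asarray(wavelengths)
    rng = np.random.default_rng(seed)
    bank = np.empty((n, len(wl)))
    for i in range(n):
        base = rng.uniform(0.05, 0.6)
        ramp = rng.uniform(-0.4, 0.6)
        spec = base + ramp * (wl - 550.0) / 300.0
        for _ in range(rng.integers(1, 4)):
            amp = rng.uniform(-0.5, 0.8)
            centre = rng.uniform(400.0, 700.0)
            width = rng.uniform(70.0, 220.0)
            spec = spec + amp * np.exp(-((wl - centre) ** 2) / (2 * width ** 2))
        bank[i] = np.clip(spec, 0.0, 1.0)
    return bank


# ---------------------------------------------------------------------------
# RGB -> cone-catch mapping
# ---------------------------------------------------------------------------

_TERMS_BY_DEGREE = {
    1: ("1", "R", "G", "B"),
    2: ("1", "R", "G", "B", "R2", "G2", "B2", "RG", "RB", "GB"),
}


def _design_matrix(rgb: np.ndarray, degree: int) -> np.ndarray:
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    cols = [np.ones_like(r), r, g, b]
    if degree >= 2:
        cols += [r * r, g * g, b * b, r * g, r * b, g * b]
    return np.stack(cols, axis=-1)


@dataclass
class MappingModel:
    """Per-system polynomial mapping from camera RGB to cone catches."""

    design_terms: tuple[str, ...]
    degree: int
    coefficients: dict[str, np.ndarray]       # system -> (n_terms, n_cones)
    cone_names: dict[str, tuple[str, ...]]
    training_fit: dict[str, dict[str, float]]  # held-out R^2 per cone

    def to_dict(self) -> dict:
        return {
            "design_terms": list(self.design_terms),
            "degree": self.degree,
            "coefficients": {k: v.tolist() for k, v in self.coefficients.items()},
            "cone_names": {k: list(v) for k, v in self.cone_names.items()},
            "heldout_r2": self.training_fit,
        }


def fit_rgb_to_cone_map(
    spectra_bank: np.ndarray,
    system: SpectralSystem,
    degree: int = 2,
    holdout_frac: float = 0.25,
    seed: int = 0,
) -> MappingModel:
    """Least-squares fit of cone catches on polynomial terms of camera catches.

    Camera and cone responses to each spectrum are computed by direct
    spectral integration; the polynomial is fitted on a seeded 75/25
    train/hold-out split and the hold-out R^2 per cone is reported.
    """
    terms = _TERMS_BY_DEGREE[degree]
    if len(spectra_bank) <= len(terms):
        raise ValueError("spectra bank must exceed the number of design terms")
    illum = system.illuminant
    camera = np.stack([quantum_catch(spectra_bank, system.sensor_sensitivities[ch], illum)
                       for ch in ("R", "G", "B")], axis=-1)
    X = _design_matrix(camera, degree)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("rank-deficient polynomial design matrix")
    rng = np.random.default_rng(seed)
    n = len(spectra_bank)
    order = rng.permutation(n)
    n_test = max(1, int(round(holdout_frac * n)))
    test_idx, train_idx = order[:n_test], order[n_test:]

    coefficients, cone_names, fits = {}, {}, {}
    for sys_name, cones in system.cone_sets.items():
        names = tuple(cones)
        Y = np.stack([quantum_catch(spectra_bank, cones[c], illum) for c in names], axis=-1)
        beta, *_ = np.linalg.lstsq(X[train_idx], Y[train_idx], rcond=None)
        pred = X[test_idx] @ beta
        fits[sys_name] = {}
        for j, cname in enumerate(names):
            resid = Y[test_idx, j] - pred[:, j]
            total = Y[test_idx, j] - Y[test_idx, j].mean()
            ss_tot = float(total @ total)
            r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
            fits[sys_name][cname] = r2
        coefficients[sys_name] = beta
        cone_names[sys_name] = names
    return MappingModel(design_terms=terms, degree=degree, coefficients=coefficients,
                        cone_names=cone_names, training_fit=fits)


def apply_map(scene: CalibratedScene, model: MappingModel,
              system_name: str) -> ConeCatchImage:
    """Map a calibrated RGB image to per-pixel cone catches for one system."""
    if system_name not in model.coefficients:
        raise KeyError(f"mapping not fitted for system '{system_name}'")
    X = _design_matrix(scene.image, model.degree)
    catches = X @ model.coefficients[system_name]
    catches = np.clip(catches, 0.0, None)
    planes = {name: catches[..., j] for j, name in enumerate(model.cone_names[system_name])}
    return ConeCatchImage(system_name=system_name, planes=planes)
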