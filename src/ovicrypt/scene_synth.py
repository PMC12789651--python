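"""Synthetic nest-scene generator.

Produces linear-reflectance images of ground-nesting shorebird clutches with
the statistical structure the downstream analysis assumes: a textured
substrate (sandy beach or salt marsh), three maculated ellipsoidal eggs, and
the two fiducials used for calibration (a grey patch of known reflectance and
a 40 mm ruler segment).  All randomness is seeded and every generating
parameter is recorded in the scene's ground truth, so each downstream stage
can be tested against known quantities.

Habitats are parameterised so that, under the defaults, salt-marsh scenes are
darker, higher-contrast and coarser-grained than beach scenes, with
pebble-scale objects; beaches are lighter, yellower and fine-grained.
Background texture is band-limited Gaussian noise (spectrally shaped at the
configured grain scale) plus explicit pebble ellipses, which gives
independent control over overall contrast and granularity.  Eggs are filled
ellipses of a lighter ground colour overlaid with dark spots and wispy
random-walk lines, and are on average darker than a beach substrate.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy import ndimage

from .imageio_masks import MaskSet

# Working resolution of all synthetic scenes (matches the standard the
# calibration stage rescales real photographs to).
SCALE_PX_PER_MM = 12.0


class SizedInputError(ValueError):
    """Requested raster too small to hold the scene elements."""


class CompositionError(RuntimeError):
    """An element could not be placed without collision."""


class EggParamError(ValueError):
    """Egg parameters violate a physical invariant."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HabitatParams:
    """Generating parameters for one background class.

    ``base_luminance`` is the mean linear reflectance, ``luminance_sd`` the
    standard deviation of the band-limited noise field, ``grain_scale_px``
    its characteristic wavelength.  ``pebble_density`` is expressed per
    10^4 px^2; each pebble is an ellipse with an independent luminance
    offset drawn with s.d. ``pebble_contrast``.
    """

    habitat_label: str
    base_luminance: float
    luminance_sd: float
    grain_scale_px: float
    pebble_density: float
    pebble_radius_px_range: tuple[float, float]
    pebble_contrast: float
    hue_rgb: tuple[float, float, float]
    #: chromatic (warm-cool) variation of the substrate, as a fraction of
    #: luminance_sd; real substrates vary from brown to grey, not only in
    #: lightness.  Zero luminance_sd implies zero chromatic variation, so
    #: the noise-free case stays exactly constant.
    chroma_ratio: float = 0.5

    def __post_init__(self) -> None:
        lo = self.base_luminance - 3.0 * self.luminance_sd
        hi = self.base_luminance + 3.0 * self.luminance_sd
        if not (0.0 <= lo and hi <= 1.0):
            raise ValueError(
                f"base_luminance +/- 3 sd must lie in [0, 1]; got [{lo}, {hi}]"
            )
        rmin, rmax = self.pebble_radius_px_range
        if not (0 < rmin <= rmax):
            raise ValueError("pebble radius range must be positive with min <= max")


@dataclass(frozen=True)
class EggParams:
    """Generating parameters for one egg: a maculated ellipse.

    Axes are semi-axes in pixels at 12 px/mm; the default major axis of
    ~190 px corresponds to an egg length of ~32 mm.  Maculation (spots and
    wisps) must be darker than the ground colour.
    """

    axes_px: tuple[float, float] = (95.0, 66.0)
    ground_rgb: tuple[float, float, float] = (0.60, 0.52, 0.40)
    maculation_rgb: tuple[float, float, float] = (0.22, 0.18, 0.15)
    spot_density: float = 6.0          # spots per 10^3 px^2
    spot_radius_px_range: tuple[float, float] = (1.0, 3.0)
    wisp_count: int = 8
    orientation_deg: float = 0.0

    def __post_init__(self) -> None:
        if np.mean(self.maculation_rgb) >= np.mean(self.ground_rgb):
            raise EggParamError("maculation must be darker than the egg ground colour")
        if self.spot_radius_px_range[1] >= min(self.axes_px):
            raise EggParamError("spot radii must be smaller than the egg minor axis")


BEACH = HabitatParams(
    habitat_label="beach",
    base_luminance=0.55,
    luminance_sd=0.05,
    grain_scale_px=4.0,
    pebble_density=0.15,
    pebble_radius_px_range=(5.0, 12.0),
    pebble_contrast=0.08,
    hue_rgb=(0.66, 0.57, 0.42),
    chroma_ratio=0.5,
)

SALTMARSH = HabitatParams(
    habitat_label="saltmarsh",
    base_luminance=0.38,
    luminance_sd=0.09,
    grain_scale_px=14.0,
    pebble_density=0.9,
    pebble_radius_px_range=(6.0, 26.0),
    pebble_contrast=0.16,
    hue_rgb=(0.47, 0.38, 0.29),
    chroma_ratio=0.9,
)

DEFAULT_HABITATS = {"beach": BEACH, "saltmarsh": SALTMARSH}


@dataclass(frozen=True)
class FiducialsConfig:
    """Layout and reflectance of the grey patch and ruler fiducials."""

    grey_reflectance: float = 0.20
    grey_size_px: int = 96
    ruler_length_px: int = 480
    ruler_width_px: int = 28
    margin_px: int = 12


@dataclass
class NestScene:
    """A synthetic nest photograph with its masks and generating truth."""

    image: np.ndarray          # rows x cols x 3, linear reflectance in [0, 1]
    masks: MaskSet
    nest_id: str
    habitat_label: str
    ground_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def _band_noise(shape: tuple[int, int], grain_scale_px: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with spectral energy concentrated at 1/grain_scale."""
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    radius = np.hypot(fy, fx)
    radius[0, 0] = 1.0
    f0 = 1.0 / grain_scale_px
    # log-Gaussian annulus, ~1.5 octave bandwidth
    weight = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * np.log(1.7) ** 2))
    weight[0, 0] = 0.0
    shaped = np.fft.ifft2(np.fft.fft2(white) * weight).real
    sd = shaped.std()
    if sd == 0:
        return np.zeros(shape)
    return shaped / sd


def _ellipse_mask_local(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle_deg: float,
) -> np.ndarray:
    """Boolean raster of a rotated filled ellipse, evaluated analytically."""
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    th = math.radians(angle_deg)
    # major axis at angle_deg anticlockwise from the column (horizontal) axis;
    # image rows increase downward, hence the sign convention below
    u = cols * math.cos(th) - rows * math.sin(th)
    v = cols * math.sin(th) + rows * math.cos(th)
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_background(
    params: HabitatParams,
    shape: tuple[int, int],
    seed: int,
) -> np.ndarray:
    """Generate a linear-RGB background raster for one habitat.

    The achromatic field is ``base_luminance`` plus band-limited noise plus
    pebble offsets; colour is applied by scaling the habitat hue so that a
    noise-free, pebble-free configuration reproduces ``hue_rgb`` exactly.
    """
    if shape[0] < 256 or shape[1] < 256:
        raise SizedInputError(f"background shape {shape} below the 256x256 minimum")
    rng = np.random.default_rng(seed)
    f = np.full(shape, params.base_luminance, dtype=float)
    chroma_sd = params.chroma_ratio * params.luminance_sd
    chroma = np.zeros(shape)
    if params.luminance_sd > 0:
        f += params.luminance_sd * _band_noise(shape, params.grain_scale_px, rng)
        if chroma_sd > 0:
            # coarser-than-grain warm-cool field: substrates vary from brown
            # to grey across egg-sized patches, not only in lightness
            chroma += chroma_sd * _band_noise(shape, 4.0 * params.grain_scale_px, rng)
    n_pebbles = rng.poisson(params.pebble_density * shape[0] * shape[1] / 1e4)
    rmin, rmax = params.pebble_radius_px_range
    for _ in range(n_pebbles):
        cy = rng.uniform(0, shape[0])
        cx = rng.uniform(0, shape[1])
        a = rng.uniform(rmin, rmax)
        b = a * rng.uniform(0.55, 1.0)
        ang = rng.uniform(0, 180)
        offset = rng.normal(0.0, params.pebble_contrast)
        chroma_offset = rng.normal(0.0, chroma_sd)
        r0 = max(0, int(cy - a - 2))
        r1 = min(shape[0], int(cy + a + 3))
        c0 = max(0, int(cx - a - 2))
        c1 = min(shape[1], int(cx + a + 3))
        if r1 <= r0 or c1 <= c0:
            continue
        local = _ellipse_mask_local((r1 - r0, c1 - c0), (cy - r0, cx - c0), (a, b), ang)
        f[r0:r1, c0:c1][local] += offset
        chroma[r0:r1, c0:c1][local] += chroma_offset
    # warm-cool axis: red up, blue down, green neutral; zero-mean, so the
    # expected image colour remains hue_rgb
    hue = np.asarray(params.hue_rgb)
    rgb = hue[None, None, :] * (
        f[:, :, None] + chroma[:, :, None] * np.array([1.0, 0.0, -1.0])
    ) / params.base_luminance
    return np.clip(rgb, 0.0, 1.0)


# ---------------------------------------------------------------------------
# eggs
# ---------------------------------------------------------------------------

def _stamp_disc(canvas: np.ndarray, mask: np.ndarray, cy: float, cx: float, radius: float,
                colour: np.ndarray) -> None:
    r0 = max(0, int(cy - radius - 1))
    r1 = min(canvas.shape[0], int(cy + radius + 2))
    c0 = max(0, int(cx - radius - 1))
    c1 = min(canvas.shape[1], int(cx + radius + 2))
    if r1 <= r0 or c1 <= c0:
        return
    yy = np.arange(r0, r1)[:, None] - cy
    xx = np.arange(c0, c1)[None, :] - cx
    disc = (yy ** 2 + xx ** 2 <= radius ** 2) & mask[r0:r1, c0:c1]
    canvas[r0:r1, c0:c1][disc] = colour


def render_egg(params: EggParams, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one egg as an RGB patch plus its elliptical boolean mask.

    The patch raster is square; pixels outside the mask are zero and are
    never composited into a scene.  Maculation consists of Poisson-placed
    dark discs and random-walk wispy polylines of 1-2 px width.
    """
    rng = np.random.default_rng(seed)
    a, b = params.axes_px
    half = int(math.ceil(max(a, b))) + 2
    size = 2 * half + 1
    mask = _ellipse_mask_local((size, size), (half, half), (a, b), params.orientation_deg)
    patch = np.zeros((size, size, 3))
    ground = np.asarray(params.ground_rgb, dtype=float)
    macu = np.asarray(params.maculation_rgb, dtype=float)
    patch[mask] = ground

    area = mask.sum()
    n_spots = rng.poisson(params.spot_density * area / 1e3)
    coords = np.argwhere(mask)
    for _ in range(n_spots):
        cy, cx = coords[rng.integers(len(coords))]
        radius = rng.uniform(*params.spot_radius_px_range)
        _stamp_disc(patch, mask, cy, cx, radius, macu)
    for _ in range(params.wisp_count):
        cy, cx = coords[rng.integers(len(coords))].astype(float)
        heading = rng.uniform(0, 2 * math.pi)
        n_steps = rng.integers(20, 60)
        width = rng.uniform(0.6, 1.1)
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.35)
            cy += math.sin(heading)
            cx += math.cos(heading)
            if not (0 <= int(cy) < size and 0 <= int(cx) < size) or not mask[int(cy), int(cx)]:
                break
            _stamp_disc(patch, mask, cy, cx, width, macu)
    return patch, mask


def maculated_fraction(patch: np.ndarray, mask: np.ndarray, params: EggParams) -> float:
    """Fraction of within-mask pixels carrying the maculation colour."""
    ground = np.asarray(params.ground_rgb)
    inside = patch[mask]
    return float(np.mean(np.any(np.abs(inside - ground) > 1e-9, axis=1)))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _rect_mask(shape: tuple[int, int], r0: int, c0: int, h: int, w: int) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[r0:r0 + h, c0:c0 + w] = True
    return m


def compose_scene(
    background: np.ndarray,
    eggs: list[EggParams],
    fiducials: FiducialsConfig,
    nest_id: str,
    habitat_label: str,
    seed: int,
    habitat_params: HabitatParams | None = None,
    egg_luminance_offset: float | None = -0.10,
    sensor_noise_sd: float = 0.0,
    psf_sigma_px: float = 1.5,
    max_retries: int = 500,
) -> NestScene:
    """Composite three eggs and the fiducials onto a background raster.

    If ``egg_luminance_offset`` is given, each egg patch is shifted so that
    its within-mask mean luminance equals the background's mean luminance
    plus the offset (applied before optional sensor noise), which makes the
    configured egg-background contrast exactly recoverable by pixel
    averaging.  The grey patch is rendered at the configured reflectance in
    every channel; the ruler is a banded strip whose mask spans exactly
    ``ruler_length_px``.  Fiducials sit in fixed corners; eggs are placed
    near the scene centre with bounded rejection retries.
    """
    if len(eggs) != 3:
        raise CompositionError(f"a nest scene requires exactly 3 eggs, got {len(eggs)}")
    rows, cols = background.shape[:2]
    fid = fiducials
    need = fid.ruler_length_px + 2 * fid.margin_px
    if rows < 256 or cols < need:
        raise SizedInputError(
            f"scene shape {(rows, cols)} too small to hold the {fid.ruler_length_px} px ruler"
        )
    rng = np.random.default_rng(seed)
    image = background.copy()
    bg_mean_lum = float(background.mean())

    # fiducials in fixed corners
    grey_mask = _rect_mask((rows, cols), fid.margin_px, fid.margin_px,
                           fid.grey_size_px, fid.grey_size_px)
    image[grey_mask] = fid.grey_reflectance
    ruler_r0 = rows - fid.margin_px - fid.ruler_width_px
    ruler_mask = _rect_mask((rows, cols), ruler_r0, fid.margin_px,
                            fid.ruler_width_px, fid.ruler_length_px)
    # 1 mm (12 px) alternating bands, dark-light, like a real ruler edge
    band = (np.arange(fid.ruler_length_px) // int(SCALE_PX_PER_MM)) % 2
    strip = np.where(band, 0.85, 0.12)[None, :, None]
    image[ruler_r0:ruler_r0 + fid.ruler_width_px,
          fid.margin_px:fid.margin_px + fid.ruler_length_px] = strip

    fiducial_zone = ndimage.binary_dilation(grey_mask | ruler_mask, iterations=8)

    egg_masks: list[np.ndarray] = []
    occupied = fiducial_zone.copy()
    egg_records = []
    for i, egg_params in enumerate(eggs):
        egg_seed = int(rng.integers(0, 2 ** 31 - 1))
        patch, pmask = render_egg(egg_params, egg_seed)
        if egg_luminance_offset is not None:
            target = bg_mean_lum + egg_luminance_offset
            shift = target - float(patch[pmask].mean())
            patch = patch.copy()
            patch[pmask] = np.clip(patch[pmask] + shift, 0.0, 1.0)
        ph = patch.shape[0]
        placed = False
        for _ in range(max_retries):
            # cluster the clutch around the scene centre, as in a nest scrape
            r0 = int(rng.uniform(rows * 0.5 - 1.3 * ph, rows * 0.5 + 0.45 * ph))
            c0 = int(rng.uniform(cols * 0.5 - 1.3 * ph, cols * 0.5 + 0.45 * ph))
            if r0 < 0 or c0 < 0 or r0 + ph > rows or c0 + ph > cols:
                continue
            window = occupied[r0:r0 + ph, c0:c0 + ph]
            if (window & pmask).any():
                continue
            full = np.zeros((rows, cols), dtype=bool)
            full[r0:r0 + ph, c0:c0 + ph] = pmask
            image[r0:r0 + ph, c0:c0 + ph][pmask] = patch[pmask]
            egg_masks.append(full)
            occupied |= ndimage.binary_dilation(full, iterations=4)
            egg_records.append({"params": dataclasses.asdict(egg_params),
                                "seed": egg_seed, "offset": (r0, c0)})
            placed = True
            break
        if not placed:
            raise CompositionError(f"could not place egg {i} after {max_retries} retries")

    if psf_sigma_px > 0:
        # optical point-spread of the camera: without it the rendered scene
        # would carry pixel-sharp (Nyquist-limited) edges no photograph has
        image = ndimage.gaussian_filter(image, (psf_sigma_px, psf_sigma_px, 0))
        # fiducials are re-stamped sharp; only their mean value (grey) and
        # extent (ruler) matter downstream
        image[grey_mask] = fid.grey_reflectance
        image[ruler_r0:ruler_r0 + fid.ruler_width_px,
              fid.margin_px:fid.margin_px + fid.ruler_length_px] = strip
    if sensor_noise_sd > 0:
        image = image + rng.normal(0.0, sensor_noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0)

    masks = MaskSet.with_default_exclusion(egg_masks, ruler_mask, grey_mask)
    truth = {
        "habitat_params": dataclasses.asdict(habitat_params) if habitat_params else None,
        "eggs": egg_records,
        "seed": seed,
        "egg_luminance_offset": egg_luminance_offset,
        "sensor_noise_sd": sensor_noise_sd,
        "psf_sigma_px": psf_sigma_px,
        "background_mean_luminance": bg_mean_lum,
        "fiducials": dataclasses.asdict(fid),
    }
    return NestScene(image=image, masks=masks, nest_id=nest_id,
                     habitat_label=habitat_label, ground_truth=truth)


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

def _jittered_egg(rng: np.random.Generator) -> EggParams:
    base = EggParams()
    scale = rng.uniform(0.95, 1.08)
    tint = rng.normal(1.0, 0.04, size=3)
    ground = tuple(np.clip(np.asarray(base.ground_rgb) * tint, 0.05, 0.95))
    return EggParams(
        axes_px=(base.axes_px[0] * scale, base.axes_px[1] * scale),
        ground_rgb=ground,
        maculation_rgb=base.maculation_rgb,
        spot_density=float(rng.uniform(4.0, 8.0)),
        spot_radius_px_range=base.spot_radius_px_range,
        wisp_count=int(rng.integers(5, 12)),
        orientation_deg=float(rng.uniform(0.0, 180.0)),
    )


def generate_dataset(
    n_beach: int = 28,
    n_saltmarsh: int = 60,
    overrides: dict | None = None,
    seed: int = 0,
    shape: tuple[int, int] = (1024, 1024),
    fiducials: FiducialsConfig | None = None,
    egg_luminance_offset: float | None = -0.10,
    sensor_noise_sd: float = 0.0,
    psf_sigma_px: float = 1.5,
) -> list[NestScene]:
    """Generate a full synthetic dataset of nest scenes.

    The default habitat counts (28 beach, 60 salt marsh) mirror the field
    sampling design the pipeline was built around.  Per-scene child seeds
    are derived deterministically from ``seed`` via a seed sequence, so the
    dataset is a pure function of its arguments.  ``overrides`` may replace
    the per-habitat defaults with custom :class:`HabitatParams`.
    """
    if n_beach < 0 or n_saltmarsh < 0:
        raise ValueError("scene counts must be non-negative")
    habitats = dict(DEFAULT_HABITATS)
    if overrides:
        habitats.update(overrides)
    fid = fiducials or FiducialsConfig()
    labels = ["beach"] * n_beach + ["saltmarsh"] * n_saltmarsh
    scenes: list[NestScene] = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31 - 1)) for s in ss.spawn(len(labels))]
    counters = {"beach": 0, "saltmarsh": 0}
    for label, child in zip(labels, child_seeds):
        counters[label] += 1
        nest_id = f"{label}{counters[label]:03d}"
        params = habitats[label]
        rng = np.random.default_rng(child)
        bg_seed = int(rng.integers(0, 2 ** 31 - 1))
        compose_seed = int(rng.integers(0, 2 ** 31 - 1))
        background = generate_background(params, shape, bg_seed)
        eggs = [_jittered_egg(rng) for _ in range(3)]
        scenes.append(compose_scene(
            background, eggs, fid, nest_id, label, compose_seed,
            habitat_params=params,
            egg_luminance_offset=egg_luminance_offset,
            sensor_noise_sd=sensor_noise_sd,
            psf_sigma_px=psf_sigma_px,
        ))
    return scenes
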