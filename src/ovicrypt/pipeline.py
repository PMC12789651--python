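"""End-to-end orchestration: config -> scenes -> features -> statistics.

The stages run in the order the analysis demands: generate (or read) scenes,
grey-calibrate and rescale, fit the RGB-to-cone mapping once, extract
per-region colour and texture features, assemble the 30-rows-per-scene
feature table, reduce texture by PCA, then run the mean-difference suite and
the discrimination suite.  Stage artifacts (scene PNGs, feature CSV, PCA
JSON, results CSVs, ROC plots) are written to the output directory so every
intermediate is inspectable, and a provenance record (config hash, seeds)
makes re-runs reproducible: an existing feature table with a matching
provenance hash is reused rather than recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibrate, discriminate, imageio_masks, sampling, scene_synth
from . import stats_models, texture, vision

logger = logging.getLogger("ovicrypt")


class ConfigurationError(ValueError):
    """Run configuration invalid or inconsistent."""


@dataclass
class RunConfig:
    mode: str = "synthetic"                 # synthetic | real
    n_beach: int = 28
    n_saltmarsh: int = 60
    seed: int = 0
    scene_shape: tuple[int, int] = (1024, 1024)
    manifest_path: str | None = None        # real mode
    out_dir: str = "results"
    egg_luminance_offset: float | None = -0.10
    sensor_noise_sd: float = 0.0
    n_spectra: int = 200
    mapping_degree: int = 2
    n_texture_pcs: int = 4
    use_random_intercept: bool = True
    write_scenes: bool = True
    run_stats: bool = True
    run_discrimination: bool = True

    def validate(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigurationError(f"unknown mode '{self.mode}'")
        if self.mode == "synthetic" and self.n_beach + self.n_saltmarsh == 0:
            raise ConfigurationError("synthetic mode needs at least one scene")
        if self.mode == "real" and not self.manifest_path:
            raise ConfigurationError("real mode needs a manifest_path")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ResultsBundle:
    feature_table: pd.DataFrame
    pca: texture.TexturePCA | None
    mapping_fit: dict | None
    stats: pd.DataFrame | None
    discrimination: pd.DataFrame | None
    roc: dict | None
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

_BANK_CACHE: dict[tuple, texture.FilterBank] = {}


def _bank_for(shape: tuple[int, int],
              params: texture.BankParams | None = None) -> texture.FilterBank:
    params = params or texture.BankParams()
    key = (shape, params)
    if key not in _BANK_CACHE:
        _BANK_CACHE[key] = texture.build_bank(params, shape)
    return _BANK_CACHE[key]


def extract_scene_features(
    scene: calibrate.CalibratedScene,
    model: calibrate.MappingModel,
    plan: sampling.SamplePlan,
    bank_params: texture.BankParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region colour and texture rows (30 each) for one calibrated scene."""
    regions = sampling.region_masks(scene, plan)
    avian = calibrate.apply_map(scene, model, "avian")
    carn = calibrate.apply_map(scene, model, "carnivore")
    human = vision.human_xyz_image(scene.image)
    key = {"nest_id": scene.nest_id, "habitat": scene.habitat_label}

    colour_rows = []
    for object_type, idx, mask in regions:
        av = vision.region_colour(avian, mask)
        ca = vision.region_colour(carn, mask)
        hu = vision.region_colour(human, mask)
        colour_rows.append({
            **key, "object_type": object_type, "sample_index": idx,
            "avian_lum": av.luminance, "avian_rg": av.rg, "avian_yb": av.yb,
            "carn_lum": ca.luminance, "carn_yb": ca.yb,
            "human_L": hu.luminance, "human_a": hu.rg, "human_b": hu.yb,
        })

    bank = _bank_for(scene.image.shape[:2], bank_params)
    lum = vision.luminance_plane_y(scene.image)
    import warnings as _warnings
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always", texture.BoundaryWarning)
        energies = texture.filter_energies_multi(lum, bank, [m for _, _, m in regions])
    n_boundary = sum(issubclass(w.category, texture.BoundaryWarning) for w in caught)
    if n_boundary:
        logger.info("%s: %d region(s) near the image border", scene.nest_id, n_boundary)
    names = bank.params.feature_names
    texture_rows = []
    for (object_type, idx, _), vec in zip(regions, energies):
        texture_rows.append({**key, "object_type": object_type, "sample_index": idx,
                             **dict(zip(names, vec))})
    return pd.DataFrame(colour_rows), pd.DataFrame(texture_rows)


def build_features(scenes, model: calibrate.MappingModel, seed: int,
                   bank_params: texture.BankParams | None = None,
                   grey_target: float = calibrate.DEFAULT_GREY_TARGET,
                   ) -> tuple[pd.DataFrame, texture.TexturePCA]:
    """Calibrate, sample and featurise a list of scenes; fit the texture PCA.

    The PCA is fitted once on the pooled egg + background table across all
    scenes and habitats (refitting per habitat would break comparability of
    the component scores).
    """
    colour_frames, texture_frames = [], []
    for scene in scenes:
        t0 = time.perf_counter()
        raw = imageio_masks.RawScene(image=scene.image, masks=scene.masks,
                                     nest_id=scene.nest_id,
                                     habitat_label=scene.habitat_label)
        calibrated = calibrate.rescale_to_standard(
            calibrate.grey_calibrate(raw, grey_target))
        plan = sampling.plan_background_samples(
            calibrated, seed=sampling.scene_seed(seed, scene.nest_id))
        colour_df, texture_df = extract_scene_features(calibrated, model, plan,
                                                       bank_params)
        colour_frames.append(colour_df)
        texture_frames.append(texture_df)
        logger.info("featurised %s (%s) in %.2f s", scene.nest_id,
                    scene.habitat_label, time.perf_counter() - t0)
    table = sampling.build_feature_table(pd.concat(colour_frames, ignore_index=True),
                                         pd.concat(texture_frames, ignore_index=True))
    bank_names = (bank_params or texture.BankParams()).feature_names
    pca = texture.fit_pca(table[bank_names])
    return table, pca


def attach_pc_scores(table: pd.DataFrame, pca: texture.TexturePCA,
                     n_pcs: int = 4) -> pd.DataFrame:
    scores = texture.project(pca, table[pca.feature_names], k=n_pcs)
    out = table.copy()
    for i in range(n_pcs):
        out[f"PC{i + 1}"] = scores[:, i]
    return out


# ---------------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------------

def _plot_roc_bundle(rocs: dict, out_path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4.5), sharey=True)
    for ax, habitat in zip(axes, ("beach", "saltmarsh")):
        for (measure, hab), roc in sorted(rocs.items()):
            if hab != habitat:
                continue
            ax.plot(roc.points["specificity"], roc.points["sensitivity"],
                    label=f"{measure} (AUC {roc.auc:.2f})")
        ax.set_xlim(1.02, -0.02)
        ax.set_xlabel("Specificity")
        ax.set_title(habitat)
        ax.legend(fontsize=6)
    axes[0].set_ylabel("Sensitivity")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def run(config: RunConfig) -> ResultsBundle:
    """Execute the configured pipeline and write all artifacts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"config": dataclasses.asdict(config), "hash": config.hash()}
    prov_path = out / "provenance.json"
    features_path = out / "feature_table.csv"
    pca_path = out / "texture_pca.json"

    spectral = calibrate.make_default_system()
    bank_seed = np.random.SeedSequence(config.seed).generate_state(1)[0] % (2 ** 31 - 1)
    spectra = calibrate.synthetic_spectra_bank(config.n_spectra, seed=int(bank_seed),
                                               wavelengths=spectral.wavelengths_nm)
    model = calibrate.fit_rgb_to_cone_map(spectra, spectral,
                                          degree=config.mapping_degree,
                                          seed=config.seed)
    (out / "mapping_model.json").write_text(json.dumps(model.to_dict(), indent=1))

    reused = False
    pca = None
    if features_path.exists() and prov_path.exists():
        try:
            prior = json.loads(prov_path.read_text())
            if prior.get("hash") == provenance["hash"]:
                table = pd.read_csv(features_path)
                pca_dict = json.loads(pca_path.read_text())
                pca = texture.TexturePCA(
                    feature_names=pca_dict["feature_names"],
                    means=np.array(pca_dict["means"]),
                    sds=np.array(pca_dict["sds"]),
                    loadings=np.array(pca_dict["loadings"]),
                    eigenvalues=np.array(pca_dict["eigenvalues"]),
                    retained_k=pca_dict["retained_k"])
                reused = True
                logger.info("reusing feature table (provenance hash %s)",
                            provenance["hash"])
        except (json.JSONDecodeError, KeyError):
            reused = False

    if not reused:
        if config.mode == "synthetic":
            scenes = scene_synth.generate_dataset(
                config.n_beach, config.n_saltmarsh, seed=config.seed,
                shape=tuple(config.scene_shape),
                egg_luminance_offset=config.egg_luminance_offset,
                sensor_noise_sd=config.sensor_noise_sd)
            if config.write_scenes:
                scene_dir = out / "scenes"
                for scene in scenes:
                    imageio_masks.write_scene(scene, scene_dir)
        else:
            scenes = imageio_masks.read_manifest(config.manifest_path)
        table, pca = build_features(scenes, model, seed=config.seed)
        table = attach_pc_scores(table, pca, n_pcs=config.n_texture_pcs)
        table.to_csv(features_path, index=False)
        pca_path.write_text(json.dumps(pca.to_dict()))
        prov_path.write_text(json.dumps(provenance, indent=1))

    stats_df = None
    if config.run_stats:
        stats_df = stats_models.run_table_suite(table, config.n_texture_pcs)
        stats_df.to_csv(out / "stats_suite.csv", index=False)

    disc_df, rocs = None, None
    if config.run_discrimination:
        bundle = discriminate.run_discrimination_suite(
            table, use_random_intercept=config.use_random_intercept)
        disc_df, rocs = bundle["grid"], bundle["roc"]
        disc_df.to_csv(out / "discrimination_grid.csv", index=False)
        roc_rows = []
        for (measure, habitat), roc in rocs.items():
            pts = roc.points.copy()
            pts.insert(0, "habitat", habitat)
            pts.insert(0, "measure", measure)
            roc_rows.append(pts)
        pd.concat(roc_rows, ignore_index=True).to_csv(out / "roc_curves.csv", index=False)
        _plot_roc_bundle(rocs, out / "roc_curves.png")

    return ResultsBundle(feature_table=table, pca=pca,
                         mapping_fit=model.training_fit, stats=stats_df,
                         discrimination=disc_df, roc=rocs, provenance=provenance)
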