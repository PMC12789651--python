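"""Shared fixtures: small synthetic datasets reused across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ovicrypt import calibrate, pipeline, scene_synth


@pytest.fixture(scope="session")
def spectral_system():
    return calibrate.make_default_system()


@pytest.fixture(scope="session")
def mapping_model(spectral_system):
    bank = calibrate.synthetic_spectra_bank(200, seed=1,
                                            wavelengths=spectral_system.wavelengths_nm)
    return calibrate.fit_rgb_to_cone_map(bank, spectral_system, seed=1)


@pytest.fixture(scope="session")
def scene_pair():
    """One beach and one salt-marsh scene under default parameters."""
    return scene_synth.generate_dataset(1, 1, seed=11)


@pytest.fixture(scope="session")
def six_scene_run(mapping_model):
    """Feature table, PCA and scenes for a 3 + 3 scene dataset."""
    scenes = scene_synth.generate_dataset(3, 3, seed=7)
    table, pca = pipeline.build_features(scenes, mapping_model, seed=7)
    table = pipeline.attach_pc_scores(table, pca, n_pcs=4)
    return {"scenes": scenes, "table": table, "pca": pca}


# ---------------------------------------------------------------------------
# table-level simulators (lightweight stand-ins for full image runs when a
# statistical property is being exercised, with known generating truth)
# ---------------------------------------------------------------------------

def simulate_lmm_table(n_scenes: int = 30, egg_offset: float = -0.10,
                       photo_sd: float = 0.05, resid_sd: float = 0.05,
                       habitat_effect_background: float = 0.0,
                       habitat_effect_egg: float = 0.0,
                       interaction: float = 0.0,
                       seed: int = 0) -> pd.DataFrame:
    """30-rows-per-scene response table with known mixed-model structure."""
    rng = np.random.default_rng(seed)
    half = n_scenes // 2
    rows = []
    for i in range(n_scenes):
        habitat = "beach" if i < half else "saltmarsh"
        hab = 0.0 if habitat == "beach" else 1.0
        b = rng.normal(0.0, photo_sd)
        for j in range(30):
            is_egg = j < 3
            mu = 0.5 + b
            mu += (egg_offset + interaction * hab) if is_egg else 0.0
            mu += (habitat_effect_egg if is_egg else habitat_effect_background) * hab
            rows.append({
                "nest_id": f"n{i:03d}", "habitat": habitat,
                "object_type": "egg" if is_egg else "background",
                "sample_index": j if is_egg else j - 3,
                "resp": mu + rng.normal(0.0, resid_sd),
            })
    return pd.DataFrame(rows)


def simulate_classifier_table(n_scenes: int = 30, colour_sep: float = 0.0,
                              pattern_sep: float = 0.0, photo_sd: float = 0.3,
                              seed: int = 0) -> pd.DataFrame:
    """Feature-table stand-in with controllable colour/texture separation.

    Colour columns and texture PC columns are unit-variance noise plus the
    configured egg-background separation (in s.d. units) plus a shared
    per-nest offset.
    """
    rng = np.random.default_rng(seed)
    half = n_scenes // 2
    colour_cols = ["avian_lum", "avian_rg", "avian_yb", "carn_lum", "carn_yb",
                   "human_L", "human_a", "human_b"]
    pc_cols = ["PC1", "PC2", "PC3", "PC4"]
    rows = []
    for i in range(n_scenes):
        habitat = "beach" if i < half else "saltmarsh"
        b = {c: rng.normal(0.0, photo_sd) for c in colour_cols + pc_cols}
        for j in range(30):
            is_egg = j < 3
            row = {"nest_id": f"n{i:03d}", "habitat": habitat,
                   "object_type": "egg" if is_egg else "background",
                   "sample_index": j if is_egg else j - 3}
            for c in colour_cols:
                row[c] = b[c] + rng.normal() + (colour_sep if is_egg else 0.0)
            for c in pc_cols:
                row[c] = b[c] + rng.normal() + (pattern_sep if is_egg else 0.0)
            rows.append(row)
    return pd.DataFrame(rows)
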