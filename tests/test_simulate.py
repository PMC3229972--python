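"""Simulator: exact rendering oracles, geometry laws, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from nucleoquant import (
    ConfigError,
    PlacementError,
    SimulationConfig,
    generate_culture_image,
    generate_tissue_section,
)

from conftest import truth_footprints


def noise_free(**kw) -> SimulationConfig:
    kw.setdefault("psf_sigma", 0.0)
    kw.setdefault("photon_scale", 0.0)
    kw.setdefault("read_noise_sigma", 0.0)
    return SimulationConfig(**kw)


def test_empty_field_is_background_only():
    cfg = noise_free(mode="culture", n_nuclei=0, image_size=(64, 64), seed=0)
    images, gt = generate_culture_image(cfg)
    assert gt.nuclei.empty and gt.foci.empty
    for ch in ("dna", "protein"):
        assert np.all(images[ch] == cfg.background)


def test_rendered_means_match_published_condition_means_exactly():
    """A noise-free nucleus renders at exactly the configured condition
    means (early-passage HDF: protein 0.30, DNA 0.38 a.u.)."""
    cfg = noise_free(
        mode="culture", n_nuclei=1, image_size=(96, 96), seed=3,
        dna_mean=0.38, dna_cv=0.0, protein_mean=0.30, protein_cv=0.0,
        eccentricity=0.0,
    )
    images, gt = generate_culture_image(cfg)
    foot = truth_footprints(gt, images.shape)[1]
    assert images["dna"][foot].mean() == pytest.approx(0.38, rel=1e-12)
    assert images["protein"][foot].mean() == pytest.approx(0.30, rel=1e-12)
    assert gt.nuclei.true_mean_dna[0] == pytest.approx(0.38, rel=1e-12)
    assert gt.nuclei.true_mean_protein[0] == pytest.approx(0.30, rel=1e-12)


def test_lognormal_ground_truth_means_recover_configured_mean():
    """Law of large numbers: the sample mean of 1000 drawn per-nucleus
    protein means lands within 3% of the configured 0.30."""
    cfg = noise_free(
        mode="culture", n_nuclei=1000, image_size=(1600, 1600), seed=7,
        nucleus_radius=8, protein_mean=0.30, protein_cv=0.3,
    )
    _, gt = generate_culture_image(cfg)
    assert len(gt.nuclei) == 1000
    assert gt.nuclei.true_mean_protein.mean() == pytest.approx(0.30, rel=0.03)
    # independent oracle: sampling the same lognormal directly
    s2 = math.log1p(0.3**2)
    draws = np.random.default_rng(7).lognormal(math.log(0.3) - s2 / 2,
                                               math.sqrt(s2), 1000)
    assert abs(draws.mean() - 0.30) / 0.30 < 0.03


def test_identical_config_and_seed_is_bit_identical():
    kw = dict(mode="tissue", n_nuclei=25, image_size=(360, 360), seed=42,
              ratio_mean=0.29, n_foci=2)
    a_img, a_gt = generate_tissue_section(SimulationConfig(**kw))
    b_img, b_gt = generate_tissue_section(SimulationConfig(**kw))
    for ch in a_img.names:
        assert np.array_equal(a_img[ch], b_img[ch])
    pd.testing.assert_frame_equal(a_gt.nuclei, b_gt.nuclei)
    pd.testing.assert_frame_equal(a_gt.foci, b_gt.foci)


def test_intensity_conservation_inside_footprints():
    """With noise and PSF off, summed intensity above background inside a
    nucleus equals (true mean - background) x area, foci included."""
    cfg = noise_free(
        mode="tissue", n_nuclei=12, image_size=(420, 420), seed=9,
        ratio_mean=0.31, n_foci=3, nucleus_radius=12,
    )
    images, gt = generate_tissue_section(cfg)
    feet = truth_footprints(gt, images.shape)
    for rec in gt.nuclei.itertuples():
        foot = feet[rec.nucleus_id]
        area = foot.sum()
        assert area == rec.area_px
        if area == 0:
            continue
        total_above_bg = images["protein"][foot].sum() - cfg.cytoplasm_level * area
        expected = (rec.true_mean_protein - cfg.cytoplasm_level) * area
        assert total_above_bg == pytest.approx(expected, abs=1e-9 * max(area, 1))


def test_tissue_cross_section_radius_law():
    cfg = SimulationConfig(mode="tissue", n_nuclei=60, image_size=(900, 900),
                           seed=5, ratio_mean=0.29)
    _, gt = generate_tissue_section(cfg)
    nuc = gt.nuclei
    assert np.all(np.abs(nuc.dz) <= nuc.radius_3d)
    np.testing.assert_allclose(nuc.radius**2, nuc.radius_3d**2 - nuc.dz**2,
                               atol=1e-9)


def test_central_sections_have_full_radius():
    cfg = SimulationConfig(mode="tissue", n_nuclei=15, image_size=(420, 420),
                           seed=6, ratio_mean=0.29, fixed_dz=0.0)
    _, gt = generate_tissue_section(cfg)
    np.testing.assert_allclose(gt.nuclei.radius, gt.nuclei.radius_3d, atol=1e-12)


def test_apparent_area_fraction_follows_sqrt_law():
    """P(area >= 0.7 pi R^2) = P(dz^2 <= 0.3 R^2) = sqrt(0.3) for uniform dz."""
    cfg = noise_free(mode="tissue", n_nuclei=1500, image_size=(2400, 2400),
                     seed=17, nucleus_radius=9, nucleus_radius_cv=0.0,
                     ratio_mean=0.29)
    _, gt = generate_tissue_section(cfg)
    frac = np.mean(gt.nuclei.radius**2 >= 0.7 * gt.nuclei.radius_3d**2)
    # Monte-Carlo oracle over dz with the same n
    mc = np.mean(np.random.default_rng(1).uniform(-1, 1, 1500) ** 2 <= 0.3)
    assert frac == pytest.approx(math.sqrt(0.3), abs=0.035)
    assert abs(frac - mc) < 0.05


def test_full_colocalization_puts_every_protein_focus_on_a_dna_focus():
    cfg = SimulationConfig(mode="tissue", n_nuclei=40, image_size=(800, 800),
                           seed=23, nucleus_radius=13, ratio_mean=0.31,
                           n_foci=3, coloc_fraction=1.0)
    _, gt = generate_tissue_section(cfg)
    prot = gt.foci[gt.foci.channel == "protein"]
    dna = gt.foci[gt.foci.channel == "dna"]
    assert len(prot) > 0
    assert prot.colocalized.all()
    for rec in prot.itertuples():
        same = dna[dna.nucleus_id == rec.nucleus_id]
        d = np.hypot(same.row - rec.row, same.col - rec.col)
        assert (d <= rec.radius).any()  # center inside a DNA focus


def test_every_focus_lies_inside_its_nucleus():
    cfg = SimulationConfig(mode="tissue", n_nuclei=40, image_size=(800, 800),
                           seed=29, nucleus_radius=12, ratio_mean=0.31, n_foci=3)
    _, gt = generate_tissue_section(cfg)
    nuc = gt.nuclei.set_index("nucleus_id")
    for rec in gt.foci.itertuples():
        host = nuc.loc[rec.nucleus_id]
        d = math.hypot(rec.row - host.row, rec.col - host.col)
        assert d + rec.radius <= host.radius + 1e-9


@pytest.mark.parametrize(
    "kw",
    [
        dict(mode="plate"),
        dict(dna_mean=-0.1),
        dict(n_nuclei=-1),
        dict(image_size=(0, 64)),
        dict(coloc_fraction=1.5),
        dict(mode="culture", ratio_mean=0.3),
        dict(mode="culture", fixed_dz=1.0),
        dict(nucleus_radius=-2.0),
    ],
)
def test_invalid_configurations_are_rejected(kw):
    with pytest.raises(ConfigError):
        SimulationConfig(**kw)


def test_overcrowded_field_raises_placement_error():
    cfg = SimulationConfig(mode="culture", n_nuclei=60, image_size=(100, 100),
                           seed=1, nucleus_radius=10, max_place_attempts=200)
    with pytest.raises(PlacementError):
        generate_culture_image(cfg)


def test_mode_dispatch_is_strict():
    culture = SimulationConfig(mode="culture", n_nuclei=1, image_size=(64, 64))
    tissue = SimulationConfig(mode="tissue", n_nuclei=1, image_size=(64, 64))
    with pytest.raises(ConfigError):
        generate_culture_image(tissue)
    with pytest.raises(ConfigError):
        generate_tissue_section(culture)
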