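"""Shared fixtures and geometry oracles for the test-suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nucleoquant import SimulationConfig, generate_culture_image

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def rasterize_ellipse(shape, row, col, a, b, angle) -> np.ndarray:
    """Independent rasterization oracle for ground-truth footprints."""
    rmax = max(a, b)
    r0 = max(int(math.floor(row - rmax - 1)), 0)
    r1 = min(int(math.ceil(row + rmax + 1)) + 1, shape[0])
    c0 = max(int(math.floor(col - rmax - 1)), 0)
    c1 = min(int(math.ceil(col + rmax + 1)) + 1, shape[1])
    out = np.zeros(shape, dtype=bool)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - row, cc - col
    u = dx * math.cos(angle) + dy * math.sin(angle)
    v = -dx * math.sin(angle) + dy * math.cos(angle)
    out[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def truth_footprints(gt, shape):
    """Boolean footprint per ground-truth nucleus, from geometry alone."""
    feet = {}
    for rec in gt.nuclei.itertuples():
        feet[rec.nucleus_id] = rasterize_ellipse(
            shape, rec.row, rec.col, rec.semi_major, rec.semi_minor, rec.angle
        )
    return feet


def matched_iou(mask, gt):
    """IoU between each ground-truth nucleus and the label at its center."""
    labels = mask.labels
    ious = []
    for rec in gt.nuclei.itertuples():
        foot = rasterize_ellipse(labels.shape, rec.row, rec.col,
                                 rec.semi_major, rec.semi_minor, rec.angle)
        lab = labels[int(round(rec.row)), int(round(rec.col))]
        if lab == 0:
            ious.append(0.0)
            continue
        obj = labels == lab
        ious.append((obj & foot).sum() / (obj | foot).sum())
    return np.asarray(ious)


@pytest.fixture(scope="session")
def clean_culture():
    """20 well-separated noise-free disk nuclei with ground truth."""
    # dna_cv kept small so every nucleus meets the >=3x background
    # contrast the recovery guarantee is scoped to
    cfg = SimulationConfig(
        mode="culture", image_size=(512, 512), n_nuclei=20, seed=101,
        eccentricity=0.0, nucleus_radius=10, nucleus_radius_cv=0.05,
        dna_cv=0.1, psf_sigma=0.0, photon_scale=0.0, read_noise_sigma=0.0,
    )
    return generate_culture_image(cfg)


@pytest.fixture(scope="session")
def noisy_culture():
    """Default-noise culture field (PSF + Poisson + read noise)."""
    cfg = SimulationConfig(
        mode="culture", image_size=(512, 512), n_nuclei=20, seed=202,
        dna_cv=0.1,
    )
    return generate_culture_image(cfg)
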