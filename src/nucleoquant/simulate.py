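"""Synthetic fluorescence-microscopy image generator with per-nucleus ground truth.

Two modes are supported, mirroring the two specimen geometries of the assay:

``culture``
    A monolayer of well-separated elliptical nuclei on a dark background,
    emulating fibroblasts grown on cover slips.  Each nucleus carries a
    per-nucleus mean intensity in every channel, drawn from a lognormal
    distribution (positive and right-skewed, as observed single-cell
    intensity histograms are).

``tissue``
    An optical section through a 3-D tissue: nuclei are spheres of radius
    R bisected by the focal plane at a uniformly random depth offset
    dz ~ U(-R, R), so each appears as a circle of radius sqrt(R² - dz²).
    The protein channel has a bright extranuclear cytoplasm field.  An
    "old" condition can add bright intranuclear protein foci, a set
    fraction of which is placed exactly on DNA-stain foci.

Rendering is binary-rasterized at the drawn per-nucleus mean, so with the
point-spread function and noise switched off the mean pixel value inside a
nucleus equals its ground-truth mean exactly — the basis for the exact
oracles used by the test-suite.  Degradation order: spectral crosstalk
(optional) → Gaussian PSF → Poisson photon noise → Gaussian read noise →
clip to [0, 1].

All randomness flows from one ``numpy`` generator seeded by
``SimulationConfig.seed``: identical configurations produce bit-identical
images and ground truth.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage as ndi

from .images import ImageSet, write_image_set

log = logging.getLogger("nucleoquant")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class PlacementError(RuntimeError):
    """Nucleus placement failed (density too high for rejection sampling)."""


# Condition presets: per-nucleus mean intensities (a.u. on [0,1]) for the
# cultured-fibroblast conditions, and per-nucleus protein/DNA ratio models
# for the liver-tissue conditions.  The culture numbers are the published
# condition means for human diploid fibroblasts (HDF) and mouse tail
# fibroblasts (MTF); the tissue ratio means 0.29 (young) and 0.36 (old)
# reproduce the reported ~1.24-fold in vivo shift, with the old condition
# modeled as a two-component lognormal mixture to give the heavier right
# tail seen in old liver, plus protein foci colocalizing with DNA foci.
CULTURE_PRESETS: dict[str, dict[str, Any]] = {
    "early_hdf": dict(protein_mean=0.30, dna_mean=0.38),
    "senescent_hdf": dict(protein_mean=0.58, dna_mean=0.40),
    "early_mtf": dict(protein_mean=0.36, dna_mean=0.31),
    "senescent_mtf": dict(protein_mean=0.59, dna_mean=0.28),
}

TISSUE_PRESETS: dict[str, dict[str, Any]] = {
    # mean ratio 0.29, single component, DNA foci only
    "young_liver": dict(ratio_mean=0.29, ratio_tail_weight=0.0, n_foci=0),
    # 0.8·0.31 + 0.2·(1.8·0.31) = 0.3596 ≈ 0.36 mean ratio (1.24× young),
    # with a heavy right tail and colocalizing protein foci
    "old_liver": dict(
        ratio_mean=0.31,
        ratio_tail_weight=0.2,
        ratio_tail_scale=1.8,
        n_foci=4,
    ),
}


@dataclasses.dataclass
class SimulationConfig:
    """Everything needed to render one simulated field of view.

    Intensity means are in a.u. on [0, 1]; radii and sigmas in pixels.
    ``photon_scale``, ``read_noise_sigma`` and ``psf_sigma`` set to 0
    switch the respective degradation off.
    """

    mode: str = "culture"
    image_size: tuple[int, int] = (512, 512)
    n_nuclei: int = 50
    condition: str = ""
    seed: int = 0

    # geometry (pixels); in tissue mode nucleus_radius is the 3-D sphere radius
    nucleus_radius: float = 10.0
    nucleus_radius_cv: float = 0.08
    eccentricity: float = 0.15          # culture: max semi-axis jitter
    touching_pairs: int = 0             # culture: pairs placed 1.5·r apart
    min_gap: float = 6.0                # extra clearance between nuclei

    # per-nucleus intensity model: lognormal(mean, cv) per channel
    dna_mean: float = 0.38
    dna_cv: float = 0.3
    protein_mean: float = 0.30
    protein_cv: float = 0.3
    if_mean: float | None = None        # optional immunofluorescence channel
    if_cv: float = 0.3

    # tissue ratio model: when ratio_mean is set, the per-nucleus protein
    # mean is ratio × DNA mean, with the ratio drawn from a lognormal
    # mixture: weight (1-w) at ratio_mean, weight w at tail_scale × ratio_mean
    ratio_mean: float | None = None
    ratio_cv: float = 0.3
    ratio_tail_weight: float = 0.0
    ratio_tail_scale: float = 1.0

    # tissue: pin the section depth instead of drawing dz ~ U(-R, R)
    fixed_dz: float | None = None

    # intranuclear foci
    n_foci: int = 0                     # protein foci per affected nucleus
    foci_nucleus_fraction: float = 1.0  # fraction of nuclei carrying protein foci
    n_dna_foci: int = 3                 # heterochromatic DNA foci per nucleus
    focus_radius: float = 1.5
    focus_amplitude: float = 3.0        # focus value = amplitude × nuclear mean
    dna_focus_amplitude: float = 2.0
    coloc_fraction: float = 0.8         # protein foci placed on DNA foci

    # optics and noise
    background: float = 0.05
    cytoplasm_level: float = 0.2        # tissue protein-channel background
    psf_sigma: float = 1.0
    photon_scale: float = 2000.0        # photons at 1.0 a.u.; 0 = no shot noise
    read_noise_sigma: float = 0.003
    crosstalk: float = 0.0              # optional DNA→protein bleed-through

    max_place_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.mode not in ("culture", "tissue"):
            raise ConfigError(f"mode must be 'culture' or 'tissue', got {self.mode!r}")
        if isinstance(self.image_size, int):
            self.image_size = (self.image_size, self.image_size)
        self.image_size = (int(self.image_size[0]), int(self.image_size[1]))
        if min(self.image_size) <= 0:
            raise ConfigError("image_size must be positive")
        if self.n_nuclei < 0:
            raise ConfigError("n_nuclei must be >= 0")
        nonneg = [
            "nucleus_radius", "nucleus_radius_cv", "eccentricity", "min_gap",
            "dna_mean", "dna_cv", "protein_mean", "protein_cv", "if_cv",
            "ratio_cv", "focus_radius", "focus_amplitude", "dna_focus_amplitude",
            "background", "cytoplasm_level", "psf_sigma", "photon_scale",
            "read_noise_sigma", "crosstalk", "ratio_tail_weight",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.if_mean is not None and self.if_mean < 0:
            raise ConfigError("if_mean must be >= 0")
        if self.ratio_mean is not None and self.ratio_mean < 0:
            raise ConfigError("ratio_mean must be >= 0")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ConfigError("coloc_fraction must be in [0, 1]")
        if not 0.0 <= self.foci_nucleus_fraction <= 1.0:
            raise ConfigError("foci_nucleus_fraction must be in [0, 1]")
        if not 0.0 <= self.ratio_tail_weight <= 1.0:
            raise ConfigError("ratio_tail_weight must be in [0, 1]")
        if self.nucleus_radius <= 0 and self.n_nuclei > 0:
            raise ConfigError("nucleus_radius must be > 0")
        if self.mode == "culture" and self.ratio_mean is not None:
            raise ConfigError("the ratio intensity model is tissue-mode only")
        if self.mode == "culture" and self.fixed_dz is not None:
            raise ConfigError("section depth offsets are tissue-mode only")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from a plain-text key: value (YAML) file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected key: value pairs")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class GroundTruthTable:
    """Simulator output: true per-nucleus geometry, intensities and foci.

    ``nuclei`` has one row per nucleus (id, condition, center, geometry,
    true per-channel mean of the rendered noise-free pixels, pixel area,
    foci counts).  ``foci`` has one row per rendered focus (nucleus id,
    channel, center, radius, colocalized flag).  ``true_mean_*`` columns
    are the means of the clean rendered pixels inside the footprint, so
    they include any focus contribution.
    """

    nuclei: pd.DataFrame
    foci: pd.DataFrame
    mode: str
    seed: int

    def __post_init__(self) -> None:
        ids = self.nuclei["nucleus_id"]
        if ids.duplicated().any():
            raise ValueError("ground-truth nucleus ids must be unique")


_NUCLEUS_COLUMNS = [
    "nucleus_id", "condition", "row", "col",
    "radius_3d", "dz", "radius", "semi_major", "semi_minor", "angle",
    "area_px", "true_mean_dna", "true_mean_protein", "true_mean_if",
    "true_ratio", "n_foci_dna", "n_foci_protein",
]
_FOCI_COLUMNS = ["nucleus_id", "channel", "row", "col", "radius", "colocalized"]


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Lognormal draws parameterized by arithmetic mean and CV."""
    if mean == 0 or cv == 0:
        return np.full(size, float(mean))
    s2 = math.log1p(cv * cv)
    mu = math.log(mean) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size)


def _draw_ratios(rng: np.random.Generator, cfg: SimulationConfig, n: int) -> np.ndarray:
    """Per-nucleus protein/DNA ratios from a two-component lognormal mixture."""
    base = _lognormal(rng, cfg.ratio_mean, cfg.ratio_cv, n)
    if cfg.ratio_tail_weight > 0 and cfg.ratio_tail_scale != 1.0:
        tail = _lognormal(rng, cfg.ratio_mean * cfg.ratio_tail_scale, cfg.ratio_cv, n)
        pick = rng.random(n) < cfg.ratio_tail_weight
        base = np.where(pick, tail, base)
    return base


def _place_centers(
    rng: np.random.Generator, cfg: SimulationConfig, radii: np.ndarray
) -> np.ndarray:
    """Rejection-sample non-overlapping centers (row, col).

    The margin keeps every nucleus plus its PSF tail clear of the image
    border so that downstream border-object removal does not censor
    simulated nuclei.  ``touching_pairs`` places the first pairs at
    1.5 × mean radius separation to exercise watershed splitting.
    """
    h, w = cfg.image_size
    n = cfg.n_nuclei
    centers = np.empty((n, 2), dtype=np.float64)
    margin = radii + 3.0 * cfg.psf_sigma + 2.0
    if n and (2 * margin.max() >= min(h, w)):
        raise PlacementError("image too small for the configured nucleus radius")
    for i in range(n):
        pair_partner = cfg.touching_pairs and i < 2 * cfg.touching_pairs and i % 2 == 1
        placed = False
        for _ in range(cfg.max_place_attempts):
            if pair_partner:
                theta = rng.uniform(0, 2 * math.pi)
                d = 1.5 * 0.5 * (radii[i] + radii[i - 1])
                cand = centers[i - 1] + d * np.array([math.sin(theta), math.cos(theta)])
                if not (margin[i] <= cand[0] <= h - 1 - margin[i]
                        and margin[i] <= cand[1] <= w - 1 - margin[i]):
                    continue
                others = np.delete(np.arange(i), i - 1)
            else:
                cand = np.array([
                    rng.uniform(margin[i], h - 1 - margin[i]),
                    rng.uniform(margin[i], w - 1 - margin[i]),
                ])
                others = np.arange(i)
            if others.size:
                dist = np.hypot(*(centers[others] - cand).T)
                min_sep = radii[others] + radii[i] + cfg.min_gap
                if np.any(dist < min_sep):
                    continue
            centers[i] = cand
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{n} after "
                f"{cfg.max_place_attempts} attempts; reduce density"
            )
    return centers


def _ellipse_footprint(
    center: np.ndarray, a: float, b: float, theta: float, shape: tuple[int, int]
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Binary rasterization of an ellipse; returns (bbox slices, inside mask)."""
    r_c, c_c = center
    rmax = max(a, b)
    r0 = max(int(math.floor(r_c - rmax - 1)), 0)
    r1 = min(int(math.ceil(r_c + rmax + 1)) + 1, shape[0])
    c0 = max(int(math.floor(c_c - rmax - 1)), 0)
    c1 = min(int(math.ceil(c_c + rmax + 1)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - r_c
    dx = cc - c_c
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return (slice(r0, r1), slice(c0, c1)), inside


def _disk_points_in_nucleus(
    rng: np.random.Generator, center: np.ndarray, reach: float, n: int
) -> np.ndarray:
    """Uniform points in a disk of radius ``reach`` around ``center``."""
    r = reach * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * math.pi, n)
    return center + np.column_stack([r * np.sin(th), r * np.cos(th)])


def _degrade(rng: np.random.Generator, cfg: SimulationConfig, clean: np.ndarray) -> np.ndarray:
    img = clean
    if cfg.psf_sigma > 0:
        img = ndi.gaussian_filter(img, cfg.psf_sigma, mode="nearest")
    if cfg.photon_scale > 0:
        img = rng.poisson(img * cfg.photon_scale).astype(np.float64) / cfg.photon_scale
    if cfg.read_noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.read_noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def _simulate(cfg: SimulationConfig) -> tuple[ImageSet, GroundTruthTable]:
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.image_size
    n = cfg.n_nuclei
    tissue = cfg.mode == "tissue"

    channel_names = ["dna", "protein"] + (["if"] if cfg.if_mean is not None else [])

    # --- geometry ------------------------------------------------------
    radii3d = _lognormal(rng, cfg.nucleus_radius, cfg.nucleus_radius_cv, n)
    if tissue:
        if cfg.fixed_dz is not None:
            dz = np.full(n, float(cfg.fixed_dz))
        else:
            dz = rng.uniform(-radii3d, radii3d) if n else np.empty(0)
        app_radius = np.sqrt(np.maximum(radii3d**2 - dz**2, 0.0))
        semi_a = semi_b = app_radius
        angle = np.zeros(n)
        place_radius = radii3d  # space by the sphere, not the cross-section
    else:
        dz = np.full(n, np.nan)
        ecc = rng.uniform(0.0, cfg.eccentricity, n)
        semi_a = radii3d * (1.0 + ecc)
        semi_b = radii3d / (1.0 + ecc)
        app_radius = np.sqrt(semi_a * semi_b)
        angle = rng.uniform(0, math.pi, n)
        place_radius = semi_a
    centers = _place_centers(rng, cfg, place_radius) if n else np.empty((0, 2))

    # --- per-nucleus intensities --------------------------------------
    dna_means = _lognormal(rng, cfg.dna_mean, cfg.dna_cv, n)
    if tissue and cfg.ratio_mean is not None:
        ratios = _draw_ratios(rng, cfg, n)
        protein_means = ratios * dna_means
    else:
        protein_means = _lognormal(rng, cfg.protein_mean, cfg.protein_cv, n)
    if_means = (
        _lognormal(rng, cfg.if_mean, cfg.if_cv, n) if cfg.if_mean is not None else None
    )

    # --- clean rendering ----------------------------------------------
    bg = {
        "dna": cfg.background,
        "protein": cfg.cytoplasm_level if tissue else cfg.background,
        "if": cfg.background,
    }
    clean = {ch: np.full((h, w), bg[ch], dtype=np.float64) for ch in channel_names}

    footprints: list[tuple[tuple[slice, slice], np.ndarray]] = []
    for i in range(n):
        sl, inside = _ellipse_footprint(centers[i], semi_a[i], semi_b[i], angle[i], (h, w))
        footprints.append((sl, inside))
        clean["dna"][sl][inside] = dna_means[i]
        clean["protein"][sl][inside] = protein_means[i]
        if if_means is not None:
            clean["if"][sl][inside] = if_means[i]

    # --- foci ----------------------------------------------------------
    foci_rows: list[dict[str, Any]] = []
    n_foci_dna = np.zeros(n, dtype=int)
    n_foci_protein = np.zeros(n, dtype=int)
    render_foci = cfg.n_dna_foci if tissue else 0
    if cfg.n_foci > 0:
        render_foci = max(render_foci, cfg.n_dna_foci)
    for i in range(n):
        reach = 0.75 * min(semi_a[i], semi_b[i])
        if (render_foci == 0 and cfg.n_foci == 0) or reach <= cfg.focus_radius:
            continue
        # resolvable separation: two blurred foci must not merge; a
        # non-colocalizing focus only needs to stay clear of the (smaller)
        # blurred DNA-focus region
        min_sep = 2.0 * cfg.focus_radius + 4.0 * cfg.psf_sigma + 1.0
        dna_clear = cfg.focus_radius + 2.0 * cfg.psf_sigma + 1.0
        # DNA (heterochromatic) foci: present in tissue regardless of age,
        # placed with a minimum pairwise separation so they stay resolvable
        dna_centers = np.empty((0, 2))
        if render_foci > 0:
            acc: list[np.ndarray] = []
            for _ in range(cfg.n_dna_foci):
                p = _sample_away_from(rng, centers[i], reach, [(acc, min_sep)])
                if p is not None:
                    acc.append(p)
            dna_centers = np.asarray(acc) if acc else np.empty((0, 2))
            for fc in dna_centers:
                _render_focus(clean["dna"], fc, cfg.focus_radius,
                              cfg.dna_focus_amplitude * dna_means[i], footprints[i])
                foci_rows.append(dict(nucleus_id=i + 1, channel="dna",
                                      row=fc[0], col=fc[1],
                                      radius=cfg.focus_radius, colocalized=np.nan))
            n_foci_dna[i] = len(dna_centers)
        # Protein foci, a set fraction placed on DNA foci.  Placement keeps
        # foci resolvable: each colocalizing focus takes a *distinct* DNA
        # focus, and all protein foci keep a minimum pairwise separation;
        # foci that cannot be placed under these constraints in a small
        # nucleus are skipped, and the ground truth records exactly what
        # was rendered.
        if cfg.n_foci > 0 and rng.random() < cfg.foci_nucleus_fraction:
            placed: list[np.ndarray] = []
            free_dna = list(range(len(dna_centers)))
            for _ in range(cfg.n_foci):
                coloc = rng.random() < cfg.coloc_fraction
                if coloc:
                    candidates = [
                        j for j in free_dna
                        if not placed or np.min(
                            np.hypot(*(np.asarray(placed) - dna_centers[j]).T)
                        ) >= min_sep
                    ]
                    if not candidates:  # skip rather than silently demote
                        continue
                    j = candidates[rng.integers(len(candidates))]
                    free_dna.remove(j)
                    fc = dna_centers[j]
                else:
                    fc = _sample_away_from(
                        rng, centers[i], reach,
                        [(dna_centers, dna_clear), (placed, min_sep)])
                    if fc is None:
                        continue
                placed.append(fc)
                _render_focus(clean["protein"], fc, cfg.focus_radius,
                              cfg.focus_amplitude * protein_means[i], footprints[i])
                foci_rows.append(dict(nucleus_id=i + 1, channel="protein",
                                      row=fc[0], col=fc[1],
                                      radius=cfg.focus_radius, colocalized=coloc))
                n_foci_protein[i] += 1

    if cfg.crosstalk > 0:
        clean["protein"] = clean["protein"] + cfg.crosstalk * clean["dna"]

    for ch in channel_names:
        np.clip(clean[ch], 0.0, 1.0, out=clean[ch])

    # --- ground truth from the clean rendering -------------------------
    rows: list[dict[str, Any]] = []
    for i in range(n):
        sl, inside = footprints[i]
        area = int(inside.sum())
        means = {}
        for ch in channel_names:
            vals = clean[ch][sl][inside]
            means[ch] = float(vals.mean()) if area else np.nan
        if area == 0:
            log.warning("nucleus %d rasterized to zero pixels (apparent radius %.2f)",
                        i + 1, app_radius[i])
        rows.append(dict(
            nucleus_id=i + 1, condition=cfg.condition,
            row=centers[i][0], col=centers[i][1],
            radius_3d=radii3d[i] if tissue else np.nan,
            dz=dz[i], radius=app_radius[i],
            semi_major=semi_a[i], semi_minor=semi_b[i], angle=angle[i],
            area_px=area,
            true_mean_dna=means["dna"],
            true_mean_protein=means["protein"],
            true_mean_if=means.get("if", np.nan),
            true_ratio=(means["protein"] / means["dna"]) if means.get("dna") else np.nan,
            n_foci_dna=n_foci_dna[i], n_foci_protein=n_foci_protein[i],
        ))

    nuclei = pd.DataFrame(rows, columns=_NUCLEUS_COLUMNS)
    foci = pd.DataFrame(foci_rows, columns=_FOCI_COLUMNS)

    # --- degradation ----------------------------------------------------
    final = {ch: _degrade(rng, cfg, clean[ch]) for ch in channel_names}
    images = ImageSet(channels=final, bit_depth=16)
    return images, GroundTruthTable(nuclei=nuclei, foci=foci, mode=cfg.mode, seed=cfg.seed)


def _render_focus(
    channel: np.ndarray,
    center: np.ndarray,
    radius: float,
    value: float,
    footprint: tuple[tuple[slice, slice], np.ndarray],
) -> None:
    """Set pixels of a focus disk, clipped to its nucleus footprint."""
    sl, inside = footprint
    rr, cc = np.mgrid[sl[0], sl[1]]
    disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    channel[sl][disk & inside] = value


def _sample_away_from(
    rng: np.random.Generator,
    center: np.ndarray,
    reach: float,
    constraints: list[tuple[np.ndarray, float]],
    attempts: int = 100,
) -> np.ndarray | None:
    """A point in the nucleus disk kept clear of existing focus centers.

    ``constraints`` pairs each set of points with its own minimum
    distance.  Returns ``None`` when the nucleus is too crowded; the
    caller then renders fewer foci rather than unresolvable overlapping
    ones.
    """
    for _ in range(attempts):
        p = _disk_points_in_nucleus(rng, center, reach, 1)[0]
        ok = True
        for pts, min_dist in constraints:
            pts = np.asarray(pts)
            if pts.size and np.min(np.hypot(*(pts - p).T)) <= min_dist:
                ok = False
                break
        if ok:
            return p
    return None


def generate_culture_image(config: SimulationConfig) -> tuple[ImageSet, GroundTruthTable]:
    """Render one culture-mode (monolayer) field with ground truth.

    Nuclei are mildly eccentric ellipses placed without overlap by
    rejection sampling; raises :class:`PlacementError` when the requested
    density cannot be met.
    """
    if config.mode != "culture":
        raise ConfigError("generate_culture_image requires mode='culture'")
    return _simulate(config)


def generate_tissue_section(config: SimulationConfig) -> tuple[ImageSet, GroundTruthTable]:
    """Render one tissue optical section with ground truth.

    Each nucleus is a sphere of radius R cut at a uniform random depth
    offset dz, appearing as a circle of radius sqrt(R² − dz²); the
    protein channel carries a bright cytoplasm field.
    """
    if config.mode != "tissue":
        raise ConfigError("generate_tissue_section requires mode='tissue'")
    return _simulate(config)


def simulate(config: SimulationConfig) -> tuple[ImageSet, GroundTruthTable]:
    """Dispatch on ``config.mode``."""
    if config.mode == "tissue":
        return generate_tissue_section(config)
    return generate_culture_image(config)


def save_simulation(
    images: ImageSet,
    truth: GroundTruthTable,
    directory: str | Path,
    prefix: str = "sim",
) -> dict[str, Path]:
    """Write 16-bit TIFFs (one per channel) plus ground-truth CSV tables."""
    directory = Path(directory)
    paths = write_image_set(images, directory, prefix)
    gt_path = directory / f"{prefix}_ground_truth.csv"
    truth.nuclei.to_csv(gt_path, index=False)
    paths["ground_truth"] = gt_path
    foci_path = directory / f"{prefix}_ground_truth_foci.csv"
    truth.foci.to_csv(foci_path, index=False)
    paths["ground_truth_foci"] = foci_path
    return paths
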