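"""End-to-end runs: configuration, stage orchestration, provenance, reports.

A run either simulates its inputs (per-condition simulator settings) or
loads existing grayscale TIFFs, then executes
segment → measure → (central-nucleus filter, tissue mode) → population
statistics → (focus analysis), writing CSV tables and a JSON run report.
Every table carries a header comment with the package version, the
configuration hash and the master seed, so any number can be traced to
the run that produced it; re-running an identical configuration
reproduces byte-identical tables.

Simulated channels are written to 16-bit TIFF and read back before
analysis, so the analyzed data went through the same quantized container
as real acquisitions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .foci import FociConfig, colocalize, detect_foci, foci_prevalence
from .images import ImageSet, read_image_set, write_image_set, write_label_mask
from .measure import measure_objects
from .segmentation import SegmentationConfig, segment_nuclei
from .simulate import (
    CULTURE_PRESETS,
    TISSUE_PRESETS,
    GroundTruthTable,
    SimulationConfig,
    simulate,
)
from .stats import (
    compare_conditions,
    make_histogram,
    pool_conditions,
    summarize,
)
from .tissue import TissueFilterRule, filter_central_nuclei

log = logging.getLogger("nucleoquant")


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""


@dataclasses.dataclass
class ConditionSpec:
    """One experimental condition: either simulated or loaded from disk.

    Exactly one of ``simulate`` (simulator parameter overrides; presets
    such as ``early_hdf`` may be named via ``preset``) and ``images``
    (list of per-image channel→path mappings) must be given.
    """

    label: str
    simulate: dict[str, Any] | None = None
    preset: str | None = None
    images: list[dict[str, str]] | None = None
    n_images: int = 1

    def __post_init__(self) -> None:
        simulated = self.simulate is not None or self.preset is not None
        if simulated == (self.images is not None):
            raise ValueError(
                f"condition {self.label!r}: give exactly one of "
                "simulator settings or input images"
            )
        if self.images is not None:
            for mapping in self.images:
                for path in mapping.values():
                    if not Path(path).exists():
                        raise FileNotFoundError(f"input image not found: {path}")


@dataclasses.dataclass
class RunConfig:
    """Everything defining one reproducible end-to-end run."""

    mode: str
    output_dir: str
    conditions: list[ConditionSpec]
    seed: int = 0
    segmentation: SegmentationConfig = dataclasses.field(default_factory=SegmentationConfig)
    tissue_rule: TissueFilterRule = dataclasses.field(default_factory=TissueFilterRule)
    foci: FociConfig | None = None
    foci_channels: tuple[str, str] = ("protein", "dna")
    test_on: str | None = None          # default: by mode
    n_bins: int = 20
    save_masks: bool = False
    keep_images: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("culture", "tissue"):
            raise ValueError("mode must be 'culture' or 'tissue'")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        if self.test_on is None:
            self.test_on = "ratio_no_dapi" if self.mode == "tissue" else "mean_protein"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        conditions = [ConditionSpec(**c) for c in data.pop("conditions", [])]
        seg = SegmentationConfig(**data.pop("segmentation", {}))
        rule = TissueFilterRule(**data.pop("tissue_rule", {}))
        foci_cfg = data.pop("foci", None)
        foci = FociConfig(**foci_cfg) if isinstance(foci_cfg, dict) else None
        return cls(conditions=conditions, segmentation=seg, tissue_rule=rule,
                   foci=foci, **data)

    def config_hash(self) -> str:
        """Hash of the scientific parameters (where outputs land is not
        part of a run's identity)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _condition_sim_config(
    spec: ConditionSpec, run: RunConfig, seed: int
) -> SimulationConfig:
    params: dict[str, Any] = {}
    if spec.preset is not None:
        presets = CULTURE_PRESETS if run.mode == "culture" else TISSUE_PRESETS
        if spec.preset not in presets:
            raise KeyError(f"unknown {run.mode} preset {spec.preset!r}")
        params.update(presets[spec.preset])
    if spec.simulate:
        params.update(spec.simulate)
    params.setdefault("mode", run.mode)
    params["condition"] = spec.label
    params["seed"] = int(seed)
    return SimulationConfig(**params)


def _write_csv(df: pd.DataFrame, path: Path, header: str, written: list[Path]) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    written.append(path)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute one full run; returns the run report (also written as JSON).

    Any stage failure aborts with a stage-labeled :class:`PipelineError`
    after removing the partial outputs of this run.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings: list[str] = []
    cfg_hash = config.config_hash()
    header = (f"# nucleoquant v{__version__} config_hash={cfg_hash} "
              f"seed={config.seed}\n")
    stage = "setup"
    try:
        # ----------------------------------------------------------- inputs
        stage = "simulate/load"
        total_images = sum(
            c.n_images if c.images is None else len(c.images)
            for c in config.conditions
        )
        child_seeds = [
            int(s) for s in
            np.random.SeedSequence(config.seed).generate_state(max(total_images, 1))
            % (2**31)
        ]
        fields: list[tuple[str, str, ImageSet, GroundTruthTable | None]] = []
        seed_iter = iter(child_seeds)
        img_dir = out / "images"
        for spec in config.conditions:
            if spec.images is not None:
                for i, mapping in enumerate(spec.images):
                    fields.append((spec.label, f"{spec.label}_{i:02d}",
                                   read_image_set(mapping), None))
                    next(seed_iter)
            else:
                for i in range(spec.n_images):
                    sim_cfg = _condition_sim_config(spec, config, next(seed_iter))
                    images, truth = simulate(sim_cfg)
                    name = f"{spec.label}_{i:02d}"
                    paths = write_image_set(images, img_dir, name)
                    written.extend(paths.values())
                    # analyze what the 16-bit container actually holds
                    images = read_image_set(paths)
                    fields.append((spec.label, name, images, truth))

        # ------------------------------------------------------ segmentation
        stage = "segment"
        masks = []
        for label, name, images, _ in fields:
            mask = segment_nuclei(images["dna"], config.segmentation)
            masks.append(mask)
            if mask.n_objects == 0:
                warnings.append(f"{name}: no nuclei found")
            if config.save_masks:
                mpath = out / "masks" / f"{name}_mask.tif"
                mpath.parent.mkdir(exist_ok=True)
                write_label_mask(mask, mpath)
                written.append(mpath)

        # ------------------------------------------------------- measurement
        stage = "measure"
        tables = {}
        for (label, name, images, _), mask in zip(fields, masks):
            tab = measure_objects(mask, images)
            tab.insert(1, "condition", label)
            tables[name] = tab
        objects = pool_conditions(tables)

        truth_frames = [t.nuclei.assign(source=name)
                        for (_, name, _, t) in fields if t is not None]
        ground_truth = pd.concat(truth_frames, ignore_index=True) \
            if truth_frames else None

        # ---------------------------------------------------- tissue filter
        stage = "tissue_filter"
        if config.mode == "tissue":
            analyzed = filter_central_nuclei(objects, config.tissue_rule,
                                             group_col="source")
            objects = objects.copy()
            objects["retained"] = objects.index.isin(analyzed.index)
        else:
            analyzed = objects

        # ------------------------------------------------------- statistics
        stage = "stats"
        labels = [c.label for c in config.conditions]
        summaries = []
        for label in labels:
            sub = analyzed[analyzed["condition"] == label]
            for ch in ("dna", "protein", "if"):
                if f"mean_{ch}" in sub.columns:
                    s = summarize(sub, ch, label)
                    summaries.append(dataclasses.asdict(s))
        summaries_df = pd.DataFrame(summaries)

        comparison = None
        if len(labels) >= 2:
            a = analyzed[analyzed["condition"] == labels[0]]
            b = analyzed[analyzed["condition"] == labels[1]]
            comparison = compare_conditions(a, b, labels[0], labels[1],
                                            test_on=config.test_on)

        values = analyzed[config.test_on].to_numpy(dtype=float)
        values = values[np.isfinite(values)]
        edges = np.histogram_bin_edges(values, bins=config.n_bins) \
            if values.size else None
        hist_rows = []
        for label in labels:
            sub = analyzed[analyzed["condition"] == label]
            v = sub[config.test_on].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                warnings.append(f"{label}: no values to histogram")
                continue
            hist = make_histogram(v, edges=edges)
            for lo, hi, pct in zip(hist.edges[:-1], hist.edges[1:], hist.percent):
                hist_rows.append(dict(condition=label, bin_left=lo, bin_right=hi,
                                      percent=pct, statistic=config.test_on))
        histograms_df = pd.DataFrame(hist_rows)

        # ------------------------------------------------------------- foci
        stage = "foci"
        foci_df = pd.DataFrame()
        coloc_rows = []
        prevalence_df = pd.DataFrame()
        if config.foci is not None:
            ch_a, ch_b = config.foci_channels
            all_foci = []
            coloc_by_cond: dict[str, dict[str, int]] = {}
            for (label, name, images, _), mask in zip(fields, masks):
                rec_a, fmask_a = detect_foci(images[ch_a], mask, config.foci, ch_a)
                rec_b, fmask_b = detect_foci(images[ch_b], mask, config.foci, ch_b)
                res = colocalize(rec_a, fmask_a, rec_b, fmask_b)
                acc = coloc_by_cond.setdefault(
                    label, dict(n_foci_a=0, n_a_colocalized=0, n_foci_b=0,
                                n_b_colocalized=0, n_pixels_a=0, n_pixels_b=0,
                                n_pixels_intersection=0))
                for key in acc:
                    acc[key] += getattr(res, key)
                for rec, ch in ((rec_a, ch_a), (rec_b, ch_b)):
                    if len(rec):
                        rec = rec.assign(source=name, condition=label)
                        all_foci.append(rec)
            foci_df = pd.concat(all_foci, ignore_index=True) if all_foci \
                else pd.DataFrame()
            for label, acc in coloc_by_cond.items():
                coloc_rows.append(dict(
                    condition=label, channel_a=ch_a, channel_b=ch_b, **acc,
                    fraction_a_colocalized=(acc["n_a_colocalized"] / acc["n_foci_a"]
                                            if acc["n_foci_a"] else 0.0),
                    fraction_b_colocalized=(acc["n_b_colocalized"] / acc["n_foci_b"]
                                            if acc["n_foci_b"] else 0.0),
                    pixel_overlap_a_in_b=(acc["n_pixels_intersection"] / acc["n_pixels_a"]
                                          if acc["n_pixels_a"] else 0.0),
                ))
            if len(foci_df):
                prevalence_df = foci_prevalence(foci_df, objects, channel=ch_a)

        # ----------------------------------------------------------- output
        stage = "write"
        _write_csv(objects, out / "objects.csv", header, written)
        _write_csv(summaries_df, out / "summaries.csv", header, written)
        _write_csv(histograms_df, out / "histograms.csv", header, written)
        if ground_truth is not None:
            _write_csv(ground_truth, out / "ground_truth.csv", header, written)
        if comparison is not None:
            comp_df = pd.DataFrame([comparison.to_dict()])
            _write_csv(comp_df, out / "comparison.csv", header, written)
        if len(foci_df):
            _write_csv(foci_df, out / "foci.csv", header, written)
            _write_csv(pd.DataFrame(coloc_rows), out / "colocalization.csv",
                       header, written)
            _write_csv(prevalence_df, out / "foci_prevalence.csv", header, written)

        n_per_condition = {
            label: int((analyzed["condition"] == label).sum()) for label in labels
        }
        for label, n in n_per_condition.items():
            if n < 500:
                warnings.append(f"{label}: only {n} nuclei analyzed (< 500)")
        report: dict[str, Any] = {
            "package": "nucleoquant",
            "version": __version__,
            "config_hash": cfg_hash,
            "seed": config.seed,
            "mode": config.mode,
            "test_on": config.test_on,
            "config": dataclasses.asdict(config),
            "n_images": len(fields),
            "n_objects_total": int(len(objects)),
            "n_analyzed_per_condition": n_per_condition,
            "summaries": summaries,
            "comparison": comparison.to_dict() if comparison else None,
            "comparison_2dp": comparison.rounded() if comparison else None,
            "colocalization": coloc_rows or None,
            "foci_prevalence": prevalence_df.to_dict("records")
            if len(prevalence_df) else None,
            "warnings": warnings,
        }
        report_path = out / "run_report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        written.append(report_path)

        if not config.keep_images and img_dir.exists():
            shutil.rmtree(img_dir)
        return report
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


# ----------------------------------------------------------------------
# canonical study configurations
# ----------------------------------------------------------------------

def hdf_culture_run(
    output_dir: str | Path,
    seed: int,
    n_per_condition: int = 1000,
    n_images: int = 4,
) -> RunConfig:
    """Culture run at the published HDF condition means.

    Early-passage (protein 0.30 / DNA 0.38 a.u.) versus senescent
    (0.58 / 0.40), lognormal per-nucleus means with CV 0.3,
    ``n_per_condition`` nuclei split over ``n_images`` fields per
    condition, default optics and noise.
    """
    per_image, rem = divmod(n_per_condition, n_images)
    if rem:
        raise ValueError("n_per_condition must be divisible by n_images")
    if per_image > 260:
        raise ValueError("raise n_images: >260 nuclei per 1024px field")
    conditions = []
    for label, preset in (("early_hdf", "early_hdf"),
                          ("senescent_hdf", "senescent_hdf")):
        conditions.append(ConditionSpec(
            label=label, preset=preset, n_images=n_images,
            simulate=dict(image_size=(1024, 1024), n_nuclei=per_image),
        ))
    return RunConfig(mode="culture", output_dir=str(output_dir), seed=seed,
                     conditions=conditions, save_masks=False, keep_images=False)


def liver_tissue_run(
    output_dir: str | Path,
    seed: int,
    n_per_image: int = 1250,
    n_images: int = 8,
    with_foci: bool = True,
) -> RunConfig:
    """Tissue run emulating young vs old liver optical sections.

    Spherical nuclei bisected at uniform random depth; per-nucleus
    NO/DAPI ratios lognormal with mean 0.29 (young) and a 0.8/0.2
    two-component mixture with mean 0.36 (old, heavier right tail;
    1.24-fold shift), bright cytoplasm in the protein channel, DNA foci
    in every nucleus and colocalizing protein foci in the old condition.
    ``n_images`` plays the role of animals whose nuclei are pooled.
    """
    conditions = [
        ConditionSpec(label="young_liver", preset="young_liver", n_images=n_images,
                      simulate=dict(image_size=(1800, 1800), n_nuclei=n_per_image)),
        ConditionSpec(label="old_liver", preset="old_liver", n_images=n_images,
                      simulate=dict(image_size=(1800, 1800), n_nuclei=n_per_image)),
    ]
    return RunConfig(
        mode="tissue", output_dir=str(output_dir), seed=seed,
        conditions=conditions,
        foci=FociConfig() if with_foci else None,
        save_masks=False, keep_images=False,
    )
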