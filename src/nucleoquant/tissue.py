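"""Central-nucleus selection for tissue optical sections.

Nuclei in a tissue slice are oriented in three dimensions, and a single
optical section cuts each roughly spherical nucleus at a random depth.
Sections far from a nucleus's equator yield small cross-sections whose
intensities misrepresent the nucleus, so the analysis retains only the
largest DNA-channel objects — the nuclei bisected close to their centers.

The rule quantifying "largest" here: retain objects with
``area >= fraction × (p-th percentile of areas in the same image)``
(defaults: fraction 0.7 of the 90th percentile).  A percentile rather than
the maximum makes the threshold robust to outliers, and on simulated
spheres of radius R the default maps to the closed-form depth bound
|dz| <= sqrt(0.3)·R, which is how the rule is validated.  The threshold is
computed once per image and frozen, so re-applying the rule to its own
output with the frozen threshold is a no-op.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

log = logging.getLogger("nucleoquant")


@dataclasses.dataclass
class TissueFilterRule:
    method: str = "fraction_of_percentile"
    percentile: float = 90.0
    fraction: float = 0.7
    min_retained: int = 100  # warn below this count

    def __post_init__(self) -> None:
        if self.method != "fraction_of_percentile":
            raise ValueError(f"unknown tissue filter method {self.method!r}")
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if not 0 < self.percentile <= 100:
            raise ValueError("percentile must be in (0, 100]")


def area_threshold(areas: np.ndarray, rule: TissueFilterRule) -> float:
    """The frozen area cutoff for one image's population of areas."""
    return rule.fraction * float(np.percentile(np.asarray(areas, dtype=float),
                                               rule.percentile))


def filter_central_nuclei(
    records: pd.DataFrame,
    rule: TissueFilterRule | None = None,
    *,
    threshold: float | None = None,
    group_col: str | None = None,
) -> pd.DataFrame:
    """Retain centrally bisected nuclei by the largest-object area rule.

    Parameters
    ----------
    records
        Per-nucleus measurement table with an ``area`` column.
    rule
        Filter parameters (default: area >= 0.7 × 90th-percentile area).
    threshold
        Pre-computed (frozen) area cutoff; when given, the percentile is
        not recomputed — used to re-apply a filter consistently.
    group_col
        Column naming the source image; the threshold is computed per
        group.  When ``None``, ``"source"`` is used if present, else the
        whole table is one group.

    Returns
    -------
    pandas.DataFrame
        The retained rows (same schema, plus a boolean ``retained``
        column that is True on every returned row).
    """
    rule = rule or TissueFilterRule()
    if records.empty:
        raise ValueError("cannot filter an empty measurement table")
    if group_col is None and "source" in records.columns:
        group_col = "source"

    if threshold is not None:
        keep = records["area"].to_numpy(dtype=float) >= threshold
    elif group_col is not None and group_col in records.columns:
        keep = np.zeros(len(records), dtype=bool)
        for _, idx in records.groupby(group_col, sort=False).groups.items():
            areas = records.loc[idx, "area"].to_numpy(dtype=float)
            keep[records.index.get_indexer(idx)] = areas >= area_threshold(areas, rule)
    else:
        keep = records["area"].to_numpy(dtype=float) >= area_threshold(
            records["area"].to_numpy(dtype=float), rule
        )

    retained = records.loc[keep].copy()
    retained["retained"] = True
    n_in, n_out = len(records), len(retained)
    log.info("central-nucleus filter: retained %d / %d (discarded %d)",
             n_out, n_in, n_in - n_out)
    if n_out == 0:
        log.warning("central-nucleus filter removed every object")
    elif n_out < rule.min_retained:
        log.warning("central-nucleus filter retained only %d objects "
                    "(< %d)", n_out, rule.min_retained)
    return retained
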