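"""ROI summaries of fitted parameter maps, merged fraction maps and
lesion-level scatter tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from renodiff.exceptions import ValidationError
from renodiff.io_formats import LabeledVolume

log = logging.getLogger(__name__)

#: columns fractions are converted to percent in display output
_FRACTION_PARAMS = {"f_star", "f_fast", "f_interm", "f_slow"}


@dataclass
class ROISummary:
    """Per-region mean/SD/count of every fitted parameter.

    Stored as a tidy frame with one row per (region, parameter).  Sample
    (n-1) standard deviations throughout.
    """

    table: pd.DataFrame  # columns: region, parameter, mean, sd, n_voxels

    def __post_init__(self):
        required = {"region", "parameter", "mean", "sd", "n_voxels"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"summary table lacks columns {sorted(missing)}")
        if (self.table["n_voxels"] <= 0).any():
            raise ValidationError("every reported region needs at least one voxel")
        if (self.table["sd"].dropna() < 0).any():
            raise ValidationError("SD must be >= 0")

    def mean(self, region: str, parameter: str) -> float:
        sel = self.table[(self.table.region == region) & (self.table.parameter == parameter)]
        if sel.empty:
            raise KeyError(f"no summary for ({region}, {parameter})")
        return float(sel["mean"].iloc[0])

    def sd(self, region: str, parameter: str) -> float:
        sel = self.table[(self.table.region == region) & (self.table.parameter == parameter)]
        if sel.empty:
            raise KeyError(f"no summary for ({region}, {parameter})")
        return float(sel["sd"].iloc[0])

    @property
    def regions(self):
        return list(dict.fromkeys(self.table["region"]))

    @property
    def parameters(self):
        return list(dict.fromkeys(self.table["parameter"]))

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: one row per region; per parameter a display
        column ``"mean (sd)"`` plus full-precision numeric columns."""
        rows = []
        for region in self.regions:
            sub = self.table[self.table.region == region]
            row = {"region": region, "n_voxels": int(sub["n_voxels"].max())}
            for _, r in sub.iterrows():
                p, m, s = r["parameter"], r["mean"], r["sd"]
                scale = 100.0 if p in _FRACTION_PARAMS else 1.0
                row[p] = f"{m * scale:.3g} ({s * scale:.3g})"
                row[f"{p}_mean"] = m
                row[f"{p}_sd"] = s
            rows.append(row)
        return pd.DataFrame(rows)


def roi_summary(maps: dict, labels: LabeledVolume) -> ROISummary:
    """Mean/SD of every map over each labeled region.

    Non-finite voxels are excluded from both the statistics and the
    voxel count; a label whose region contains no voxels on the grid is
    an error.
    """
    if not maps:
        raise ValidationError("no parameter maps supplied")
    for name, m in maps.items():
        if np.asarray(m).shape != labels.data.shape:
            raise ValidationError(
                f"map {name!r} shape {np.asarray(m).shape} does not match "
                f"label grid {labels.data.shape}"
            )
    rows = []
    for label, region in sorted(labels.labels.items()):
        mask = labels.mask(label)
        if not mask.any():
            raise ValidationError(f"label {label} ({region}) has no voxels on the grid")
        for name, m in maps.items():
            vals = np.asarray(m)[mask]
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                raise ValidationError(
                    f"label {label} ({region}) has no finite voxels in map {name!r}"
                )
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            rows.append({
                "region": region, "parameter": name,
                "mean": float(np.mean(vals)), "sd": sd, "n_voxels": len(vals),
            })
    return ROISummary(pd.DataFrame(rows))


def merged_fraction_map(f_fast_map, f_interm_map) -> np.ndarray:
    """RGB volume merging tri-exponential fractions.

    Channel coding: red = f_fast, green = f_slow = 1 - f_fast - f_interm,
    blue = f_interm, so channels sum to 1 wherever the fractions are
    valid.  Out-of-range inputs are clipped (count logged); non-finite
    voxels stay NaN in all channels.
    """
    ff = np.asarray(f_fast_map, dtype=float)
    fi = np.asarray(f_interm_map, dtype=float)
    if ff.shape != fi.shape:
        raise ValidationError("fraction maps must share a grid")
    finite = np.isfinite(ff) & np.isfinite(fi)
    n_clipped = int(np.sum((ff[finite] < 0) | (ff[finite] > 1))
                    + np.sum((fi[finite] < 0) | (fi[finite] > 1)))
    if n_clipped:
        log.warning("clipped %d out-of-range fraction values", n_clipped)
    ff = np.clip(ff, 0.0, 1.0)
    fi = np.clip(fi, 0.0, 1.0)
    fs = np.clip(1.0 - ff - fi, 0.0, 1.0)
    rgb = np.stack([ff, fs, fi], axis=-1)
    rgb[~finite] = np.nan
    return rgb


def lesion_scatter_table(lesion_summaries) -> pd.DataFrame:
    """One row per lesion with its per-parameter ROI means.

    ``lesion_summaries`` is an iterable of ``(lesion_id, lesion_type,
    ROISummary)`` triples (each summary holding one lesion region) or of
    ready-made row dicts.  This is the plot-ready table behind
    per-lesion scatter and box plots.
    """
    rows = []
    for item in lesion_summaries:
        if isinstance(item, dict):
            rows.append(dict(item))
            continue
        lesion_id, lesion_type, summary = item
        if len(summary.regions) != 1:
            raise ValidationError(
                f"lesion {lesion_id}: expected a single-region summary, "
                f"got {summary.regions}"
            )
        region = summary.regions[0]
        row = {"lesion_id": lesion_id, "type": lesion_type}
        for p in summary.parameters:
            scale = 100.0 if p in _FRACTION_PARAMS else 1.0
            row[p] = summary.mean(region, p) * scale
        rows.append(row)
    if not rows:
        raise ValidationError("need at least one lesion summary")
    return pd.DataFrame(rows)
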