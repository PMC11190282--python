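"""Single-cell feature engineering: the 151-column feature schema.

Each segmented cell carries, per glucose condition (2.2 mM "low" and
16.7 mM "high"), an autofluorescence-intensity image, per-pixel phasor
coordinate maps ``g`` and ``s``, and a binary ROI mask.  This module turns
such a bundle pair into one :class:`CellRecord` holding exactly 151 named
feature values, grouped into seven families:

==================  ==========================================================
family              content
==================  ==========================================================
intensity           descriptive statistics of pixel intensities over three
                    pixel subsets (all / lipofuscin / non-lipofuscin) and
                    both glucose conditions
phasor              descriptive statistics of the lipofuscin-excluded g and
                    s maps plus the phasor-cloud barycenter and dispersion
metabolism          the glucose-stimulated phasor-shift descriptors
morphology          cell area, perimeter and circularity
lipofuscin          granule area fraction, count and granule-area summaries
donor               donor age, BMI and insulin stimulatory index
experimental        numeric encoding of the glucose condition of the row
==================  ==========================================================

The descriptive-statistics block is fixed at twelve statistics: min, max,
mean, median, sd, q1, q3, iqr, Tukey whiskers, the center of the fullest
bin of a 64-bin histogram ("range of most common values"), and skewness.
Quantiles use linear interpolation; the standard deviation and skewness use
the population convention.  Missing blocks (e.g. a cell without lipofuscin)
stay NaN and are imputed to zero at preprocessing, encoding true absence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from .phasor_core import (
    GranuleSet,
    PhasorCloud,
    PhasorSummary,
    ThresholdPolicy,
    cloud_summary,
    lipofuscin_mask,
    metabolic_shift,
    monoexponential_phasor,
)

__all__ = [
    "STAT_NAMES",
    "CellImageBundle",
    "DonorInfo",
    "FeatureSchema",
    "CellRecord",
    "StatsBlock",
    "default_schema",
    "circularity",
    "morphology",
    "descriptive_stats",
    "extract_cell_features",
    "build_feature_matrix",
]

CONDITIONS = ("low", "high")
#: mM glucose for the two experimental conditions
GLUCOSE_MM = {"low": 2.2, "high": 16.7}
#: numeric encoding of the glucose condition of a matrix row
GLUCOSE_CODE = {"low": 0.0, "high": 1.0, "both": 0.5}

STAT_NAMES = (
    "min", "max", "mean", "median", "sd", "q1", "q3", "iqr",
    "whisker_low", "whisker_high", "mode_bin_center", "skewness",
)

#: default free / protein-bound NAD(P)H lifetimes (ns) used as the
#: metabolic-axis reference points of the shift descriptor
TAU_FREE_NS = 0.4
TAU_BOUND_NS = 3.4


@dataclass
class DonorInfo:
    donor_id: str
    age: float
    bmi: float
    stimulatory_index: float


@dataclass
class CellImageBundle:
    """One cell's rasters for one glucose condition.

    All rasters share one shape; the ROI mask must be non-empty.
    """

    cell_id: str
    islet_id: str
    donor_id: str
    glucose_condition: float  # mM, one of GLUCOSE_MM values
    intensity: np.ndarray
    g_map: np.ndarray
    s_map: np.ndarray
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in
                  (self.intensity, self.g_map, self.s_map, self.roi_mask)}
        if len(shapes) != 1:
            raise ValueError(
                f"cell {self.cell_id}: rasters have mismatched shapes {shapes}")
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if not self.roi_mask.any():
            raise ValueError(f"cell {self.cell_id}: empty ROI mask")
        if self.glucose_condition not in GLUCOSE_MM.values():
            raise ValueError(
                f"cell {self.cell_id}: glucose_condition "
                f"{self.glucose_condition} not in {sorted(GLUCOSE_MM.values())}")

    @property
    def condition_name(self) -> str:
        return "low" if self.glucose_condition == GLUCOSE_MM["low"] else "high"


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str
    signal: str
    statistic: str


class FeatureSchema:
    """Ordered, versioned list of the 151 feature descriptors."""

    N_FEATURES = 151
    VERSION = "1.0"

    def __init__(self, descriptors: list[FeatureDescriptor],
                 version: str = VERSION):
        names = [d.name for d in descriptors]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if len(descriptors) != self.N_FEATURES:
            raise ValueError(
                f"schema must hold exactly {self.N_FEATURES} descriptors, "
                f"got {len(descriptors)}")
        self.descriptors = list(descriptors)
        self.version = version

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def __len__(self) -> int:
        return len(self.descriptors)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, FeatureSchema)
                and self.descriptors == other.descriptors)

    def to_json(self, path: str | Path) -> None:
        payload = {"version": self.version,
                   "features": [vars(d) for d in self.descriptors]}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSchema":
        payload = json.loads(Path(path).read_text())
        return cls([FeatureDescriptor(**d) for d in payload["features"]],
                   version=payload.get("version", cls.VERSION))


def default_schema() -> FeatureSchema:
    """Construct the frozen 151-feature schema.

    Layout: 72 intensity statistics (3 pixel subsets x 2 conditions x 12
    statistics), 48 phasor-coordinate statistics (g/s x 2 conditions x 12),
    8 phasor-cloud summaries, 6 metabolic-shift descriptors, 3 morphology
    values, 8 lipofuscin quantities, 2 integrated intensities, 3 donor
    covariates and 1 experimental encoding = 151 columns.
    """
    d: list[FeatureDescriptor] = []
    for subset in ("all", "lipo", "nonlipo"):
        for cond in CONDITIONS:
            for stat in STAT_NAMES:
                d.append(FeatureDescriptor(
                    f"intensity_{subset}_{cond}_{stat}", "intensity",
                    f"intensity[{subset}]@{cond}", stat))
    for coord in ("g", "s"):
        for cond in CONDITIONS:
            for stat in STAT_NAMES:
                d.append(FeatureDescriptor(
                    f"{coord}_{cond}_{stat}", "phasor",
                    f"{coord}[nonlipo]@{cond}", stat))
    for cond in CONDITIONS:
        for q in ("barycenter_g", "barycenter_s", "sd_g", "sd_s"):
            d.append(FeatureDescriptor(
                f"phasor_{cond}_{q}", "phasor", f"phasor_cloud@{cond}", q))
    for q in ("delta_g", "delta_s", "magnitude", "projection",
              "delta_sd_g", "delta_sd_s"):
        d.append(FeatureDescriptor(f"shift_{q}", "metabolism",
                                   "phasor_shift", q))
    for q in ("area", "perimeter", "circularity"):
        d.append(FeatureDescriptor(f"morph_{q}", "morphology", "roi_mask", q))
    for cond in CONDITIONS:
        for q in ("area_fraction", "granule_count",
                  "mean_granule_area", "total_granule_area"):
            d.append(FeatureDescriptor(
                f"lipo_{q}_{cond}", "lipofuscin", f"granules@{cond}", q))
    for cond in CONDITIONS:
        d.append(FeatureDescriptor(f"intensity_total_{cond}",
                                   "intensity-statistics",
                                   f"intensity[all]@{cond}", "total"))
    for q, col in (("age", "donor_age"), ("bmi", "donor_bmi"),
                   ("stimulatory_index", "donor_si")):
        d.append(FeatureDescriptor(col, "donor", "donor_table", q))
    d.append(FeatureDescriptor("glucose_code", "experimental",
                               "glucose_condition", "code"))
    return FeatureSchema(d)


@dataclass
class CellRecord:
    """One cell's identifiers, 151 feature values and class label."""

    cell_id: str
    islet_id: str
    donor_id: str
    values: dict[str, float]
    label: str = "unknown"  # {"alpha", "beta", "unknown"}
    complete: bool = True

    def as_row(self, schema: FeatureSchema) -> list[float]:
        return [self.values.get(name, np.nan) for name in schema.names]


@dataclass
class StatsBlock:
    min: float
    max: float
    mean: float
    median: float
    sd: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    mode_bin_center: float
    skewness: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in STAT_NAMES}

    @classmethod
    def missing(cls) -> "StatsBlock":
        return cls(*([float("nan")] * len(STAT_NAMES)))


def descriptive_stats(values: np.ndarray, n_mode_bins: int = 64) -> StatsBlock:
    """Twelve-statistic descriptive summary of a numeric vector.

    Whiskers follow the Tukey convention: the most extreme observations
    within ``[q1 - 1.5 iqr, q3 + 1.5 iqr]``.  ``mode_bin_center`` is the
    center of the fullest bin of a fixed 64-bin histogram over [min, max].
    NaNs are dropped; an empty (or all-NaN) input yields an all-missing
    block, which downstream preprocessing imputes to zero.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        return StatsBlock.missing()
    vmin, vmax = float(v.min()), float(v.max())
    mean = float(v.mean())
    median = float(np.median(v))
    sd = float(v.std())  # population convention
    q1, q3 = (float(q) for q in np.percentile(v, [25, 75]))  # linear interp
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    whisker_low = float(inside.min()) if inside.size else vmin
    whisker_high = float(inside.max()) if inside.size else vmax
    # histogram needs a resolvable range: guard against 1-ulp spreads
    resolvable = (vmax - vmin) > n_mode_bins * np.finfo(float).eps * max(
        abs(vmin), abs(vmax), 1.0)
    if resolvable:
        hist, edges = np.histogram(v, bins=n_mode_bins, range=(vmin, vmax))
        k = int(np.argmax(hist))
        mode_center = float(0.5 * (edges[k] + edges[k + 1]))
    else:
        mode_center = vmin
    if sd > 0:
        skew = float(np.mean(((v - mean) / sd) ** 3))
    else:
        skew = 0.0
    return StatsBlock(vmin, vmax, mean, median, sd, q1, q3, iqr,
                      whisker_low, whisker_high, mode_center, skew)


def circularity(area: float, perimeter: float) -> float:
    """Shape circularity ``4 pi area / perimeter^2`` (1 for a perfect circle)."""
    if perimeter <= 0:
        raise ValueError("perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def _contour_perimeter(mask: np.ndarray, smooth_window: int = 3) -> float:
    """Closed-polygon length of the traced, lightly smoothed boundary."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    contour = max(contours, key=len)[:-1]  # drop the duplicate endpoint
    w = smooth_window
    if w > 1 and len(contour) > w:
        kernel = np.ones(w) / w
        contour = np.column_stack([
            np.convolve(np.r_[contour[-(w // 2):, i], contour[:, i],
                              contour[:w // 2, i]], kernel, mode="valid")
            for i in (0, 1)])
    diffs = np.diff(np.vstack([contour, contour[:1]]), axis=0)
    return float(np.sqrt((diffs ** 2).sum(axis=1)).sum())


def morphology(roi_mask: np.ndarray, pixel_size: float = 1.0,
               cell_id: str = "?") -> tuple[float, float, float]:
    """Cell area, perimeter and circularity from a binary ROI mask.

    The perimeter is measured by contour tracing: the marching-squares
    boundary at the 0.5 level, lightly smoothed (3-point moving average)
    to remove the pixel staircase, then summed as a closed polygon.  This
    keeps a rasterized disk's circularity near 1 while a square mask stays
    near pi/4.  The mask must be a single connected component with
    interior; degenerate one-pixel-wide masks are rejected.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if not mask.any():
        raise ValueError(f"cell {cell_id}: empty mask")
    n_comp = measure.label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(
            f"cell {cell_id}: mask has {n_comp} connected components")
    from scipy.ndimage import binary_erosion
    if not binary_erosion(mask).any():
        raise ValueError(f"cell {cell_id}: degenerate (one-pixel-wide) mask")
    area_px = float(mask.sum())
    perim_px = _contour_perimeter(mask)
    area = area_px * pixel_size**2
    perim = perim_px * pixel_size
    return area, perim, circularity(area, perim)


def _nonempty_cloud_summary(bundle: CellImageBundle,
                            keep: np.ndarray) -> PhasorSummary | None:
    cloud = PhasorCloud.from_maps(bundle.g_map, bundle.s_map, keep)
    if cloud.n_points == 0:
        return None
    return cloud_summary(cloud, cell_id=bundle.cell_id)


def _condition_features(bundle: CellImageBundle,
                        policy: ThresholdPolicy) -> tuple[dict, PhasorSummary | None]:
    cond = bundle.condition_name
    out: dict[str, float] = {}
    roi = bundle.roi_mask
    granules: GranuleSet = lipofuscin_mask(bundle.intensity, roi, policy)
    lipo = granules.mask
    nonlipo = roi & ~lipo
    subsets = {"all": roi, "lipo": lipo, "nonlipo": nonlipo}
    for name, m in subsets.items():
        block = descriptive_stats(bundle.intensity[m])
        for stat, val in block.as_dict().items():
            out[f"intensity_{name}_{cond}_{stat}"] = val
    for coord, cmap in (("g", bundle.g_map), ("s", bundle.s_map)):
        block = descriptive_stats(cmap[nonlipo])
        for stat, val in block.as_dict().items():
            out[f"{coord}_{cond}_{stat}"] = val
    summary = _nonempty_cloud_summary(bundle, nonlipo)
    if summary is None:
        for q in ("barycenter_g", "barycenter_s", "sd_g", "sd_s"):
            out[f"phasor_{cond}_{q}"] = np.nan
    else:
        out[f"phasor_{cond}_barycenter_g"] = summary.barycenter_g
        out[f"phasor_{cond}_barycenter_s"] = summary.barycenter_s
        out[f"phasor_{cond}_sd_g"] = summary.sd_g
        out[f"phasor_{cond}_sd_s"] = summary.sd_s
    out[f"lipo_area_fraction_{cond}"] = granules.area_fraction
    out[f"lipo_granule_count_{cond}"] = float(granules.granule_count)
    out[f"lipo_mean_granule_area_{cond}"] = (
        float(granules.granule_areas.mean()) if granules.granule_count
        else np.nan)
    out[f"lipo_total_granule_area_{cond}"] = granules.total_area
    out[f"intensity_total_{cond}"] = float(bundle.intensity[roi].sum())
    return out, summary


def extract_cell_features(low: CellImageBundle, high: CellImageBundle,
                          donor: DonorInfo,
                          schema: FeatureSchema | None = None,
                          pixel_size: float = 1.0,
                          lipofuscin_policy: ThresholdPolicy = ThresholdPolicy(),
                          tau_free: float = TAU_FREE_NS,
                          tau_bound: float = TAU_BOUND_NS,
                          period_ns: float = 1e3 / 80.0,
                          label: str = "unknown") -> CellRecord:
    """Populate one cell's 151-feature record from its two condition bundles."""
    if schema is None:
        schema = default_schema()
    if low.cell_id != high.cell_id:
        raise ValueError(
            f"bundle pair mixes cells {low.cell_id!r} and {high.cell_id!r}")
    if low.donor_id != donor.donor_id:
        raise ValueError(
            f"cell {low.cell_id}: donor mismatch "
            f"({low.donor_id!r} vs {donor.donor_id!r})")
    if low.condition_name != "low" or high.condition_name != "high":
        raise ValueError(f"cell {low.cell_id}: bundles in wrong condition order")

    values: dict[str, float] = {}
    vals_low, summ_low = _condition_features(low, lipofuscin_policy)
    vals_high, summ_high = _condition_features(high, lipofuscin_policy)
    values.update(vals_low)
    values.update(vals_high)

    free_pt = monoexponential_phasor(tau_free, period=period_ns)
    bound_pt = monoexponential_phasor(tau_bound, period=period_ns)
    if summ_low is not None and summ_high is not None:
        shift = metabolic_shift(summ_low, summ_high, free_pt, bound_pt)
        values.update({
            "shift_delta_g": shift.delta_g, "shift_delta_s": shift.delta_s,
            "shift_magnitude": shift.magnitude,
            "shift_projection": shift.projection,
            "shift_delta_sd_g": shift.delta_sd_g,
            "shift_delta_sd_s": shift.delta_sd_s,
        })
    else:
        for q in ("delta_g", "delta_s", "magnitude", "projection",
                  "delta_sd_g", "delta_sd_s"):
            values[f"shift_{q}"] = np.nan

    area, perim, circ = morphology(low.roi_mask, pixel_size,
                                   cell_id=low.cell_id)
    values["morph_area"] = area
    values["morph_perimeter"] = perim
    values["morph_circularity"] = circ

    values["donor_age"] = donor.age
    values["donor_bmi"] = donor.bmi
    values["donor_si"] = donor.stimulatory_index
    values["glucose_code"] = np.nan  # set per row at matrix assembly

    missing = set(schema.names) - set(values)
    if missing:
        raise RuntimeError(f"schema columns left unpopulated: {sorted(missing)}")
    return CellRecord(cell_id=low.cell_id, islet_id=low.islet_id,
                      donor_id=low.donor_id, values=values, label=label)


def build_feature_matrix(records: list[CellRecord],
                         schema: FeatureSchema | None = None,
                         layout: str = "per_condition",
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble records into the N x 151 feature matrix and label vector.

    ``layout="per_condition"`` emits one row per cell per glucose condition
    (the deposited-data convention: 966 cells -> 1932 rows), distinguishing
    the rows by the ``glucose_code`` column, with the cell's label
    replicated across its rows.  ``layout="per_cell"`` emits one row per
    cell with a neutral glucose code.  Rows are sorted canonically by
    (donor, islet, cell, condition) so shuffled input yields an identical
    matrix.
    """
    if schema is None:
        schema = default_schema()
    if layout not in ("per_condition", "per_cell"):
        raise ValueError(f"unknown layout {layout!r}")
    rows, labels, index = [], [], []
    conds = CONDITIONS if layout == "per_condition" else ("both",)
    for rec in records:
        base = rec.as_row(schema)
        gcol = schema.names.index("glucose_code")
        for cond in conds:
            row = list(base)
            row[gcol] = GLUCOSE_CODE[cond]
            rows.append(row)
            labels.append(rec.label)
            index.append((rec.donor_id, rec.islet_id, rec.cell_id, cond))
    order = sorted(range(len(index)), key=index.__getitem__)
    idx = pd.MultiIndex.from_tuples(
        [index[i] for i in order],
        names=["donor_id", "islet_id", "cell_id", "condition"])
    matrix = pd.DataFrame([rows[i] for i in order], columns=schema.names,
                          index=idx)
    target = pd.Series([labels[i] for i in order], index=idx, name="label")
    return matrix, target


def write_feature_matrix(matrix: pd.DataFrame, target: pd.Series,
                         csv_path: str | Path,
                         schema: FeatureSchema | None = None) -> None:
    """Write the matrix as CSV (labels in a final column) + JSON schema sidecar."""
    if schema is None:
        schema = default_schema()
    out = matrix.copy()
    out["label"] = target
    out.to_csv(csv_path)
    schema.to_json(Path(csv_path).with_suffix(".schema.json"))


def read_feature_matrix(csv_path: str | Path
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Read a feature-matrix CSV written by :func:`write_feature_matrix`."""
    df = pd.read_csv(csv_path, index_col=[0, 1, 2, 3])
    target = df.pop("label")
    return df, target
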