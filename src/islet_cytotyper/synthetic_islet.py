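"""Synthetic human-islet micrograph generator with ground-truth labels.

The generator emulates the statistical structure of label-free
autofluorescence / phasor-FLIM acquisitions of living human islets:

* a ~2:1 beta:alpha cell-count ratio,
* twofold higher lipofuscin granule content in beta cells,
* per-pixel NAD(P)H decays that are two-component mixtures of a free
  (tau ~ 0.4 ns) and a protein-bound (tau ~ 3.4 ns) monoexponential,
  ``I(t) = A [f_b exp(-t/tau_bound) + (1 - f_b) exp(-t/tau_free)]``,
* a glucose-stimulated increase of the bound fraction (a phasor shift
  toward the oxidative pole) that is stronger in beta cells,
* spatially intermingled cell placement (no core/mantle sorting), and
* donor-level covariates (age, BMI, insulin stimulatory index).

Each cell is rendered as a star-convex polygon mask whose pixels carry
synthetic 256-bin decay histograms over one 12.5 ns laser period (80 MHz
repetition rate); Poisson photon noise is applied per bin, intensity is
the per-pixel total photon count, and the g/s maps come from the
first-harmonic phasor transform of the very same decays, so every phasor
identity the analysis relies on holds by construction.

Two generation paths share identical per-cell random streams:
``generate_cohort`` composites cells into full islet canvases (one per
glucose condition), while ``generate_feature_matrix`` renders each cell in
its own small bounding box and extracts features directly — a fast path
whose per-cell pixel populations are distributed exactly as the islet
renderer's, usable as a mutual oracle for it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import draw

from . import cell_features as cf
from .cell_features import (
    CellImageBundle, CellRecord, DonorInfo, FeatureSchema,
    build_feature_matrix, default_schema, extract_cell_features,
)
from .phasor_core import decays_to_phasor, default_bin_times

__all__ = ["SynthConfig", "SyntheticCohort", "generate_cohort",
           "generate_feature_matrix", "write_cohort"]


@dataclass
class SynthConfig:
    """Generative parameters of a synthetic islet cohort.

    Defaults encode the study conditions the pipeline targets: a 2:1
    beta:alpha ratio, twofold beta lipofuscin content, free/bound NAD(P)H
    lifetimes of 0.4/3.4 ns at 80 MHz, and a glucose-induced bound-fraction
    increase that is five times larger in beta than in alpha cells.
    ``bound_fraction_*`` values are amplitude fractions of the bound
    component in the decay model above.
    """

    n_cells: int = 900
    beta_fraction: float = 2.0 / 3.0
    lipofuscin_ratio_beta_alpha: float = 2.0
    #: mean lipofuscin granule count per alpha cell (beta = ratio x this)
    lipofuscin_mean_granules_alpha: float = 2.0
    #: granule radii drawn from this inclusive px range ...
    granule_radius_range: tuple[int, int] = (2, 6)
    #: ... with these weights (small granules dominate, as in real cells)
    granule_radius_weights: tuple[float, ...] = (0.5, 0.3, 0.13, 0.05, 0.02)
    #: cap on total nominal granule area as a fraction of the cell area;
    #: keeps the background the majority signal in every cell
    granule_area_cap: float = 0.45
    #: granule brightness multiplier range relative to the cell's NAD(P)H level
    granule_brightness_range: tuple[float, float] = (3.0, 6.0)
    tau_free: float = 0.4          # ns
    tau_bound: float = 3.4         # ns
    tau_lipofuscin: float = 1.2    # ns, fixed granule phasor signature
    bound_fraction_low_glucose: dict = field(
        default_factory=lambda: {"alpha": 0.25, "beta": 0.25})
    bound_fraction_shift: dict = field(
        default_factory=lambda: {"alpha": 0.02, "beta": 0.10})
    #: cell-level biological scatter of the bound fraction (shared across
    #: conditions) and residual per-condition scatter
    bound_fraction_cell_sd: float = 0.08
    bound_fraction_condition_sd: float = 0.04
    rep_rate: float = 80.0         # MHz
    n_decay_bins: int = 256
    image_size: int = 512          # islet canvas side, px
    #: lognormal cell-mean photon budget per pixel, per type: (median, sigma);
    #: the class brightness difference is mild — most of the beta intensity
    #: excess emerges through lipofuscin granules
    intensity_params: dict = field(
        default_factory=lambda: {"alpha": (60.0, 0.45), "beta": (66.0, 0.45)})
    #: per-donor lognormal brightness multiplier sigma
    donor_intensity_sd: float = 0.35
    #: per-pixel lognormal texture sigma within a cell
    pixel_texture_sd: float = 0.20
    poisson_noise: bool = True
    gaussian_sd: float = 0.0       # additive intensity read noise
    cell_radius_mean: float = 14.0  # px
    cell_radius_sd: float = 2.0
    cell_radius_min: float = 8.0
    shape_perturbation: float = 0.2  # star-convex radial perturbation <= 20%
    n_vertices: int = 16
    n_donors: int = 4
    n_islets: int = 15
    donor_params: dict = field(default_factory=lambda: {
        "age": (46.0, 85.0), "bmi": (23.0, 27.7),
        "stimulatory_index": (1.0, 4.0)})
    #: matrix layout: one row per cell per condition (deposit convention)
    #: or one row per cell
    layout: str = "per_condition"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.beta_fraction < 1.0:
            raise ValueError("beta_fraction must lie in (0, 1)")
        if self.tau_free >= self.tau_bound:
            raise ValueError("tau_free must be smaller than tau_bound")
        for t in ("alpha", "beta"):
            fb = self.bound_fraction_low_glucose[t]
            sh = self.bound_fraction_shift[t]
            if not (0.0 <= fb <= 1.0 and 0.0 <= sh <= 1.0 and fb + sh <= 1.0):
                raise ValueError(
                    f"bound fraction + shift for {t} must stay within [0, 1]")
        if self.lipofuscin_ratio_beta_alpha < 0:
            raise ValueError("lipofuscin ratio must be non-negative")
        n_beta = round(self.n_cells * self.beta_fraction)
        n_alpha = self.n_cells - n_beta
        if min(n_alpha, n_beta) < 2:
            raise ValueError(
                "need at least 2 cells per class for downstream splits "
                f"(got {n_alpha} alpha, {n_beta} beta)")
        if self.layout not in ("per_condition", "per_cell"):
            raise ValueError(f"unknown layout {self.layout!r}")
        lo, hi = self.granule_radius_range
        if len(self.granule_radius_weights) != hi - lo + 1:
            raise ValueError("granule_radius_weights must cover the radius range")

    @property
    def period_ns(self) -> float:
        return 1e3 / self.rep_rate

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthConfig":
        payload = json.loads(Path(path).read_text())
        if "granule_radius_range" in payload:
            payload["granule_radius_range"] = tuple(
                payload["granule_radius_range"])
        if "granule_brightness_range" in payload:
            payload["granule_brightness_range"] = tuple(
                payload["granule_brightness_range"])
        if "granule_radius_weights" in payload:
            payload["granule_radius_weights"] = tuple(
                payload["granule_radius_weights"])
        for key in ("intensity_params", "donor_params"):
            if key in payload:
                payload[key] = {k: tuple(v)
                                for k, v in payload[key].items()}
        return cls(**payload)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class CellTruth:
    """Generative parameters of one synthetic cell (the ground truth)."""

    cell_id: str
    islet_id: str
    donor_id: str
    cell_type: str                 # "alpha" | "beta"
    radius: float
    vertex_radii: np.ndarray
    amplitude: float               # mean photons / px
    bound_fraction: dict           # per condition amplitude fraction
    granule_radii: np.ndarray
    granule_offsets: np.ndarray    # (n, 2) offsets from the cell center, px
    granule_brightness: np.ndarray

    def as_jsonable(self) -> dict:
        d = asdict(self)
        for k in ("vertex_radii", "granule_radii", "granule_offsets",
                  "granule_brightness"):
            d[k] = np.asarray(d[k]).tolist()
        return d


@dataclass
class SyntheticCohort:
    """A generated cohort: image bundles, labels, donors and ground truth."""

    bundles: list[CellImageBundle]     # one per cell per condition
    labels: pd.Series                  # per cell_id: "alpha" | "beta"
    donor_table: pd.DataFrame
    truth_params: list[CellTruth]
    config: SynthConfig

    def bundle_pairs(self) -> list[tuple[CellImageBundle, CellImageBundle]]:
        """(low, high) bundle pair per cell, in cell order."""
        by_cell: dict[str, dict[str, CellImageBundle]] = {}
        for b in self.bundles:
            by_cell.setdefault(b.cell_id, {})[b.condition_name] = b
        return [(by_cell[t.cell_id]["low"], by_cell[t.cell_id]["high"])
                for t in self.truth_params]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _sample_donors(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_donors):
        rows.append({
            "donor_id": f"D{i:02d}",
            "age": float(rng.uniform(*cfg.donor_params["age"])),
            "bmi": float(rng.uniform(*cfg.donor_params["bmi"])),
            "stimulatory_index": float(
                rng.uniform(*cfg.donor_params["stimulatory_index"])),
            "intensity_multiplier": float(
                rng.lognormal(0.0, cfg.donor_intensity_sd)),
        })
    return pd.DataFrame(rows).set_index("donor_id")


def _sample_truths(cfg: SynthConfig, assign_rng: np.random.Generator,
                   cell_seeds: list[np.random.SeedSequence],
                   donors: pd.DataFrame) -> list[CellTruth]:
    n_beta = round(cfg.n_cells * cfg.beta_fraction)
    types = np.array(["beta"] * n_beta + ["alpha"] * (cfg.n_cells - n_beta))
    assign_rng.shuffle(types)  # intermingled identities
    islet_of_cell = np.arange(cfg.n_cells) % cfg.n_islets
    donor_ids = list(donors.index)
    donor_of_islet = [donor_ids[i % cfg.n_donors] for i in range(cfg.n_islets)]

    lo, hi = cfg.granule_radius_range
    truths = []
    for i in range(cfg.n_cells):
        rng = np.random.default_rng(cell_seeds[i])
        ctype = str(types[i])
        donor_id = donor_of_islet[islet_of_cell[i]]
        radius = max(cfg.cell_radius_min,
                     rng.normal(cfg.cell_radius_mean, cfg.cell_radius_sd))
        vertex_radii = radius * (1.0 + rng.uniform(
            -cfg.shape_perturbation, cfg.shape_perturbation, cfg.n_vertices))
        median, sigma = cfg.intensity_params[ctype]
        amplitude = (median * rng.lognormal(0.0, sigma)
                     * float(donors.loc[donor_id, "intensity_multiplier"]))
        fb0 = cfg.bound_fraction_low_glucose[ctype]
        shift = cfg.bound_fraction_shift[ctype]
        cell_off = rng.normal(0.0, cfg.bound_fraction_cell_sd)
        cond_off = rng.normal(0.0, cfg.bound_fraction_condition_sd, 2)
        fb = {
            "low": float(np.clip(fb0 + cell_off + cond_off[0], 0.02, 0.98)),
            "high": float(np.clip(fb0 + shift + cell_off + cond_off[1],
                                  0.02, 0.98)),
        }
        mean_gran = cfg.lipofuscin_mean_granules_alpha * (
            cfg.lipofuscin_ratio_beta_alpha if ctype == "beta" else 1.0)
        n_gran = int(rng.poisson(mean_gran))
        gr_max = max(2, int(radius * 0.45))
        g_radii = np.minimum(
            rng.choice(np.arange(lo, hi + 1), size=n_gran,
                       p=np.asarray(cfg.granule_radius_weights)
                       / np.sum(cfg.granule_radius_weights)),
            gr_max)
        budget = cfg.granule_area_cap * np.pi * radius**2
        keep = np.cumsum(np.pi * g_radii.astype(float) ** 2) <= budget
        g_radii = g_radii[keep]
        # placement zone trades a little class-fair boundary clipping for
        # minimal granule overlap (overlap would deflate the high-count
        # class's total granule area disproportionately)
        offsets = _place_granules(rng, 0.85 * radius, g_radii)
        brightness = rng.uniform(*cfg.granule_brightness_range, n_gran)
        truths.append(CellTruth(
            cell_id=f"C{i:04d}", islet_id=f"I{islet_of_cell[i]:02d}",
            donor_id=donor_id, cell_type=ctype, radius=float(radius),
            vertex_radii=vertex_radii, amplitude=float(amplitude),
            bound_fraction=fb, granule_radii=g_radii,
            granule_offsets=offsets, granule_brightness=brightness))
    return truths


def _place_granules(rng: np.random.Generator, zone_radius: float,
                    g_radii: np.ndarray, max_tries: int = 200) -> np.ndarray:
    """Granule centers inside the placement zone, rejecting overlaps when
    possible (falling back to the first candidate when the cell is full)."""
    placed: list[np.ndarray] = []
    for gr in g_radii:
        margin = max(zone_radius - 0.5 * gr, 2.0)
        best, best_sep = None, -np.inf
        for _ in range(max_tries):
            ang = rng.uniform(0, 2 * np.pi)
            rad = margin * np.sqrt(rng.uniform())
            cand = np.array([rad * np.cos(ang), rad * np.sin(ang)])
            sep = min((np.linalg.norm(cand - p[:2]) - (gr + p[2])
                       for p in placed), default=np.inf)
            if sep > best_sep:
                best, best_sep = cand, sep
            if sep > 0:
                break
        placed.append(np.array([best[0], best[1], gr]))
    return (np.array([p[:2] for p in placed]) if placed
            else np.empty((0, 2)))


def _polygon_mask(truth: CellTruth, shape: tuple[int, int],
                  center: tuple[float, float]) -> np.ndarray:
    angles = np.linspace(0.0, 2 * np.pi, truth.vertex_radii.size,
                         endpoint=False)
    rr = center[0] + truth.vertex_radii * np.sin(angles)
    cc = center[1] + truth.vertex_radii * np.cos(angles)
    mask = np.zeros(shape, dtype=bool)
    pr, pc = draw.polygon(rr, cc, shape=shape)
    mask[pr, pc] = True
    return mask


def _decay_basis(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Normalized decay shapes for the free, bound and lipofuscin species."""
    t = default_bin_times(cfg.n_decay_bins, cfg.period_ns)

    def shape(tau: float) -> np.ndarray:
        s = np.exp(-t / tau)
        return s / s.sum()

    return t, shape(cfg.tau_free), shape(cfg.tau_bound), shape(cfg.tau_lipofuscin)


def _render_cell(truth: CellTruth, cfg: SynthConfig,
                 noise_rng: np.random.Generator,
                 ) -> tuple[np.ndarray, dict[str, dict[str, np.ndarray]]]:
    """Render one cell's mask and per-condition rasters in its bounding box.

    Returns ``(mask, {cond: {"intensity": ..., "g": ..., "s": ...}})``.
    The noise stream is consumed in a fixed order (texture, then per
    condition Poisson / Gaussian draws) so the islet and fast paths agree.
    """
    r_out = float(truth.vertex_radii.max())
    half = int(np.ceil(r_out)) + 2
    side = 2 * half + 1
    center = (float(half), float(half))
    mask = _polygon_mask(truth, (side, side), center)
    n_px = int(mask.sum())

    t, e_free, e_bound, e_lipo = _decay_basis(cfg)
    texture = truth.amplitude * noise_rng.lognormal(
        0.0, cfg.pixel_texture_sd, n_px)

    lipo_amp = np.zeros(n_px)
    if truth.granule_radii.size:
        rows, cols = np.nonzero(mask)
        for (dy, dx), gr, bright in zip(truth.granule_offsets,
                                        truth.granule_radii,
                                        truth.granule_brightness):
            inside = ((rows - (center[0] + dy)) ** 2
                      + (cols - (center[1] + dx)) ** 2) <= gr ** 2
            lipo_amp[inside] = np.maximum(lipo_amp[inside],
                                          bright * truth.amplitude)

    out: dict[str, dict[str, np.ndarray]] = {}
    for cond in ("low", "high"):
        fb = truth.bound_fraction[cond]
        nadph_shape = fb * e_bound + (1.0 - fb) * e_free
        nadph_shape = nadph_shape / nadph_shape.sum()
        expected = (texture[:, None] * nadph_shape[None, :]
                    + lipo_amp[:, None] * e_lipo[None, :])
        counts = (noise_rng.poisson(expected).astype(float)
                  if cfg.poisson_noise else expected)
        intensity_in = counts.sum(axis=1)
        if cfg.gaussian_sd > 0:
            intensity_in = intensity_in + noise_rng.normal(
                0.0, cfg.gaussian_sd, n_px)
        g_in, s_in = decays_to_phasor(counts, t, period=cfg.period_ns)
        intensity = np.zeros((side, side))
        g_map = np.full((side, side), np.nan)
        s_map = np.full((side, side), np.nan)
        intensity[mask] = intensity_in
        g_map[mask] = g_in
        s_map[mask] = s_in
        out[cond] = {"intensity": intensity, "g": g_map, "s": s_map}
    return mask, out


def _spawn_streams(cfg: SynthConfig):
    root = np.random.SeedSequence(cfg.seed)
    donor_ss, assign_ss, place_ss, noise_root = root.spawn(4)
    cell_param_seeds = noise_root.spawn(2 * cfg.n_cells)
    return donor_ss, assign_ss, place_ss, cell_param_seeds


def _cohort_pieces(cfg: SynthConfig):
    donor_ss, assign_ss, place_ss, cell_ss = _spawn_streams(cfg)
    donors = _sample_donors(cfg, np.random.default_rng(donor_ss))
    truths = _sample_truths(cfg, np.random.default_rng(assign_ss),
                            cell_ss[:cfg.n_cells], donors)
    noise_rngs = [np.random.default_rng(s) for s in cell_ss[cfg.n_cells:]]
    return donors, truths, noise_rngs, np.random.default_rng(place_ss)


def _grid_positions(cfg: SynthConfig, truths: list[CellTruth],
                    place_rng: np.random.Generator) -> list[tuple[int, int]]:
    """Jittered-grid, non-overlapping cell centers on the islet canvas."""
    max_r = max(float(t.vertex_radii.max()) for t in truths)
    spacing = int(np.ceil(2 * max_r)) + 3
    margin = spacing // 2 + 2
    usable = cfg.image_size - 2 * margin
    per_side = usable // spacing + 1 if usable >= 0 else 0
    if per_side * per_side < len(truths):
        raise ValueError(
            f"image_size {cfg.image_size} too small to place "
            f"{len(truths)} cells of radius <= {max_r:.1f}")
    slots = [(margin + spacing * i, margin + spacing * j)
             for i in range(per_side) for j in range(per_side)]
    chosen = place_rng.choice(len(slots), size=len(truths), replace=False)
    jitter = place_rng.integers(-1, 2, size=(len(truths), 2))
    return [(slots[k][0] + int(jitter[m, 0]), slots[k][1] + int(jitter[m, 1]))
            for m, k in enumerate(chosen)]


def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Generate a full synthetic islet cohort with per-cell image bundles.

    Cells are composited, intermingled, into one canvas per glucose
    condition; every cell's bundle shares the canvas rasters and carries
    its own full-size ROI mask.  Fixed seed implies bit-identical output.
    """
    cfg = config
    donors, truths, noise_rngs, place_rng = _cohort_pieces(cfg)
    positions = _grid_positions(cfg, truths, place_rng)

    size = cfg.image_size
    canvas = {c: {"intensity": np.zeros((size, size)),
                  "g": np.full((size, size), np.nan),
                  "s": np.full((size, size), np.nan)}
              for c in ("low", "high")}
    masks = []
    for truth, rng, (cy, cx) in zip(truths, noise_rngs, positions):
        mask_s, rasters = _render_cell(truth, cfg, rng)
        half = mask_s.shape[0] // 2
        y0, x0 = cy - half, cx - half
        sl = (slice(y0, y0 + mask_s.shape[0]), slice(x0, x0 + mask_s.shape[1]))
        full_mask = np.zeros((size, size), dtype=bool)
        full_mask[sl] = mask_s
        masks.append(full_mask)
        for cond in ("low", "high"):
            for key in ("intensity", "g", "s"):
                region = canvas[cond][key][sl]
                canvas[cond][key][sl] = np.where(
                    mask_s, rasters[cond][key], region)

    bundles = []
    for truth, full_mask in zip(truths, masks):
        for cond in ("low", "high"):
            bundles.append(CellImageBundle(
                cell_id=truth.cell_id, islet_id=truth.islet_id,
                donor_id=truth.donor_id,
                glucose_condition=cf.GLUCOSE_MM[cond],
                intensity=canvas[cond]["intensity"],
                g_map=canvas[cond]["g"], s_map=canvas[cond]["s"],
                roi_mask=full_mask))
    labels = pd.Series({t.cell_id: t.cell_type for t in truths}, name="label")
    return SyntheticCohort(bundles=bundles, labels=labels,
                           donor_table=donors, truth_params=truths,
                           config=cfg)


def _donor_info(donors: pd.DataFrame, donor_id: str) -> DonorInfo:
    row = donors.loc[donor_id]
    return DonorInfo(donor_id=donor_id, age=float(row["age"]),
                     bmi=float(row["bmi"]),
                     stimulatory_index=float(row["stimulatory_index"]))


def generate_feature_matrix(config: SynthConfig,
                            schema: FeatureSchema | None = None,
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Fast path: render cells individually and extract features directly.

    Skips islet-canvas compositing; per-cell pixel populations follow the
    same distributions as :func:`generate_cohort` (identical random
    streams), so feature means agree with the image path within Monte
    Carlo error.  Returns the N x 151 matrix and aligned label vector in
    the configured row layout.
    """
    cfg = config
    if schema is None:
        schema = default_schema()
    donors, truths, noise_rngs, _ = _cohort_pieces(cfg)
    records = []
    for truth, rng in zip(truths, noise_rngs):
        mask, rasters = _render_cell(truth, cfg, rng)
        pair = {}
        for cond in ("low", "high"):
            pair[cond] = CellImageBundle(
                cell_id=truth.cell_id, islet_id=truth.islet_id,
                donor_id=truth.donor_id,
                glucose_condition=cf.GLUCOSE_MM[cond],
                intensity=rasters[cond]["intensity"],
                g_map=rasters[cond]["g"], s_map=rasters[cond]["s"],
                roi_mask=mask)
        records.append(extract_cell_features(
            pair["low"], pair["high"], _donor_info(donors, truth.donor_id),
            schema=schema, tau_free=cfg.tau_free, tau_bound=cfg.tau_bound,
            period_ns=cfg.period_ns, label=truth.cell_type))
    return build_feature_matrix(records, schema=schema, layout=cfg.layout)


def extract_cohort_features(cohort: SyntheticCohort,
                            schema: FeatureSchema | None = None,
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """Run feature extraction over a rendered cohort's bundle pairs."""
    cfg = cohort.config
    if schema is None:
        schema = default_schema()
    records: list[CellRecord] = []
    label_of = cohort.labels.to_dict()
    for low, high in cohort.bundle_pairs():
        records.append(extract_cell_features(
            low, high, _donor_info(cohort.donor_table, low.donor_id),
            schema=schema, tau_free=cfg.tau_free, tau_bound=cfg.tau_bound,
            period_ns=cfg.period_ns, label=label_of[low.cell_id]))
    return build_feature_matrix(records, schema=schema, layout=cfg.layout)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort to disk: per-condition TIFF stacks, per-cell mask
    TIFFs, CSV donor table and feature matrix, JSON truth sidecar."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seen = set()
    for b in cohort.bundles:
        cond = b.condition_name
        if cond not in seen:
            tifffile.imwrite(out / f"islet_{cond}_intensity.tif",
                             b.intensity.astype(np.float32))
            tifffile.imwrite(out / f"islet_{cond}_g.tif",
                             b.g_map.astype(np.float32))
            tifffile.imwrite(out / f"islet_{cond}_s.tif",
                             b.s_map.astype(np.float32))
            seen.add(cond)
        tifffile.imwrite(out / f"mask_{b.cell_id}.tif",
                         b.roi_mask.astype(np.uint8))
    cohort.donor_table.to_csv(out / "donors.csv")
    matrix, target = extract_cohort_features(cohort)
    cf.write_feature_matrix(matrix, target, out / "features.csv")
    truth = {"config": asdict(cohort.config),
             "cells": [t.as_jsonable() for t in cohort.truth_params]}
    (out / "truth.json").write_text(json.dumps(truth))
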