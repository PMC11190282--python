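"""Phasor-FLIM primitives.

Per-pixel fluorescence-lifetime decays are converted to phasor coordinates
by a first-harmonic Fourier transform: a decay histogram ``c(t)`` sampled
over one laser period maps to

    g = sum_i c_i cos(n w t_i) / sum_i c_i
    s = sum_i c_i sin(n w t_i) / sum_i c_i

with ``w = 2 pi / period`` and harmonic ``n``.  Monoexponential decays of
lifetime ``tau`` land on the universal semicircle at

    g = 1 / (1 + (w tau)^2),   s = w tau / (1 + (w tau)^2)

and mixtures of decays fall on the chord between their component phasors,
weighted by photon fractions.  This module also houses the phasor-cloud
summaries (frequency-weighted barycenter and standard deviation), the
lipofuscin granule segmentation used to separate granule autofluorescence
from NAD(P)H signal, and the glucose-stimulated metabolic-shift descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DecayHistogram",
    "PhasorCloud",
    "PhasorSummary",
    "ThresholdPolicy",
    "GranuleSet",
    "ShiftDescriptor",
    "decay_to_phasor",
    "decays_to_phasor",
    "monoexponential_phasor",
    "cloud_summary",
    "lipofuscin_mask",
    "metabolic_shift",
    "semicircle_excess",
]

#: Laser repetition rate of the acquisition the pipeline models, MHz.
DEFAULT_REP_RATE_MHZ = 80.0
#: One laser period at 80 MHz, in ns.
DEFAULT_PERIOD_NS = 1e3 / DEFAULT_REP_RATE_MHZ  # 12.5 ns
#: Number of time bins used to histogram a decay over one period.
DEFAULT_N_BINS = 256


@dataclass
class DecayHistogram:
    """Photon counts per time bin over (at most) one laser period.

    Parameters
    ----------
    counts : ndarray
        Non-negative photon counts, one entry per time bin.
    bin_times : ndarray
        Bin-center times in ns, strictly increasing, spanning <= one period.
    period : float
        Laser period in ns (1 / repetition rate).
    """

    counts: np.ndarray
    bin_times: np.ndarray
    period: float = DEFAULT_PERIOD_NS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.bin_times = np.asarray(self.bin_times, dtype=float)
        if self.counts.shape != self.bin_times.shape:
            raise ValueError("counts and bin_times must have the same shape")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")
        if np.any(np.diff(self.bin_times) <= 0):
            raise ValueError("bin_times must be strictly increasing")
        if self.bin_times[-1] > self.period:
            raise ValueError("bin_times must span at most one period")

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


def default_bin_times(n_bins: int = DEFAULT_N_BINS,
                      period: float = DEFAULT_PERIOD_NS) -> np.ndarray:
    """Bin-center times for an ``n_bins``-bin histogram over one period."""
    return (np.arange(n_bins) + 0.5) * (period / n_bins)


def decay_to_phasor(decay: DecayHistogram, harmonic: int = 1) -> tuple[float, float]:
    """First- (or n-th-) harmonic phasor coordinates of a decay histogram.

    Returns ``(nan, nan)`` for an all-zero decay: the result is a *missing*
    phasor, which downstream feature extraction treats as an absent value
    (imputed to zero at preprocessing), never as an error.
    """
    if harmonic < 1:
        raise ValueError("harmonic must be >= 1")
    total = decay.total_counts
    if total <= 0:
        return (float("nan"), float("nan"))
    omega = 2.0 * np.pi / decay.period * harmonic
    g = float(np.dot(decay.counts, np.cos(omega * decay.bin_times)) / total)
    s = float(np.dot(decay.counts, np.sin(omega * decay.bin_times)) / total)
    return (g, s)


def decays_to_phasor(counts: np.ndarray, bin_times: np.ndarray,
                     period: float = DEFAULT_PERIOD_NS,
                     harmonic: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized phasor transform of many decays.

    ``counts`` has shape ``(..., n_bins)``; the transform is applied along
    the last axis.  Pixels with zero total counts yield NaN coordinates.
    """
    counts = np.asarray(counts, dtype=float)
    omega = 2.0 * np.pi / period * harmonic
    total = counts.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts @ np.cos(omega * bin_times) / total
        s = counts @ np.sin(omega * bin_times) / total
    empty = total <= 0
    if np.any(empty):
        g = np.where(empty, np.nan, g)
        s = np.where(empty, np.nan, s)
    return g, s


def monoexponential_phasor(tau: float, period: float = DEFAULT_PERIOD_NS,
                           harmonic: int = 1) -> tuple[float, float]:
    """Closed-form phasor of a monoexponential decay of lifetime ``tau`` ns."""
    wt = 2.0 * np.pi / period * harmonic * tau
    return (1.0 / (1.0 + wt * wt), wt / (1.0 + wt * wt))


def semicircle_excess(g: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Signed distance of ``(g - 1/2)^2 + s^2`` from the universal semicircle radius^2.

    Positive values flag points outside the semicircle disk (possible only
    through noise for physical decays); they are reported, never clamped.
    """
    return (np.asarray(g) - 0.5) ** 2 + np.asarray(s) ** 2 - 0.25


@dataclass
class PhasorCloud:
    """A population of (g, s) phasor points with occurrence weights."""

    g: np.ndarray
    s: np.ndarray
    frequency: np.ndarray

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float).ravel()
        self.s = np.asarray(self.s, dtype=float).ravel()
        self.frequency = np.asarray(self.frequency, dtype=float).ravel()
        if not (self.g.shape == self.s.shape == self.frequency.shape):
            raise ValueError("g, s and frequency must have equal length")
        if np.any(self.frequency < 0):
            raise ValueError("frequencies must be non-negative")

    @classmethod
    def from_maps(cls, g_map: np.ndarray, s_map: np.ndarray,
                  mask: np.ndarray) -> "PhasorCloud":
        """Collect the phasor points of the pixels selected by ``mask``.

        Pixels whose coordinates are NaN (empty decays) are dropped.
        """
        g = np.asarray(g_map)[mask]
        s = np.asarray(s_map)[mask]
        ok = np.isfinite(g) & np.isfinite(s)
        return cls(g[ok], s[ok], np.ones(int(ok.sum())))

    @property
    def n_points(self) -> int:
        return self.g.size

    def outside_semicircle(self, tol: float = 0.0) -> np.ndarray:
        """Boolean flags for points outside the universal semicircle disk."""
        return semicircle_excess(self.g, self.s) > tol


@dataclass
class PhasorSummary:
    """Frequency-weighted barycenter and dispersion of a phasor cloud."""

    barycenter_g: float
    barycenter_s: float
    sd_g: float
    sd_s: float
    cell_id: str | None = None


def cloud_summary(cloud: PhasorCloud, cell_id: str | None = None) -> PhasorSummary:
    """Weighted barycenter and population standard deviation of a cloud.

    The standard deviation divides by the total weight (population
    convention), so a single point has sd exactly 0.
    """
    w = cloud.frequency
    total = w.sum()
    if cloud.n_points == 0 or total <= 0:
        raise ValueError("cannot summarise an empty phasor cloud")
    bg = float(np.average(cloud.g, weights=w))
    bs = float(np.average(cloud.s, weights=w))
    sd_g = float(np.sqrt(np.average((cloud.g - bg) ** 2, weights=w)))
    sd_s = float(np.sqrt(np.average((cloud.s - bs) ** 2, weights=w)))
    return PhasorSummary(bg, bs, sd_g, sd_s, cell_id=cell_id)


@dataclass(frozen=True)
class ThresholdPolicy:
    """Robust intensity threshold for lipofuscin granule detection.

    A pixel belongs to a granule candidate when its intensity exceeds
    ``median + n_mads * MAD`` computed within the cell mask; connected
    components (8-connectivity) smaller than ``min_size`` pixels are dropped.
    The MAD is one-sided (median deviation of the below-median pixels only),
    so the estimate stays robust even when bright granules occupy a large
    fraction of the cell — a two-sided MAD inflates with granule load and
    would under-segment lipofuscin-rich cells.
    """

    n_mads: float = 3.0
    min_size: int = 4


@dataclass
class GranuleSet:
    """Segmented lipofuscin granules of one cell."""

    labels: np.ndarray          # 0 = background, 1..n granule ids
    granule_count: int
    granule_areas: np.ndarray   # px^2, one per granule
    total_area: float           # px^2
    cell_area: float            # px^2
    area_fraction: float
    threshold: float = field(default=float("nan"))

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


# 8-connectivity structuring element for granule labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)


def lipofuscin_mask(intensity: np.ndarray, cell_mask: np.ndarray,
                    policy: ThresholdPolicy = ThresholdPolicy()) -> GranuleSet:
    """Segment bright lipofuscin granules inside a cell.

    Granule pixels are intensity outliers above ``median + n_mads * MAD``
    of the within-cell intensity distribution, grouped by 8-connectivity;
    components below ``policy.min_size`` px are discarded.  A cell with no
    pixel above threshold yields an empty set with ``area_fraction`` 0.
    """
    intensity = np.asarray(intensity, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("cell mask is empty")
    inside = intensity[cell_mask]
    med = float(np.median(inside))
    lower = inside[inside <= med]
    mad = float(np.median(med - lower)) if lower.size else 0.0
    threshold = med + policy.n_mads * mad
    candidate = cell_mask & (intensity > threshold)
    labels, n = ndimage.label(candidate, structure=_STRUCT8)
    if n and policy.min_size > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(sizes >= policy.min_size) + 1
        relabel = np.zeros(n + 1, dtype=labels.dtype)
        relabel[keep] = np.arange(1, keep.size + 1)
        labels = relabel[labels]
        n = keep.size
    areas = (np.bincount(labels.ravel())[1:].astype(float)
             if n else np.empty(0))
    cell_area = float(cell_mask.sum())
    total = float(areas.sum())
    return GranuleSet(labels=labels, granule_count=int(n),
                      granule_areas=areas, total_area=total,
                      cell_area=cell_area,
                      area_fraction=total / cell_area,
                      threshold=threshold)


@dataclass
class ShiftDescriptor:
    """Glucose-stimulated displacement of a cell's phasor barycenter.

    ``projection`` is the signed component of the shift along the unit
    vector pointing from the free-NAD(P)H phasor toward the bound pole:
    positive values indicate a move toward oxidative (bound) metabolism.
    """

    delta_g: float
    delta_s: float
    magnitude: float
    projection: float
    delta_sd_g: float = 0.0
    delta_sd_s: float = 0.0


def metabolic_shift(summary_low: PhasorSummary, summary_high: PhasorSummary,
                    free_point: tuple[float, float],
                    bound_point: tuple[float, float]) -> ShiftDescriptor:
    """Describe the low->high glucose phasor shift of one cell.

    Both summaries must come from the same cell with lipofuscin pixels
    excluded upstream, so the barycenters reflect NAD(P)H only.
    """
    if (summary_low.cell_id is not None and summary_high.cell_id is not None
            and summary_low.cell_id != summary_high.cell_id):
        raise ValueError(
            f"summaries belong to different cells: "
            f"{summary_low.cell_id!r} vs {summary_high.cell_id!r}")
    dg = summary_high.barycenter_g - summary_low.barycenter_g
    ds = summary_high.barycenter_s - summary_low.barycenter_s
    axis = np.array([bound_point[0] - free_point[0],
                     bound_point[1] - free_point[1]], dtype=float)
    norm = float(np.linalg.norm(axis))
    if norm == 0:
        raise ValueError("free and bound reference points coincide")
    axis /= norm
    proj = float(dg * axis[0] + ds * axis[1])
    return ShiftDescriptor(
        delta_g=float(dg), delta_s=float(ds),
        magnitude=float(np.hypot(dg, ds)), projection=proj,
        delta_sd_g=float(summary_high.sd_g - summary_low.sd_g),
        delta_sd_s=float(summary_high.sd_s - summary_low.sd_s))
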