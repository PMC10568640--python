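"""Gating primitives and the density mathematics behind peak splitting.

Everything here operates on raw intensities in RFU.  Conventions, chosen once
and used everywhere:

* interval gates are half-open, ``low <= v < high`` — no event can fall in
  the crack between two adjacent bins that share a boundary;
* quantiles are linearly interpolated order statistics (the "type 7"
  estimator, numpy's default);
* density estimation happens in a log-like transformed space (intensities
  span ~4 decades) with a Gaussian kernel and Silverman's bandwidth
  ``0.9 * min(sd, IQR/1.34) * n**(-1/5)``;
* the two-population cutpoint is the density minimum strictly between the
  two tallest peaks (leftmost grid point on ties), mapped back to RFU; a
  unimodal distribution falls back to a fixed threshold (default 10 RFU,
  the background level the instrument gains are tuned to).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    ConfigurationError,
    DegenerateDistributionError,
    InsufficientDataError,
)
from .fcs_io import Sample
from .transforms import TransformSpec, apply_transform, invert_transform

__all__ = [
    "RectGate",
    "RangeBin",
    "QuadrantScheme",
    "SplitConfig",
    "SplitResult",
    "empirical_quantile",
    "apply_rect_gate",
    "apply_range_bin",
    "quadrant_counts",
    "kde_density",
    "find_density_peaks",
    "mindensity_cutpoint",
    "singlet_mask",
    "silverman_bandwidth",
]

BIN_LABELS = ("GFP-low", "GFP-medium", "GFP-high")


@dataclass(frozen=True)
class RectGate:
    """Axis-aligned rectangle on two channels; ``inf`` means unbounded."""

    channel_x: str
    channel_y: str
    x_min: float = -np.inf
    x_max: float = np.inf
    y_min: float = -np.inf
    y_max: float = np.inf

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ConfigurationError("rectangular gate requires min < max on both axes")


@dataclass(frozen=True)
class RangeBin:
    """One GFP-expression window, half-open ``[low, high)``.

    ``low`` may be ``None`` for the first bin of an analysis, meaning "use
    the fitted GFP threshold as the lower bound".
    """

    label: str
    channel: str
    low: float | None
    high: float

    def __post_init__(self) -> None:
        if self.low is not None and not self.low < self.high:
            raise ConfigurationError(f"bin {self.label!r}: low must be < high")


@dataclass(frozen=True)
class QuadrantScheme:
    """Two fixed thresholds splitting the GFP x MyHC plane into Q1–Q4."""

    x_threshold: float  # GFP
    y_threshold: float  # MyHC

    def __post_init__(self) -> None:
        if not (self.x_threshold > 0 and self.y_threshold > 0):
            raise ConfigurationError("quadrant thresholds must be > 0")


@dataclass(frozen=True)
class SplitConfig:
    """Parameters of the two-peak splitting step."""

    transform: TransformSpec = field(default_factory=TransformSpec)
    min_events: int = 50
    min_prominence_fraction: float = 0.05
    fallback_threshold: float = 10.0  # RFU; instrument background level
    grid_size: int = 512


@dataclass(frozen=True)
class SplitResult:
    """Outcome of one peak-splitting call.

    ``cutpoint`` and ``peak_positions`` are in RFU; ``method`` records whether
    a density valley was found or the fixed fallback threshold was used.
    """

    cutpoint: float
    method: str  # "density_valley" | "fallback_threshold"
    n_events: int
    peak_positions: tuple[float, ...] = ()


def empirical_quantile(values, q: float) -> float:
    """Linear-interpolation (type 7) sample quantile.

    The fraction of values at or below the result differs from ``q`` by at
    most ``1/n``, which is what calibrating a gate "below which 99% of cells
    are found" relies on.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise InsufficientDataError("cannot take a quantile of zero events")
    if not 0.0 < q < 1.0:
        raise ConfigurationError("quantile level must lie in (0, 1)")
    return float(np.quantile(v, q))  # numpy default == type 7


def apply_rect_gate(sample: Sample, gate: RectGate) -> np.ndarray:
    """Membership mask: ``x_min <= x < x_max`` and ``y_min <= y < y_max``."""
    x = sample.channel_data(gate.channel_x)
    y = sample.channel_data(gate.channel_y)
    return (x >= gate.x_min) & (x < gate.x_max) & (y >= gate.y_min) & (y < gate.y_max)


def apply_range_bin(sample: Sample, rbin: RangeBin) -> np.ndarray:
    """Membership mask for a resolved bin (``low`` must not be ``None``)."""
    if rbin.low is None:
        raise ConfigurationError(f"bin {rbin.label!r} has an unresolved lower bound")
    v = sample.channel_data(rbin.channel)
    return (v >= rbin.low) & (v < rbin.high)


def quadrant_counts(
    sample: Sample,
    scheme: QuadrantScheme,
    base_mask: np.ndarray,
    gfp_channel: str,
    myhc_channel: str,
) -> dict[str, int]:
    """Partition of ``base_mask`` into Q1..Q4 of the GFP x MyHC plane.

    Placement follows the instrument display: MyHC+ alone in Q1 (top left),
    double-positive in Q2 (top right), double-negative in Q3 (bottom left),
    GFP+ alone in Q4 (bottom right).
    """
    base_mask = np.asarray(base_mask, dtype=bool)
    if base_mask.shape != (sample.n_events,):
        raise ConfigurationError("base mask length must equal the event count")
    g = sample.channel_data(gfp_channel)
    m = sample.channel_data(myhc_channel)
    gpos = g >= scheme.x_threshold
    mpos = m >= scheme.y_threshold
    return {
        "Q1": int(np.sum(base_mask & ~gpos & mpos)),
        "Q2": int(np.sum(base_mask & gpos & mpos)),
        "Q3": int(np.sum(base_mask & ~gpos & ~mpos)),
        "Q4": int(np.sum(base_mask & gpos & ~mpos)),
    }


def silverman_bandwidth(t: np.ndarray, n_effective: int | None = None) -> float:
    """``0.9 * min(sd, IQR/1.34) * n**(-1/5)`` on already-transformed values.

    Both spread statistics are functionals of the empirical CDF (population
    sd and inverted-CDF quartiles), so the bandwidth — and hence the density
    estimate — is exactly invariant under duplication of the sample when the
    ``n`` in the rule is held fixed.  Falls back to the sd alone when the IQR
    degenerates to 0 (heavily tied data), which keeps the bandwidth positive
    whenever >= 2 distinct values exist.
    """
    n = n_effective if n_effective is not None else t.size
    sd = float(np.std(t))
    q75, q25 = np.quantile(t, [0.75, 0.25], method="inverted_cdf")
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if not spread > 0:
        raise DegenerateDistributionError("all values identical; no bandwidth")
    return 0.9 * spread * n ** (-0.2)


def kde_density(
    values,
    transform: TransformSpec | None = None,
    grid_size: int = 512,
    n_effective: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel density of transformed intensities on a regular grid.

    The grid spans ``[min - 3*bw, max + 3*bw]`` so the density decays to
    (numerically) zero at both ends and its trapezoidal integral is 1 to
    within 1%.  ``n_effective`` overrides the sample size in the bandwidth
    rule only (normalization always uses the actual count); it exists so the
    estimate can be made exactly invariant under event duplication.
    """
    transform = transform or TransformSpec()
    t = apply_transform(np.asarray(values, dtype=np.float64), transform)
    if np.unique(t).size < 2:
        raise DegenerateDistributionError("need >= 2 distinct values for a density estimate")
    if grid_size < 8:
        raise ConfigurationError("grid_size too small")
    bw = silverman_bandwidth(t, n_effective)
    grid = np.linspace(t.min() - 3.0 * bw, t.max() + 3.0 * bw, grid_size)
    # direct evaluation, chunked over events to bound memory at large n
    dens = np.zeros(grid_size)
    for chunk in np.array_split(t, max(1, t.size // 4096)):
        z = (grid[None, :] - chunk[:, None]) / bw
        dens += np.exp(-0.5 * z * z).sum(axis=0)
    dens /= t.size * bw * np.sqrt(2.0 * np.pi)
    return grid, dens


def find_density_peaks(
    grid: np.ndarray,
    density: np.ndarray,
    min_prominence_fraction: float = 0.05,
) -> np.ndarray:
    """Local maxima with prominence >= fraction * max(density).

    Returned in transformed (grid) units, sorted by peak height descending.
    A flat or empty density yields no peaks.
    """
    density = np.asarray(density, dtype=np.float64)
    if density.size == 0 or density.max() <= 0:
        return np.asarray([])
    idx, _ = find_peaks(density, prominence=min_prominence_fraction * density.max())
    order = np.argsort(density[idx])[::-1]
    return np.asarray(grid)[idx[order]]


def mindensity_cutpoint(
    values, config: SplitConfig | None = None, n_effective: int | None = None
) -> SplitResult:
    """Split a 1-D intensity distribution at the valley between its two modes.

    Transform the values, estimate the density, take the two tallest peaks,
    and put the cutpoint at the grid position of the global density minimum
    strictly between them (leftmost on ties), mapped back to RFU.  If fewer
    than two peaks are found the distribution is treated as single-population
    background and the configured fallback threshold is returned instead.
    Positive membership downstream is ``value >= cutpoint``.
    """
    config = config or SplitConfig()
    v = np.asarray(values, dtype=np.float64)
    if v.size < config.min_events:
        raise InsufficientDataError(
            f"{v.size} events < min_events={config.min_events}; bin not analyzable"
        )
    grid, dens = kde_density(v, config.transform, config.grid_size, n_effective)
    peaks_t = find_density_peaks(grid, dens, config.min_prominence_fraction)
    peaks_rfu = tuple(float(x) for x in invert_transform(peaks_t, config.transform))
    if peaks_t.size < 2:
        return SplitResult(
            cutpoint=float(config.fallback_threshold),
            method="fallback_threshold",
            n_events=int(v.size),
            peak_positions=peaks_rfu,
        )
    left_t, right_t = sorted(peaks_t[:2])
    interior = (grid > left_t) & (grid < right_t)
    idx_interior = np.nonzero(interior)[0]
    if idx_interior.size == 0:  # adjacent peaks; split midway
        cut_t = 0.5 * (left_t + right_t)
    else:
        cut_t = grid[idx_interior[np.argmin(dens[idx_interior])]]  # argmin: leftmost tie
    cutpoint = float(invert_transform(np.asarray([cut_t]), config.transform)[0])
    return SplitResult(
        cutpoint=cutpoint,
        method="density_valley",
        n_events=int(v.size),
        peak_positions=peaks_rfu,
    )


def singlet_mask(
    sample: Sample,
    tolerance: float = 0.25,
    area_channel: str = "FSC-HLin",
    height_channel: str = "FSC-H",
) -> np.ndarray:
    """Keep events whose FSC area/height ratio is within ``±tolerance``
    (relative) of the sample median ratio; doublets sit near twice the
    singlet ratio and are removed."""
    if sample.n_events == 0:
        return np.zeros(0, dtype=bool)
    area = sample.channel_data(area_channel)
    height = sample.channel_data(height_channel)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(height > 0, area / np.maximum(height, 1e-300), np.inf)
    med = float(np.median(ratio[np.isfinite(ratio)])) if np.isfinite(ratio).any() else 1.0
    return np.abs(ratio - med) <= tolerance * med
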