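"""Sample-level preprocessing: low-intensity filtering, spatial detrending
and quantile normalization.

All steps operate on log-transformed intensities.  Dark probes (scanner
artifacts near the array edges, probes that failed synthesis) are set to
missing using a cutoff walked down from the mode of the intensity
histogram; smooth spatial blotches are corrected by rescaling each spot by
the ratio of the global median to the median in a window centered on it;
and sample groups are quantile normalized against the mean of their sorted
distributions, which additionally extrapolates the compressed high-
intensity tail of saturated samples while preserving within-sample rank
order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import DomainError
from .io import PBMSample


@dataclass
class IntensityHistogram:
    """Equal-width histogram of a sample's non-missing log intensities."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts and bin_edges lengths are inconsistent")
        if len(self.counts) == 0:
            raise ValueError("empty histogram")

    @property
    def mode_bin(self) -> int:
        return int(np.argmax(self.counts))


def intensity_histogram(sample: PBMSample, n_bins: int = 100) -> IntensityHistogram:
    values = sample.intensities()
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise DomainError("sample has no non-missing intensities")
    counts, edges = np.histogram(values, bins=n_bins)
    return IntensityHistogram(edges, counts)


def log_transform(sample: PBMSample, base: float = 2.0) -> PBMSample:
    """Replace each intensity by log_base(intensity).

    Zero intensities are set missing before the transform (a dark spot
    carries no signal); negative intensities are a domain error.
    """
    if base <= 1.0:
        raise ValueError("log base must be > 1")
    out = sample.copy()
    v = out.intensities()
    if np.nanmin(v, initial=np.inf) < 0:
        raise DomainError("negative intensities present; cannot log-transform")
    v = np.where(v == 0.0, np.nan, v)
    with np.errstate(invalid="ignore"):
        v = np.log(v) / math.log(base)
    out.set_intensities(v)
    out.log_base = base
    out.provenance.append(f"log{base:g}")
    return out


def low_intensity_threshold(hist: IntensityHistogram,
                            fraction: float = 0.05) -> float:
    """Log-intensity cutoff below which probes are considered dark.

    Starting from the histogram mode, bins are scanned toward lower
    intensities; the cutoff is the upper edge of the first bin whose count
    falls below ``fraction`` times the mode count.  If no bin qualifies the
    lowest edge is returned (nothing lies below the data range).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    mode = hist.mode_bin
    limit = fraction * hist.counts[mode]
    for k in range(mode - 1, -1, -1):
        if hist.counts[k] < limit:
            return float(hist.bin_edges[k + 1])
    return float(hist.bin_edges[0])


def filter_low_intensity(sample: PBMSample, fraction: float = 0.05,
                         n_bins: int = 100) -> PBMSample:
    """Set intensities below the histogram-derived cutoff to missing.

    Probes are retained as grid positions (their intensity becomes NA), so
    spatial detrending still sees the full grid.
    """
    hist = intensity_histogram(sample, n_bins=n_bins)
    cutoff = low_intensity_threshold(hist, fraction=fraction)
    out = sample.copy()
    v = out.intensities()
    with np.errstate(invalid="ignore"):
        v = np.where(v < cutoff, np.nan, v)
    out.set_intensities(v)
    out.provenance.append(f"filter_low_intensity(fraction={fraction:g})")
    return out


def spatial_detrend(sample: PBMSample, window: int = 7,
                    mode: str = "multiplicative") -> PBMSample:
    """Rescale each spot by global median / local windowed median.

    The window (default 7x7) is truncated at array borders and local
    medians ignore missing cells; a spot whose window is entirely missing,
    or whose local median is zero in multiplicative mode, is left
    unchanged.  ``mode='multiplicative'`` multiplies the log value by the
    median ratio (the literal reading of the procedure on log data);
    ``mode='additive'`` adds the median difference, i.e. a multiplicative
    correction of the raw intensities.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if mode not in ("multiplicative", "additive"):
        raise ValueError(f"unknown detrend mode {mode!r}")
    grid = sample.grid()
    if np.isnan(grid).all():
        raise DomainError("all intensities missing; nothing to detrend")
    global_median = float(np.nanmedian(grid))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        local = ndimage.generic_filter(grid, np.nanmedian, size=window,
                                       mode="constant", cval=np.nan)
    out = sample.copy()
    new = grid.copy()
    ok = ~np.isnan(grid) & ~np.isnan(local)
    if mode == "multiplicative":
        ok &= local != 0.0
        new[ok] = grid[ok] * global_median / local[ok]
    else:
        new[ok] = grid[ok] + global_median - local[ok]
    out.set_from_grid(new)
    out.provenance.append(f"spatial_detrend(window={window},mode={mode})")
    return out


def _averaged_ties(values: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Assign to each value its rank-mapped target, averaging over ties."""
    uniq, inv = np.unique(values, return_inverse=True)
    sums = np.bincount(inv, weights=targets, minlength=len(uniq))
    cnts = np.bincount(inv, minlength=len(uniq))
    return (sums / cnts)[inv]


def quantile_normalize(samples: list[PBMSample],
                       reference: np.ndarray | None = None) -> list[PBMSample]:
    """Quantile normalize a group of samples to a common distribution.

    The i-th ranked non-missing value of each sample is replaced by the
    i-th quantile of the reference distribution — by default the mean of
    the samples' sorted value vectors, interpolated onto a common quantile
    grid so samples with different missing-value masks can be combined.
    Ties receive the mean of the reference quantiles they span, so rank
    order is preserved exactly.
    """
    if not samples:
        raise ValueError("empty sample list")
    value_arrays = []
    masks = []
    for s in samples:
        v = s.intensities()
        ok = ~np.isnan(v)
        if ok.sum() < 2:
            raise DomainError(
                f"sample {s.name or '?'} has fewer than 2 non-missing values")
        value_arrays.append(v)
        masks.append(ok)

    m = max(int(ok.sum()) for ok in masks)
    grid = np.linspace(0.0, 1.0, m)
    if reference is not None:
        ref_sorted = np.sort(np.asarray(reference, dtype=float))
        ref_sorted = ref_sorted[~np.isnan(ref_sorted)]
        ref = np.interp(grid, np.linspace(0.0, 1.0, len(ref_sorted)), ref_sorted)
    else:
        interped = []
        for v, ok in zip(value_arrays, masks):
            sv = np.sort(v[ok])
            interped.append(np.interp(grid, np.linspace(0.0, 1.0, len(sv)), sv))
        ref = np.mean(interped, axis=0)

    out = []
    for s, v, ok in zip(samples, value_arrays, masks):
        vals = v[ok]
        n = len(vals)
        targets_sorted = np.interp(np.linspace(0.0, 1.0, n), grid, ref)
        order = np.argsort(vals, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = targets_sorted
        assigned = _averaged_ties(vals, assigned)
        new = v.copy()
        new[ok] = assigned
        ns = s.copy()
        ns.set_intensities(new)
        ns.provenance.append("quantile_normalize")
        out.append(ns)
    return out
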