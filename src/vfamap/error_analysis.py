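"""Statistical summaries of voxelwise errors and test-retest variability.

Three summaries commonly used to validate relaxometry estimators:

* transmit-field-binned error histograms — percent errors binned by ft,
  summarized per bin by the median and a 95% interval (2.5th-97.5th
  percentiles of the within-bin voxel distribution, i.e. sample spread,
  not a standard error of the median);
* 2-D density histograms of error against ft;
* the within-participant coefficient of variation (WCV) of test-retest
  summary measures, the standard paired within-subject CV
  ``WCV(%) = 100 sqrt( (1/N) sum_i d_i^2 / (2 m_i^2) )`` with ``d_i`` the
  test-retest difference and ``m_i`` the pair mean.

Percentiles use linear interpolation between order statistics
throughout (numpy's default), fixed for reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "BinnedErrors",
    "Density2D",
    "WcvResult",
    "bin_errors_by_ft",
    "compute_ft_inclusion_range",
    "density2d",
    "wcv",
]


@dataclass
class BinnedErrors:
    """Per-bin order statistics of percent errors, binned by ft.

    Bins are left-closed right-open with the final bin closed, so the
    range endpoints are both included.
    """

    bin_edges: np.ndarray
    n: np.ndarray
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_excluded: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ft_bin_low": self.bin_edges[:-1],
                "ft_bin_high": self.bin_edges[1:],
                "n": self.n,
                "median": self.median,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def bin_errors_by_ft(
    errors,
    ft,
    ft_range: Tuple[float, float],
    bin_width: float = 0.05,
) -> BinnedErrors:
    """Bin paired (error, ft) samples by ft and summarize each bin.

    Samples with ft outside ``[lo, hi]`` (or with NaN in either member)
    are excluded and counted in ``n_excluded``.  Empty bins report NaN
    statistics with n=0.
    """
    errors = np.asarray(errors, dtype=float).ravel()
    ft = np.asarray(ft, dtype=float).ravel()
    if errors.size != ft.size:
        raise ValueError("errors and ft must be paired (equal length)")
    lo, hi = float(ft_range[0]), float(ft_range[1])
    if not lo < hi:
        raise ValueError("ft_range must satisfy lo < hi")
    if not bin_width > 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(round((hi - lo) / bin_width))
    if n_bins < 1 or not math.isclose(lo + n_bins * bin_width, hi, rel_tol=1e-9):
        raise ValueError("ft_range must be an integer number of bin widths")
    edges = lo + bin_width * np.arange(n_bins + 1)

    finite = np.isfinite(errors) & np.isfinite(ft)
    in_range = finite & (ft >= lo) & (ft <= hi)
    n_excluded = int(errors.size - in_range.sum())
    if not in_range.any():
        raise ValueError("no samples fall inside the ft range")
    e = errors[in_range]
    f = ft[in_range]
    # right-open bins, except the final bin which also takes ft == hi
    idx = np.minimum(((f - lo) / bin_width).astype(int), n_bins - 1)

    n = np.bincount(idx, minlength=n_bins)
    median = np.full(n_bins, np.nan)
    ci_low = np.full(n_bins, np.nan)
    ci_high = np.full(n_bins, np.nan)
    for b in range(n_bins):
        vals = e[idx == b]
        if vals.size:
            ci_low[b], median[b], ci_high[b] = np.percentile(vals, [2.5, 50.0, 97.5])
    return BinnedErrors(
        bin_edges=edges,
        n=n,
        median=median,
        ci_low=ci_low,
        ci_high=ci_high,
        n_excluded=n_excluded,
    )


def compute_ft_inclusion_range(
    ft_samples, coverage: float = 0.99, step: float = 0.05
) -> Tuple[float, float]:
    """Central-coverage ft interval, outward-rounded to a step.

    Takes the ``0.5 - coverage/2`` and ``0.5 + coverage/2`` quantiles of
    the samples and rounds the lower bound down / upper bound up to the
    nearest multiple of ``step`` — the rule used to pick plotting/binning
    ranges that avoid sparsely populated tails.
    """
    ft = np.asarray(ft_samples, dtype=float).ravel()
    ft = ft[np.isfinite(ft)]
    if ft.size == 0:
        raise ValueError("no finite ft samples")
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    if not step > 0:
        raise ValueError("step must be > 0")
    q_lo = np.quantile(ft, 0.5 - coverage / 2.0)
    q_hi = np.quantile(ft, 0.5 + coverage / 2.0)
    # tolerance absorbs float division artefacts (e.g. 1.0/0.05 = 20.000...4)
    lo = math.floor(q_lo / step + 1e-9) * step
    hi = math.ceil(q_hi / step - 1e-9) * step
    return (lo, hi)


@dataclass
class Density2D:
    """2-D histogram of (ft, error) samples."""

    ft_edges: np.ndarray
    err_edges: np.ndarray
    counts: np.ndarray  # shape (n_ft_bins, n_err_bins)
    n_dropped: int

    def to_dataframe(self) -> pd.DataFrame:
        ft_lo, err_lo = np.meshgrid(
            self.ft_edges[:-1], self.err_edges[:-1], indexing="ij"
        )
        ft_hi, err_hi = np.meshgrid(
            self.ft_edges[1:], self.err_edges[1:], indexing="ij"
        )
        return pd.DataFrame(
            {
                "ft_bin_low": ft_lo.ravel(),
                "ft_bin_high": ft_hi.ravel(),
                "err_bin_low": err_lo.ravel(),
                "err_bin_high": err_hi.ravel(),
                "count": self.counts.ravel().astype(int),
            }
        )


def density2d(errors, ft, ft_edges, err_edges) -> Density2D:
    """Joint histogram of errors against ft on the given edge grids.

    Out-of-range and non-finite samples are dropped and counted.
    """
    errors = np.asarray(errors, dtype=float).ravel()
    ft = np.asarray(ft, dtype=float).ravel()
    if errors.size != ft.size:
        raise ValueError("errors and ft must be paired")
    ft_edges = np.asarray(ft_edges, dtype=float)
    err_edges = np.asarray(err_edges, dtype=float)
    for name, e in (("ft_edges", ft_edges), ("err_edges", err_edges)):
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError(f"{name} must be strictly increasing with >= 2 entries")
    finite = np.isfinite(errors) & np.isfinite(ft)
    counts, _, _ = np.histogram2d(ft[finite], errors[finite], bins=[ft_edges, err_edges])
    n_dropped = int(errors.size - counts.sum())
    return Density2D(
        ft_edges=ft_edges, err_edges=err_edges, counts=counts, n_dropped=n_dropped
    )


@dataclass
class WcvResult:
    """Within-participant coefficient of variation over test-retest pairs."""

    wcv_pct: float
    n_subjects: int
    pair_means: np.ndarray
    pair_diffs: np.ndarray


def wcv(test, retest) -> WcvResult:
    """Paired within-subject CV of test-retest measurements, in percent.

    ``WCV(%) = 100 sqrt( (1/N) sum_i (x_i1 - x_i2)^2 / (2 m_i^2) )``
    where ``m_i`` is the pair mean.  Scale-invariant: rescaling all
    measurements by a common factor leaves the result unchanged.
    """
    t = np.asarray(test, dtype=float).ravel()
    r = np.asarray(retest, dtype=float).ravel()
    if t.size != r.size or t.size == 0:
        raise ValueError("test and retest must be paired with N >= 1")
    if np.any(t <= 0) or np.any(r <= 0) or not (
        np.all(np.isfinite(t)) and np.all(np.isfinite(r))
    ):
        raise ValueError("WCV requires strictly positive finite measurements")
    m = 0.5 * (t + r)
    d = t - r
    value = 100.0 * np.sqrt(np.mean(d**2 / (2.0 * m**2)))
    return WcvResult(
        wcv_pct=float(value), n_subjects=t.size, pair_means=m, pair_diffs=d
    )
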