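"""High-peak-density (HPD) artifact detection.

Direct-infusion FT-MS peaklists from Orbitrap-class instruments can contain
"fuzzy sites": 0.5-3 m/z wide stretches packed with far more centroids than
their surroundings, with intermediate intensities and poor scan-to-scan peak
correspondence.  They are detected here purely from local peak density, in
three steps:

1. **Density profile** — a ``window_width`` (default 1 m/z) window slides
   across the spectrum in ``step`` (default 0.1 m/z) increments; the peak
   count in each window is assigned to the window's center m/z.

2. **Density statistic** — each test window is compared against ``n_pairs``
   pairs of non-overlapping reference windows (default two pairs, each
   reference window 3 m/z wide) tiled symmetrically outward from the test
   window.  For pair *k* with pooled reference density mean ``mu_k`` and
   population standard deviation ``sigma_k`` (floored at ``sigma_floor``),

       S_k = ((d - mu_k) / max(sigma_k, sigma_floor))**2   if d > mu_k else 0

   and ``S = max_k S_k``.  Taking the maximum keeps sensitivity when one
   reference pair itself overlaps an artifact.  Near the spectrum edges only
   the reference windows that fit inside the acquisition range are used; a
   center with no usable reference window gets S = 0.

3. **Region calling** — maximal runs of consecutive grid centers with
   ``S > threshold`` (default 100, i.e. 10 reference standard deviations)
   whose center span is at least ``min_region_width`` (default 0.3 m/z)
   are reported as HPD regions, extended by half a grid step on each side.

The statistic flattens instrument- and m/z-dependent baseline density, so a
single unitless threshold works across instruments and acquisition ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .peaklist_io import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionParams",
    "DensityProfile",
    "StatProfile",
    "HPDRegion",
    "DetectionResult",
    "WindowLayout",
    "count_peaks_in_window",
    "density_profile",
    "reference_layout",
    "density_statistic",
    "call_hpd_regions",
    "detect",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the three-step detector (defaults are the
    published operating point)."""

    window_width: float = 1.0
    step: float = 0.1
    n_pairs: int = 2
    ref_width: float = 3.0
    threshold: float = 100.0
    min_region_width: float = 0.3
    sigma_floor: float = 1.0
    one_sided: bool = True

    def __post_init__(self) -> None:
        if not self.window_width > 0:
            raise ValueError("window_width must be > 0")
        if not 0 < self.step <= self.window_width:
            raise ValueError("step must satisfy 0 < step <= window_width")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.ref_width < self.window_width:
            raise ValueError("ref_width must be >= window_width")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        if self.min_region_width < self.step:
            raise ValueError("min_region_width must be >= step")
        if not self.sigma_floor > 0:
            raise ValueError("sigma_floor must be > 0")


@dataclass(frozen=True)
class DensityProfile:
    """Peak counts per sliding window, indexed by window-center m/z."""

    centers: np.ndarray
    densities: np.ndarray
    params: DetectionParams


@dataclass(frozen=True)
class StatProfile:
    """Density statistic S per grid center, plus per-pair reference stats.

    ``pair_mu``/``pair_sigma`` have shape ``(n_pairs, n_centers)`` and are
    NaN where a pair has no usable reference window.
    """

    centers: np.ndarray
    S: np.ndarray
    pair_mu: np.ndarray
    pair_sigma: np.ndarray
    params: DetectionParams


@dataclass(frozen=True)
class HPDRegion:
    """A called artifact interval ``[lo, hi)`` with its peak statistic."""

    lo: float
    hi: float
    max_S: float
    n_peaks: int


@dataclass(frozen=True)
class WindowLayout:
    """Test window and per-pair (left, right) reference intervals, all
    half-open ``[lo, hi)`` and tiled outward without gaps."""

    test: tuple[float, float]
    pairs: tuple[tuple[tuple[float, float], tuple[float, float]], ...]


@dataclass(frozen=True)
class DetectionResult:
    profile: DensityProfile
    stat: StatProfile
    regions: tuple[HPDRegion, ...]


def count_peaks_in_window(spectrum: Spectrum, lo: float, hi: float) -> int:
    """Number of peaks with ``lo <= m/z < hi`` via two binary searches."""
    if lo >= hi:
        raise ValueError(f"window is empty or inverted: [{lo}, {hi})")
    mz = spectrum.mz
    return int(np.searchsorted(mz, hi, side="left") - np.searchsorted(mz, lo, side="left"))


def _grid(spectrum: Spectrum, params: DetectionParams) -> np.ndarray:
    lo, hi = spectrum.mz_range if spectrum.mz_range else (0.0, 0.0)
    span = hi - lo
    w = params.window_width
    if span < w:
        logger.warning(
            "mz_range span %.3f narrower than window %.3f; empty profile", span, w
        )
        return np.empty(0)
    n = int(np.floor((span - w) / params.step + 1e-9)) + 1
    return lo + w / 2.0 + params.step * np.arange(n)


def density_profile(spectrum: Spectrum, params: DetectionParams | None = None) -> DensityProfile:
    """Step 1: sliding-window peak counts on the detection grid.

    The grid is anchored at ``mz_range.lo + window_width/2`` and stepped by
    ``step``; each count is over the half-open window centered on the grid
    point.
    """
    params = params or DetectionParams()
    if spectrum.mz_range is None:
        raise ValueError("spectrum has no mz_range and no peaks to infer one")
    centers = _grid(spectrum, params)
    half = params.window_width / 2.0
    left = np.searchsorted(spectrum.mz, centers - half, side="left")
    right = np.searchsorted(spectrum.mz, centers + half, side="left")
    return DensityProfile(centers=centers, densities=(right - left).astype(np.int64), params=params)


def reference_layout(center: float, params: DetectionParams | None = None) -> WindowLayout:
    """The test window and its ``n_pairs`` symmetric reference-window pairs.

    Pair *k* occupies ``[center - w/2 - k*ref, center - w/2 - (k-1)*ref)`` on
    the left and its mirror image on the right, so all windows tile outward
    from the test window with no gaps and no overlap.
    """
    params = params or DetectionParams()
    half = params.window_width / 2.0
    ref = params.ref_width
    pairs = []
    for k in range(1, params.n_pairs + 1):
        left = (center - half - k * ref, center - half - (k - 1) * ref)
        right = (center + half + (k - 1) * ref, center + half + k * ref)
        pairs.append((left, right))
    return WindowLayout(test=(center - half, center + half), pairs=tuple(pairs))


def density_statistic(
    spectrum: Spectrum,
    params: DetectionParams | None = None,
    profile: DensityProfile | None = None,
) -> StatProfile:
    """Step 2: the chi-squared-inspired density statistic S at every center.

    The reference mean and population sigma of pair *k* are pooled over the
    density-profile values whose full test windows lie inside the pair's left
    and right reference windows; a side that extends beyond the acquisition
    range is dropped, and a pair with neither side usable is skipped.
    """
    params = params or DetectionParams()
    prof = profile if profile is not None else density_profile(spectrum, params)
    centers = prof.centers
    n = centers.size
    d = prof.densities.astype(np.float64)
    pair_mu = np.full((params.n_pairs, n), np.nan)
    pair_sigma = np.full((params.n_pairs, n), np.nan)
    if n == 0:
        return StatProfile(centers, np.empty(0), pair_mu, pair_sigma, params)

    cs = np.concatenate([[0.0], np.cumsum(d)])
    cs2 = np.concatenate([[0.0], np.cumsum(d * d)])
    idx = np.arange(n)
    best = np.zeros(n)
    any_valid = np.zeros(n, dtype=bool)
    step, w, ref = params.step, params.window_width, params.ref_width

    for k in range(1, params.n_pairs + 1):
        # profile centers at grid offset j from the test center fit inside
        # pair k's left window iff  -k*ref <= j*step <= -((k-1)*ref + w)
        b = int(np.floor(k * ref / step + 1e-9))
        a = int(np.ceil(((k - 1) * ref + w) / step - 1e-9))
        if b < a:
            continue
        m = b - a + 1

        def _side(starts: np.ndarray, stops: np.ndarray, valid: np.ndarray):
            s0 = np.clip(starts, 0, n)
            s1 = np.clip(stops + 1, 0, n)
            tot = cs[s1] - cs[s0]
            tot2 = cs2[s1] - cs2[s0]
            return np.where(valid, tot, 0.0), np.where(valid, tot2, 0.0)

        lvalid = idx - b >= 0
        rvalid = idx + b <= n - 1
        lsum, lsum2 = _side(idx - b, idx - a, lvalid)
        rsum, rsum2 = _side(idx + a, idx + b, rvalid)
        cnt = m * (lvalid.astype(np.int64) + rvalid.astype(np.int64))
        valid = cnt > 0
        cntf = np.where(valid, cnt, 1).astype(np.float64)
        mu = (lsum + rsum) / cntf
        var = np.clip((lsum2 + rsum2) / cntf - mu * mu, 0.0, None)
        sigma = np.sqrt(var)
        pair_mu[k - 1] = np.where(valid, mu, np.nan)
        pair_sigma[k - 1] = np.where(valid, sigma, np.nan)
        sp = np.maximum(sigma, params.sigma_floor)
        delta = d - mu
        sk = (delta / sp) ** 2
        if params.one_sided:
            sk = np.where(delta > 0, sk, 0.0)
        best = np.where(valid & (sk > best), sk, best)
        any_valid |= valid

    S = np.where(any_valid, best, 0.0)
    n_degenerate = int(n - any_valid.sum())
    if n_degenerate:
        logger.info("%d grid centers had no usable reference window (S=0)", n_degenerate)
    return StatProfile(centers=centers, S=S, pair_mu=pair_mu, pair_sigma=pair_sigma, params=params)


def call_hpd_regions(
    stat: StatProfile, spectrum: Spectrum, params: DetectionParams | None = None
) -> tuple[HPDRegion, ...]:
    """Step 3: maximal runs with S strictly above threshold become regions.

    A run of flagged centers spanning at least ``min_region_width`` is
    reported as ``[first - step/2, last + step/2)`` with the run's maximum S
    and the source spectrum's peak count inside the interval.
    """
    params = params or stat.params
    S = stat.S
    if S.size == 0:
        return ()
    flagged = S > params.threshold
    regions: list[HPDRegion] = []
    half_step = params.step / 2.0
    i = 0
    n = S.size
    while i < n:
        if not flagged[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and flagged[j + 1]:
            j += 1
        span = stat.centers[j] - stat.centers[i]
        if span + 1e-9 >= params.min_region_width:
            lo = float(stat.centers[i] - half_step)
            hi = float(stat.centers[j] + half_step)
            regions.append(
                HPDRegion(
                    lo=lo,
                    hi=hi,
                    max_S=float(S[i : j + 1].max()),
                    n_peaks=count_peaks_in_window(spectrum, lo, hi),
                )
            )
        i = j + 1
    return tuple(regions)


def detect(spectrum: Spectrum, params: DetectionParams | None = None) -> DetectionResult:
    """Run the full three-step detection on one spectrum."""
    params = params or DetectionParams()
    if spectrum.n_peaks == 0 and spectrum.mz_range is None:
        empty = np.empty(0)
        prof = DensityProfile(empty, empty.astype(np.int64), params)
        stat = StatProfile(empty, empty, np.empty((params.n_pairs, 0)), np.empty((params.n_pairs, 0)), params)
        return DetectionResult(prof, stat, ())
    prof = density_profile(spectrum, params)
    stat = density_statistic(spectrum, params, profile=prof)
    regions = call_hpd_regions(stat, spectrum, params)
    logger.info(
        "detect(%s): %d peaks, %d grid centers, %d regions",
        spectrum.sample_id or "<unnamed>",
        spectrum.n_peaks,
        prof.centers.size,
        len(regions),
    )
    return DetectionResult(profile=prof, stat=stat, regions=regions)
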