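"""Seeded synthetic DI-FT-MS peaklist generator with ground-truth artifacts.

The generator emulates the phenomenology that makes HPD artifacts detectable
and harmful, not instrument physics:

- a noise baseline whose peak density decays exponentially with m/z (peak
  density in FT-MS falls with m/z as signal-to-noise and digitization drop);
- sparse high-intensity signal peaks that reappear scan-to-scan within a
  small m/z jitter (well below the detector's 0.1 m/z step);
- **fuzzy sites**: 0.5-3 m/z wide intervals packed with extra peaks at
  ``multiplier`` times the local baseline density, intensities drawn from a
  truncated normal between the noise level and half the signal level.  At
  the scan level only a random sub-interval of fractional width
  ``scan_coverage`` is populated, re-drawn every scan, so scan-to-scan peak
  correspondence inside a site is poor while the aggregate envelope fills in
  as scans accumulate;
- **ringing**: evenly spaced side peaks flanking one intense peak with
  geometrically decaying intensity (scan-level; the aggregate-level variant
  is labelled partial ringing);
- two-class cohorts in which fuzzy-site centers shift by a per-class offset
  (a few m/z up to >12 m/z), the mechanism by which artifacts become class
  predictive.

Every injected artifact is recorded in a :class:`SimTruth`, the oracle used
by the test-suite and the acceptance checks.  All output is a deterministic
function of the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consistency import FeatureTable
from .peaklist_io import ScanSet, Spectrum, aggregate_scans

__all__ = [
    "FuzzySite",
    "RingingSite",
    "SimConfig",
    "TruthInterval",
    "SampleTruth",
    "SimTruth",
    "local_rate",
    "simulate_baseline",
    "inject_fuzzy_site",
    "inject_ringing",
    "simulate_sample",
    "simulate_cohort",
    "default_cohort_config",
    "subinterval_overlap_probability",
]


@dataclass(frozen=True)
class FuzzySite:
    """A fuzzy-site artifact: ``multiplier`` x local baseline density of
    extra peaks over ``[center - width/2, center + width/2)``."""

    center: float
    width: float
    multiplier: float = 10.0
    intensity_scale: float = 1.0

    @property
    def lo(self) -> float:
        return self.center - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.center + self.width / 2.0


@dataclass(frozen=True)
class RingingSite:
    """Evenly spaced side peaks around one intense parent peak."""

    center: float
    spacing: float = 0.01
    count: int = 4
    decay: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic acquisition.

    ``baseline_rate`` is the expected noise-peak density (peaks per m/z) at
    ``mz_range[0]``; it decays as ``exp(-(mz - lo)/baseline_decay)``.  Noise
    intensities are log-normal around ``noise_median``; signal peaks are
    placed at their stated m/z (tiny jitter) with their stated intensity.
    With ``n_scans > 1`` each scan is an independent draw and fuzzy sites
    populate only a ``scan_coverage`` fraction of their width per scan.
    """

    mz_range: tuple[float, float] = (150.0, 1600.0)
    baseline_rate: float = 6.0
    baseline_decay: float = 2000.0
    noise_median: float = 1.0e3
    noise_sigma: float = 0.5
    signal_intensity: float = 1.0e6
    signal_peaks: tuple[tuple[float, float], ...] = ()
    fuzzy_sites: tuple[FuzzySite, ...] = ()
    ringing_sites: tuple[RingingSite, ...] = ()
    n_scans: int = 1
    scan_coverage: float = 0.2
    seed: int = 0
    enforce_site_widths: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range must be increasing")
        if self.baseline_rate < 0 or self.baseline_decay <= 0:
            raise ValueError("baseline_rate >= 0 and baseline_decay > 0 required")
        if not 0 < self.scan_coverage <= 1:
            raise ValueError("scan_coverage must be in (0, 1]")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        object.__setattr__(self, "fuzzy_sites", tuple(self.fuzzy_sites))
        object.__setattr__(self, "ringing_sites", tuple(self.ringing_sites))
        object.__setattr__(self, "signal_peaks", tuple(tuple(p) for p in self.signal_peaks))
        for s in self.fuzzy_sites:
            if s.multiplier <= 1:
                raise ValueError("fuzzy-site density multiplier must be > 1")
            if self.enforce_site_widths and not 0.5 <= s.width <= 3.0:
                raise ValueError(
                    f"fuzzy-site width {s.width} outside the observed 0.5-3 m/z "
                    "range (set enforce_site_widths=False to override)"
                )
            if s.lo < lo or s.hi > hi:
                raise ValueError(f"fuzzy site {s} extends beyond mz_range")


@dataclass(frozen=True)
class TruthInterval:
    lo: float
    hi: float
    kind: str  # "fuzzy" | "ringing" | "partial_ringing"


@dataclass
class SampleTruth:
    sample_id: str
    intervals: list[TruthInterval] = field(default_factory=list)
    # site index -> per-scan populated sub-intervals (scan-level sims only)
    scan_subintervals: dict[int, list[tuple[float, float]]] = field(default_factory=dict)


@dataclass
class SimTruth:
    samples: dict[str, SampleTruth] = field(default_factory=dict)
    site_intervals_by_class: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def to_json(self) -> str:
        doc = {
            "samples": {
                sid: {
                    "intervals": [[t.lo, t.hi, t.kind] for t in st.intervals],
                    "scan_subintervals": {
                        str(k): v for k, v in st.scan_subintervals.items()
                    },
                }
                for sid, st in self.samples.items()
            },
            "site_intervals_by_class": self.site_intervals_by_class,
        }
        return json.dumps(doc, indent=1)


def local_rate(config: SimConfig, mz) -> np.ndarray:
    """Expected noise-peak density (peaks per m/z) at ``mz``."""
    lo = config.mz_range[0]
    return config.baseline_rate * np.exp(-(np.asarray(mz, dtype=float) - lo) / config.baseline_decay)


def _draw_baseline_positions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous Poisson positions via inverse-CDF of the decaying rate."""
    lo, hi = config.mz_range
    L = config.baseline_decay
    span = hi - lo
    mass = 1.0 - np.exp(-span / L)
    lam_total = config.baseline_rate * L * mass
    n = rng.poisson(lam_total)
    u = rng.random(n)
    return lo - L * np.log1p(-u * mass)


def _noise_intensities(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    return config.noise_median * np.exp(rng.normal(0.0, config.noise_sigma, size=n))


def simulate_baseline(config: SimConfig, rng: np.random.Generator | None = None) -> Spectrum:
    """Noise baseline plus signal peaks, no artifacts.

    Signal peaks get a per-draw m/z jitter of 5e-4 m/z (well below both the
    detector step and any peak-matching tolerance used downstream).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    mz = _draw_baseline_positions(config, rng)
    inten = _noise_intensities(config, mz.size, rng)
    if config.signal_peaks:
        smz = np.array([p[0] for p in config.signal_peaks], dtype=float)
        sint = np.array([p[1] for p in config.signal_peaks], dtype=float)
        smz = smz + rng.normal(0.0, 5e-4, size=smz.size)
        mz = np.concatenate([mz, smz])
        inten = np.concatenate([inten, sint])
    return Spectrum(mz=mz, intensity=inten, mz_range=config.mz_range)


def _fuzzy_intensities(
    config: SimConfig, site: FuzzySite, n: int, rng: np.random.Generator
) -> np.ndarray:
    # Gaussian-like envelope between the noise level and half the signal level
    lo = config.noise_median
    hi = 0.5 * config.signal_intensity * site.intensity_scale
    mean = 0.5 * (lo + hi)
    sd = (hi - lo) / 4.0
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def inject_fuzzy_site(
    config: SimConfig,
    site: FuzzySite,
    rng: np.random.Generator,
    scan_fraction: float | None = None,
) -> tuple[np.ndarray, np.ndarray, TruthInterval, tuple[float, float]]:
    """Draw the extra peaks of one fuzzy site.

    Aggregate-level injection (``scan_fraction=None``) places a Poisson
    number of peaks with expectation ``multiplier * local_rate * width``
    uniformly over the site.  Scan-level injection populates only a randomly
    placed sub-interval of fractional width ``scan_fraction``, with the same
    local density, so the expected per-scan count is scaled by the coverage.

    Returns ``(mz, intensity, truth_interval, populated_interval)``.
    """
    lo, hi = config.mz_range
    if site.lo < lo or site.hi > hi:
        raise ValueError(f"fuzzy site {site} outside mz_range {config.mz_range}")
    rate = float(local_rate(config, site.center))
    if scan_fraction is None:
        sub_lo, sub_hi = site.lo, site.hi
    else:
        f = float(scan_fraction)
        if not 0 < f <= 1:
            raise ValueError("scan_fraction must be in (0, 1]")
        sub_w = f * site.width
        start = rng.uniform(0.0, site.width - sub_w) if f < 1 else 0.0
        sub_lo = site.lo + start
        sub_hi = sub_lo + sub_w
    n = rng.poisson(site.multiplier * rate * (sub_hi - sub_lo))
    mz = rng.uniform(sub_lo, sub_hi, size=n)
    inten = _fuzzy_intensities(config, site, n, rng)
    return mz, inten, TruthInterval(site.lo, site.hi, "fuzzy"), (sub_lo, sub_hi)


def inject_ringing(
    spectrum: Spectrum,
    center: float,
    spacing: float,
    count: int,
    decay: float,
    rng: np.random.Generator | None = None,
    kind: str = "ringing",
    match_tol: float = 0.01,
) -> tuple[Spectrum, TruthInterval | None]:
    """Add ``count`` symmetric side peaks around an existing intense peak.

    Side peak *k* sits at ``center ± k*spacing`` with intensity
    ``parent * decay**k`` (strictly decreasing outward for ``decay < 1``).
    Raises if no peak lies within ``match_tol`` of ``center``.
    """
    if count < 0 or spacing <= 0 or not 0 < decay < 1:
        raise ValueError("need count >= 0, spacing > 0, 0 < decay < 1")
    if count == 0:
        return spectrum, None
    i = int(np.searchsorted(spectrum.mz, center))
    cand = [j for j in (i - 1, i) if 0 <= j < spectrum.n_peaks]
    if not cand or min(abs(spectrum.mz[j] - center) for j in cand) > match_tol:
        raise ValueError(f"no peak within {match_tol} of m/z {center} to ring")
    j = min(cand, key=lambda j: abs(spectrum.mz[j] - center))
    parent_mz, parent_int = spectrum.mz[j], spectrum.intensity[j]
    k = np.arange(1, count + 1, dtype=float)
    offsets = np.concatenate([-k[::-1], k]) * spacing
    side_mz = parent_mz + offsets
    side_int = parent_int * decay ** np.abs(np.concatenate([-k[::-1], k]))
    out = Spectrum(
        mz=np.concatenate([spectrum.mz, side_mz]),
        intensity=np.concatenate([spectrum.intensity, side_int]),
        sample_id=spectrum.sample_id,
        class_label=spectrum.class_label,
        instrument=spectrum.instrument,
        n_scans=spectrum.n_scans,
        mz_range=spectrum.mz_range,
    )
    truth = TruthInterval(float(side_mz.min()), float(side_mz.max()), kind)
    return out, truth


def simulate_sample(
    config: SimConfig, sample_id: str = "S0", class_label: str | None = None
) -> tuple[Spectrum, SampleTruth, ScanSet | None]:
    """Simulate one acquisition: aggregate spectrum, truth, and (for
    ``n_scans > 1``) the underlying scans.

    With multiple scans each scan is a full independent baseline draw and
    fuzzy sites populate a re-drawn sub-interval per scan; the aggregate is
    the plain concatenation of scans (no centroid merging), mirroring how
    scan summation piles fuzzy-site peaks into their full envelope.
    """
    rng = np.random.default_rng(config.seed)
    truth = SampleTruth(sample_id=sample_id)
    for idx, site in enumerate(config.fuzzy_sites):
        truth.intervals.append(TruthInterval(site.lo, site.hi, "fuzzy"))
        if config.n_scans > 1:
            truth.scan_subintervals[idx] = []

    def _one_scan(scan_rng: np.random.Generator, scan_level: bool) -> Spectrum:
        base = simulate_baseline(config, scan_rng)
        mz_parts = [base.mz]
        int_parts = [base.intensity]
        for idx, site in enumerate(config.fuzzy_sites):
            frac = config.scan_coverage if scan_level else None
            smz, sint, _, sub = inject_fuzzy_site(config, site, scan_rng, scan_fraction=frac)
            mz_parts.append(smz)
            int_parts.append(sint)
            if scan_level:
                truth.scan_subintervals[idx].append(sub)
        spec = Spectrum(
            mz=np.concatenate(mz_parts),
            intensity=np.concatenate(int_parts),
            sample_id=sample_id,
            class_label=class_label,
            n_scans=1,
            mz_range=config.mz_range,
        )
        for ring in config.ringing_sites:
            kind = "ringing" if scan_level else "partial_ringing"
            spec, rt = inject_ringing(
                spec, ring.center, ring.spacing, ring.count, ring.decay, scan_rng, kind=kind
            )
            if rt is not None:
                truth.intervals.append(rt)
        return spec

    if config.n_scans == 1:
        agg = _one_scan(rng, scan_level=False)
        return agg, truth, None
    scans = []
    ring_truth_seen = len(truth.intervals)
    for _ in range(config.n_scans):
        scans.append(_one_scan(rng, scan_level=True))
        # record ringing truth once, not once per scan
        del truth.intervals[ring_truth_seen + len(config.ringing_sites):]
    scan_set = ScanSet(scans=tuple(scans))
    agg = aggregate_scans(scan_set, merge_tolerance="none")
    agg = Spectrum(
        mz=agg.mz,
        intensity=agg.intensity,
        sample_id=sample_id,
        class_label=class_label,
        n_scans=config.n_scans,
        mz_range=config.mz_range,
    )
    return agg, truth, scan_set


def subinterval_overlap_probability(scan_coverage: float) -> float:
    """Probability that two independently placed sub-intervals of fractional
    width ``f`` (starts uniform on ``[0, 1-f]``) overlap: ``1 - ((1-2f)/(1-f))^2``
    for ``f < 1/2``, else 1."""
    f = float(scan_coverage)
    if not 0 < f <= 1:
        raise ValueError("scan_coverage must be in (0, 1]")
    if f >= 0.5:
        return 1.0
    g = 1.0 - f
    return 1.0 - ((g - f) / g) ** 2


# --- cohorts ----------------------------------------------------------------

_DEFAULT_SITE_CENTERS = (300.0, 550.0, 800.0, 1100.0, 1400.0)
_DEFAULT_SITE_WIDTHS = (0.8, 1.2, 1.6, 2.2, 3.0)
_DEFAULT_CLASS_OFFSETS: dict[str, object] = {"A": 0.0, "B": (2.0, 2.0, 2.0, 2.0, 12.0)}


def default_cohort_config(seed: int = 0) -> SimConfig:
    """The default cohort study conditions: a 150-1600 m/z acquisition with a
    ~6 -> ~3 peaks/(m/z) decaying noise baseline and five fuzzy sites whose
    widths grow with m/z (0.8-3.0 m/z) at 10x local baseline density."""
    sites = tuple(
        FuzzySite(center=c, width=w, multiplier=10.0)
        for c, w in zip(_DEFAULT_SITE_CENTERS, _DEFAULT_SITE_WIDTHS)
    )
    return SimConfig(fuzzy_sites=sites, seed=seed)


def _broadcast_offsets(offsets, n_sites: int) -> np.ndarray:
    arr = np.asarray(offsets, dtype=float)
    if arr.ndim == 0:
        return np.full(n_sites, float(arr))
    if arr.size != n_sites:
        raise ValueError(f"need 1 or {n_sites} offsets, got {arr.size}")
    return arr


def simulate_cohort(
    n_per_class: int = 10,
    class_site_offsets: Mapping[str, object] | None = None,
    config: SimConfig | None = None,
    seed: int = 0,
    n_signal: int = 40,
    n_discriminating: int = 8,
    fold_change: float = 2.0,
    biological_sigma: float = 0.3,
    n_artifact_features_per_site: int = 4,
    match_tol: float = 0.05,
) -> tuple[dict[str, Spectrum], FeatureTable, SimTruth]:
    """Simulate a two-class cohort with class-shifted fuzzy sites.

    Each class uses the same site list shifted by its per-class offsets
    (default: class B shifted by 2 m/z, 12 m/z for the last site).  True
    biology is ``n_signal`` shared signal peaks, of which the first
    ``n_discriminating`` differ between classes by ``fold_change`` with
    log-normal between-sample noise ``biological_sigma``; signal positions
    are kept at least 5 m/z away from every (shifted) site so biology and
    artifact do not overlap by construction.

    The feature table emulates peak assignment: candidate feature m/z values
    (all signal positions plus ``n_artifact_features_per_site`` positions
    inside every class's site intervals) are matched against each sample's
    aggregate spectrum within ``± match_tol``; the value is the maximum
    matched intensity, or missing when no peak matches.
    """
    config = config if config is not None else default_cohort_config(seed)
    offsets_by_class = dict(class_site_offsets or _DEFAULT_CLASS_OFFSETS)
    if len(offsets_by_class) != 2:
        raise ValueError("simulate_cohort requires exactly two classes")
    classes = sorted(offsets_by_class)
    n_sites = len(config.fuzzy_sites)
    shifted: dict[str, tuple[FuzzySite, ...]] = {}
    for lab in classes:
        off = _broadcast_offsets(offsets_by_class[lab], n_sites)
        shifted[lab] = tuple(
            replace(s, center=s.center + o) for s, o in zip(config.fuzzy_sites, off)
        )

    master = np.random.default_rng(seed)
    lo, hi = config.mz_range

    # forbidden zones: any class's site interval +- 5 m/z
    forb = [
        (s.lo - 5.0, s.hi + 5.0) for lab in classes for s in shifted[lab]
    ]

    def _clear(x: float) -> bool:
        return all(not (a <= x <= b) for a, b in forb)

    signal_mz = []
    while len(signal_mz) < n_signal:
        x = master.uniform(lo + 20.0, hi - 20.0)
        if _clear(x):
            signal_mz.append(x)
    signal_mz = np.sort(np.array(signal_mz))
    disc = np.zeros(n_signal, dtype=bool)
    disc[master.choice(n_signal, size=n_discriminating, replace=False)] = True

    # artifact-candidate feature positions, fixed per class-specific site
    feature_mz: list[float] = list(signal_mz)
    feature_ids = [f"F{i:04d}" for i in range(n_signal)]
    fid = n_signal
    for lab in classes:
        for s in shifted[lab]:
            pos = master.uniform(s.lo, s.hi, size=n_artifact_features_per_site)
            for p in np.sort(pos):
                feature_ids.append(f"F{fid:04d}")
                feature_mz.append(float(p))
                fid += 1
    feature_mz = np.array(feature_mz)

    truth = SimTruth()
    for lab in classes:
        truth.site_intervals_by_class[lab] = [(s.lo, s.hi) for s in shifted[lab]]

    spectra: dict[str, Spectrum] = {}
    values = {}
    class_of: dict[str, str] = {}
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_per_class * 2)
    si = 0
    for lab in classes:
        for r in range(n_per_class):
            sid = f"{lab}{r:02d}"
            samp_rng = np.random.default_rng(int(child_seeds[si]) % (2**31 - 1))
            si += 1
            factors = np.exp(samp_rng.normal(0.0, biological_sigma, size=n_signal))
            inten = config.signal_intensity * factors
            if lab == classes[1]:
                inten = np.where(disc, inten * fold_change, inten)
            cfg = replace(
                config,
                fuzzy_sites=shifted[lab],
                signal_peaks=tuple(zip(signal_mz, inten)),
                seed=int(child_seeds[si]) % (2**31 - 1),
            )
            si += 1
            spec, st, _ = simulate_sample(cfg, sample_id=sid, class_label=lab)
            spectra[sid] = spec
            truth.samples[sid] = st
            class_of[sid] = lab
            # assignment emulation: max intensity within +- match_tol
            li = np.searchsorted(spec.mz, feature_mz - match_tol, side="left")
            ri = np.searchsorted(spec.mz, feature_mz + match_tol, side="right")
            col = np.full(feature_mz.size, np.nan)
            for fi in range(feature_mz.size):
                if ri[fi] > li[fi]:
                    col[fi] = spec.intensity[li[fi] : ri[fi]].max()
            values[sid] = col

    table = FeatureTable(
        values=pd.DataFrame(values, index=feature_ids),
        feature_mz=pd.Series(feature_mz, index=feature_ids, name="mz"),
        classes=pd.Series(class_of, name="class_label"),
    )
    return spectra, table, truth
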