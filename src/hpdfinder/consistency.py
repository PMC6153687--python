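"""Cohort-consistent HPD regions and artifact-aware feature filtering.

Per-spectrum HPD calls contain spurious regions; artifact (fuzzy) sites,
however, recur at nearly the same m/z across the spectra of a cohort.  A
consistent region is an m/z interval containing a called HPD region in at
least ``min_fraction`` (default 10%) of the cohort's spectra, computed on a
fixed occupancy grid (default 0.1 m/z, the detector step).

Features whose m/z falls inside a consistent region are "HPD-tainted" and
presumed artifactual.  Three removal strategies are provided:

- ``none``            — keep everything (baseline).
- ``sample_specific`` — blank a feature only in samples whose own spectrum
  has an HPD region at the feature m/z.  This can *indirectly* encode sample
  class: the feature stays present precisely in the class whose artifact
  sites are elsewhere.
- ``consistent``      — drop any feature inside a consistent region from
  every sample.  The retained-feature m/z set is then identical across
  samples, so absence of a feature cannot encode class membership.

A prevalence filter (default: drop features present in < 25% of either
class) mirrors the usual pre-classification cleanup of assignment tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .detector import HPDRegion

__all__ = [
    "ConsistentRegion",
    "FeatureTable",
    "consistent_regions",
    "tag_features",
    "filter_features",
    "prevalence_filter",
    "read_feature_table",
    "write_feature_table",
]


@dataclass(frozen=True)
class ConsistentRegion:
    """An m/z interval ``[lo, hi)`` with the fraction of cohort spectra whose
    HPD calls overlap it (maximum over its occupancy bins)."""

    lo: float
    hi: float
    occupancy: float


@dataclass(frozen=True)
class FeatureTable:
    """Features x samples with class labels and optional taint flags.

    ``values`` is indexed by feature id with one column per sample; NaN means
    "absent".  ``feature_mz`` maps feature id to m/z and ``classes`` maps
    sample id to class label.  ``taint`` is set by :func:`tag_features`.
    """

    values: pd.DataFrame
    feature_mz: pd.Series
    classes: pd.Series
    taint: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.feature_mz.index):
            raise ValueError("values index and feature_mz index differ")
        if set(self.values.columns) != set(self.classes.index):
            raise ValueError("values columns and classes index differ")
        if self.taint is not None and not self.taint.index.equals(self.values.index):
            raise ValueError("taint index does not match features")

    @property
    def n_features(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[1])

    def presence(self) -> pd.DataFrame:
        """Boolean presence matrix: value is neither missing nor zero."""
        return self.values.notna() & (self.values != 0)

    def subset(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            values=self.values.loc[feature_ids],
            feature_mz=self.feature_mz.loc[feature_ids],
            classes=self.classes,
            taint=None if self.taint is None else self.taint.loc[feature_ids],
        )


def _mz_in_regions(mz: np.ndarray, regions: Sequence) -> np.ndarray:
    """Boolean mask: m/z lies in some half-open region ``[lo, hi)``."""
    if len(regions) == 0 or mz.size == 0:
        return np.zeros(mz.size, dtype=bool)
    los = np.array([r.lo for r in regions])
    his = np.array([r.hi for r in regions])
    order = np.argsort(los)
    los, his = los[order], his[order]
    pos = np.searchsorted(los, mz, side="right") - 1
    hit = pos >= 0
    hit[hit] = mz[hit] < his[pos[hit]]
    return hit


def consistent_regions(
    per_sample_regions: Mapping[str, Sequence[HPDRegion]],
    grid: float = 0.1,
    min_fraction: float = 0.10,
) -> list[ConsistentRegion]:
    """Merge per-sample HPD regions into cohort-consistent intervals.

    m/z is discretized onto bins of width ``grid`` (anchored at 0); a bin's
    occupancy is the fraction of samples with any HPD region overlapping it.
    Bins with occupancy >= ``min_fraction`` ("at least", inclusive) that were
    hit by at least one sample are merged into maximal contiguous regions
    carrying the maximum bin occupancy.  Samples with no regions still count
    in the denominator.
    """
    if not per_sample_regions:
        raise ValueError("per_sample_regions is empty: need at least one sample")
    if grid <= 0:
        raise ValueError("grid must be > 0")
    n_samples = len(per_sample_regions)
    counts: dict[int, int] = {}
    for regs in per_sample_regions.values():
        bins: set[int] = set()
        for r in regs:
            if r.hi <= r.lo:
                continue
            j0 = int(np.floor(r.lo / grid + 1e-9))
            j1 = int(np.ceil(r.hi / grid - 1e-9)) - 1
            bins.update(range(j0, j1 + 1))
        for j in bins:
            counts[j] = counts.get(j, 0) + 1
    qualifying = sorted(
        j for j, c in counts.items() if c / n_samples >= min_fraction - 1e-12
    )
    out: list[ConsistentRegion] = []
    i = 0
    while i < len(qualifying):
        j = i
        while j + 1 < len(qualifying) and qualifying[j + 1] == qualifying[j] + 1:
            j += 1
        occ = max(counts[b] for b in qualifying[i : j + 1]) / n_samples
        out.append(
            ConsistentRegion(
                lo=qualifying[i] * grid,
                hi=(qualifying[j] + 1) * grid,
                occupancy=occ,
            )
        )
        i = j + 1
    return out


def tag_features(table: FeatureTable, regions: Sequence[ConsistentRegion]) -> FeatureTable:
    """Flag features whose m/z lies in any consistent region (``[lo, hi)``)."""
    mask = _mz_in_regions(table.feature_mz.to_numpy(dtype=float), regions)
    return replace(table, taint=pd.Series(mask, index=table.values.index, name="hpd_tainted"))


def filter_features(
    table: FeatureTable,
    mode: str,
    per_sample_regions: Mapping[str, Sequence[HPDRegion]] | None = None,
    consistent: Sequence[ConsistentRegion] | None = None,
) -> FeatureTable:
    """Apply one of the three HPD removal strategies.

    ``sample_specific`` blanks a feature (sets it missing) in each sample
    whose own HPD regions cover the feature m/z, then drops features absent
    everywhere; ``consistent`` drops features inside any consistent region
    from every sample.
    """
    mz = table.feature_mz.to_numpy(dtype=float)
    if mode == "none":
        return replace(table)
    if mode == "sample_specific":
        if per_sample_regions is None:
            raise ValueError("mode 'sample_specific' requires per_sample_regions")
        values = table.values.copy()
        for sid in values.columns:
            regs = per_sample_regions.get(sid, ())
            hit = _mz_in_regions(mz, regs)
            if hit.any():
                values.loc[hit, sid] = np.nan
        keep = values.notna().any(axis=1)
        return FeatureTable(
            values=values.loc[keep],
            feature_mz=table.feature_mz.loc[keep],
            classes=table.classes,
            taint=None if table.taint is None else table.taint.loc[keep],
        )
    if mode == "consistent":
        if consistent is None:
            raise ValueError("mode 'consistent' requires consistent regions")
        keep = ~_mz_in_regions(mz, consistent)
        return table.subset(table.values.index[keep])
    raise ValueError(f"unknown filter mode {mode!r}")


def prevalence_filter(table: FeatureTable, min_fraction: float = 0.25) -> FeatureTable:
    """Drop features present in less than ``min_fraction`` of either class.

    Presence is a non-missing, non-zero value; a feature at exactly the
    threshold fraction in both classes is retained (the drop rule is a strict
    "<").  Requires exactly two class labels.
    """
    labels = sorted(set(table.classes))
    if len(labels) != 2:
        raise ValueError(f"prevalence_filter requires exactly 2 classes, got {labels}")
    pres = table.presence()
    keep = np.ones(table.n_features, dtype=bool)
    for lab in labels:
        cols = table.classes.index[table.classes == lab]
        frac = pres[cols].mean(axis=1)
        keep &= (frac >= min_fraction - 1e-12).to_numpy()
    return table.subset(table.values.index[keep])


# --- TSV I/O ----------------------------------------------------------------

def write_feature_table(table: FeatureTable, features_path: str | Path, samples_path: str | Path) -> None:
    df = pd.concat(
        [table.feature_mz.rename("mz"), table.values], axis=1
    )
    df.index.name = "feature_id"
    df.to_csv(features_path, sep="\t", float_format="%.6g")
    meta = table.classes.rename("class_label").to_frame()
    meta.index.name = "sample_id"
    meta.to_csv(samples_path, sep="\t")


def read_feature_table(features_path: str | Path, samples_path: str | Path) -> FeatureTable:
    df = pd.read_csv(features_path, sep="\t", index_col="feature_id")
    meta = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    mz = df["mz"].astype(float)
    values = df.drop(columns=["mz"]).astype(float)
    values.columns = values.columns.astype(str)
    classes = meta["class_label"].astype(str)
    classes.index = classes.index.astype(str)
    return FeatureTable(values=values, feature_mz=mz, classes=classes)
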