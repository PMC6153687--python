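"""Peaklist and region-report I/O.

Centroided direct-infusion FT-MS spectra are exchanged as JSON peaklists
(schema ``hpdfinder-v1``)::

    {
      "sample_id": str,
      "class_label": str | null,
      "instrument": str | null,
      "n_scans": int | null,
      "mz_range": [lo, hi] | null,
      "peaks": [{"mz": float, "intensity": float}, ...]
    }

Peaks are sorted ascending in m/z on load (stable for ties), which the
detector relies on for binary searching.  Region reports (called artifact
intervals) round-trip through TSV or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

SCHEMA_NAME = "hpdfinder-v1"

__all__ = [
    "Peak",
    "Spectrum",
    "ScanSet",
    "PeaklistError",
    "read_peaklist",
    "write_peaklist",
    "aggregate_scans",
    "write_regions",
    "read_regions",
    "write_consistent_regions",
    "read_consistent_regions",
]


class PeaklistError(ValueError):
    """Malformed or invalid peaklist content."""


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """An m/z-sorted centroided spectrum with sample metadata.

    ``mz`` and ``intensity`` are parallel float64 arrays; construction sorts
    them (stably) and validates that every m/z is finite and positive and
    every intensity finite and non-negative.  ``mz_range`` is the acquisition
    range; when omitted it is inferred from the observed peaks.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    class_label: str | None = None
    instrument: str | None = None
    n_scans: int | None = None
    mz_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64).ravel()
        inten = np.asarray(self.intensity, dtype=np.float64).ravel()
        if mz.shape != inten.shape:
            raise PeaklistError(
                f"mz and intensity lengths differ: {mz.size} vs {inten.size}"
            )
        if mz.size:
            if not np.all(np.isfinite(mz)) or np.any(mz <= 0):
                raise PeaklistError("m/z values must be finite and > 0")
            if not np.all(np.isfinite(inten)) or np.any(inten < 0):
                raise PeaklistError("intensities must be finite and >= 0")
            order = np.argsort(mz, kind="stable")
            mz = mz[order]
            inten = inten[order]
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        rng = self.mz_range
        if rng is None:
            if mz.size:
                rng = (float(mz[0]), float(mz[-1]))
        else:
            rng = (float(rng[0]), float(rng[1]))
            if rng[0] > rng[1]:
                raise PeaklistError(f"mz_range is inverted: {rng}")
            if mz.size and (rng[0] > mz[0] or rng[1] < mz[-1]):
                raise PeaklistError(
                    "mz_range does not cover the observed peaks: "
                    f"{rng} vs [{mz[0]}, {mz[-1]}]"
                )
        object.__setattr__(self, "mz_range", rng)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(float(m), float(i)) for m, i in zip(self.mz, self.intensity)]


@dataclass(frozen=True)
class ScanSet:
    """A collection of single-scan spectra from one acquisition."""

    scans: tuple[Spectrum, ...]

    def __post_init__(self) -> None:
        scans = tuple(self.scans)
        if not scans:
            raise PeaklistError("ScanSet requires at least one scan")
        sid = scans[0].sample_id
        if any(s.sample_id != sid for s in scans):
            raise PeaklistError("all scans in a ScanSet must share sample_id")
        object.__setattr__(self, "scans", scans)

    @property
    def sample_id(self) -> str:
        return self.scans[0].sample_id

    def __len__(self) -> int:
        return len(self.scans)


def _require(record: Mapping, key: str, where: str):
    if key not in record:
        raise PeaklistError(f"{where}: missing required field {key!r}")
    return record[key]


def spectrum_to_dict(spectrum: Spectrum) -> dict:
    return {
        "schema": SCHEMA_NAME,
        "sample_id": spectrum.sample_id,
        "class_label": spectrum.class_label,
        "instrument": spectrum.instrument,
        "n_scans": spectrum.n_scans,
        "mz_range": list(spectrum.mz_range) if spectrum.mz_range else None,
        "peaks": [
            {"mz": float(m), "intensity": float(i)}
            for m, i in zip(spectrum.mz, spectrum.intensity)
        ],
    }


def spectrum_from_dict(doc: Mapping, where: str = "peaklist") -> Spectrum:
    peaks = _require(doc, "peaks", where)
    if not isinstance(peaks, list):
        raise PeaklistError(f"{where}: 'peaks' must be an array")
    mz = np.empty(len(peaks))
    inten = np.empty(len(peaks))
    for i, rec in enumerate(peaks):
        if not isinstance(rec, Mapping):
            raise PeaklistError(f"{where}: peak record {i} is not an object")
        try:
            mz[i] = float(_require(rec, "mz", f"{where}: peak record {i}"))
            inten[i] = float(_require(rec, "intensity", f"{where}: peak record {i}"))
        except (TypeError, ValueError) as exc:
            raise PeaklistError(f"{where}: peak record {i}: {exc}") from exc
        if not np.isfinite(mz[i]) or mz[i] <= 0:
            raise PeaklistError(
                f"{where}: peak record {i}: m/z must be finite and > 0, got {mz[i]}"
            )
        if not np.isfinite(inten[i]) or inten[i] < 0:
            raise PeaklistError(
                f"{where}: peak record {i}: intensity must be finite and >= 0, "
                f"got {inten[i]}"
            )
    rng = doc.get("mz_range")
    return Spectrum(
        mz=mz,
        intensity=inten,
        sample_id=str(doc.get("sample_id", "")),
        class_label=doc.get("class_label"),
        instrument=doc.get("instrument"),
        n_scans=doc.get("n_scans"),
        mz_range=tuple(rng) if rng is not None else None,
    )


def read_peaklist(path: str | Path, schema: str = SCHEMA_NAME) -> Spectrum:
    """Read a JSON peaklist into a sorted :class:`Spectrum`.

    Raises :class:`PeaklistError` naming the offending record for malformed
    files, non-positive m/z, or negative intensity.
    """
    if schema != SCHEMA_NAME:
        raise PeaklistError(f"unknown peaklist schema {schema!r}")
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise PeaklistError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, Mapping):
        raise PeaklistError(f"{path}: top level must be a JSON object")
    return spectrum_from_dict(doc, where=str(path))


def write_peaklist(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as a JSON peaklist (full float precision)."""
    Path(path).write_text(json.dumps(spectrum_to_dict(spectrum), indent=1) + "\n")


def aggregate_scans(scans: ScanSet, merge_tolerance: float | str = "none") -> Spectrum:
    """Combine the scans of a :class:`ScanSet` into one aggregate spectrum.

    With ``merge_tolerance="none"`` the result is the sorted concatenation of
    all scan peaks.  With a numeric tolerance, runs of peaks whose successive
    m/z gaps are within the tolerance are merged into a single centroid at the
    intensity-weighted mean m/z with summed intensity.
    """
    first = scans.scans[0]
    mz = np.concatenate([s.mz for s in scans.scans])
    inten = np.concatenate([s.intensity for s in scans.scans])
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    if merge_tolerance != "none":
        tol = float(merge_tolerance)
        if tol < 0:
            raise ValueError("merge_tolerance must be >= 0 or 'none'")
        if mz.size:
            # new cluster wherever the gap to the previous peak exceeds tol
            breaks = np.flatnonzero(np.diff(mz) > tol)
            starts = np.concatenate([[0], breaks + 1])
            ends = np.concatenate([breaks + 1, [mz.size]])
            wsum = np.add.reduceat(mz * inten, starts)
            isum = np.add.reduceat(inten, starts)
            # zero-intensity clusters fall back to the plain mean m/z
            counts = ends - starts
            plain = np.add.reduceat(mz, starts) / counts
            with np.errstate(invalid="ignore"):
                mz = np.where(isum > 0, wsum / np.maximum(isum, 1e-300), plain)
            inten = isum
    los = [s.mz_range[0] for s in scans.scans if s.mz_range]
    his = [s.mz_range[1] for s in scans.scans if s.mz_range]
    return Spectrum(
        mz=mz,
        intensity=inten,
        sample_id=first.sample_id,
        class_label=first.class_label,
        instrument=first.instrument,
        n_scans=sum(s.n_scans or 1 for s in scans.scans),
        mz_range=(min(los), max(his)) if los else None,
    )


# --- region reports ---------------------------------------------------------

_REGION_COLUMNS = ("sample_id", "lo_mz", "hi_mz", "max_statistic", "n_peaks")
_CONSISTENT_COLUMNS = ("lo_mz", "hi_mz", "occupancy")


def _region_records(
    regions: Sequence | Mapping[str, Sequence], default_sample: str
) -> list[tuple]:
    if isinstance(regions, Mapping):
        items: Iterable[tuple[str, Sequence]] = regions.items()
    else:
        items = [(default_sample, regions)]
    rows = []
    for sid, regs in items:
        for r in regs:
            rows.append((sid, float(r.lo), float(r.hi), float(r.max_S), int(r.n_peaks)))
    return rows


def write_regions(
    regions: Sequence | Mapping[str, Sequence],
    path: str | Path,
    format: str = "tsv",
    sample_id: str = "",
) -> None:
    """Write called HPD regions as TSV (with header) or JSON.

    ``regions`` is either a flat sequence (labelled with ``sample_id``) or a
    mapping of sample id to region sequence.
    """
    rows = _region_records(regions, sample_id)
    path = Path(path)
    if format == "tsv":
        lines = ["\t".join(_REGION_COLUMNS)]
        for sid, lo, hi, s, n in rows:
            lines.append(f"{sid}\t{lo!r}\t{hi!r}\t{s!r}\t{n}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        path.write_text(
            json.dumps(
                [dict(zip(_REGION_COLUMNS, row)) for row in rows], indent=1
            )
            + "\n"
        )
    else:
        raise ValueError(f"unknown region format {format!r}")


def read_regions(path: str | Path) -> dict[str, list]:
    """Read a region report (TSV or JSON) into ``{sample_id: [HPDRegion, ...]}``."""
    from .detector import HPDRegion  # local import to avoid a cycle

    path = Path(path)
    text = path.read_text()
    rows: list[dict]
    if path.suffix.lower() == ".json" or text.lstrip().startswith("["):
        rows = json.loads(text)
    else:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if tuple(header) != _REGION_COLUMNS:
            raise PeaklistError(f"{path}: unexpected region header {header}")
        rows = [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
    out: dict[str, list] = {}
    for rec in rows:
        out.setdefault(str(rec["sample_id"]), []).append(
            HPDRegion(
                lo=float(rec["lo_mz"]),
                hi=float(rec["hi_mz"]),
                max_S=float(rec["max_statistic"]),
                n_peaks=int(rec["n_peaks"]),
            )
        )
    return out


def write_consistent_regions(
    regions: Sequence, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    rows = [(float(r.lo), float(r.hi), float(r.occupancy)) for r in regions]
    if format == "tsv":
        lines = ["\t".join(_CONSISTENT_COLUMNS)]
        lines += [f"{lo!r}\t{hi!r}\t{occ!r}" for lo, hi, occ in rows]
        path.write_text("\n".join(lines) + "\n")
    elif format == "json":
        path.write_text(
            json.dumps([dict(zip(_CONSISTENT_COLUMNS, r)) for r in rows], indent=1)
            + "\n"
        )
    else:
        raise ValueError(f"unknown region format {format!r}")


def read_consistent_regions(path: str | Path) -> list:
    from .consistency import ConsistentRegion

    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json" or text.lstrip().startswith("["):
        rows = json.loads(text)
    else:
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if tuple(header) != _CONSISTENT_COLUMNS:
            raise PeaklistError(f"{path}: unexpected header {header}")
        rows = [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
    return [
        ConsistentRegion(
            lo=float(r["lo_mz"]), hi=float(r["hi_mz"]), occupancy=float(r["occupancy"])
        )
        for r in rows
    ]
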