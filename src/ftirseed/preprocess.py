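"""Spectrum preprocessing: baseline correction, replicate averaging, and
fixed-size absorption-peak tables.

The baseline corrector is the classic rubber-band method: the lower convex
hull of the trace is stretched under the spectrum and subtracted, which by
construction leaves a non-negative trace and removes any linear (or convex)
drift exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .errors import GridMismatchError, InsufficientPeaksError
from .synth import Spectrum


def _lower_hull_baseline(y: np.ndarray) -> np.ndarray:
    """Piecewise-linear lower convex hull of ``(i, y[i])``, evaluated at
    every index (Andrew's monotone chain, lower half only)."""
    n = y.size
    hull = [0]
    for i in range(1, n):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above the chord j -> i
            if (y[k] - y[j]) * (i - j) >= (y[i] - y[j]) * (k - j):
                hull.pop()
            else:
                break
        hull.append(i)
    hull_arr = np.asarray(hull)
    return np.interp(np.arange(n), hull_arr, y[hull_arr])


def baseline_correct(spectrum: Spectrum) -> Spectrum:
    """Rubber-band baseline correction.

    Subtracts the lower convex hull of the absorbance trace.  The result is
    non-negative up to floating-point round-off, annihilates purely linear
    input exactly, and is idempotent: the hull of a corrected trace is the
    zero chord between its end points.
    """
    baseline = _lower_hull_baseline(spectrum.absorbance)
    return replace(spectrum, absorbance=spectrum.absorbance - baseline)


def average_replicates(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate scans of one specimen.

    All inputs must share the wavenumber grid and specimen id; the result
    inherits the metadata of the first replicate with ``replicate_id=0``.
    """
    if len(spectra) == 0:
        raise ValueError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.grid != first.grid:
            raise GridMismatchError("replicates measured on different grids")
        if s.specimen_id != first.specimen_id:
            raise ValueError(
                f"replicates mix specimens {first.specimen_id} and {s.specimen_id}"
            )
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    return replace(first, absorbance=mean, replicate_id=0)


@dataclass
class PeakTable:
    """The ``m`` most prominent absorption peaks of one specimen, sorted by
    descending wavenumber."""

    specimen_id: int
    wavenumbers: np.ndarray
    absorbances: np.ndarray
    class_id: int | None = None
    batch_id: str | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.wavenumbers.shape != self.absorbances.shape:
            raise ValueError("peak position/absorbance length mismatch")
        if np.any(np.diff(self.wavenumbers) >= 0):
            raise ValueError("peaks must be sorted by strictly descending wavenumber")

    def __len__(self) -> int:
        return self.wavenumbers.size


def pick_peaks(spectrum: Spectrum, m: int = 17) -> PeakTable:
    """Select the ``m`` topographically most prominent local maxima.

    Peaks must be at least 3 grid points apart; prominence ties are broken
    in favour of the lower wavenumber.  Raises
    :class:`InsufficientPeaksError` when the trace has fewer than ``m``
    admissible local maxima.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    y = spectrum.absorbance
    idx, _ = find_peaks(y, distance=3)
    if idx.size < m:
        raise InsufficientPeaksError(
            f"only {idx.size} local maxima found, {m} requested"
        )
    prom = peak_prominences(y, idx)[0]
    # primary key: prominence descending; tie-break: lower wavenumber, i.e.
    # larger grid index (the grid is stored in descending wavenumber order)
    order = np.lexsort((-idx, -prom))
    chosen = np.sort(idx[order[:m]])  # ascending index = descending wavenumber
    wn = spectrum.grid.wavenumbers[chosen]
    return PeakTable(
        specimen_id=spectrum.specimen_id,
        wavenumbers=wn,
        absorbances=y[chosen],
        class_id=spectrum.class_id,
        batch_id=spectrum.batch_id,
    )


def align_peak_tables(
    tables: Sequence[PeakTable],
    reference_centers: Sequence[float],
    spectra: Sequence[Spectrum] | None = None,
    tolerance: float = 20.0,
) -> pd.DataFrame:
    """Map per-specimen peak tables onto a common attribute space.

    Each picked peak is assigned to the nearest reference band center within
    ``tolerance`` cm⁻¹ (closer match wins when two peaks claim one center);
    the attribute set is the union of centers matched by at least one
    specimen, ordered by descending wavenumber.  Where a specimen has no
    matched peak for an attribute, its absorbance at the center's grid point
    is used (read from the parallel ``spectra`` sequence if given, otherwise
    linearly interpolated from the specimen's own peak table — a coarse
    fallback).

    Returns a DataFrame indexed by specimen_id with one column per attribute
    center, plus ``class_id``/``batch_id`` metadata columns.
    """
    centers = np.sort(np.asarray(reference_centers, dtype=float))[::-1]
    matched: list[dict[float, float]] = []
    used_centers: set[float] = set()
    for table in tables:
        assign: dict[float, tuple[float, float]] = {}  # center -> (dist, absorbance)
        for wn, ab in zip(table.wavenumbers, table.absorbances):
            dist = np.abs(centers - wn)
            j = int(np.argmin(dist))
            if dist[j] <= tolerance:
                c = centers[j]
                if c not in assign or dist[j] < assign[c][0]:
                    assign[c] = (float(dist[j]), float(ab))
        matched.append({c: v[1] for c, v in assign.items()})
        used_centers.update(matched[-1])
    attrs = [c for c in centers if c in used_centers]
    rows = []
    for i, table in enumerate(tables):
        row: dict[str, object] = {}
        for c in attrs:
            if c in matched[i]:
                row[c] = matched[i][c]
            elif spectra is not None:
                s = spectra[i]
                row[c] = float(s.absorbance[s.grid.index_of(c)])
            else:
                row[c] = float(
                    np.interp(c, table.wavenumbers[::-1], table.absorbances[::-1])
                )
        row["class_id"] = table.class_id
        row["batch_id"] = table.batch_id
        rows.append(row)
    df = pd.DataFrame(rows, index=[t.specimen_id for t in tables])
    df.index.name = "specimen_id"
    return df


def peak_tables_to_csv(tables: Sequence[PeakTable], path: str) -> None:
    """Flat CSV export: specimen_id, peak_1_cm1, peak_1_abs, ..."""
    rows = []
    for t in tables:
        row: dict[str, object] = {"specimen_id": t.specimen_id}
        for i, (wn, ab) in enumerate(zip(t.wavenumbers, t.absorbances), start=1):
            row[f"peak_{i}_cm1"] = wn
            row[f"peak_{i}_abs"] = ab
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
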