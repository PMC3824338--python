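"""Synthetic mid-infrared absorbance spectrum generator.

Emulates attenuated-total-reflection FT-IR spectra of three confusable
plant-seed classes on the standard 4000-650 cm⁻¹ grid at 2 cm⁻¹ spacing:

* classes 1 and 2 are *siblings* — their band amplitude profiles are nearly
  identical (controlled by ``sibling_overlap``), so whole-spectrum distances
  barely separate them;
* class 3 is chemically distinct (different relative band amplitudes);
* specimens come from three location batches with a mild per-batch
  multiplicative gain and wavenumber calibration shift;
* every specimen is "scanned" three times: replicates share the specimen's
  band-amplitude jitter and differ by baseline drift and detector noise.

All randomness is keyed by ``(seed, batch, specimen, replicate)`` — never by
class — so a dataset is bit-reproducible and, in the ``sibling_overlap=1``
limit, class-1 and class-2 spectra of the same specimen index are identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InvalidGridError

#: Default location-batch labels (three collection sites).
BATCHES: tuple[str, ...] = ("jinhua", "linyi", "leshan")

#: Class labels: 1 and 2 are the sibling pair, 3 the distinct class.
CLASSES: tuple[int, ...] = (1, 2, 3)


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly descending wavenumber grid (cm⁻¹)."""

    start: float = 4000.0
    stop: float = 650.0
    step: float = 2.0

    def __post_init__(self) -> None:
        if self.start <= self.stop:
            raise InvalidGridError(
                f"grid start ({self.start}) must exceed stop ({self.stop})"
            )
        if self.step <= 0:
            raise InvalidGridError(f"grid step must be positive, got {self.step}")
        span = self.start - self.stop
        ratio = span / self.step
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidGridError(
                f"span {span} cm-1 is not divisible by step {self.step} cm-1"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.start - self.stop) / self.step)) + 1

    @property
    def wavenumbers(self) -> np.ndarray:
        """Descending wavenumber axis, shape ``(n_points,)``."""
        return self.start - self.step * np.arange(self.n_points)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest ``wavenumber``."""
        idx = int(round((self.start - wavenumber) / self.step))
        return min(max(idx, 0), self.n_points - 1)


def make_grid(start: float = 4000.0, stop: float = 650.0, step: float = 2.0) -> WavenumberGrid:
    """Build a uniform descending grid; raises :class:`InvalidGridError` if
    the span is not an integer number of steps or start does not exceed stop."""
    return WavenumberGrid(start=start, stop=stop, step=step)


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: position, full width at half maximum, and the
    peak absorbance it contributes in each of the three classes."""

    center: float
    width: float
    amplitude_by_class: tuple[float, float, float]
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be positive, got {self.width}")
        if any(a < 0 for a in self.amplitude_by_class):
            raise ValueError("band amplitudes must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")


# Shared band table: (center cm-1, FWHM cm-1, class-1 amplitude, class-3
# amplitude).  Centers are the classic seed-tissue assignments (O-H/N-H
# stretch, unsaturated and saturated C-H, ester carbonyl, amide I/II/III,
# fingerprint C-O/C-C/P-O modes) padded with minor fingerprint bands so a
# 17-peak table is always well defined.  The class-2 amplitude is derived
# from the sibling construction in :func:`default_bands`.
_BASE_BANDS: list[tuple[float, float, float, float]] = [
    (3400.0, 220.0, 0.55, 0.40),  # O-H / N-H stretch (carbohydrate, protein)
    (3010.0, 30.0, 0.10, 0.22),   # =C-H stretch (unsaturated fatty esters)
    (2925.0, 45.0, 0.45, 0.60),   # CH2 asymmetric stretch (lipid)
    (2854.0, 35.0, 0.25, 0.35),   # CH2 symmetric stretch
    (2100.0, 40.0, 0.03, 0.03),   # weak combination/overtone
    (1745.0, 35.0, 0.30, 0.55),   # C=O ester (membrane lipid, pectin)
    (1650.0, 45.0, 0.50, 0.35),   # amide I
    (1545.0, 40.0, 0.25, 0.18),   # amide II
    (1456.0, 30.0, 0.28, 0.25),   # N-H / CH2 scissor
    (1415.0, 25.0, 0.15, 0.12),
    (1380.0, 25.0, 0.18, 0.20),   # CH3 symmetric bend
    (1315.0, 30.0, 0.12, 0.10),
    (1240.0, 35.0, 0.22, 0.18),   # amide III / C-N
    (1150.0, 30.0, 0.28, 0.20),   # C-O / C-C stretch
    (1100.0, 30.0, 0.20, 0.15),
    (1035.0, 40.0, 0.60, 0.35),   # C-O polysaccharide (fingerprint)
    (990.0, 25.0, 0.15, 0.25),
    (930.0, 30.0, 0.08, 0.12),
    (860.0, 30.0, 0.10, 0.08),
    (815.0, 25.0, 0.06, 0.10),
    (720.0, 30.0, 0.12, 0.08),    # CH2 rock
]

# Class-2-only low-amplitude marker band: (center, FWHM, base amplitude).
# Its amplitude is scaled by (1 - sibling_overlap) so the overlap -> 1 limit
# makes classes 1 and 2 exactly identical, while at the default overlap the
# siblings stay separable in principle though not by whole-spectrum distance.
# The band sits in the quiet 2500-1800 cm-1 window (a nitrile-type stretch)
# so its narrow-scale wavelet signature is not masked by the crowded
# fingerprint bands shared by all classes.
_MARKER_BAND: tuple[float, float, float] = (2240.0, 22.0, 0.40)


def default_bands(sibling_overlap: float = 0.9) -> list[BandSpec]:
    """Default shared band table for the three classes.

    Class 2's amplitude at every shared band is class 1's amplitude pulled
    toward the class-1/class-3 midpoint by ``(1 - sibling_overlap)``; one
    additional low-amplitude band at 1515 cm⁻¹ (amplitude proportional to
    ``1 - sibling_overlap``) belongs to class 2 alone.
    """
    if not 0.0 <= sibling_overlap <= 1.0:
        raise ValueError("sibling_overlap must lie in [0, 1]")
    pull = 1.0 - sibling_overlap
    bands = []
    for center, width, a1, a3 in _BASE_BANDS:
        target = 0.5 * (a1 + a3)
        a2 = a1 + pull * (target - a1)
        bands.append(BandSpec(center, width, (a1, a2, a3)))
    mc, mw, ma = _MARKER_BAND
    bands.append(BandSpec(mc, mw, (0.0, ma * pull, 0.0)))
    return bands


@dataclass(eq=False)
class Spectrum:
    """One absorbance trace with its acquisition metadata."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    class_id: int
    batch_id: str
    specimen_id: int
    replicate_id: int
    split: str | None = None

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.shape != (self.grid.n_points,):
            raise ValueError(
                f"absorbance length {self.absorbance.shape} does not match "
                f"grid with {self.grid.n_points} points"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")


@dataclass
class GeneratorConfig:
    """Everything that defines the synthetic acquisition conditions.

    Parameters
    ----------
    bands
        Shared band table; ``None`` means :func:`default_bands`.
    sibling_overlap
        How close the class-2 amplitude profile sits to class 1's
        (1 = identical).  Default 0.9: confusable but resolvable.
    batch_shift_sd
        SD (cm⁻¹) of the per-batch wavenumber calibration offset.
    batch_gain_sd
        SD of the per-batch multiplicative gain about 1.
    specimen_gain_sd
        SD of the per-specimen global gain (sample amount / contact pressure).
    band_jitter_sd
        SD of the independent per-band amplitude jitter within a specimen
        (biological composition variation).
    noise_sd
        SD (absorbance units) of i.i.d. detector noise per replicate scan.
    baseline_offset_range, baseline_slope_range
        Uniform ranges for the per-replicate linear baseline, parameterised
        as ``offset + slope * t`` with ``t`` running 0→1 across the grid.
    """

    grid: WavenumberGrid = field(default_factory=WavenumberGrid)
    bands: list[BandSpec] | None = None
    sibling_overlap: float = 0.9
    batch_shift_sd: float = 1.0
    batch_gain_sd: float = 0.02
    specimen_gain_sd: float = 0.02
    band_jitter_sd: float = 0.03
    noise_sd: float = 0.002
    baseline_offset_range: tuple[float, float] = (0.02, 0.06)
    baseline_slope_range: tuple[float, float] = (0.0, 0.04)
    batches: tuple[str, ...] = BATCHES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sibling_overlap <= 1.0:
            raise ValueError("sibling_overlap must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.bands is None:
            self.bands = default_bands(self.sibling_overlap)
        for b in self.bands:
            if not (self.grid.stop <= b.center <= self.grid.start):
                raise ValueError(f"band center {b.center} outside grid range")


def _stream(*key: int) -> np.random.Generator:
    """Deterministic generator for a hierarchical integer key."""
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _band_profiles(diff: np.ndarray, widths: np.ndarray, shapes: Sequence[str]) -> np.ndarray:
    """Unit-amplitude band shapes; ``diff`` is (bands, points) center offsets."""
    out = np.empty_like(diff)
    w = widths[:, None]
    for i, shape in enumerate(shapes):
        if shape == "gaussian":
            out[i] = np.exp(-4.0 * np.log(2.0) * (diff[i] / w[i]) ** 2)
        else:  # lorentzian
            out[i] = 1.0 / (1.0 + (2.0 * diff[i] / w[i]) ** 2)
    return out


def generate_spectrum(
    config: GeneratorConfig,
    class_id: int,
    batch_id: str,
    specimen_id: int,
    replicate_id: int,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Synthesize one replicate scan.

    The spectrum is a sum of band shapes (class amplitudes × specimen jitter
    × specimen gain × batch gain, centers offset by the batch calibration
    shift) plus a linear baseline and i.i.d. noise.  Specimen-level draws are
    keyed by ``(seed, batch, specimen)``; replicate-level draws (baseline,
    noise) come from ``rng`` if given, else from a stream keyed additionally
    by ``replicate_id`` — so passing the same ``rng`` state reproduces the
    same spectrum bit for bit.
    """
    if class_id not in CLASSES:
        raise DomainError(f"class_id must be one of {CLASSES}, got {class_id!r}")
    if batch_id not in config.batches:
        raise DomainError(
            f"batch_id must be one of {config.batches}, got {batch_id!r}"
        )
    batch_idx = config.batches.index(batch_id)
    bands = config.bands
    centers = np.array([b.center for b in bands])
    widths = np.array([b.width for b in bands])
    amps = np.array([b.amplitude_by_class[class_id - 1] for b in bands])
    shapes = [b.shape for b in bands]

    batch_rng = _stream(config.seed, 1, batch_idx)
    batch_gain = 1.0 + config.batch_gain_sd * batch_rng.standard_normal()
    batch_shift = config.batch_shift_sd * batch_rng.standard_normal()

    spec_rng = _stream(config.seed, 2, batch_idx, specimen_id)
    jitter = 1.0 + config.band_jitter_sd * spec_rng.standard_normal(len(bands))
    jitter = np.clip(jitter, 0.0, None)
    specimen_gain = 1.0 + config.specimen_gain_sd * spec_rng.standard_normal()

    rep_rng = rng if rng is not None else _stream(
        config.seed, 3, batch_idx, specimen_id, replicate_id
    )
    lo, hi = config.baseline_offset_range
    offset = rep_rng.uniform(lo, hi)
    lo, hi = config.baseline_slope_range
    slope = rep_rng.uniform(lo, hi)

    x = config.grid.wavenumbers
    diff = x[None, :] - (centers + batch_shift)[:, None]
    profiles = _band_profiles(diff, widths, shapes)
    signal = (amps * jitter * specimen_gain * batch_gain) @ profiles

    t = np.linspace(0.0, 1.0, config.grid.n_points)
    baseline = offset + slope * t
    noise = rep_rng.normal(0.0, config.noise_sd, config.grid.n_points) \
        if config.noise_sd > 0 else 0.0

    return Spectrum(
        grid=config.grid,
        absorbance=signal + baseline + noise,
        class_id=class_id,
        batch_id=batch_id,
        specimen_id=specimen_id,
        replicate_id=replicate_id,
    )


def generate_dataset(
    config: GeneratorConfig,
    n_per_cell: int = 20,
    seed: int | None = None,
) -> list[Spectrum]:
    """Generate the full benchmark: ``n_per_cell`` specimens per
    (class × batch) cell in each of the train and test splits, three
    replicate scans per specimen.

    Returns spectra in a fixed deterministic order; specimen ids are unique
    across the whole dataset.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be at least 1")
    cfg = replace(config, seed=seed) if seed is not None else config
    spectra: list[Spectrum] = []
    specimen_id = 0
    for split in ("train", "test"):
        for class_id in CLASSES:
            for batch_id in cfg.batches:
                for _ in range(n_per_cell):
                    for replicate_id in (1, 2, 3):
                        s = generate_spectrum(
                            cfg, class_id, batch_id, specimen_id, replicate_id
                        )
                        s.split = split
                        spectra.append(s)
                    specimen_id += 1
    return spectra


# ---------------------------------------------------------------------------
# CSV interchange: one file per replicate scan plus a manifest.

def write_dataset(spectra: Sequence[Spectrum], outdir: str | os.PathLike) -> str:
    """Write one two-column CSV per spectrum plus ``manifest.csv``; returns
    the manifest path."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for s in spectra:
        fname = f"spec_{s.specimen_id:05d}_r{s.replicate_id}.csv"
        pd.DataFrame(
            {"wavenumber_cm1": s.grid.wavenumbers, "absorbance": s.absorbance}
        ).to_csv(os.path.join(outdir, fname), index=False)
        rows.append(
            dict(
                file=fname,
                class_id=s.class_id,
                batch_id=s.batch_id,
                specimen_id=s.specimen_id,
                replicate_id=s.replicate_id,
                split=s.split if s.split is not None else "",
            )
        )
    manifest = os.path.join(outdir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(datadir: str | os.PathLike) -> list[Spectrum]:
    """Read a dataset written by :func:`write_dataset`."""
    manifest = pd.read_csv(os.path.join(datadir, "manifest.csv"))
    spectra: list[Spectrum] = []
    grid: WavenumberGrid | None = None
    for row in manifest.itertuples(index=False):
        df = pd.read_csv(os.path.join(datadir, row.file))
        wn = df["wavenumber_cm1"].to_numpy(dtype=float)
        if grid is None:
            step = wn[0] - wn[1]
            grid = WavenumberGrid(start=wn[0], stop=wn[-1], step=step)
        split = None if pd.isna(row.split) or row.split == "" else str(row.split)
        spectra.append(
            Spectrum(
                grid=grid,
                absorbance=df["absorbance"].to_numpy(dtype=float),
                class_id=int(row.class_id),
                batch_id=str(row.batch_id),
                specimen_id=int(row.specimen_id),
                replicate_id=int(row.replicate_id),
                split=split,
            )
        )
    return spectra
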