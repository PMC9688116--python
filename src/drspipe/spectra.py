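"""Spectrum containers, reflectance computation and dual-spectrometer merging.

A broadband tissue spectrum is assembled from two spectrometers: a
visible/NIR unit (350–1140 nm) and a NIR/SWIR unit (1090–1920 nm) that
share a 1090–1140 nm overlap.  Raw detector counts are converted to
dimensionless reflectance against a diffuse reflectance standard, the two
halves are blended across the overlap with linear weights, and the result
is resampled onto a common wavelength grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "RawMeasurement",
    "LabeledSpectraSet",
    "InstrumentProfile",
    "compute_reflectance",
    "merge_spectra",
    "resample",
    "read_spectra_table",
    "write_spectra_table",
]

LABELS = ("mucosa", "tumor")
PROBES = ("short_SDD", "long_SDD")


@dataclass(frozen=True)
class Spectrum:
    """One measurement: a wavelength grid (nm) plus values.

    ``kind`` distinguishes raw detector counts (``"intensity"``) from
    dimensionless reflectance (``"reflectance"``).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be 1-D with length >= 2")
        if not np.all(np.isfinite(wl)):
            raise ValueError("wavelengths must be finite")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if vals.shape != wl.shape:
            raise ValueError("values and wavelengths must have equal length")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")
        if self.kind not in ("intensity", "reflectance"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass(frozen=True)
class RawMeasurement:
    """Raw intensity triple (tissue, background, reference) on one grid.

    ``reference_reflectivity`` is the calibrated reflectivity of the
    reflectance standard, either a scalar or a spectrum on the same grid.
    """

    tissue: Spectrum
    background: Spectrum
    reference: Spectrum
    reference_reflectivity: float | Spectrum = 0.99

    def __post_init__(self) -> None:
        grids = [self.tissue.wavelengths, self.background.wavelengths, self.reference.wavelengths]
        if not (np.array_equal(grids[0], grids[1]) and np.array_equal(grids[0], grids[2])):
            raise ValueError("tissue, background and reference must share one wavelength grid")
        rho = self.reference_reflectivity
        if isinstance(rho, Spectrum):
            if not np.array_equal(rho.wavelengths, grids[0]):
                raise ValueError("reference_reflectivity spectrum must share the measurement grid")
            vals = rho.values
        else:
            vals = np.asarray([float(rho)])
        if np.any(vals <= 0) or np.any(vals > 1):
            raise ValueError("reference_reflectivity must lie in (0, 1]")


@dataclass
class InstrumentProfile:
    """Wavelength coverage of the two spectrometers and the output grid."""

    vis_range: tuple[float, float] = (350.0, 1140.0)
    nir_range: tuple[float, float] = (1090.0, 1920.0)
    overlap: tuple[float, float] = (1090.0, 1140.0)
    output_grid: np.ndarray = field(
        default_factory=lambda: np.arange(350.0, 1921.0, 1.0)
    )

    def __post_init__(self) -> None:
        self.output_grid = np.asarray(self.output_grid, dtype=float)
        lo, hi = self.overlap
        if not (self.vis_range[0] <= lo < hi <= self.vis_range[1]):
            raise ValueError("overlap must lie within the VIS range")
        if not (self.nir_range[0] <= lo < hi <= self.nir_range[1]):
            raise ValueError("overlap must lie within the NIR range")


@dataclass
class LabeledSpectraSet:
    """Reflectance matrix (sites x wavelengths) with labels and patient IDs."""

    spectra: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray
    probe: str = "short_SDD"

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        n, m = self.spectra.shape
        if self.wavelengths.shape != (m,):
            raise ValueError("wavelength grid does not match spectra columns")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.labels.shape != (n,) or self.patient_ids.shape != (n,):
            raise ValueError("labels and patient_ids must have one entry per site")
        bad = set(self.labels) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(map(str, bad))}")
        if self.probe not in PROBES:
            raise ValueError(f"unknown probe {self.probe!r}")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra contain non-finite values")

    @property
    def n_sites(self) -> int:
        return self.spectra.shape[0]

    def class_mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def require_both_classes(self) -> None:
        present = set(self.labels)
        if set(LABELS) - present:
            raise ValueError("both classes (mucosa, tumor) must be present")


def compute_reflectance(raw: RawMeasurement, *, clip_negative: bool = True) -> Spectrum:
    """Convert a raw intensity triple into reflectance.

    reflectance(λ) = (tissue − background) / (reference − background)
    divided by the reflectivity of the reference standard.  Negative
    values (detector noise below background) are clipped to zero with a
    warning unless ``clip_negative`` is False.
    """
    wl = raw.tissue.wavelengths
    denom = raw.reference.values - raw.background.values
    if np.any(denom <= 0):
        bad = wl[denom <= 0]
        raise ValueError(
            "reference minus background is non-positive at wavelengths "
            f"{np.array2string(bad, max_line_width=120)}"
        )
    rho = raw.reference_reflectivity
    rho_vals = rho.values if isinstance(rho, Spectrum) else float(rho)
    refl = (raw.tissue.values - raw.background.values) / denom / rho_vals
    if clip_negative and np.any(refl < 0):
        warnings.warn("negative reflectance values clipped to 0", stacklevel=2)
        refl = np.clip(refl, 0.0, None)
    return Spectrum(wl, refl, kind="reflectance")


def resample(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.span
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond spectrum span [{lo}, {hi}]"
        )
    vals = np.interp(grid, s.wavelengths, s.values)
    return Spectrum(grid, vals, kind=s.kind)


def merge_spectra(vis: Spectrum, nir: Spectrum, profile: InstrumentProfile | None = None) -> Spectrum:
    """Blend VIS and NIR reflectance spectra into one broadband spectrum.

    Inside the overlap both spectra are interpolated onto 101 evenly spaced
    points indexed i = 0..100 and combined with weights (100−i)/100 for the
    VIS arm and i/100 for the NIR arm, so the merge is continuous at both
    overlap endpoints.  Outside the overlap each arm is used alone.
    """
    if profile is None:
        profile = InstrumentProfile()
    lo, hi = profile.overlap
    for name, s, rng in (("vis", vis, profile.vis_range), ("nir", nir, profile.nir_range)):
        s_lo, s_hi = s.span
        if s_lo > max(rng[0], lo) or s_hi < min(rng[1], hi):
            raise ValueError(f"{name} spectrum does not cover its required range incl. overlap")

    i = np.arange(101)
    overlap_grid = lo + (hi - lo) * i / 100.0
    v = np.interp(overlap_grid, vis.wavelengths, vis.values)
    n = np.interp(overlap_grid, nir.wavelengths, nir.values)
    blended = ((100 - i) * v + i * n) / 100.0

    out = profile.output_grid
    below = out < lo
    above = out > hi
    inside = ~below & ~above
    merged = np.empty_like(out)
    merged[below] = np.interp(out[below], vis.wavelengths, vis.values)
    merged[above] = np.interp(out[above], nir.wavelengths, nir.values)
    merged[inside] = np.interp(out[inside], overlap_grid, blended)
    return Spectrum(out, merged, kind="reflectance")


# ---------------------------------------------------------------------------
# tabular I/O

def write_spectra_table(dataset: LabeledSpectraSet, path) -> None:
    """Write a labeled spectra set as delimited text (CSV).

    Header: label,patient_id,probe,λ1,λ2,...; one row per measurement site.
    """
    cols = ["label", "patient_id", "probe"] + [f"{w:g}" for w in dataset.wavelengths]
    df = pd.DataFrame(dataset.spectra, columns=cols[3:])
    df.insert(0, "probe", dataset.probe)
    df.insert(0, "patient_id", dataset.patient_ids)
    df.insert(0, "label", dataset.labels)
    df.to_csv(path, index=False)


def read_spectra_table(path) -> LabeledSpectraSet:
    """Read a labeled spectra set written by :func:`write_spectra_table`."""
    try:
        df = pd.read_csv(path, dtype={"label": str, "patient_id": str, "probe": str})
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed spectra table {path}: {exc}") from exc
    required = ("label", "patient_id", "probe")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"spectra table missing required column {col!r}")
    wl_cols = [c for c in df.columns if c not in required]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header in {path}: {exc}") from exc
    values = df[wl_cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        rows = np.unique(np.nonzero(~np.isfinite(values))[0])
        raise ValueError(f"non-numeric or missing cells in rows {rows.tolist()}")
    bad = [i for i, lab in enumerate(df["label"]) if lab not in LABELS]
    if bad:
        raise ValueError(f"unknown labels in rows {bad}")
    probes = df["probe"].unique()
    if len(probes) != 1:
        raise ValueError(f"spectra table mixes probes: {probes.tolist()}")
    return LabeledSpectraSet(
        spectra=values,
        wavelengths=wavelengths,
        labels=df["label"].to_numpy(dtype=object),
        patient_ids=df["patient_id"].to_numpy(dtype=object),
        probe=str(probes[0]),
    )


def read_raw_triple(tissue_path, background_path, reference_path,
                    reference_reflectivity: float = 0.99) -> RawMeasurement:
    """Read three two-column CSVs (wavelength, counts) into a RawMeasurement."""
    def _read(p) -> Spectrum:
        df = pd.read_csv(p)
        if df.shape[1] < 2:
            raise ValueError(f"raw intensity file {p} needs (wavelength, counts) columns")
        return Spectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float),
                        kind="intensity")

    return RawMeasurement(
        tissue=_read(tissue_path),
        background=_read(background_path),
        reference=_read(reference_path),
        reference_reflectivity=reference_reflectivity,
    )
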