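"""Chromophore absorption library and tissue optical-property model.

The library holds smooth parametric approximations (Gaussian bands on top
of gently decaying baselines) of the specific absorption of the four
chromophores that dominate soft-tissue contrast between 350 and 1920 nm:
deoxyhemoglobin (Hb), oxyhemoglobin (HbO2), water and lipid.  Band centers
sit at the canonical peak wavelengths — HbO2 at 414/542/576 nm, Hb at
433/556/757 nm, the lipid doublet between 1700 and 1800 nm, the water edge
rising toward 1900 nm — and magnitudes follow literature scale:
hemoglobin curves are expressed per unit blood volume fraction (whole
blood, 150 g/L hemoglobin), water and lipid per unit volume fraction of
the pure substance, all in mm^-1.

These curves are synthetic approximations built for shape-based analysis
(peak positions, band correlations), not for quantitative concentration
fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "ChromophoreLibrary",
    "TissueComposition",
    "AttributionBands",
    "absorption",
    "mu_a",
    "mu_s_prime",
    "DEFAULT_LIBRARY",
]

WL_MIN, WL_MAX = 350.0, 1920.0

CHROMOPHORES = ("Hb", "HbO2", "water", "lipid")


def _gauss(wl: np.ndarray, center: float, amp: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def _hbo2(wl: np.ndarray) -> np.ndarray:
    # Soret band + Q-band doublet + weak NIR absorption (per blood volume fraction)
    out = _gauss(wl, 414.0, 150.0, 12.0)
    out += _gauss(wl, 542.0, 30.0, 9.0)
    out += _gauss(wl, 576.0, 28.0, 8.0)
    out += _gauss(wl, 930.0, 0.55, 90.0)
    out += 4.0 * np.exp(-(wl - 350.0) / 55.0) + 0.08
    return out


def _hb(wl: np.ndarray) -> np.ndarray:
    out = _gauss(wl, 433.0, 140.0, 13.0)
    out += _gauss(wl, 556.0, 32.0, 11.0)
    out += _gauss(wl, 757.0, 1.6, 22.0)
    out += 5.0 * np.exp(-(wl - 350.0) / 55.0) + 0.12
    return out


def _water(wl: np.ndarray) -> np.ndarray:
    out = _gauss(wl, 975.0, 0.045, 35.0)
    out += _gauss(wl, 1197.0, 0.11, 45.0)
    out += _gauss(wl, 1450.0, 3.0, 60.0)
    out += _gauss(wl, 1940.0, 12.0, 80.0)
    out += 1e-4
    return out


def _lipid(wl: np.ndarray) -> np.ndarray:
    out = _gauss(wl, 761.0, 0.012, 10.0)
    out += _gauss(wl, 930.0, 0.12, 20.0)
    out += _gauss(wl, 1210.0, 0.6, 35.0)
    out += _gauss(wl, 1400.0, 0.2, 40.0)
    out += _gauss(wl, 1728.0, 6.0, 16.0)
    out += _gauss(wl, 1765.0, 5.5, 14.0)
    out += 1e-3
    return out


_CURVES = {"Hb": _hb, "HbO2": _hbo2, "water": _water, "lipid": _lipid}


@dataclass(frozen=True)
class ChromophoreLibrary:
    """Specific absorption curves, nm -> mm^-1 per unit concentration."""

    curves: dict = field(default_factory=lambda: dict(_CURVES))

    def names(self) -> tuple[str, ...]:
        return tuple(self.curves)

    def absorption(self, chromophore: str, wavelengths) -> Spectrum:
        """Sample one chromophore's specific absorption on a grid."""
        if chromophore not in self.curves:
            raise KeyError(
                f"unknown chromophore {chromophore!r}; available: {sorted(self.curves)}"
            )
        wl = np.asarray(wavelengths, dtype=float)
        if wl.min() < WL_MIN or wl.max() > WL_MAX:
            raise ValueError(f"grid must lie within [{WL_MIN}, {WL_MAX}] nm")
        return Spectrum(wl, self.curves[chromophore](wl), kind="reflectance")

    def to_csv(self, path, grid=None) -> None:
        wl = np.arange(WL_MIN, WL_MAX + 1.0) if grid is None else np.asarray(grid, float)
        df = pd.DataFrame({"wavelength": wl})
        for name in self.curves:
            df[name] = self.absorption(name, wl).values
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChromophoreLibrary":
        """Load tabulated curves; values between grid points are interpolated."""
        df = pd.read_csv(path)
        wl = df["wavelength"].to_numpy(float)
        curves = {}
        for name in df.columns:
            if name == "wavelength":
                continue
            vals = df[name].to_numpy(float)
            curves[name] = (lambda w, _wl=wl, _v=vals: np.interp(w, _wl, _v))
        return cls(curves=curves)


DEFAULT_LIBRARY = ChromophoreLibrary()


def absorption(chromophore: str, wavelengths, library: ChromophoreLibrary | None = None) -> Spectrum:
    """Module-level convenience for :meth:`ChromophoreLibrary.absorption`."""
    return (library or DEFAULT_LIBRARY).absorption(chromophore, wavelengths)


@dataclass(frozen=True)
class TissueComposition:
    """Chromophore concentrations and scattering parameters of one tissue.

    total_hemoglobin is the blood volume fraction (hemoglobin curves are
    per-unit-blood), sto2 the oxygen saturation, water/lipid the volume
    fractions, and reduced scattering follows the power law
    a * (λ/λ0)^(−b) with amplitude ``scatter_amplitude`` (mm^-1) at the
    reference wavelength λ0.
    """

    total_hemoglobin: float = 0.01
    sto2: float = 0.75
    water_fraction: float = 0.65
    lipid_fraction: float = 0.10
    scatter_amplitude: float = 2.0
    scatter_power: float = 1.2
    lambda0: float = 500.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sto2 <= 1.0:
            raise ValueError("sto2 must lie in [0, 1]")
        for name in ("water_fraction", "lipid_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.total_hemoglobin < 0:
            raise ValueError("total_hemoglobin must be non-negative")
        if self.scatter_amplitude <= 0:
            raise ValueError("scatter_amplitude must be positive")
        if self.scatter_power < 0:
            raise ValueError("scatter_power must be non-negative")

    def scaled(self, **factors: float) -> "TissueComposition":
        """Return a copy with named parameters multiplied by given factors."""
        return replace(self, **{k: getattr(self, k) * f for k, f in factors.items()})


def mu_a(comp: TissueComposition, wavelengths,
         library: ChromophoreLibrary | None = None) -> Spectrum:
    """Absorption coefficient (mm^-1): linear mixture of the library curves.

    μa(λ) = tHb·[StO2·εHbO2 + (1−StO2)·εHb] + f_water·μa,water + f_lipid·μa,lipid
    """
    lib = library or DEFAULT_LIBRARY
    wl = np.asarray(wavelengths, dtype=float)
    hb = lib.absorption("Hb", wl).values
    hbo2 = lib.absorption("HbO2", wl).values
    water = lib.absorption("water", wl).values
    lipid = lib.absorption("lipid", wl).values
    total = comp.total_hemoglobin * (comp.sto2 * hbo2 + (1.0 - comp.sto2) * hb)
    total = total + comp.water_fraction * water + comp.lipid_fraction * lipid
    return Spectrum(wl, total, kind="reflectance")


def mu_s_prime(comp: TissueComposition, wavelengths) -> Spectrum:
    """Reduced scattering coefficient (mm^-1), power-law in wavelength."""
    wl = np.asarray(wavelengths, dtype=float)
    vals = comp.scatter_amplitude * (wl / comp.lambda0) ** (-comp.scatter_power)
    return Spectrum(wl, vals, kind="reflectance")


@dataclass
class AttributionBands:
    """Wavelength intervals used for shape-matching loadings to chromophores.

    ``chromophore_bands`` maps each chromophore to intervals where its
    absorption features are distinctive; ``scattering_windows`` are the
    low-absorption regions where a flat, monotone loading is read as a
    scattering signature.
    """

    chromophore_bands: dict = field(default_factory=lambda: {
        "Hb": [(380.0, 450.0), (530.0, 590.0), (740.0, 780.0)],
        "HbO2": [(380.0, 450.0), (530.0, 590.0), (740.0, 780.0)],
        "water": [(950.0, 1000.0), (1150.0, 1250.0), (1380.0, 1500.0), (1850.0, 1920.0)],
        "lipid": [(740.0, 780.0), (1150.0, 1250.0), (1700.0, 1800.0)],
    })
    scattering_windows: dict = field(default_factory=lambda: {
        "VIS scattering": (600.0, 1000.0),
        "NIR scattering": (1000.0, 1350.0),
    })
    # coarse regions for loading-amplitude profiling and the attribution
    # amplitude gate (UV-visible / optical window / SWIR)
    amplitude_regions: list = field(default_factory=lambda: [
        (350.0, 600.0), (600.0, 1350.0), (1350.0, 1900.0),
    ])

    def __post_init__(self) -> None:
        for name, bands in self.chromophore_bands.items():
            for lo, hi in bands:
                if not (WL_MIN <= lo < hi <= WL_MAX):
                    raise ValueError(f"band ({lo}, {hi}) for {name} outside valid range")
        for name, (lo, hi) in self.scattering_windows.items():
            if not (WL_MIN <= lo < hi <= WL_MAX):
                raise ValueError(f"window ({lo}, {hi}) for {name} outside valid range")
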