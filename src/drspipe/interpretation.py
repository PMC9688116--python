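"""Attribution of PLSC loadings to chromophores and scattering.

The per-wavelength loading of each PLS component is (a) ranked by mean
absolute amplitude across named wavelength regions, and (b) matched in
shape against the chromophore absorption library: within each
chromophore's characteristic bands the absolute Pearson correlation
between loading and absorption is computed, and a chromophore is marked
as contributing when the correlation clears a threshold in a band whose
amplitude also clears the component's median regional amplitude.
Scattering is attributed when the loading is flat and monotone across a
low-absorption window (normalized total variation near 1 plus a high
monotone fraction).  These quantitative surrogates replace what is, in
practice, a visual comparison; every positive cell carries an evidence
record with the band, metric and threshold that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chromophores import AttributionBands, ChromophoreLibrary, DEFAULT_LIBRARY
from .pls_knn import PLSModel

__all__ = [
    "AmplitudeProfile",
    "AttributionMatrix",
    "amplitude_profile",
    "attribute_chromophores",
    "attribute_scattering",
    "build_attribution_matrix",
    "export_loadings",
]

_MIN_BAND_POINTS = 5

ATTRIBUTION_COLUMNS = ("VIS scattering", "NIR scattering",
                       "Hb", "HbO2", "MetHb", "water", "lipid")


@dataclass
class AmplitudeProfile:
    """Mean |loading| per named region, per component, with rankings."""

    regions: list                 # [(lo, hi), ...]
    means: np.ndarray             # (n_components, n_regions)
    rankings: list                # per component: region indices, descending mean

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{lo:g}-{hi:g} nm" for lo, hi in self.regions]
        idx = [f"PLSC{i + 1}" for i in range(self.means.shape[0])]
        return pd.DataFrame(self.means, index=idx, columns=cols)


@dataclass
class AttributionMatrix:
    """Boolean component × feature matrix plus per-cell evidence records."""

    matrix: pd.DataFrame          # index PLSC1.., columns ATTRIBUTION_COLUMNS
    evidence: list = field(default_factory=list)
    probe: str | None = None

    def to_csv(self, path) -> None:
        out = self.matrix.map(lambda v: "X" if v else "")
        out.to_csv(path)


def _band_slice(wavelengths: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.flatnonzero((wavelengths >= lo) & (wavelengths <= hi))


def _model_grid(model: PLSModel) -> np.ndarray:
    if model.wavelengths is None:
        raise ValueError("model has no wavelength grid attached")
    return model.wavelengths


def amplitude_profile(model: PLSModel, regions: list) -> AmplitudeProfile:
    """Mean absolute loading per region, ranked descending per component.

    Ties in the ranking break toward the lower-wavelength region.
    """
    wl = _model_grid(model)
    idx_sets = []
    for lo, hi in regions:
        idx = _band_slice(wl, lo, hi)
        if idx.size == 0:
            raise ValueError(f"region ({lo}, {hi}) contains no grid points")
        idx_sets.append(idx)
    means = np.array([
        [np.abs(model.loadings[idx, c]).mean() for idx in idx_sets]
        for c in range(model.n_components)
    ])
    order = sorted(range(len(regions)), key=lambda r: regions[r][0])
    rankings = [
        sorted(order, key=lambda r: -means[c, r])
        for c in range(model.n_components)
    ]
    return AmplitudeProfile(regions=list(regions), means=means, rankings=rankings)


def attribute_chromophores(model: PLSModel,
                           library: ChromophoreLibrary | None = None,
                           bands: AttributionBands | None = None,
                           r_threshold: float = 0.6) -> tuple[pd.DataFrame, list]:
    """Shape-match each component's loading against each chromophore.

    A chromophore is marked for a component when, in at least one of its
    characteristic bands, |Pearson r(loading, absorption)| >= r_threshold
    AND the band's mean |loading| exceeds the component's median regional
    amplitude, where the regions are the coarse amplitude-profile regions
    (UV-visible / optical window / SWIR).  The gate discards shape matches
    in bands where the component carries negligible weight.  Returns the
    boolean frame and the evidence records behind every True cell.
    """
    library = library or DEFAULT_LIBRARY
    bands = bands or AttributionBands()
    wl = _model_grid(model)

    all_bands = sorted({b for bl in bands.chromophore_bands.values() for b in bl})
    band_idx = {}
    for lo, hi in all_bands:
        idx = _band_slice(wl, lo, hi)
        if idx.size < _MIN_BAND_POINTS:
            raise ValueError(
                f"band ({lo}, {hi}) has {idx.size} grid points; need >= {_MIN_BAND_POINTS}"
            )
        band_idx[(lo, hi)] = idx

    chroms = list(bands.chromophore_bands)
    out = pd.DataFrame(False, index=[f"PLSC{c + 1}" for c in range(model.n_components)],
                       columns=chroms)
    evidence = []
    region_idx = [_band_slice(wl, lo, hi) for lo, hi in bands.amplitude_regions]
    region_idx = [idx for idx in region_idx if idx.size > 0]
    for c in range(model.n_components):
        loading = model.loadings[:, c]
        regional = np.array([np.abs(loading[idx]).mean() for idx in region_idx])
        amp_gate = np.median(regional)
        candidates = []
        for chrom in chroms:
            for b in bands.chromophore_bands[chrom]:
                idx = band_idx[tuple(b)]
                absorb = library.absorption(chrom, wl[idx]).values
                seg = loading[idx]
                sa = seg - seg.mean()
                sb = absorb - absorb.mean()
                denom = np.sqrt((sa @ sa) * (sb @ sb))
                if denom == 0:
                    continue
                r = abs(float(sa @ sb / denom))
                band_amp = np.abs(seg).mean()
                if r >= r_threshold and band_amp > amp_gate:
                    candidates.append({
                        "component": f"PLSC{c + 1}", "feature": chrom,
                        "band": tuple(b), "abs_r": r, "r_threshold": r_threshold,
                        "band_amplitude": float(band_amp),
                        "amplitude_gate": float(amp_gate),
                    })
        # Hemoglobin and lipid share a NIR band (Hb peak 757 nm vs lipid
        # 761 nm); attribute it to blood when the blood correlation is at
        # least as strong — Hb dominates tissue absorption there.
        blood_r = {tuple(e["band"]): e["abs_r"] for e in candidates
                   if e["feature"] in ("Hb", "HbO2")}
        kept = [e for e in candidates
                if not (e["feature"] == "lipid"
                        and blood_r.get(tuple(e["band"]), -1.0) >= e["abs_r"])]
        for e in kept:
            out.iloc[c, out.columns.get_loc(e["feature"])] = True
        evidence.extend(kept)
    return out, evidence


def _smooth(x: np.ndarray, width: int = 5) -> np.ndarray:
    if x.size < width:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x, pad, mode="edge")
    return np.convolve(xp, kernel, mode="valid")


def attribute_scattering(model: PLSModel,
                         bands: AttributionBands | None = None,
                         flatness_threshold: float = 1.5,
                         monotone_threshold: float = 0.8) -> tuple[pd.DataFrame, list]:
    """Mark scattering when a loading is flat and monotone in a window.

    Flatness: normalized total variation TV = Σ|Δloading| / (range + ε);
    a strictly monotone segment has TV = 1, oscillation pushes it above.
    Monotonicity: fraction of first differences sharing the majority sign
    after 5-point smoothing.  Both criteria must pass.
    """
    bands = bands or AttributionBands()
    wl = _model_grid(model)
    windows = list(bands.scattering_windows)
    out = pd.DataFrame(False, index=[f"PLSC{c + 1}" for c in range(model.n_components)],
                       columns=windows)
    evidence = []
    eps = 1e-12
    for c in range(model.n_components):
        loading = model.loadings[:, c]
        for name in windows:
            lo, hi = bands.scattering_windows[name]
            idx = _band_slice(wl, lo, hi)
            if idx.size < _MIN_BAND_POINTS:
                continue
            seg = _smooth(loading[idx])
            diffs = np.diff(seg)
            tv = np.sum(np.abs(diffs)) / (seg.max() - seg.min() + eps)
            signs = np.sign(diffs[diffs != 0])
            mono = 0.5 if signs.size == 0 else max(
                np.mean(signs > 0), np.mean(signs < 0))
            if tv <= flatness_threshold and mono >= monotone_threshold:
                out.iloc[c, out.columns.get_loc(name)] = True
                evidence.append({
                    "component": f"PLSC{c + 1}", "feature": name,
                    "band": (lo, hi), "tv": float(tv),
                    "tv_threshold": flatness_threshold,
                    "monotone_fraction": float(mono),
                    "monotone_threshold": monotone_threshold,
                })
    return out, evidence


def build_attribution_matrix(model: PLSModel,
                             library: ChromophoreLibrary | None = None,
                             bands: AttributionBands | None = None,
                             r_threshold: float = 0.6,
                             flatness_threshold: float = 1.5,
                             probe: str | None = None) -> AttributionMatrix:
    """Combine chromophore and scattering attribution into one matrix.

    The MetHb column is kept for layout fidelity with the conventional
    feature table but is always False with the default library, which
    does not include methemoglobin.
    """
    chrom, ev1 = attribute_chromophores(model, library, bands, r_threshold)
    scat, ev2 = attribute_scattering(model, bands, flatness_threshold)
    idx = chrom.index
    full = pd.DataFrame(False, index=idx, columns=list(ATTRIBUTION_COLUMNS))
    for col in chrom.columns:
        full[col] = chrom[col]
    for col in scat.columns:
        full[col] = scat[col]
    return AttributionMatrix(matrix=full, evidence=ev1 + ev2, probe=probe)


def export_loadings(model: PLSModel, csv_path, plot_path=None) -> pd.DataFrame:
    """Write raw and absolute loadings per component to CSV (and a plot).

    The CSV has one wavelength column plus, per component, a raw and an
    absolute-value column.
    """
    wl = _model_grid(model)
    df = pd.DataFrame({"wavelength": wl})
    for c in range(model.n_components):
        df[f"PLSC{c + 1}_raw"] = model.loadings[:, c]
        df[f"PLSC{c + 1}_abs"] = np.abs(model.loadings[:, c])
    df.to_csv(csv_path, index=False)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
        for c in range(model.n_components):
            axes[0].plot(wl, model.loadings[:, c], label=f"PLSC{c + 1}")
            axes[1].plot(wl, np.abs(model.loadings[:, c]))
        axes[0].set_ylabel("loading")
        axes[1].set_ylabel("|loading|")
        axes[1].set_xlabel("wavelength (nm)")
        axes[0].legend(frameon=False, ncol=4)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return df
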