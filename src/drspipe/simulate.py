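"""Synthetic two-probe DRS dataset generator.

Emulates the statistical structure of an ex-vivo colorectal study: two
tissue classes (mucosa, tumor) differing in blood content, oxygenation,
water, lipid and scattering; hierarchical patient- and site-level
variability; a fiber-probe forward model (steady-state diffusion
approximation of a semi-infinite homogeneous medium); triplicate-averaged
detector noise; and an optional split into raw VIS/NIR spectrometer pairs
so the merging step can be exercised end to end.

Default cohort geometry mirrors the study design the pipeline is aimed
at: 47 patients, ~15 mucosa and ~15 tumor sites each, two probes with
source–detector separations of 630 µm and 2500 µm.

The default class contrast (tumor: total hemoglobin ×2.0, StO2 0.75→0.60,
water 0.65→0.70, lipid 0.10→0.05, scattering amplitude ×1.2) is a stated
scenario of the generator — directionally consistent with the tissue
biology the pipeline targets, not a fitted claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chromophores import ChromophoreLibrary, TissueComposition, mu_a, mu_s_prime
from .spectra import InstrumentProfile, LabeledSpectraSet, Spectrum, merge_spectra

__all__ = [
    "ProbeGeometry",
    "PopulationSpec",
    "ForwardModelConfig",
    "SHORT_SDD",
    "LONG_SDD",
    "MUCOSA_DEFAULT",
    "TUMOR_DEFAULT",
    "forward_reflectance",
    "sample_tissue",
    "simulate_dataset",
]


@dataclass(frozen=True)
class ProbeGeometry:
    """Fiber-probe geometry: source-to-detector distance in µm."""

    sdd: float
    name: str

    def __post_init__(self) -> None:
        if self.sdd <= 0:
            raise ValueError("sdd must be positive")

    @property
    def rho_mm(self) -> float:
        return self.sdd / 1000.0


SHORT_SDD = ProbeGeometry(sdd=630.0, name="short_SDD")
LONG_SDD = ProbeGeometry(sdd=2500.0, name="long_SDD")

MUCOSA_DEFAULT = TissueComposition(
    total_hemoglobin=0.01, sto2=0.75, water_fraction=0.65,
    lipid_fraction=0.10, scatter_amplitude=2.0, scatter_power=1.2,
)
TUMOR_DEFAULT = TissueComposition(
    total_hemoglobin=0.02, sto2=0.60, water_fraction=0.70,
    lipid_fraction=0.05, scatter_amplitude=2.4, scatter_power=1.2,
)

# parameters subject to patient/site log-normal variation
_VARYING = ("total_hemoglobin", "sto2", "water_fraction",
            "lipid_fraction", "scatter_amplitude")


@dataclass(frozen=True)
class PopulationSpec:
    """Cohort design: class means, hierarchical variability, noise, counts."""

    mucosa: TissueComposition = MUCOSA_DEFAULT
    tumor: TissueComposition = TUMOR_DEFAULT
    patient_cv: float = 0.2
    site_cv: float = 0.1
    n_patients: int = 47
    sites_per_patient_per_class: int = 15
    noise_multiplicative: float = 0.01
    noise_additive: float = 1e-4
    noise_swir_factor: float = 3.0   # σ inflation above noise_swir_edge
    noise_swir_edge: float = 1850.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patient_cv < 0 or self.site_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.n_patients < 1 or self.sites_per_patient_per_class < 1:
            raise ValueError("counts must be >= 1")

    def class_mean(self, label: str) -> TissueComposition:
        if label == "mucosa":
            return self.mucosa
        if label == "tumor":
            return self.tumor
        raise ValueError(f"unknown class {label!r}")

    def null_scenario(self) -> "PopulationSpec":
        """Both classes share the mucosa mean (for calibration checks)."""
        return replace(self, tumor=self.mucosa)


@dataclass(frozen=True)
class ForwardModelConfig:
    """Forward-model choice and output wavelength grid."""

    model: str = "diffusion"
    refractive_index: float = 1.4
    grid: np.ndarray = field(default_factory=lambda: np.arange(350.0, 1921.0, 1.0))
    collection_area_mm2: float = 0.283  # 600 µm core fiber
    library: ChromophoreLibrary | None = None

    def __post_init__(self) -> None:
        if self.model not in ("diffusion", "exp_attenuation"):
            raise ValueError(f"unknown forward model {self.model!r}")
        object.__setattr__(self, "grid", np.asarray(self.grid, dtype=float))


def _boundary_A(n: float) -> float:
    # Groenhuis internal-reflection parameter for a refractive-index
    # mismatched boundary
    r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


def _farrell(mua: np.ndarray, musp: np.ndarray, rho: float, n: float) -> np.ndarray:
    """Diffusion-approximation local reflectance (per mm^2) at distance rho."""
    mut = mua + musp
    z0 = 1.0 / mut
    D = 1.0 / (3.0 * mut)
    mueff = np.sqrt(3.0 * mua * mut)
    zb = 2.0 * _boundary_A(n) * D
    r1 = np.sqrt(z0**2 + rho**2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho**2)
    albedo = musp / mut
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    return albedo / (4.0 * np.pi) * (term1 + term2)


def forward_reflectance(comp: TissueComposition, probe: ProbeGeometry,
                        cfg: ForwardModelConfig | None = None) -> Spectrum:
    """Model reflectance spectrum for one tissue composition and probe.

    The default model is the Farrell-type steady-state diffusion
    approximation of a semi-infinite homogeneous medium evaluated at the
    probe's source–detector separation, scaled by a fixed effective
    collection area and clipped to (0, 1].  ``exp_attenuation`` is a
    simple Beer–Lambert-like fallback R = exp(−μeff·ρ_eff).
    """
    cfg = cfg or ForwardModelConfig()
    wl = cfg.grid
    mua = mu_a(comp, wl, library=cfg.library).values
    musp = mu_s_prime(comp, wl).values
    if np.any(musp <= 0):
        raise ValueError("diffusion model requires mu_s' > 0 everywhere")
    rho = probe.rho_mm
    if cfg.model == "diffusion":
        refl = _farrell(mua, musp, rho, cfg.refractive_index) * cfg.collection_area_mm2
    else:
        mueff = np.sqrt(3.0 * mua * (mua + musp))
        refl = np.exp(-mueff * rho)
    refl = np.clip(refl, np.finfo(float).tiny, 1.0)
    return Spectrum(wl, refl, kind="reflectance")


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative log-normal effects with unit median and given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return np.exp(rng.normal(0.0, sigma, size))


def _perturb(mean: TissueComposition, factors: np.ndarray) -> TissueComposition:
    updates = {}
    for name, f in zip(_VARYING, factors):
        v = getattr(mean, name) * f
        if name in ("sto2", "water_fraction", "lipid_fraction"):
            v = min(v, 1.0)
        updates[name] = v
    return replace(mean, **updates)


def sample_tissue(label: str, spec: PopulationSpec,
                  patient_rng: np.random.Generator,
                  site_rng: np.random.Generator) -> TissueComposition:
    """Draw one site's composition: class mean × patient effect × site effect.

    Both effects are log-normal with unit median; fraction-valued
    parameters are truncated to [0, 1] after perturbation.
    """
    mean = spec.class_mean(label)
    pf = _lognormal_factors(patient_rng, spec.patient_cv, len(_VARYING))
    sf = _lognormal_factors(site_rng, spec.site_cv, len(_VARYING))
    return _perturb(mean, pf * sf)


def _noise_sigma(wl: np.ndarray, spec: PopulationSpec) -> tuple[np.ndarray, np.ndarray]:
    infl = np.where(wl > spec.noise_swir_edge, spec.noise_swir_factor, 1.0)
    return spec.noise_multiplicative * infl, spec.noise_additive * infl


def _apply_noise(clean: np.ndarray, wl: np.ndarray, spec: PopulationSpec,
                 rng: np.random.Generator, n_replicates: int = 3) -> np.ndarray:
    """Average of triplicate noisy acquisitions of one clean spectrum."""
    mult_s, add_s = _noise_sigma(wl, spec)
    reps = clean * (1.0 + rng.normal(0.0, 1.0, (n_replicates, clean.size)) * mult_s)
    reps += rng.normal(0.0, 1.0, (n_replicates, clean.size)) * add_s
    return np.clip(reps.mean(axis=0), 0.0, None)


def simulate_dataset(spec: PopulationSpec | None = None,
                     probe: ProbeGeometry = SHORT_SDD,
                     cfg: ForwardModelConfig | None = None,
                     raw_pairs: bool = False,
                     profile: InstrumentProfile | None = None):
    """Simulate a labeled two-class dataset for one probe.

    For every patient, ``sites_per_patient_per_class`` mucosa and as many
    tumor sites are drawn hierarchically (a patient-level physiological
    factor shared by both classes within the patient, plus independent
    site-level factors), pushed through the forward model, and observed
    as the average of three noisy acquisitions.

    With ``raw_pairs=True``, each site is additionally measured as a
    (VIS, NIR) spectrometer pair with independent noise on the native
    ranges, merged via :func:`drspipe.spectra.merge_spectra`; the merged
    spectra are returned as the dataset and the pairs alongside it.

    Returns the :class:`LabeledSpectraSet` (and the list of pairs when
    ``raw_pairs`` is set).
    """
    spec = spec or PopulationSpec()
    cfg = cfg or ForwardModelConfig()
    wl = cfg.grid
    ss = np.random.SeedSequence(spec.seed)
    patient_seed, site_seed, noise_seed = ss.spawn(3)
    patient_rng = np.random.default_rng(patient_seed)
    site_rng = np.random.default_rng(site_seed)
    noise_rng = np.random.default_rng(noise_seed)

    if raw_pairs:
        profile = profile or InstrumentProfile(output_grid=wl)
        vis_grid = wl[(wl >= profile.vis_range[0]) & (wl <= profile.vis_range[1])]
        nir_grid = wl[(wl >= profile.nir_range[0]) & (wl <= profile.nir_range[1])]
        if vis_grid.size < 2 or nir_grid.size < 2:
            raise ValueError("grid too coarse to split into VIS/NIR arms")

    rows, labels, patient_ids, pairs = [], [], [], []
    for p in range(spec.n_patients):
        # one physiological baseline per patient, shared across classes
        pf = _lognormal_factors(patient_rng, spec.patient_cv, len(_VARYING))
        for label in ("mucosa", "tumor"):
            mean = spec.class_mean(label)
            for _ in range(spec.sites_per_patient_per_class):
                sf = _lognormal_factors(site_rng, spec.site_cv, len(_VARYING))
                comp = _perturb(mean, pf * sf)
                clean = forward_reflectance(comp, probe, cfg).values
                if raw_pairs:
                    vis_clean = np.interp(vis_grid, wl, clean)
                    nir_clean = np.interp(nir_grid, wl, clean)
                    vis = Spectrum(vis_grid, _apply_noise(vis_clean, vis_grid, spec, noise_rng))
                    nir = Spectrum(nir_grid, _apply_noise(nir_clean, nir_grid, spec, noise_rng))
                    merged = merge_spectra(vis, nir, profile)
                    pairs.append((vis, nir))
                    rows.append(merged.values)
                else:
                    rows.append(_apply_noise(clean, wl, spec, noise_rng))
                labels.append(label)
                patient_ids.append(f"P{p + 1:03d}")

    dataset = LabeledSpectraSet(
        spectra=np.asarray(rows),
        wavelengths=wl,
        labels=np.asarray(labels, dtype=object),
        patient_ids=np.asarray(patient_ids, dtype=object),
        probe=probe.name,
    )
    if raw_pairs:
        return dataset, pairs
    return dataset
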