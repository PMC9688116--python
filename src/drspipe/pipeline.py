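"""End-to-end pipeline: simulate → preprocess → select bands → classify → interpret.

A single YAML-serializable :class:`RunConfig` drives the whole run; one
global seed fans out to per-stage seeds through a numpy SeedSequence so
a stored config reproduces a run bit-identically.  Outputs (spectra
table, per-wavelength p-values, band set, classification report,
attribution matrix, loadings) are written atomically next to a manifest
recording the config hash, seeds and row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .band_selection import BandSet, select_bands, screen_wavelengths
from .chromophores import AttributionBands, TissueComposition
from .interpretation import build_attribution_matrix, export_loadings
from .pls_knn import apply_scaling, cross_validate, fit_pls, fit_scaling
from .simulate import (LONG_SDD, SHORT_SDD, ForwardModelConfig,
                       PopulationSpec, simulate_dataset)
from .spectra import write_spectra_table

logger = logging.getLogger("drspipe")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    out_dir: str = "drspipe_run"
    seed: int = 0
    probes: tuple = ("short_SDD",)
    grid_start: float = 350.0
    grid_stop: float = 1920.0
    grid_step: float = 1.0
    population: dict = field(default_factory=dict)   # PopulationSpec overrides
    mucosa: dict = field(default_factory=dict)       # TissueComposition overrides
    tumor: dict = field(default_factory=dict)
    forward_model: str = "diffusion"
    alpha: float = 0.001
    alpha_norm: float = 0.05
    min_run: int = 3
    max_gap: int = 0
    n_components: int = 4
    k_nn: int = 10
    iterations: int = 20
    leakage_free: bool = False
    raw_pairs: bool = False
    band_sets: list = field(default_factory=list)    # extra [[lo, hi], ...] lists
    r_threshold: float = 0.6
    flatness_threshold: float = 1.5

    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + self.grid_step / 2,
                         self.grid_step)

    def population_spec(self, seed: int) -> PopulationSpec:
        from .simulate import MUCOSA_DEFAULT, TUMOR_DEFAULT
        mucosa = replace(MUCOSA_DEFAULT, **self.mucosa) if self.mucosa else MUCOSA_DEFAULT
        tumor = replace(TUMOR_DEFAULT, **self.tumor) if self.tumor else TUMOR_DEFAULT
        return PopulationSpec(mucosa=mucosa, tumor=tumor, seed=seed, **self.population)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "probes" in data:
        data["probes"] = tuple(data["probes"])
    return RunConfig(**data)


_PROBES = {"short_SDD": SHORT_SDD, "long_SDD": LONG_SDD}


def _atomic_write(path: Path, writer) -> None:
    """Write via a temp file in the same directory, then rename."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name)
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage for each configured probe.

    Returns a manifest dict (also written to ``out_dir/manifest.json``)
    with per-probe row counts, band sets and report paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    sim_seeds, cv_seeds = ss.spawn(2)
    manifest: dict = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": {},
        "probes": {},
    }
    grid = config.grid()
    cfg = ForwardModelConfig(model=config.forward_model, grid=grid)

    for pi, probe_name in enumerate(config.probes):
        t0 = time.time()
        if probe_name not in _PROBES:
            raise ValueError(f"stage simulate: unknown probe {probe_name!r}")
        probe = _PROBES[probe_name]
        sim_seed = int(sim_seeds.spawn(1)[0].generate_state(1)[0] % (2**31))
        cv_seed = int(cv_seeds.spawn(1)[0].generate_state(1)[0] % (2**31))
        spec = config.population_spec(seed=sim_seed)

        logger.info("simulate: probe=%s n_patients=%d", probe_name, spec.n_patients)
        dataset = simulate_dataset(spec, probe, cfg)
        spectra_path = out_dir / f"spectra_{probe_name}.csv"
        _atomic_write(spectra_path, lambda p, d=dataset: write_spectra_table(d, p))

        logger.info("select-bands: probe=%s", probe_name)
        result = screen_wavelengths(dataset, alpha_norm=config.alpha_norm)
        bands = select_bands(result, alpha=config.alpha,
                             min_run=config.min_run, max_gap=config.max_gap)
        _atomic_write(out_dir / f"pvalues_{probe_name}.csv",
                      lambda p, r=result: r.to_frame().to_csv(p, index=False))
        _atomic_write(out_dir / f"bands_{probe_name}.json",
                      lambda p, b=bands: Path(p).write_text(json.dumps(b.to_json())))

        logger.info("classify: probe=%s bands=%d", probe_name, len(bands))
        band_sets = [bands] + [BandSet.from_json(b, alpha=config.alpha)
                               for b in config.band_sets]
        rows = []
        for bs in band_sets:
            report = cross_validate(dataset, bs, n_components=config.n_components,
                                    k_nn=config.k_nn, iterations=config.iterations,
                                    seed=cv_seed, leakage_free=config.leakage_free)
            rows.append(report.to_row())
        report_df = pd.DataFrame(rows)
        _atomic_write(out_dir / f"report_{probe_name}.csv",
                      lambda p, d=report_df: d.to_csv(p, index=False))

        logger.info("interpret: probe=%s", probe_name)
        params = fit_scaling(dataset.spectra)
        model = fit_pls(apply_scaling(dataset.spectra, params), dataset.labels,
                        config.n_components, wavelengths=dataset.wavelengths)
        attribution = build_attribution_matrix(
            model, bands=AttributionBands(), r_threshold=config.r_threshold,
            flatness_threshold=config.flatness_threshold, probe=probe_name)
        _atomic_write(out_dir / f"attribution_{probe_name}.csv",
                      lambda p, a=attribution: a.to_csv(p))
        _atomic_write(out_dir / f"loadings_{probe_name}.csv",
                      lambda p, m=model: export_loadings(m, p))

        manifest["probes"][probe_name] = {
            "n_sites": dataset.n_sites,
            "n_wavelengths": int(dataset.wavelengths.size),
            "sim_seed": sim_seed,
            "cv_seed": cv_seed,
            "bands": bands.to_json(),
            "report": str(out_dir / f"report_{probe_name}.csv"),
            "elapsed_s": round(time.time() - t0, 2),
        }

    _atomic_write(out_dir / "manifest.json",
                  lambda p: Path(p).write_text(json.dumps(manifest, indent=2)))
    config.to_yaml(out_dir / "config.yaml")
    return manifest
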