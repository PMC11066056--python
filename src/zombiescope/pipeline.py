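"""End-to-end orchestration: simulate fields -> cytometry -> regressions.

Mirrors the study chain: render a ground-truthed time series of FISH
fields, count cells with the gating rules, assemble the per-day relative
abundances into a regression dataset, and fit the three logit-link beta
regressions (infected ~ zombie, zombie ~ SAR11, infected ~ FDC%).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cytometry import GateConfig, calibrate_gates, run_cytometry
from .stats import McmcConfig, fit_beta_regression, transform_zero
from .synthetic_imaging import (SceneSpec, render_fields, scene_for_fractions,
                                write_field)

log = logging.getLogger(__name__)

REGRESSION_FORMULAS = (
    "rel_infT ~ Zombie_cells",
    "Zombie_cells_T ~ rel_SAR11_abundance",
    "rel_infT ~ FDC_percent",
)


@dataclass(frozen=True)
class RunConfig:
    """Settings for a demo end-to-end run."""

    n_days: int = 12
    cells_per_day: int = 400
    fields_per_day: int = 1
    peak_infected_frac: float = 0.19     # early-May peak prevalence
    peak_zombie_frac: float = 0.144
    base_sar11_frac: float = 0.45
    dividing_fraction: float = 0.08
    seed: int = 0
    mcmc: McmcConfig = dc_field(default_factory=McmcConfig)
    out_dir: str | None = None


def _meta_header(seed: int, cfg_dict: dict) -> str:
    blob = json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    h = hashlib.sha256(blob).hexdigest()[:12]
    return (f"# zombiescope v{__version__}\n"
            f"# seed={seed} config_sha256={h}\n")


def write_tsv(df: pd.DataFrame, path, seed: int, cfg_dict: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_meta_header(seed, cfg_dict))
        df.to_csv(fh, sep="\t", index=False)


def timeseries_specs(cfg: RunConfig) -> list[tuple[int, SceneSpec]]:
    """Bloom-shaped infection trajectory over ``n_days`` days.

    Infection prevalence follows a Gaussian bump peaking mid-series at
    ``peak_infected_frac``; zombie fraction tracks it; SAR11 relative
    abundance dips as infection peaks (the observed boom-and-bust).
    """
    days = np.arange(cfg.n_days)
    mid = (cfg.n_days - 1) / 2
    bump = np.exp(-0.5 * ((days - mid) / (cfg.n_days / 6)) ** 2)
    specs = []
    for d in days:
        inf = cfg.peak_infected_frac * bump[d]
        zom = cfg.peak_zombie_frac * bump[d]
        sar = cfg.base_sar11_frac * (1 - 0.8 * bump[d]) + 0.05
        spec = scene_for_fractions(
            n_cells=cfg.cells_per_day,
            infected_frac=inf, zombie_frac=zom, sar11_frac=sar,
            dividing_fraction=cfg.dividing_fraction,
            n_free_phage=max(2, cfg.cells_per_day // 40),
            seed=cfg.seed + 7919 * int(d),
        )
        specs.append((int(d), spec))
    return specs


def run_end_to_end(cfg: RunConfig | None = None) -> dict:
    """Simulate, count, regress; returns a report dict (and writes TSVs
    when ``cfg.out_dir`` is set)."""
    cfg = cfg or RunConfig()
    t0 = time.time()
    specs = timeseries_specs(cfg)
    gates = calibrate_gates(specs[0][1])

    rows = []
    for day, spec in specs:
        fields = [f for f, _ in render_fields(spec, cfg.fields_per_day)]
        res = run_cytometry(fields, gates)
        log.info("day %d: %d objects, %d cells, %d infected, %d zombies",
                 day, res.n_objects, res.total_cells, res.infected_cells,
                 res.zombie_cells)
        rows.append({
            "day": day,
            "total_cells": res.total_cells,
            "sar11_cells": res.sar11_cells,
            "infected_cells": res.infected_cells,
            "zombie_cells": res.zombie_cells,
            "rel_infected": res.rel_infected,
            "rel_zombie": res.rel_zombie,
            "rel_SAR11_abundance": res.rel_sar11,
            "FDC_percent": 100.0 * res.fdc if np.isfinite(res.fdc) else np.nan,
            "undefined": ";".join(res.undefined),
        })
    table = pd.DataFrame(rows)

    # regression dataset: +0.001 transform on the beta responses
    ds = table.dropna(subset=["rel_infected", "rel_zombie",
                              "rel_SAR11_abundance", "FDC_percent"]).copy()
    report: dict = {"version": __version__, "seed": cfg.seed,
                    "n_days": cfg.n_days,
                    "runtime_s": None, "fits": {}}
    if len(ds) >= 10:
        ds["rel_infT"] = transform_zero(ds["rel_infected"].to_numpy())
        ds["Zombie_cells"] = ds["rel_zombie"]
        ds["Zombie_cells_T"] = transform_zero(ds["rel_zombie"].to_numpy())
        mcmc = dataclasses.replace(cfg.mcmc, seed=cfg.seed)
        for formula in REGRESSION_FORMULAS:
            fit = fit_beta_regression(ds, formula, mcmc=mcmc)
            report["fits"][formula] = {
                "slope_mean": fit.mean["slope"],
                "slope_sd": fit.sd["slope"],
                "slope_ci95": list(fit.ci95["slope"]),
                "intercept_mean": fit.mean["intercept"],
                "converged": fit.converged,
            }
    else:
        report["fits"]["skipped"] = (
            f"only {len(ds)} usable days (< 10 rows required)")
    report["runtime_s"] = round(time.time() - t0, 2)
    report["counts"] = table.to_dict(orient="list")

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg_dict = dataclasses.asdict(cfg)
        write_tsv(table, out / "daily_counts.tsv", cfg.seed, cfg_dict)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
    return report


def make_fixtures(out_dir, seed: int = 0) -> pd.DataFrame:
    """Write the small canonical fixtures used by the test suite.

    All synthetic, all plain text or uncompressed TIFF: a noise-free field
    plus ground truth, a negative-control field, a probe-design genome
    (FASTA), a hand-checkable count table, and a simulated regression
    dataset.  Returns a manifest with sha256 checksums.
    """
    from .probe_design import make_synthetic_phage_genome
    from .stats import simulate_beta_data
    from .synthetic_imaging import render_field, render_negative_control

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    spec = scene_for_fractions(n_cells=30, infected_frac=0.2,
                               zombie_frac=0.1, sar11_frac=0.6,
                               n_free_phage=4, seed=seed,
                               field_shape=(384, 384), noise_sd=0.0)
    field, truth = render_field(spec)
    write_field(out / "field_noisefree.tif", field)
    truth.to_csv(out / "field_noisefree_truth.tsv", sep="\t", index=False)
    files += [out / "field_noisefree.tif", out / "field_noisefree_truth.tsv"]

    neg, _ = render_negative_control(spec.replace(noise_sd=2.0))
    write_field(out / "field_negative_control.tif", neg)
    files.append(out / "field_negative_control.tif")

    (gid, gseq), genes = make_synthetic_phage_genome(length=8000, seed=seed)
    with open(out / "probe_genome.fasta", "w") as fh:
        fh.write(f">{gid}\n")
        for i in range(0, len(gseq), 80):
            fh.write(gseq[i:i + 80] + "\n")
    genes.to_csv(out / "probe_genes.tsv", sep="\t", index=False)
    files += [out / "probe_genome.fasta", out / "probe_genes.tsv"]

    counts = pd.DataFrame([
        {"sample": "s1", "reference": "magA", "reference_class": "sar11_mag",
         "mapped_reads": 1000, "length_kb": 1300.0, "total_reads": 1_000_000},
        {"sample": "s1", "reference": "magB", "reference_class": "sar11_mag",
         "mapped_reads": 250, "length_kb": 900.0, "total_reads": 1_000_000},
        {"sample": "s1", "reference": "phage1", "reference_class": "phage",
         "mapped_reads": 100, "length_kb": 50.0, "total_reads": 1_000_000},
    ])
    counts.to_csv(out / "mapping_counts.tsv", sep="\t", index=False)
    files.append(out / "mapping_counts.tsv")

    sim = simulate_beta_data(intercept=-3.72, slope=6.92, phi=30.0,
                             n=148, seed=seed)
    sim.to_csv(out / "regression_dataset.tsv", sep="\t", index=False)
    files.append(out / "regression_dataset.tsv")

    manifest = pd.DataFrame([
        {"file": f.name,
         "sha256": hashlib.sha256(f.read_bytes()).hexdigest()}
        for f in files
    ])
    manifest.to_csv(out / "MANIFEST.tsv", sep="\t", index=False)
    return manifest
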