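"""Configuration and the simulate → analyze → assign → habits pipeline."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import assignment, habit_model, nmr_forward, spectral_analysis
from .reference_data import (
    ReferenceSet,
    ialpha_reference,
    ibeta_reference,
    load_shift_table,
    poplar_reference,
)

__all__ = ["PipelineConfig", "run_pipeline", "simulate_is_ratio"]

log = logging.getLogger("fibrilshift")

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Resolved parameters for one end-to-end run."""

    shift_table: str | None = None
    habit: str = "234432"
    surface_split: dict[str, float] = field(
        default_factory=lambda: dict(nmr_forward.DEFAULT_SURFACE_SPLIT)
    )
    parity: int = 0
    lineshape: str = "lorentzian"
    fwhm: float = nmr_forward.DEFAULT_FWHM
    noise_sigma: float = 0.0
    seed: int = 0
    tolerance_ppm: float = 0.1
    hydration_threshold: float = 1.2
    pdsd_mixing_ms: float = 30.0
    habit_search: dict[str, Any] = field(
        default_factory=lambda: {
            "n_min": 18,
            "n_max": 24,
            "max_sheets": 7,
            "ratio_tol": 0.1,
            "require_equal_oc": False,
        }
    )
    contact_map: str | None = None
    water_profile: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for attr in ("shift_table", "contact_map", "water_profile"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{attr}: no such file: {value}")
        if not self.tolerance_ppm > 0:
            raise ValueError("tolerance_ppm must be > 0")
        if not self.fwhm > 0:
            raise ValueError("fwhm must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")

    def resolved(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def default_config() -> PipelineConfig:
    return PipelineConfig.from_yaml(
        Path(resources.files("fibrilshift.data") / "default_config.yaml")
    )


def _load_table(config: PipelineConfig) -> ReferenceSet:
    if config.shift_table is None:
        return poplar_reference()
    return load_shift_table(config.shift_table, tolerance_ppm=config.tolerance_ppm)


def simulate_is_ratio(
    table: ReferenceSet,
    report: habit_model.HabitReport,
    surface_split: Mapping[str, float] | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    fwhm: float = nmr_forward.DEFAULT_FWHM,
    parity: int = 0,
):
    """Round-trip helper: habit → C1 spectrum → fit → i:s ratio.

    Simulates the C1 region with per-site amplitudes proportional to the
    habit's chain multiplicities (noise relative to the spectrum
    maximum), fits it at the table's C1 positions, and recovers the
    interior:surface ratio.
    """
    multiplicities = nmr_forward.site_multiplicities(report, surface_split, parity)
    peaks = nmr_forward.peaks_from_table(
        table, carbons=(1,), amplitudes=multiplicities, fwhm=fwhm
    )
    axis = nmr_forward.make_axis(98.0, 112.0, 0.02)
    clean = nmr_forward.simulate_1d(peaks, axis=axis)
    sigma = noise_sigma * float(clean.intensity.max()) if noise_sigma > 0 else 0.0
    spectrum = nmr_forward.simulate_1d(peaks, axis=axis, noise_sigma=sigma, seed=seed)
    positions = {s.site_id: s.shift(1) for s in table.major_sites()}
    fit = spectral_analysis.fit_c1_region(spectrum, positions, fwhm=fwhm)
    return spectral_analysis.interior_surface_ratio(
        fit.amplitudes, covariance=fit.covariance, site_order=fit.site_order
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Any]:
    """Execute simulate → trace → match → ratio → habit-filter.

    Writes ``report.json`` plus the simulated spectrum (CSV), peak lists
    and habit table (TSV) under ``out_dir``; returns the report dict.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline config: %s", json.dumps(config.resolved(), sort_keys=True))

    report: dict[str, Any] = {"schema_version": SCHEMA_VERSION, "config": config.resolved()}

    log.info("stage simulate: loading table and building habit %s", config.habit)
    table = _load_table(config)
    habit = habit_model.Habit.from_string(config.habit)
    hr = habit_model.habit_report(habit)
    multiplicities = nmr_forward.site_multiplicities(
        hr, config.surface_split, config.parity
    )
    report["habit"] = {
        "habit": str(habit),
        "n_chains": hr.n_chains,
        "n_interior": hr.n_interior,
        "n_surface": hr.n_surface,
        "is_ratio": hr.is_ratio,
        "origin_center_interior": [list(x) for x in hr.origin_center_interior],
    }
    report["multiplicities"] = multiplicities

    majors = table.major_sites()
    inadequate = nmr_forward.simulate_inadequate(majors, amplitudes=multiplicities)
    inadequate.write_tsv(out / "inadequate.tsv")

    peaks1d = nmr_forward.peaks_from_table(
        table, amplitudes=multiplicities, fwhm=config.fwhm
    )
    spectrum = nmr_forward.simulate_1d(
        peaks1d,
        lineshape=config.lineshape,
        noise_sigma=config.noise_sigma,
        seed=config.seed,
    )
    spectrum.write_csv(out / "spectrum_1d.csv")

    log.info("stage trace: spin-system tracing at tol %.3g ppm", config.tolerance_ppm)
    systems = spectral_analysis.trace_spin_systems(
        inadequate, tol=config.tolerance_ppm, table=table
    )
    report["spin_systems"] = [
        {
            "shifts": [None if math.isnan(v) else v for v in s.shifts],
            "complete": s.complete,
            "ambiguous": s.ambiguous,
            "site_id": s.site_id,
        }
        for s in systems
    ]
    report["n_complete_systems"] = sum(s.complete for s in systems)

    log.info("stage assign: allomorph matching")
    complete = [s for s in systems if s.complete]
    allomorphs = assignment.classify_allomorphs(
        complete, ibeta_reference(), ialpha_reference(), tol=config.tolerance_ppm
    )
    report["allomorphs"] = {
        "ibeta_present": allomorphs.ibeta_present,
        "ialpha_present": allomorphs.ialpha_present,
        "ialpha_probe_hits": list(allomorphs.ialpha.probe_hits),
        "ibeta_matches": [
            {
                "system_index": m.system_index,
                "reference_site": m.reference_site,
                "max_abs_deviation": m.max_abs_deviation,
                "verdict": m.verdict,
            }
            for m in allomorphs.ibeta_matches
        ],
    }

    log.info("stage ratio: C1-region fit and i:s")
    c1_positions = {
        s.site_id: s.shift(1) for s in complete if s.site_id is not None
    } or {s.site_id: s.shift(1) for s in majors}
    c1_axis = nmr_forward.make_axis(98.0, 112.0, 0.02)
    c1_peaks = nmr_forward.peaks_from_table(
        table, carbons=(1,), amplitudes=multiplicities, fwhm=config.fwhm
    )
    clean = nmr_forward.simulate_1d(c1_peaks, axis=c1_axis)
    sigma = (
        config.noise_sigma * float(clean.intensity.max())
        if config.noise_sigma > 0
        else 0.0
    )
    c1_spectrum = nmr_forward.simulate_1d(
        c1_peaks, axis=c1_axis, noise_sigma=sigma, seed=config.seed
    )
    fit = spectral_analysis.fit_c1_region(c1_spectrum, c1_positions, fwhm=config.fwhm)
    is_result = spectral_analysis.interior_surface_ratio(
        fit.amplitudes, covariance=fit.covariance, site_order=fit.site_order
    )
    report["is_ratio"] = {
        "ratio": is_result.ratio,
        "sigma": is_result.sigma,
        "defined": is_result.defined,
        "amplitudes": fit.amplitudes,
    }

    ci = spectral_analysis.crystallinity_index(spectrum)
    report["crystallinity"] = {
        "ci": None if not ci.defined else ci.ci,
        "d1_d2_ratio": None if not ci.defined else ci.d1_d2_ratio,
        "defined": ci.defined,
    }

    log.info("stage water: enhancement factors")
    profile = (
        nmr_forward.default_water_edit_profile()
        if config.water_profile is None
        else nmr_forward.WaterEditProfile.from_yaml(config.water_profile)
    )
    contact_map = (
        nmr_forward.default_contact_map()
        if config.contact_map is None
        else nmr_forward.load_contact_map(config.contact_map)
    )
    standard = nmr_forward.simulate_pdsd(
        majors, config.pdsd_mixing_ms, contact_map=contact_map,
        amplitudes=multiplicities,
    )
    edited = nmr_forward.apply_water_edit(standard, profile)
    water = spectral_analysis.enhancement_factors(
        standard, edited, threshold=config.hydration_threshold
    )
    report["water_edit"] = {
        "hydrated_at_c4": sorted(
            site for (site, carbon), flag in water.hydrated.items()
            if carbon == 4 and flag
        ),
        "factors": {
            f"{site}:C{carbon}": value
            for (site, carbon), value in sorted(water.factors.items())
        },
    }

    log.info("stage habits: enumeration and filtering")
    search = config.habit_search
    candidates = habit_model.enumerate_habits(
        search["n_min"], search["n_max"], search["max_sheets"]
    )
    kept = habit_model.filter_habits(
        candidates,
        target_ratio=is_result.ratio,
        tol=search["ratio_tol"],
        require_equal_oc=search["require_equal_oc"],
    )
    report["habit_candidates"] = [
        {
            "habit": str(r.habit),
            "n_chains": r.n_chains,
            "n_interior": r.n_interior,
            "n_surface": r.n_surface,
            "ratio": r.is_ratio,
            "oc_parity0": list(r.origin_center_interior[0]),
            "oc_parity1": list(r.origin_center_interior[1]),
        }
        for r in kept
    ]
    write_habit_tsv(kept, out / "habits.tsv")

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("pipeline complete: %s", out / "report.json")
    return report


def write_habit_tsv(reports, path: str | Path) -> None:
    lines = ["habit\tn_chains\tn_interior\tn_surface\tratio\toc_parity0\toc_parity1"]
    for r in reports:
        o0, c0 = r.origin_center_interior[0]
        o1, c1 = r.origin_center_interior[1]
        lines.append(
            f"{r.habit}\t{r.n_chains}\t{r.n_interior}\t{r.n_surface}"
            f"\t{r.is_ratio:.6g}\t{o0}:{c0}\t{o1}:{c1}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
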