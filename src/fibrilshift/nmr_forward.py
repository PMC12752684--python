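"""Forward simulation of 1D and 2D ¹³C MAS NMR observables of cellulose.

The synthetic-data generator of the package: it turns a shift table
(plus, optionally, a habit's chain multiplicities) into

* 1D spectra — sums of Lorentzian/Gaussian resonances on a ppm grid with
  seeded additive Gaussian noise;
* refocused-INADEQUATE peak lists — for every directly bonded carbon
  pair the double-quantum (DQ) coordinate is the sum of the two
  single-quantum (SQ) shifts, and each pair emits one peak per SQ
  position;
* proton-driven spin-diffusion (PDSD) peak lists — all intra-ring
  carbon pairs at any mixing time, plus inter-site contacts that only
  appear once the mixing time reaches a contact's threshold;
* water-edited variants, in which each site (and optionally each
  carbon) is scaled by a hydration enhancement factor.

Amplitudes are arbitrary units; cross-polarisation dynamics and
relaxation are deliberately ignored.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .habit_model import HabitReport
from .reference_data import CARBONS, SHIFT_RANGE, ReferenceSet, SiteShifts

__all__ = [
    "Peak1D",
    "Spectrum1D",
    "CrossPeak",
    "CrossPeakList",
    "Contact",
    "WaterEditProfile",
    "BONDED_PAIRS",
    "DEFAULT_FWHM",
    "make_axis",
    "site_multiplicities",
    "DEFAULT_SURFACE_SPLIT",
    "peaks_from_table",
    "simulate_1d",
    "simulate_inadequate",
    "simulate_pdsd",
    "apply_water_edit",
    "default_contact_map",
    "default_water_edit_profile",
]

#: Directly bonded carbon pairs along the glucose ring.
BONDED_PAIRS = ((1, 2), (2, 3), (3, 4), (4, 5), (5, 6))

#: Default full width at half maximum, ppm.  Linewidths of the major
#: domain-1 and domain-2 environments are comparable, so one default
#: serves all sites; override per peak where needed.
DEFAULT_FWHM = 0.5

#: Default split of surface-chain intensity over the four major surface
#: environments (site b plus the three domain-2 sites), as fractions.
DEFAULT_SURFACE_SPLIT = {"b": 2 / 12, "f": 4 / 12, "g": 3 / 12, "j": 3 / 12}


@dataclass(frozen=True)
class Peak1D:
    """A single 1D resonance."""

    site_id: str
    carbon: int
    position: float
    fwhm: float = DEFAULT_FWHM
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.carbon not in CARBONS:
            raise ValueError(f"carbon must be 1–6, got {self.carbon}")
        lo, hi = SHIFT_RANGE
        if not lo <= self.position <= hi:
            raise ValueError(f"peak position {self.position} outside [{lo}, {hi}]")
        if not self.fwhm > 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class Spectrum1D:
    """A ppm axis (strictly descending, NMR convention) with intensities."""

    axis: np.ndarray
    intensity: np.ndarray
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if axis.ndim != 1 or axis.shape != intensity.shape:
            raise ValueError("axis and intensity must be 1-D and equal length")
        if not np.all(np.diff(axis) < 0):
            raise ValueError("axis must be strictly descending in ppm")
        if not np.all(np.isfinite(intensity)):
            raise ValueError("intensity must be finite")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)

    @property
    def step(self) -> float:
        return float(abs(self.axis[1] - self.axis[0]))

    def write_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.axis, self.intensity]),
            delimiter=",",
            header="ppm,intensity",
            comments="",
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "Spectrum1D":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(axis=data[:, 0], intensity=data[:, 1])


@dataclass(frozen=True)
class CrossPeak:
    """One 2D peak; dims are (SQ, DQ) for INADEQUATE, (ppm, ppm) for PDSD."""

    dim1: float
    dim2: float
    amplitude: float
    site_i: str
    carbon_i: int
    site_j: str
    carbon_j: int


@dataclass(frozen=True)
class CrossPeakList:
    """A 2D peak list tagged with the experiment that produced it."""

    experiment: str  # "inadequate" | "pdsd"
    peaks: tuple[CrossPeak, ...]
    mixing_time_ms: float | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("inadequate", "pdsd"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        object.__setattr__(self, "peaks", tuple(self.peaks))

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(
                ["dim1", "dim2", "amplitude", "site_i", "carbon_i", "site_j", "carbon_j"]
            )
            for p in self.peaks:
                writer.writerow(
                    [f"{p.dim1:.4f}", f"{p.dim2:.4f}", f"{p.amplitude:.6g}",
                     p.site_i, p.carbon_i, p.site_j, p.carbon_j]
                )

    @classmethod
    def read_tsv(
        cls, path: str | Path, experiment: str, mixing_time_ms: float | None = None
    ) -> "CrossPeakList":
        peaks = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                peaks.append(
                    CrossPeak(
                        dim1=float(row["dim1"]),
                        dim2=float(row["dim2"]),
                        amplitude=float(row["amplitude"]),
                        site_i=row["site_i"],
                        carbon_i=int(row["carbon_i"]),
                        site_j=row["site_j"],
                        carbon_j=int(row["carbon_j"]),
                    )
                )
        return cls(experiment=experiment, peaks=tuple(peaks), mixing_time_ms=mixing_time_ms)


@dataclass(frozen=True)
class Contact:
    """An inter-site through-space contact that lights up at long mixing."""

    site_i: str
    carbon_i: int
    site_j: str
    carbon_j: int
    min_mixing_ms: float
    relative_amplitude: float

    def __post_init__(self) -> None:
        if not self.min_mixing_ms > 0:
            raise ValueError("min_mixing_ms must be > 0")
        if not 0 < self.relative_amplitude <= 1:
            raise ValueError("relative_amplitude must be in (0, 1]")


@dataclass(frozen=True)
class WaterEditProfile:
    """Per-site (optionally per-carbon) water-edit enhancement factors."""

    site_factors: Mapping[str, float]
    carbon_overrides: Mapping[str, Mapping[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, w in self.site_factors.items():
            if not (math.isfinite(w) and w >= 0):
                raise ValueError(f"factor for site {site!r} must be finite and >= 0")
        for site, per_carbon in self.carbon_overrides.items():
            for carbon, w in per_carbon.items():
                if not (math.isfinite(w) and w >= 0):
                    raise ValueError(
                        f"override for site {site!r} carbon {carbon} invalid"
                    )

    def factor(self, site_id: str, carbon: int) -> float:
        if site_id not in self.site_factors:
            raise KeyError(f"site {site_id!r} missing from water-edit profile")
        override = self.carbon_overrides.get(site_id, {})
        return float(override.get(carbon, self.site_factors[site_id]))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WaterEditProfile":
        raw = yaml.safe_load(Path(path).read_text())
        overrides = {
            site: {int(c): float(w) for c, w in per_carbon.items()}
            for site, per_carbon in (raw.get("carbon_overrides") or {}).items()
        }
        return cls(
            site_factors={s: float(w) for s, w in raw["site_factors"].items()},
            carbon_overrides=overrides,
        )


def _packaged(filename: str) -> Path:
    return Path(resources.files("fibrilshift.data") / filename)


def default_contact_map() -> tuple[Contact, ...]:
    """Packaged inter-site contacts: a↔c C1 at ≥200 ms; C4 contacts from
    a and b to the domain-2 sites at ≥400 ms, weaker ones from c."""
    contacts = []
    with open(_packaged("contact_map.tsv"), newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            contacts.append(
                Contact(
                    site_i=row["site_i"],
                    carbon_i=int(row["carbon_i"]),
                    site_j=row["site_j"],
                    carbon_j=int(row["carbon_j"]),
                    min_mixing_ms=float(row["min_mixing_ms"]),
                    relative_amplitude=float(row["relative_amplitude"]),
                )
            )
    return tuple(contacts)


def load_contact_map(path: str | Path) -> tuple[Contact, ...]:
    contacts = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            contacts.append(
                Contact(
                    site_i=row["site_i"],
                    carbon_i=int(row["carbon_i"]),
                    site_j=row["site_j"],
                    carbon_j=int(row["carbon_j"]),
                    min_mixing_ms=float(row["min_mixing_ms"]),
                    relative_amplitude=float(row["relative_amplitude"]),
                )
            )
    return tuple(contacts)


def default_water_edit_profile() -> WaterEditProfile:
    """Packaged hydration profile: domain-2 sites and b enhanced, core not."""
    return WaterEditProfile.from_yaml(_packaged("water_edit.yaml"))


def site_multiplicities(
    habit_report: HabitReport,
    surface_split: Mapping[str, float] | None = None,
    parity: int = 0,
) -> dict[str, float]:
    """Chain counts per NMR site implied by a habit.

    Interior origin chains count toward site a, interior center chains
    toward site c; surface intensity is split over the surface sites by
    ``surface_split`` (fractions summing to 1).  Fractional counts are
    allowed: NMR is a bulk measurement, so the spectrum averages over an
    ensemble of fibrils.
    """
    split = dict(DEFAULT_SURFACE_SPLIT if surface_split is None else surface_split)
    total = sum(split.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"surface split fractions must sum to 1, got {total}")
    n_origin, n_center = habit_report.origin_center_interior[parity]
    counts = {"a": float(n_origin), "c": float(n_center)}
    for site, fraction in split.items():
        counts[site] = habit_report.n_surface * fraction
    return counts


def make_axis(lo: float = 55.0, hi: float = 115.0, step: float = 0.02) -> np.ndarray:
    """A descending ppm grid covering [lo, hi]."""
    if not (lo < hi and step > 0):
        raise ValueError("need lo < hi and step > 0")
    n = int(round((hi - lo) / step)) + 1
    return hi - step * np.arange(n)


def peaks_from_table(
    table: ReferenceSet | Iterable[SiteShifts],
    carbons: Iterable[int] = CARBONS,
    amplitudes: Mapping[str, float] | None = None,
    fwhm: float | Mapping[str, float] = DEFAULT_FWHM,
    major_only: bool = True,
) -> list[Peak1D]:
    """Expand a shift table into 1D peaks for the requested carbons."""
    sites = list(table)
    if major_only:
        sites = [s for s in sites if s.is_major]
    peaks = []
    for site in sites:
        amp = 1.0 if amplitudes is None else float(amplitudes.get(site.site_id, 0.0))
        if amp == 0.0:
            continue
        width = fwhm[site.site_id] if isinstance(fwhm, Mapping) else fwhm
        for carbon in carbons:
            position = site.shift(carbon)
            if math.isnan(position):
                continue
            peaks.append(Peak1D(site.site_id, carbon, position, width, amp))
    return peaks


def _lineshape(axis: np.ndarray, position: float, fwhm: float, kind: str) -> np.ndarray:
    if kind == "lorentzian":
        gamma = fwhm / 2.0
        return gamma**2 / ((axis - position) ** 2 + gamma**2)
    if kind == "gaussian":
        sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        return np.exp(-0.5 * ((axis - position) / sigma) ** 2)
    raise ValueError(f"unknown lineshape {kind!r}")


def simulate_1d(
    peaks: Sequence[Peak1D],
    axis: np.ndarray | None = None,
    lineshape: str = "lorentzian",
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> Spectrum1D:
    """Sum unit-height lineshapes plus seeded Gaussian noise.

    With ``noise_sigma=0`` the output is deterministic; the same seed
    always reproduces the identical spectrum.
    """
    if axis is None:
        axis = make_axis()
    axis = np.asarray(axis, dtype=float)
    intensity = np.zeros_like(axis)
    lo, hi = float(axis.min()), float(axis.max())
    for peak in peaks:
        if not lo <= peak.position <= hi:
            warnings.warn(
                f"peak {peak.site_id} C{peak.carbon} at {peak.position} ppm "
                f"outside axis [{lo}, {hi}]; skipped",
                stacklevel=2,
            )
            continue
        intensity += peak.amplitude * _lineshape(axis, peak.position, peak.fwhm, lineshape)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + noise_sigma * rng.standard_normal(axis.shape)
    return Spectrum1D(axis=axis, intensity=intensity, noise_sigma=noise_sigma, seed=seed)


def simulate_inadequate(
    sites: Iterable[SiteShifts],
    amplitudes: Mapping[str, float] | None = None,
) -> CrossPeakList:
    """Refocused-INADEQUATE peak list: two (SQ, DQ) peaks per bonded pair."""
    sites = list(sites)
    if not sites:
        raise ValueError("need at least one site")
    peaks = []
    for site in sites:
        amp = 1.0 if amplitudes is None else float(amplitudes.get(site.site_id, 0.0))
        if amp == 0.0:
            continue
        for ci, cj in BONDED_PAIRS:
            di, dj = site.shift(ci), site.shift(cj)
            if math.isnan(di) or math.isnan(dj):
                continue
            dq = di + dj
            peaks.append(CrossPeak(di, dq, amp, site.site_id, ci, site.site_id, cj))
            peaks.append(CrossPeak(dj, dq, amp, site.site_id, cj, site.site_id, ci))
    return CrossPeakList(experiment="inadequate", peaks=tuple(peaks))


def simulate_pdsd(
    sites: Iterable[SiteShifts],
    mixing_time_ms: float,
    contact_map: Sequence[Contact] | None = None,
    amplitudes: Mapping[str, float] | None = None,
) -> CrossPeakList:
    """PDSD peak list at a given mixing time.

    Intra-ring carbon pairs always correlate; inter-site contacts appear
    only once ``mixing_time_ms`` reaches the contact's threshold, scaled
    by its relative amplitude.  Peak lists are symmetric about the
    diagonal.
    """
    if not mixing_time_ms > 0:
        raise ValueError("mixing_time_ms must be > 0")
    sites = list(sites)
    by_id = {s.site_id: s for s in sites}
    if contact_map is None:
        contact_map = default_contact_map()

    def amp_of(site_id: str) -> float:
        return 1.0 if amplitudes is None else float(amplitudes.get(site_id, 0.0))

    peaks = []
    for site in sites:
        amp = amp_of(site.site_id)
        if amp == 0.0:
            continue
        for ci, cj in ((i, j) for i in CARBONS for j in CARBONS if i < j):
            di, dj = site.shift(ci), site.shift(cj)
            if math.isnan(di) or math.isnan(dj):
                continue
            peaks.append(CrossPeak(di, dj, amp, site.site_id, ci, site.site_id, cj))
            peaks.append(CrossPeak(dj, di, amp, site.site_id, cj, site.site_id, ci))
    for contact in contact_map:
        if contact.min_mixing_ms > mixing_time_ms:
            continue
        if contact.site_i not in by_id or contact.site_j not in by_id:
            continue
        amp = math.sqrt(amp_of(contact.site_i) * amp_of(contact.site_j))
        if amp == 0.0:
            continue
        di = by_id[contact.site_i].shift(contact.carbon_i)
        dj = by_id[contact.site_j].shift(contact.carbon_j)
        if math.isnan(di) or math.isnan(dj):
            continue
        scaled = amp * contact.relative_amplitude
        peaks.append(
            CrossPeak(di, dj, scaled, contact.site_i, contact.carbon_i,
                      contact.site_j, contact.carbon_j)
        )
        peaks.append(
            CrossPeak(dj, di, scaled, contact.site_j, contact.carbon_j,
                      contact.site_i, contact.carbon_i)
        )
    return CrossPeakList(experiment="pdsd", peaks=tuple(peaks), mixing_time_ms=mixing_time_ms)


def apply_water_edit(
    peaks: CrossPeakList | Sequence[Peak1D],
    profile: WaterEditProfile,
):
    """Scale a peak list by water-edit enhancement factors.

    1D peaks scale by the factor of their (site, carbon); 2D cross-peaks
    scale by the geometric mean of the factors of their two (site,
    carbon) ends, since both spins must carry water-derived
    magnetization.
    """
    if isinstance(peaks, CrossPeakList):
        edited = tuple(
            replace(
                p,
                amplitude=p.amplitude
                * math.sqrt(
                    profile.factor(p.site_i, p.carbon_i)
                    * profile.factor(p.site_j, p.carbon_j)
                ),
            )
            for p in peaks
        )
        return CrossPeakList(
            experiment=peaks.experiment, peaks=edited, mixing_time_ms=peaks.mixing_time_ms
        )
    return [
        replace(p, amplitude=p.amplitude * profile.factor(p.site_id, p.carbon))
        for p in peaks
    ]
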