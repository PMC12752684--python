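"""Recover site information from simulated or imported cellulose spectra.

Inverse operations to the forward simulator: 1D peak picking with
sub-grid parabolic refinement, spin-system tracing through INADEQUATE
DQ–SQ peak lists, window integration, the domain-1/domain-2 ratio and
"crystallinity index", constrained fitting of the C1 region into
per-site amplitudes, the interior:surface chain ratio, and water-edit
enhancement factors.

A note on the crystallinity index: CI = I(D1) / (I(D1) + I(D2)) over
the C4 region is implemented here because it is ubiquitous in the
cellulose literature, but it is not a meaningful measure of fibril
crystallinity.  The domain split tracks the C6 hydroxymethyl
conformation (tg vs gt/gg), and one domain-1 environment (site b) is a
hydrated, probably surface, site — so CI systematically overestimates
the interior fraction of the fibril.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar, nnls
from scipy.signal import find_peaks

from .nmr_forward import DEFAULT_FWHM, CrossPeakList, Spectrum1D, _lineshape
from .reference_data import CARBONS, ReferenceSet

__all__ = [
    "SpinSystem",
    "CrystallinityResult",
    "C1FitResult",
    "IsRatioResult",
    "EnhancementReport",
    "CARBON_WINDOWS",
    "pick_peaks_1d",
    "trace_spin_systems",
    "integrate_window",
    "crystallinity_index",
    "fit_c1_region",
    "interior_surface_ratio",
    "enhancement_factors",
]

#: Plausible ppm windows for each glucose ring carbon, used to gate the
#: spin-system walk (C1 anomeric ~105, C4 ~84–89, C6 ~61–66, the rest
#: crowded in 69–78).
CARBON_WINDOWS: dict[int, tuple[float, float]] = {
    1: (100.0, 110.0),
    2: (68.0, 80.0),
    3: (68.0, 80.0),
    4: (80.0, 93.0),
    5: (68.0, 80.0),
    6: (58.0, 68.0),
}


@dataclass(frozen=True)
class SpinSystem:
    """Six traced C1…C6 shifts for one glucose environment.

    ``complete`` is True when all six carbons were linked through shared
    DQ coordinates; NaN marks untraced carbons.  ``ambiguous`` flags
    systems for which some link had more than one partner within
    tolerance (branches were explored; the best-scoring one is kept).
    """

    shifts: tuple[float, ...]
    complete: bool
    ambiguous: bool = False
    site_id: str | None = None
    amplitude: float = 1.0

    def shift(self, carbon: int) -> float:
        return self.shifts[carbon - 1]


# ---------------------------------------------------------------------------
# 1D operations


def pick_peaks_1d(
    spectrum: Spectrum1D,
    min_height: float = 0.05,
    min_separation: float = 0.1,
) -> np.ndarray:
    """Local maxima above ``min_height``·max, parabolic sub-grid refinement.

    Returns peak positions in ppm, descending.  A flat or all-zero
    spectrum yields an empty array.
    """
    y = spectrum.intensity
    top = float(y.max())
    if top <= 0 or np.allclose(y, y[0]):
        return np.array([])
    distance = max(1, int(round(min_separation / spectrum.step)))
    idx, _ = find_peaks(y, height=min_height * top, distance=distance)
    positions = []
    for i in idx:
        if 0 < i < len(y) - 1:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
        else:
            delta = 0.0
        # axis is descending: moving +1 in index moves -step in ppm
        positions.append(float(spectrum.axis[i] - delta * spectrum.step))
    return np.array(sorted(positions, reverse=True))


def integrate_window(spectrum: Spectrum1D, lo: float, hi: float) -> float:
    """Trapezoidal integral of intensity over [lo, hi] ppm."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    axis_lo, axis_hi = float(spectrum.axis.min()), float(spectrum.axis.max())
    if lo < axis_lo or hi > axis_hi:
        raise ValueError(
            f"window [{lo}, {hi}] outside axis [{axis_lo}, {axis_hi}]"
        )
    mask = (spectrum.axis >= lo) & (spectrum.axis <= hi)
    # integrate on an ascending copy so the area is positive
    x = spectrum.axis[mask][::-1]
    y = spectrum.intensity[mask][::-1]
    return float(np.trapezoid(y, x))


@dataclass(frozen=True)
class CrystallinityResult:
    """Domain-1 fraction of the C4 region; see the module caveat on CI."""

    ci: float
    d1_area: float
    d2_area: float
    d1_d2_ratio: float
    defined: bool


def crystallinity_index(
    spectrum: Spectrum1D,
    boundary_ppm: float = 86.5,
    d1_window: tuple[float, float] = (86.5, 92.0),
    d2_window: tuple[float, float] = (80.0, 86.5),
) -> CrystallinityResult:
    """CI = I(D1)/(I(D1)+I(D2)) over the C4 region, plus the D1:D2 ratio.

    Implemented for comparability with the literature; this is *not* a
    measure of crystallinity (see module docstring).
    """
    for window in (d1_window, d2_window):
        if not (80.0 <= window[0] < window[1] <= 92.0):
            raise ValueError(f"window {window} outside the C4 region [80, 92]")
    d1 = integrate_window(spectrum, *d1_window)
    d2 = integrate_window(spectrum, *d2_window)
    total = d1 + d2
    if total <= 0:
        return CrystallinityResult(math.nan, d1, d2, math.nan, defined=False)
    ratio = d1 / d2 if d2 > 0 else math.inf
    return CrystallinityResult(d1 / total, d1, d2, ratio, defined=True)


# ---------------------------------------------------------------------------
# spin-system tracing


@dataclass(frozen=True)
class _PairRow:
    """One DQ row: a bonded pair observed at two SQ positions."""

    sq1: float
    sq2: float
    dq: float
    amplitude: float

    def partner(self, sq: float) -> float:
        return self.sq2 if abs(sq - self.sq1) <= abs(sq - self.sq2) else self.sq1


def _pair_rows(peaks: CrossPeakList, tol: float) -> list[_PairRow]:
    """Reassemble (SQ, DQ) entries into bonded-pair rows.

    Two entries belong to the same row when their DQ coordinates agree
    within tol and their SQ positions sum to that DQ within tol.  Greedy
    minimum-error matching resolves collisions between rows whose DQ
    coordinates accidentally coincide.
    """
    entries = list(peaks)
    candidates = []
    for i in range(len(entries)):
        for j in range(i + 1, len(entries)):
            a, b = entries[i], entries[j]
            if abs(a.dim2 - b.dim2) > tol:
                continue
            dq = 0.5 * (a.dim2 + b.dim2)
            sum_err = abs(a.dim1 + b.dim1 - dq)
            if sum_err > tol:
                continue
            candidates.append((sum_err + abs(a.dim2 - b.dim2), i, j))
    candidates.sort()
    used: set[int] = set()
    rows = []
    for _, i, j in candidates:
        if i in used or j in used:
            continue
        used.update((i, j))
        a, b = entries[i], entries[j]
        rows.append(
            _PairRow(
                sq1=a.dim1,
                sq2=b.dim1,
                dq=0.5 * (a.dim2 + b.dim2),
                amplitude=0.5 * (a.amplitude + b.amplitude),
            )
        )
    return rows


def _candidate_links(
    rows: Sequence[_PairRow],
    used: set[int],
    shift: float,
    next_carbon: int,
    tol: float,
) -> list[tuple[float, float, int]]:
    """Rows that could link ``shift`` to carbon ``next_carbon``.

    Ordered closest-shift-first, then by DQ, for deterministic walks.
    """
    lo, hi = CARBON_WINDOWS[next_carbon]
    out = []
    for k, row in enumerate(rows):
        if k in used:
            continue
        err = min(abs(shift - row.sq1), abs(shift - row.sq2))
        if err > tol:
            continue
        partner = row.partner(shift)
        if not lo <= partner <= hi:
            continue
        out.append((err, row.dq, k))
    out.sort()
    return out


def trace_spin_systems(
    peaks: CrossPeakList,
    tol: float = 0.1,
    table: ReferenceSet | None = None,
) -> list[SpinSystem]:
    """Walk DQ–SQ peak lists into six-carbon spin systems.

    Starting from C1 candidates (SQ above 100 ppm), each DQ row pairs a
    carbon with its bonded partner; chaining via the shared SQ shift
    follows C1→C2→…→C6.  Each pair row is consumed by at most one
    system; when several partners lie within tolerance all branches are
    explored (closest-shift-first) and the system is flagged ambiguous.
    Incomplete walks are returned with ``complete=False``.  If ``table``
    is given, complete systems are labelled with the best-matching site.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    if peaks.experiment != "inadequate":
        raise ValueError("spin-system tracing expects an INADEQUATE peak list")
    rows = _pair_rows(peaks, tol)

    c1_lo, _ = CARBON_WINDOWS[1]
    seeds = []
    for k, row in enumerate(rows):
        for c1, c2 in ((row.sq1, row.sq2), (row.sq2, row.sq1)):
            lo2, hi2 = CARBON_WINDOWS[2]
            if c1 > c1_lo and lo2 <= c2 <= hi2:
                seeds.append((c1, c2, k))
                break
    seeds.sort(reverse=True)  # descending C1

    used: set[int] = set()
    systems = []
    for c1, c2, seed_row in seeds:
        if seed_row in used:
            continue
        used.add(seed_row)
        amplitude = rows[seed_row].amplitude
        ambiguous = False
        best_partial = [c1, c2]

        def walk(shifts: list[float]) -> list[float] | None:
            nonlocal ambiguous, best_partial
            carbon = len(shifts)
            if carbon == len(CARBONS):
                return shifts
            cands = _candidate_links(rows, used, shifts[-1], carbon + 1, tol)
            if len(cands) > 1:
                ambiguous = True
            for _, _, k in cands:
                used.add(k)
                result = walk(shifts + [rows[k].partner(shifts[-1])])
                if result is not None:
                    return result
                used.discard(k)
            if len(shifts) > len(best_partial):
                best_partial = list(shifts)
            return None

        traced = walk([c1, c2])
        if traced is None:
            shifts = tuple(best_partial) + (math.nan,) * (len(CARBONS) - len(best_partial))
            systems.append(
                SpinSystem(shifts=shifts, complete=False, ambiguous=ambiguous,
                           amplitude=amplitude)
            )
        else:
            systems.append(
                SpinSystem(shifts=tuple(traced), complete=True, ambiguous=ambiguous,
                           amplitude=amplitude)
            )

    if table is not None:
        labelled = []
        for system in systems:
            site_id = None
            if system.complete:
                best = math.inf
                for site in table:
                    devs = [
                        abs(system.shift(c) - site.shift(c))
                        for c in CARBONS
                        if not math.isnan(site.shift(c))
                    ]
                    if devs and max(devs) < best:
                        best = max(devs)
                        best_site = site.site_id
                if best <= tol:
                    site_id = best_site
            labelled.append(
                SpinSystem(system.shifts, system.complete, system.ambiguous,
                           site_id, system.amplitude)
            )
        systems = labelled
    return systems


# ---------------------------------------------------------------------------
# C1-region fitting and ratios


@dataclass(frozen=True)
class C1FitResult:
    """Per-site amplitudes from a fixed-position fit of the C1 region."""

    amplitudes: dict[str, float]
    site_order: tuple[str, ...]
    fwhm: float
    residual_norm: float
    covariance: np.ndarray


def fit_c1_region(
    spectrum: Spectrum1D,
    positions: Mapping[str, float],
    fwhm: float = DEFAULT_FWHM,
    lineshape: str = "lorentzian",
    fit_fwhm: bool = False,
    window: tuple[float, float] = (100.0, 110.0),
) -> C1FitResult:
    """Non-negative least-squares amplitudes at fixed C1 positions.

    Positions come from the resolved 2D spectrum (traced spin systems)
    and are held fixed — blind 1D deconvolution with free positions and
    widths is exactly the unstable procedure this analysis avoids.  A
    shared linewidth is used for all sites; with ``fit_fwhm`` it may
    float within ±50% of the initial value.
    """
    if not positions:
        raise ValueError("need at least one site position")
    for site, pos in positions.items():
        if not 100.0 <= pos <= 110.0:
            raise ValueError(f"C1 position for {site!r} at {pos} outside [100, 110]")
    mask = (spectrum.axis >= window[0]) & (spectrum.axis <= window[1])
    if not mask.any():
        raise ValueError(f"window {window} outside the spectrum axis")
    x = spectrum.axis[mask]
    y = spectrum.intensity[mask]
    order = tuple(positions)

    def design(width: float) -> np.ndarray:
        return np.column_stack(
            [_lineshape(x, positions[s], width, lineshape) for s in order]
        )

    def solve(width: float):
        amps, rnorm = nnls(design(width), y)
        return amps, rnorm

    if fit_fwhm:
        res = minimize_scalar(
            lambda w: solve(w)[1], bounds=(0.5 * fwhm, 1.5 * fwhm), method="bounded"
        )
        if not res.success:
            raise RuntimeError(f"linewidth optimisation failed: {res.message}")
        fwhm = float(res.x)
    amps, rnorm = solve(fwhm)

    a_matrix = design(fwhm)
    dof = max(len(y) - len(order), 1)
    sigma2 = rnorm**2 / dof
    covariance = sigma2 * np.linalg.pinv(a_matrix.T @ a_matrix)
    return C1FitResult(
        amplitudes={s: float(a) for s, a in zip(order, amps)},
        site_order=order,
        fwhm=fwhm,
        residual_norm=float(rnorm),
        covariance=covariance,
    )


@dataclass(frozen=True)
class IsRatioResult:
    """Interior:surface chain ratio with a propagated ± band."""

    ratio: float
    sigma: float
    defined: bool
    core_sum: float
    surface_sum: float


def interior_surface_ratio(
    amplitudes: Mapping[str, float],
    core_ids: Sequence[str] = ("a", "c"),
    surface_ids: Sequence[str] = ("b", "f", "g", "j"),
    covariance: np.ndarray | None = None,
    site_order: Sequence[str] | None = None,
) -> IsRatioResult:
    """i:s = Σ(core amplitudes) / Σ(surface amplitudes).

    If the amplitude covariance from :func:`fit_c1_region` is supplied,
    the uncertainty is propagated through the ratio.
    """
    missing = [s for s in (*core_ids, *surface_ids) if s not in amplitudes]
    if missing:
        raise KeyError(f"amplitudes missing for site(s) {missing}")
    core = sum(amplitudes[s] for s in core_ids)
    surface = sum(amplitudes[s] for s in surface_ids)
    if surface <= 0:
        return IsRatioResult(math.nan, math.nan, False, core, surface)
    ratio = core / surface
    sigma = math.nan
    if covariance is not None and site_order is not None:
        grad = np.zeros(len(site_order))
        for k, site in enumerate(site_order):
            if site in core_ids:
                grad[k] = 1.0 / surface
            elif site in surface_ids:
                grad[k] = -core / surface**2
        sigma = float(math.sqrt(max(grad @ covariance @ grad, 0.0)))
    return IsRatioResult(ratio, sigma, True, core, surface)


# ---------------------------------------------------------------------------
# water-edit analysis


@dataclass(frozen=True)
class EnhancementReport:
    """Per-(site, carbon) water-edit factors and hydration verdicts."""

    factors: dict[tuple[str, int], float]
    hydrated: dict[tuple[str, int], bool]
    threshold: float
    normalize_to: str

    def factor(self, site_id: str, carbon: int) -> float:
        return self.factors[(site_id, carbon)]

    def site_hydrated(self, site_id: str, carbon: int = 4) -> bool:
        return self.hydrated[(site_id, carbon)]


def enhancement_factors(
    standard: CrossPeakList,
    edited: CrossPeakList,
    normalize_to: str = "a",
    threshold: float = 1.2,
) -> EnhancementReport:
    """Per-site, per-carbon enhancement = edited/standard amplitude.

    Peaks are matched by their (site, carbon, site, carbon) labels; each
    (site, carbon) is summarised by the median ratio over every peak in
    which it takes part, then normalised to the reference site (the
    hydration contrast, not the absolute scaling, is meaningful).  A
    (site, carbon) is classified hydrated when its normalised factor
    exceeds ``threshold``.
    """
    std = {}
    for p in standard:
        std[(p.site_i, p.carbon_i, p.site_j, p.carbon_j)] = p.amplitude
    ratios: dict[tuple[str, int], list[float]] = {}
    for p in edited:
        key = (p.site_i, p.carbon_i, p.site_j, p.carbon_j)
        if key not in std or std[key] <= 0:
            continue
        ratios.setdefault((p.site_i, p.carbon_i), []).append(p.amplitude / std[key])

    factors = {key: statistics.median(vals) for key, vals in ratios.items()}
    norm_vals = [f for (site, _), f in factors.items() if site == normalize_to]
    if not norm_vals:
        raise ValueError(f"normalization site {normalize_to!r} has no matched peaks")
    norm = statistics.median(norm_vals)
    if norm <= 0:
        raise ValueError(f"normalization site {normalize_to!r} has zero amplitude")
    factors = {key: f / norm for key, f in factors.items()}
    hydrated = {key: f > threshold for key, f in factors.items()}
    return EnhancementReport(
        factors=factors, hydrated=hydrated, threshold=threshold, normalize_to=normalize_to
    )
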