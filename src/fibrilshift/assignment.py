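"""Allomorph classification of traced spin systems.

Matches observed glucose spin systems against cellulose Iβ/Iα
reference shifts (max-absolute-deviation criterion, matching the
"within ~0.1 ppm" language of the solid-state NMR literature), runs the
Iα presence test (both triclinic environments must be present at
comparable intensity, and the diagnostic second-environment C4 at
90.3 ppm must be observed), and resolves the historical C1 pairing
ambiguity of a two-site Iβ reference using intra-ring PDSD
cross-peaks — the INADEQUATE experiment alone cannot distinguish which
C1 belongs with which residue when the two C2 shifts nearly coincide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .nmr_forward import CrossPeakList
from .reference_data import CARBONS, ReferenceSet, SiteShifts
from .spectral_analysis import SpinSystem

__all__ = [
    "MatchResult",
    "AllomorphReport",
    "IalphaResult",
    "PairingResult",
    "match_to_reference",
    "ialpha_presence_test",
    "classify_allomorphs",
    "resolve_c1_pairing",
]


@dataclass(frozen=True)
class MatchResult:
    """Best reference site for one observed system."""

    system_index: int
    reference_site: str
    deviations: dict[int, float]  # per carbon, reported even when excluded
    max_abs_deviation: float
    tolerance: float
    excluded_carbons: frozenset[int]

    @property
    def verdict(self) -> str:
        return "match" if self.max_abs_deviation <= self.tolerance else "no-match"

    @property
    def is_match(self) -> bool:
        return self.verdict == "match"


def _shifts_of(obj: SpinSystem | SiteShifts) -> tuple[float, ...]:
    if isinstance(obj, SpinSystem):
        return obj.shifts
    return obj.shifts


def match_to_reference(
    system: SpinSystem | SiteShifts,
    ref: ReferenceSet,
    tol: float = 0.1,
    exclude_carbons: Iterable[int] = (),
    system_index: int = 0,
) -> MatchResult:
    """Best reference site by minimal max-|deviation| over included carbons.

    Carbons in ``exclude_carbons`` do not count toward the verdict but
    their deviations are still reported (the classic analysis excludes
    C1, whose literature assignment was historically swapped).
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    if len(ref) == 0:
        raise ValueError(f"reference set {ref.name!r} is empty")
    excluded = frozenset(exclude_carbons)
    observed = _shifts_of(system)

    best: tuple[float, str, dict[int, float]] | None = None
    for site in ref:
        deviations = {}
        included = []
        for carbon in CARBONS:
            obs, expect = observed[carbon - 1], site.shift(carbon)
            if math.isnan(obs) or math.isnan(expect):
                continue
            dev = abs(obs - expect)
            deviations[carbon] = dev
            if carbon not in excluded:
                included.append(dev)
        if not included:
            continue
        score = max(included)
        if best is None or score < best[0]:
            best = (score, site.site_id, deviations)
    if best is None:
        raise ValueError("no comparable carbons between system and reference")
    score, site_id, deviations = best
    return MatchResult(
        system_index=system_index,
        reference_site=site_id,
        deviations=deviations,
        max_abs_deviation=score,
        tolerance=tol,
        excluded_carbons=excluded,
    )


@dataclass(frozen=True)
class IalphaResult:
    """Outcome of the Iα presence probe."""

    present: bool
    matches: tuple[MatchResult, ...]
    matched_sites: dict[str, int]  # Iα reference site -> system index
    amplitude_ratio: float | None
    probe_c4: float
    probe_hits: tuple[float, ...]  # observed C4 shifts near the probe


def ialpha_presence_test(
    systems: Sequence[SpinSystem],
    ialpha_ref: ReferenceSet,
    tol: float = 0.1,
    probe_c4: float = 90.3,
    equal_intensity_band: tuple[float, float] = (0.5, 2.0),
    probe_window: float = 0.2,
) -> IalphaResult:
    """Test whether both Iα environments are present at similar intensity.

    Iα is called present only when each of its two reference
    environments matches a *distinct* observed system within tolerance
    and the two matched amplitudes are comparable (ratio inside the
    band).  Additionally reports any observed C4 within ``probe_window``
    of the diagnostic second-environment C4 (default 90.3 ppm).
    """
    if len(ialpha_ref) != 2:
        raise ValueError("Iα reference must contain exactly two environments")

    matches = []
    matched: dict[str, int] = {}
    for ref_site in ialpha_ref:
        single = ReferenceSet(name=ref_site.site_id, sites=(ref_site,),
                              tolerance_ppm=ialpha_ref.tolerance_ppm)
        best_idx, best_result = None, None
        for idx, system in enumerate(systems):
            try:
                result = match_to_reference(system, single, tol=tol, system_index=idx)
            except ValueError:
                continue
            if best_result is None or result.max_abs_deviation < best_result.max_abs_deviation:
                best_idx, best_result = idx, result
        if best_result is not None:
            matches.append(best_result)
            if best_result.is_match:
                matched[ref_site.site_id] = best_idx

    present = False
    amp_ratio = None
    if len(matched) == 2:
        idx1, idx2 = matched.values()
        if idx1 != idx2:
            a1, a2 = systems[idx1].amplitude, systems[idx2].amplitude
            if a2 > 0:
                amp_ratio = a1 / a2
                lo, hi = equal_intensity_band
                present = lo <= amp_ratio <= hi

    hits = tuple(
        s.shift(4)
        for s in systems
        if not math.isnan(s.shift(4)) and abs(s.shift(4) - probe_c4) <= probe_window
    )
    return IalphaResult(
        present=present,
        matches=tuple(matches),
        matched_sites=matched,
        amplitude_ratio=amp_ratio,
        probe_c4=probe_c4,
        probe_hits=hits,
    )


@dataclass(frozen=True)
class AllomorphReport:
    """Combined Iβ / Iα verdicts with the supporting evidence."""

    ibeta_present: bool
    ialpha_present: bool
    ibeta_matches: tuple[MatchResult, ...]
    ialpha: IalphaResult


def classify_allomorphs(
    systems: Sequence[SpinSystem],
    ibeta_ref: ReferenceSet,
    ialpha_ref: ReferenceSet,
    tol: float = 0.1,
    exclude_carbons: Iterable[int] = (1,),
) -> AllomorphReport:
    """Match every system against Iβ and run the Iα presence test.

    Iβ is called present when both reference chains (origin and center)
    are matched by distinct observed systems.  C1 is excluded from the
    Iβ criterion by default (see :func:`match_to_reference`).
    """
    ibeta_matches = tuple(
        match_to_reference(s, ibeta_ref, tol=tol, exclude_carbons=exclude_carbons,
                           system_index=i)
        for i, s in enumerate(systems)
    )
    matched_refs = {m.reference_site for m in ibeta_matches if m.is_match}
    ibeta_present = matched_refs == set(ibeta_ref.site_ids)
    ialpha = ialpha_presence_test(systems, ialpha_ref, tol=tol)
    return AllomorphReport(
        ibeta_present=ibeta_present,
        ialpha_present=ialpha.present,
        ibeta_matches=ibeta_matches,
        ialpha=ialpha,
    )


@dataclass(frozen=True)
class PairingResult:
    """Which C1↔residue pairing the intra-ring cross-peaks support."""

    chosen: str  # "original" | "swapped"
    score_original: float
    score_swapped: float
    ambiguous: bool


def _c1_cross_positions(sites: Sequence[SiteShifts]) -> list[tuple[float, float]]:
    positions = []
    for site in sites:
        c1 = site.shift(1)
        if math.isnan(c1):
            continue
        for carbon in CARBONS[1:]:
            other = site.shift(carbon)
            if math.isnan(other):
                continue
            positions.append((c1, other))
            positions.append((other, c1))
    return positions


def resolve_c1_pairing(
    ref_two_sites: Sequence[SiteShifts],
    intra_ring_peaks: CrossPeakList,
    c1_window: tuple[float, float] = (100.0, 110.0),
) -> PairingResult:
    """Decide which C1 belongs with which residue's C2…C6.

    For the original and the C1-swapped pairing, predict every
    intra-ring cross-peak position involving C1 and score each pairing
    by the summed distance from its predictions to the nearest observed
    peak.  Short-mixing (~30 ms) PDSD peaks are the right input: they
    correlate only carbons within one glucose ring, so they tie each C1
    to the rest of its own residue — which the DQ-only INADEQUATE
    geometry cannot do when the two C2 shifts coincide.
    """
    if len(ref_two_sites) != 2:
        raise ValueError("need exactly two candidate sites")
    observed = [
        (p.dim1, p.dim2)
        for p in intra_ring_peaks
        if c1_window[0] <= p.dim1 <= c1_window[1]
        or c1_window[0] <= p.dim2 <= c1_window[1]
    ]
    if not observed:
        raise ValueError("no C1-involving cross-peaks in the input peak list")

    site1, site2 = ref_two_sites
    swapped = (
        SiteShifts(site1.site_id, (site2.shift(1),) + site1.shifts[1:],
                   site1.domain, site1.role, site1.is_major),
        SiteShifts(site2.site_id, (site1.shift(1),) + site2.shifts[1:],
                   site2.domain, site2.role, site2.is_major),
    )

    def score(sites: Sequence[SiteShifts]) -> float:
        total = 0.0
        for pred in _c1_cross_positions(sites):
            total += min(
                math.hypot(pred[0] - obs[0], pred[1] - obs[1]) for obs in observed
            )
        return total

    s_orig = score(ref_two_sites)
    s_swap = score(swapped)
    ambiguous = math.isclose(s_orig, s_swap, abs_tol=1e-9)
    chosen = "original" if s_orig <= s_swap else "swapped"
    return PairingResult(
        chosen=chosen, score_original=s_orig, score_swapped=s_swap, ambiguous=ambiguous
    )
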