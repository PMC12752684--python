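"""Microfibril cross-section habits on a stacked-sheet lattice.

A cellulose microfibril cross-section is modelled as a stack of sheets
of glucan chains; a habit is the ordered list of sheet sizes (written as
a digit string, e.g. ``"234432"`` for the 18-chain habit with sheets of
2, 3, 4, 4, 3 and 2 chains).  Sheets are mutually centered on a common
axis, so chain x-coordinates are integers or half-integers.

Chains are classified interior vs surface by a coverage rule: a chain is
interior iff it has both intra-sheet neighbours (|Δx| = 1) and, in each
of the two adjacent sheets, some chain lies within ``coverage_threshold``
(default half a lattice spacing) of its x position.  The cellulose Iβ
lattice places its two crystallographically distinct chain types —
origin and center — in alternating sheets, so origin/center labels are
a sheet-parity choice; both parities are always reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Habit",
    "Chain",
    "CrossSection",
    "HabitReport",
    "build_cross_section",
    "classify_chains",
    "label_origin_center",
    "habit_report",
    "enumerate_habits",
    "filter_habits",
]

#: Default coverage distance (lattice spacings) for the interior rule.
DEFAULT_COVERAGE = 0.5


@dataclass(frozen=True)
class Habit:
    """An ordered list of sheet sizes."""

    sheet_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.sheet_sizes:
            raise ValueError("a habit needs at least one sheet")
        if any(s < 1 for s in self.sheet_sizes):
            raise ValueError(f"sheet sizes must be >= 1, got {self.sheet_sizes}")
        object.__setattr__(self, "sheet_sizes", tuple(int(s) for s in self.sheet_sizes))

    @classmethod
    def from_string(cls, text: str) -> "Habit":
        """Parse a digit string such as ``"234432"``."""
        if not text or not text.isdigit():
            raise ValueError(f"habit string must be digits, got {text!r}")
        return cls(tuple(int(ch) for ch in text))

    @property
    def n_chains(self) -> int:
        return sum(self.sheet_sizes)

    @property
    def n_sheets(self) -> int:
        return len(self.sheet_sizes)

    def canonical(self) -> "Habit":
        """Lexicographically smaller of the habit and its reflection."""
        rev = tuple(reversed(self.sheet_sizes))
        return Habit(min(self.sheet_sizes, rev))

    def is_convex(self) -> bool:
        """True if sheet sizes are unimodal (non-decreasing then non-increasing)."""
        sizes = self.sheet_sizes
        peak = sizes.index(max(sizes))
        rising = all(a <= b for a, b in zip(sizes[: peak + 1], sizes[1 : peak + 1]))
        falling = all(a >= b for a, b in zip(sizes[peak:], sizes[peak + 1 :]))
        return rising and falling

    def __str__(self) -> str:
        return "".join(str(s) for s in self.sheet_sizes)


@dataclass(frozen=True)
class Chain:
    """One glucan chain at sheet ``sheet``, lattice coordinate ``x``."""

    sheet: int
    x: float


@dataclass(frozen=True)
class CrossSection:
    """Chains of a habit, optionally with interior/surface and origin labels."""

    habit: Habit
    chains: tuple[Chain, ...]
    interior: frozenset[Chain] | None = None
    origin: frozenset[Chain] | None = None

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_interior(self) -> int:
        if self.interior is None:
            raise ValueError("chains not classified yet")
        return len(self.interior)

    @property
    def n_surface(self) -> int:
        return self.n_chains - self.n_interior

    def sheet_chains(self, sheet: int) -> tuple[Chain, ...]:
        return tuple(c for c in self.chains if c.sheet == sheet)


@dataclass(frozen=True)
class HabitReport:
    """Interior/surface and origin/center bookkeeping for one habit."""

    habit: Habit
    n_interior: int
    n_surface: int
    #: interior (origin, center) counts for sheet-parity 0 and 1
    origin_center_interior: tuple[tuple[int, int], tuple[int, int]]

    @property
    def n_chains(self) -> int:
        return self.habit.n_chains

    @property
    def is_ratio(self) -> float:
        if self.n_surface == 0:
            return float("inf") if self.n_interior else 0.0
        return self.n_interior / self.n_surface

    def has_equal_origin_center(self) -> bool:
        """True if some parity splits the interior chains equally."""
        return any(o == c for o, c in self.origin_center_interior)


def build_cross_section(habit: Habit) -> CrossSection:
    """Place each sheet's chains at consecutive x, centered on 0."""
    chains = []
    for sheet, size in enumerate(habit.sheet_sizes):
        offset = (size - 1) / 2.0
        for k in range(size):
            chains.append(Chain(sheet, k - offset))
    return CrossSection(habit=habit, chains=tuple(chains))


def classify_chains(
    cs: CrossSection, coverage_threshold: float = DEFAULT_COVERAGE
) -> CrossSection:
    """Label chains interior/surface by the neighbour-coverage rule."""
    if not coverage_threshold > 0:
        raise ValueError("coverage_threshold must be > 0")
    n_sheets = cs.habit.n_sheets
    xs_by_sheet = {s: [c.x for c in cs.sheet_chains(s)] for s in range(n_sheets)}
    eps = 1e-9

    interior = set()
    for chain in cs.chains:
        if chain.sheet == 0 or chain.sheet == n_sheets - 1:
            continue  # outermost sheets are surface by construction
        own = xs_by_sheet[chain.sheet]
        has_left = any(abs(x - (chain.x - 1)) < eps for x in own)
        has_right = any(abs(x - (chain.x + 1)) < eps for x in own)
        if not (has_left and has_right):
            continue
        covered = all(
            any(abs(x - chain.x) <= coverage_threshold + eps for x in xs_by_sheet[adj])
            for adj in (chain.sheet - 1, chain.sheet + 1)
        )
        if covered:
            interior.add(chain)
    return CrossSection(
        habit=cs.habit, chains=cs.chains, interior=frozenset(interior), origin=cs.origin
    )


def label_origin_center(cs: CrossSection, parity: int) -> CrossSection:
    """Assign origin to sheets with index ≡ parity (mod 2), center otherwise."""
    if cs.interior is None:
        raise ValueError("classify chains before labelling origin/center")
    if parity not in (0, 1):
        raise ValueError("parity must be 0 or 1")
    origin = frozenset(c for c in cs.chains if c.sheet % 2 == parity)
    return CrossSection(habit=cs.habit, chains=cs.chains, interior=cs.interior, origin=origin)


def _interior_origin_center(cs: CrossSection) -> tuple[int, int]:
    assert cs.interior is not None and cs.origin is not None
    n_origin = sum(1 for c in cs.interior if c in cs.origin)
    return n_origin, len(cs.interior) - n_origin


def habit_report(
    habit: Habit, coverage_threshold: float = DEFAULT_COVERAGE
) -> HabitReport:
    """Build, classify and label a habit; collect the counts."""
    cs = classify_chains(build_cross_section(habit), coverage_threshold)
    splits = tuple(
        _interior_origin_center(label_origin_center(cs, parity)) for parity in (0, 1)
    )
    return HabitReport(
        habit=habit,
        n_interior=cs.n_interior,
        n_surface=cs.n_surface,
        origin_center_interior=splits,
    )


def _compositions(n: int, max_parts: int) -> Iterable[tuple[int, ...]]:
    """All ordered compositions of n into 1..max_parts positive parts."""
    if max_parts >= 1:
        yield (n,)
    if max_parts <= 1:
        return
    for first in range(1, n):
        for rest in _compositions(n - first, max_parts - 1):
            yield (first,) + rest


def enumerate_habits(
    n_chains_min: int,
    n_chains_max: int,
    max_sheets: int = 8,
    convex_only: bool = True,
) -> list[Habit]:
    """All habits (canonical under reflection) with total chains in range."""
    if not 1 <= n_chains_min <= n_chains_max:
        raise ValueError(
            f"need 1 <= n_chains_min <= n_chains_max, got {n_chains_min}, {n_chains_max}"
        )
    if max_sheets < 1:
        raise ValueError("max_sheets must be >= 1")
    seen = set()
    habits = []
    for n in range(n_chains_min, n_chains_max + 1):
        for sizes in _compositions(n, max_sheets):
            habit = Habit(sizes)
            if convex_only and not habit.is_convex():
                continue
            canon = habit.canonical()
            if canon.sheet_sizes in seen:
                continue
            seen.add(canon.sheet_sizes)
            habits.append(canon)
    habits.sort(key=lambda h: (h.n_chains, str(h)))
    return habits


def filter_habits(
    habits: Sequence[Habit],
    target_ratio: float,
    tol: float,
    require_equal_oc: bool = False,
    n_range: tuple[int, int] | None = None,
    coverage_threshold: float = DEFAULT_COVERAGE,
) -> list[HabitReport]:
    """Keep habits whose interior:surface ratio is within tol of target."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    reports = []
    for habit in habits:
        if n_range is not None and not n_range[0] <= habit.n_chains <= n_range[1]:
            continue
        report = habit_report(habit, coverage_threshold)
        if abs(report.is_ratio - target_ratio) > tol:
            continue
        if require_equal_oc and not report.has_equal_origin_center():
            continue
        reports.append(report)
    reports.sort(key=lambda r: (r.n_chains, str(r.habit)))
    return reports
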