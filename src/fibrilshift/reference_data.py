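"""Chemical-shift reference tables for glucose environments in cellulose.

Each glucose residue environment in a ¹³C MAS NMR spectrum of plant
cellulose is characterised by six chemical shifts (C1…C6, in ppm).  The
packaged poplar table holds the six major environments (a, b, c in
spectral domain 1; f, g, j in spectral domain 2) and the minor ones
(d, e, k).  Domain 1 vs domain 2 is the classic split of the C4/C6
region (~89 vs ~84 ppm at C4) that tracks the *tg* vs *gt/gg*
hydroxymethyl conformation.

Allomorph reference sets for cellulose Iβ (two sites: origin and
center chain) and Iα (two sites in the triclinic unit cell) are
shipped alongside and can be replaced by user-edited files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SiteShifts",
    "ReferenceSet",
    "SchemaError",
    "ShiftValidationError",
    "CARBONS",
    "SHIFT_RANGE",
    "DOMAIN_BOUNDARY_PPM",
    "domain_of",
    "load_shift_table",
    "write_shift_table",
    "poplar_reference",
    "ibeta_reference",
    "ialpha_reference",
]

#: Carbon positions of a glucosyl ring, in bond order.
CARBONS = (1, 2, 3, 4, 5, 6)

#: Plausible ppm window for any glucose ring carbon.
SHIFT_RANGE = (55.0, 115.0)

#: Default C4 boundary between spectral domain 1 (~89 ppm) and domain 2
#: (~84 ppm).  Midway between the two C4 clusters; the literature states
#: no explicit cut, so it is configurable everywhere it is used.
DOMAIN_BOUNDARY_PPM = 86.5

ROLES = ("core-origin", "core-center", "surface", "unassigned")

_COLUMNS = ("site", "c1", "c2", "c3", "c4", "c5", "c6", "domain", "role", "major")


class SchemaError(ValueError):
    """A shift table is structurally unusable (missing columns, empty file)."""


class ShiftValidationError(ValueError):
    """A parsed shift value violates its invariant; names the offending cell."""


@dataclass(frozen=True)
class SiteShifts:
    """One glucose environment: six ¹³C shifts plus structural metadata.

    ``shifts`` holds (C1, C2, C3, C4, C5, C6) in ppm.  Minor sites may
    carry NaN where the literature reports no value (e.g. site e's C2).
    """

    site_id: str
    shifts: tuple[float, ...]
    domain: int = 1
    role: str = "unassigned"
    is_major: bool = True

    def __post_init__(self) -> None:
        if len(self.shifts) != len(CARBONS):
            raise ShiftValidationError(
                f"site {self.site_id!r}: expected {len(CARBONS)} shifts, "
                f"got {len(self.shifts)}"
            )
        lo, hi = SHIFT_RANGE
        for carbon, value in zip(CARBONS, self.shifts):
            if not math.isnan(value) and not lo <= value <= hi:
                raise ShiftValidationError(
                    f"site {self.site_id!r} column c{carbon}: {value} ppm "
                    f"outside [{lo}, {hi}]"
                )
        if self.domain not in (1, 2):
            raise ShiftValidationError(
                f"site {self.site_id!r}: domain must be 1 or 2, got {self.domain}"
            )
        if self.role not in ROLES:
            raise ShiftValidationError(
                f"site {self.site_id!r}: unknown role {self.role!r}"
            )
        object.__setattr__(self, "shifts", tuple(float(v) for v in self.shifts))

    def shift(self, carbon: int) -> float:
        """Chemical shift of carbon ``carbon`` (1-based)."""
        return self.shifts[carbon - 1]

    @property
    def c1(self) -> float:
        return self.shifts[0]

    @property
    def c4(self) -> float:
        return self.shifts[3]

    @property
    def c6(self) -> float:
        return self.shifts[5]


@dataclass(frozen=True)
class ReferenceSet:
    """A named collection of :class:`SiteShifts` with a matching tolerance."""

    name: str
    sites: tuple[SiteShifts, ...]
    tolerance_ppm: float = 0.1

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ShiftValidationError(f"duplicate site ids in table {self.name!r}")
        if not self.tolerance_ppm > 0:
            raise ShiftValidationError("tolerance_ppm must be > 0")
        object.__setattr__(self, "sites", tuple(self.sites))

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def get(self, site_id: str) -> SiteShifts:
        for site in self.sites:
            if site.site_id == site_id:
                return site
        raise KeyError(f"no site {site_id!r} in table {self.name!r}")

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.site_id for s in self.sites)

    def major_sites(self) -> tuple[SiteShifts, ...]:
        return tuple(s for s in self.sites if s.is_major)


def domain_of(site: SiteShifts, boundary_ppm: float = DOMAIN_BOUNDARY_PPM) -> int:
    """Spectral domain (1 or 2) of a site from its C4 shift.

    A C4 exactly on the boundary is assigned to domain 2 by convention.
    """
    if not 85.0 <= boundary_ppm <= 88.0:
        raise ValueError(f"boundary_ppm {boundary_ppm} outside the C4 gap [85, 88]")
    return 1 if site.c4 > boundary_ppm else 2


_TRUTHY = {"true", "1", "yes", "t", "y"}
_FALSY = {"false", "0", "no", "f", "n"}


def _parse_bool(value, context: str) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise SchemaError(f"{context}: cannot parse {value!r} as a boolean")


def load_shift_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    name: str | None = None,
    tolerance_ppm: float = 0.1,
) -> ReferenceSet:
    """Read a delimited (tab or comma) shift table into a :class:`ReferenceSet`.

    The expected header is ``site,c1,…,c6,domain,role,major``; ``schema``
    maps those canonical names to the file's actual column names.  Blank
    shift cells are accepted (stored as NaN) so that minor sites with
    incomplete literature values can be carried.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"shift table not found: {path}")
    if not path.read_text().strip():
        raise SchemaError(f"{path}: empty shift table")
    try:
        frame = pd.read_csv(path, sep=None, engine="python", skipinitialspace=True)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty shift table") from exc
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    colmap = {key: key for key in _COLUMNS}
    if schema:
        colmap.update({k.lower(): v.lower() for k, v in schema.items()})
    missing = [colmap[k] for k in _COLUMNS if colmap[k] not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")

    sites = []
    for _, row in frame.iterrows():
        site_id = str(row[colmap["site"]]).strip()
        shifts = []
        for carbon in CARBONS:
            raw = row[colmap[f"c{carbon}"]]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() in ("", "-"):
                shifts.append(math.nan)
                continue
            try:
                shifts.append(float(raw))
            except (TypeError, ValueError) as exc:
                raise SchemaError(
                    f"{path}: site {site_id!r} column c{carbon}: "
                    f"cannot parse {raw!r} as ppm"
                ) from exc
        sites.append(
            SiteShifts(
                site_id=site_id,
                shifts=tuple(shifts),
                domain=int(row[colmap["domain"]]),
                role=str(row[colmap["role"]]).strip(),
                is_major=_parse_bool(row[colmap["major"]], f"site {site_id!r}"),
            )
        )
    if not sites:
        raise SchemaError(f"{path}: no data rows")
    return ReferenceSet(name=name or path.stem, sites=tuple(sites), tolerance_ppm=tolerance_ppm)


def write_shift_table(ref: ReferenceSet, path: str | Path, sep: str = "\t") -> None:
    """Write a reference set back to delimited text (ppm to one decimal)."""
    path = Path(path)
    lines = [sep.join(_COLUMNS)]
    for site in ref.sites:
        cells = [site.site_id]
        cells += ["" if math.isnan(v) else f"{v:.1f}" for v in site.shifts]
        cells += [str(site.domain), site.role, "true" if site.is_major else "false"]
        lines.append(sep.join(cells))
    path.write_text("\n".join(lines) + "\n")


def _packaged(filename: str) -> Path:
    return Path(resources.files("fibrilshift.data") / filename)


def poplar_reference() -> ReferenceSet:
    """The packaged poplar wood shift table (sites a–e, f–k)."""
    return load_shift_table(_packaged("poplar_table1.tsv"), name="poplar-Table1")


def ibeta_reference() -> ReferenceSet:
    """Cellulose Iβ reference (origin and center chain environments)."""
    ref = load_shift_table(_packaged("ibeta_reference.tsv"), name="Ibeta")
    assert len(ref) == 2
    return ref


def ialpha_reference() -> ReferenceSet:
    """Cellulose Iα reference (two triclinic environments, user-editable).

    Seeded plausible values; the structurally diagnostic number is the
    second environment's C4 at 90.3 ppm, whose absence from a spectrum
    rules out Iα.
    """
    ref = load_shift_table(_packaged("ialpha_reference.tsv"), name="Ialpha")
    assert len(ref) == 2
    return ref
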