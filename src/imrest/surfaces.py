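"""Stratified registry count tables: age grids, count/population surfaces, site catalog.

The package works on dense "surfaces": nonnegative counts (deaths or incident
cases) or person-years indexed by 5-year age group and calendar year, one
surface per sex and cancer site.  Surfaces are the common currency passed
between the mortality projection, the IMR model and the validation machinery.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AgeGrid",
    "CountSurface",
    "PopulationSurface",
    "SiteCatalog",
    "read_count_surface",
    "read_count_surfaces",
    "read_population_surface",
    "write_count_surface",
    "write_population_surface",
    "aggregate_all_sites",
    "marginal_by_year",
]


@dataclass(frozen=True)
class AgeGrid:
    """Ordered age bands, 5-year by default (0-4 ... 85+), last band open-ended."""

    lower_bounds: tuple[int, ...] = tuple(range(0, 90, 5))
    open_ended_last: bool = True

    def __post_init__(self) -> None:
        lb = self.lower_bounds
        if len(lb) < 2:
            raise ValueError("age grid needs at least two bands")
        if any(b >= a for a, b in zip(lb[1:], lb[:-1])):
            raise ValueError("age band lower bounds must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.lower_bounds)

    @property
    def labels(self) -> tuple[str, ...]:
        labs = []
        lb = self.lower_bounds
        for i, lo in enumerate(lb):
            if i == len(lb) - 1 and self.open_ended_last:
                labs.append(f"{lo}+")
            else:
                hi = lb[i + 1] - 1 if i + 1 < len(lb) else lo + 4
                labs.append(f"{lo}-{hi}")
        return tuple(labs)

    @property
    def midpoints(self) -> np.ndarray:
        """Band midpoints in years; the open-ended band uses lower bound + 2.5."""
        lb = np.asarray(self.lower_bounds, dtype=float)
        mids = np.empty_like(lb)
        mids[:-1] = (lb[:-1] + lb[1:]) / 2.0
        # 85+ -> 87.5: registry convention for the open band
        mids[-1] = lb[-1] + (lb[-1] - lb[-2]) / 2.0 if len(lb) > 1 else lb[-1] + 2.5
        return mids

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown age group label {label!r}") from None


def _check_years(years: np.ndarray) -> np.ndarray:
    years = np.asarray(years, dtype=int)
    if years.size == 0:
        raise ValueError("empty year range")
    if not np.all(np.diff(years) == 1):
        raise ValueError("years must be contiguous")
    return years


@dataclass(frozen=True)
class CountSurface:
    """Dense nonnegative counts per (age group, year) for one sex x site stratum.

    ``kind`` is "mortality" or "incidence"; ``counts`` has shape
    (n_age_groups, n_years).  Every cell is present; zeros are explicit.
    """

    kind: str
    sex: str
    site: str
    years: np.ndarray
    counts: np.ndarray
    ages: AgeGrid = field(default_factory=AgeGrid)

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", _check_years(self.years))
        counts = np.asarray(self.counts)
        if counts.shape != (self.ages.n, self.years.size):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{self.ages.n} age groups x {self.years.size} years"
            )
        if np.any(counts < 0):
            raise ValueError(f"negative counts in {self.sex}/{self.site}")
        object.__setattr__(self, "counts", counts)
        if self.kind not in ("mortality", "incidence"):
            raise ValueError(f"kind must be 'mortality' or 'incidence', got {self.kind!r}")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def year_index(self, year: int) -> int:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= self.years.size:
            raise KeyError(f"year {year} outside surface range {self.years[0]}-{self.years[-1]}")
        return idx

    def window(self, first: int, last: int) -> "CountSurface":
        """Restrict to the inclusive year range [first, last]."""
        i, j = self.year_index(first), self.year_index(last)
        if j < i:
            raise ValueError("empty window")
        return replace(self, years=self.years[i : j + 1], counts=self.counts[:, i : j + 1])

    def truncate_after(self, last_year: int) -> "CountSurface":
        """Drop all years after ``last_year`` (reporting-lag guard)."""
        return self.window(int(self.years[0]), min(int(self.years[-1]), last_year))

    def to_frame(self) -> pd.DataFrame:
        labels = self.ages.labels
        rows = [
            (self.sex, self.site, labels[a], int(y), int(self.counts[a, j]))
            for a in range(self.ages.n)
            for j, y in enumerate(self.years)
        ]
        return pd.DataFrame(rows, columns=["sex", "site", "age_group", "year", "count"])


@dataclass(frozen=True)
class PopulationSurface:
    """Person-years at risk per (age group, year) for one sex."""

    sex: str
    years: np.ndarray
    person_years: np.ndarray
    ages: AgeGrid = field(default_factory=AgeGrid)

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", _check_years(self.years))
        py = np.asarray(self.person_years, dtype=float)
        if py.shape != (self.ages.n, self.years.size):
            raise ValueError("person_years shape mismatch")
        if np.any(py <= 0):
            raise ValueError("person_years must be strictly positive")
        object.__setattr__(self, "person_years", py)

    def year_index(self, year: int) -> int:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= self.years.size:
            raise KeyError(f"year {year} outside population range")
        return idx

    def window(self, first: int, last: int) -> "PopulationSurface":
        i, j = self.year_index(first), self.year_index(last)
        return replace(
            self, years=self.years[i : j + 1], person_years=self.person_years[:, i : j + 1]
        )

    def to_frame(self) -> pd.DataFrame:
        labels = self.ages.labels
        rows = [
            (self.sex, labels[a], int(y), float(self.person_years[a, j]))
            for a in range(self.ages.n)
            for j, y in enumerate(self.years)
        ]
        return pd.DataFrame(rows, columns=["sex", "age_group", "year", "person_years"])


# ---------------------------------------------------------------------------
# ICD-10 site catalog


_ICD_RANGE = re.compile(r"^([A-Z])(\d{2})(?:[-–]([A-Z])?(\d{2}))?$")


def _expand_codes(tokens: Iterable[str]) -> frozenset[str]:
    """Expand ICD-10 tokens like 'C19-C20' into individual 3-character codes.

    Subcategory codes with a decimal (D09.0) are kept verbatim.
    """
    out: set[str] = set()
    for tok in tokens:
        tok = tok.strip()
        if "." in tok:
            out.add(tok)
            continue
        m = _ICD_RANGE.match(tok)
        if not m:
            raise ValueError(f"cannot parse ICD-10 token {tok!r}")
        letter, lo, letter2, hi = m.group(1), int(m.group(2)), m.group(3), m.group(4)
        if hi is None:
            out.add(f"{letter}{lo:02d}")
        else:
            if letter2 is not None and letter2 != letter:
                raise ValueError(f"cross-letter ICD range unsupported: {tok!r}")
            out.update(f"{letter}{k:02d}" for k in range(lo, int(hi) + 1))
    return frozenset(out)


@dataclass(frozen=True)
class SiteCatalog:
    """Cancer-site groupings (label -> ICD-10 code set) per sex, plus the
    all-sites-except-non-melanoma-skin aggregate label."""

    sites: Mapping[str, Mapping[str, frozenset[str]]]
    aggregate_label: str = "all sites (except non-melanoma skin)"

    def __post_init__(self) -> None:
        for sex, mapping in self.sites.items():
            seen: dict[str, str] = {}
            for label, codes in mapping.items():
                for code in codes:
                    if code in seen:
                        raise ValueError(
                            f"{sex}: ICD-10 code {code} assigned to both "
                            f"{seen[code]!r} and {label!r}"
                        )
                    seen[code] = label

    @classmethod
    def from_yaml(cls, path: str | Path | None = None) -> "SiteCatalog":
        if path is None:
            text = resources.files("imrest.data").joinpath("sites.yaml").read_text()
        else:
            text = Path(path).read_text()
        raw = yaml.safe_load(text)
        sites = {
            sex: {label: _expand_codes(tokens) for label, tokens in mapping.items()}
            for sex, mapping in raw["sites"].items()
        }
        return cls(sites=sites, aggregate_label=raw.get("aggregate_label", cls.aggregate_label))

    def site_labels(self, sex: str) -> tuple[str, ...]:
        return tuple(self.sites[sex].keys())


# ---------------------------------------------------------------------------
# Readers / writers

COUNT_COLUMNS = ("sex", "site", "age_group", "year", "count")
POP_COLUMNS = ("sex", "age_group", "year", "person_years")


def _apply_schema(df: pd.DataFrame, schema: Mapping[str, str] | None, required: tuple) -> pd.DataFrame:
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing}; provide a schema mapping")
    return df


def _frame_to_surface(
    df: pd.DataFrame,
    kind: str,
    sex: str,
    site: str,
    ages: AgeGrid,
    allow_sparse: bool,
) -> CountSurface:
    dup = df.duplicated(subset=["sex", "site", "age_group", "year"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            "duplicate stratum row: "
            f"sex={row['sex']} site={row['site']} age_group={row['age_group']} year={row['year']}"
        )
    if (df["count"] < 0).any():
        bad = df[df["count"] < 0].iloc[0]
        raise ValueError(f"negative count at age_group={bad['age_group']} year={bad['year']}")
    years = np.arange(int(df["year"].min()), int(df["year"].max()) + 1)
    counts = np.zeros((ages.n, years.size))
    seen = np.zeros_like(counts, dtype=bool)
    label_index = {lab: i for i, lab in enumerate(ages.labels)}
    for _, row in df.iterrows():
        lab = str(row["age_group"])
        if lab not in label_index:
            raise ValueError(f"age group {lab!r} not in grid {ages.labels}")
        a, j = label_index[lab], int(row["year"]) - years[0]
        counts[a, j] = row["count"]
        seen[a, j] = True
    if not seen.all() and not allow_sparse:
        a, j = np.argwhere(~seen)[0]
        raise ValueError(
            f"missing cell age_group={ages.labels[a]} year={years[j]} "
            "(zeros must be explicit; pass allow_sparse=True to fill with 0)"
        )
    return CountSurface(kind=kind, sex=sex, site=site, years=years, counts=counts, ages=ages)


def read_count_surfaces(
    path: str | Path,
    kind: str,
    schema: Mapping[str, str] | None = None,
    ages: AgeGrid | None = None,
    allow_sparse: bool = False,
) -> dict[tuple[str, str], CountSurface]:
    """Read a delimited count table into one dense surface per (sex, site)."""
    ages = ages or AgeGrid()
    df = _apply_schema(pd.read_csv(path, comment="#"), schema, COUNT_COLUMNS)
    out = {}
    for (sex, site), grp in df.groupby(["sex", "site"], sort=True):
        out[(str(sex), str(site))] = _frame_to_surface(grp, kind, str(sex), str(site), ages, allow_sparse)
    return out


def read_count_surface(
    path: str | Path,
    kind: str,
    schema: Mapping[str, str] | None = None,
    sex: str | None = None,
    site: str | None = None,
    ages: AgeGrid | None = None,
    allow_sparse: bool = False,
) -> CountSurface:
    """Read a single (sex, site) stratum; errors if the file holds several and
    no selectors pin one down."""
    surfaces = read_count_surfaces(path, kind, schema=schema, ages=ages, allow_sparse=allow_sparse)
    keys = [
        k for k in surfaces
        if (sex is None or k[0] == sex) and (site is None or k[1] == site)
    ]
    if len(keys) != 1:
        raise ValueError(
            f"expected exactly one (sex, site) stratum, found {sorted(keys)}; "
            "pass sex=/site= to select one"
        )
    return surfaces[keys[0]]


def read_population_surface(
    path: str | Path,
    sex: str | None = None,
    schema: Mapping[str, str] | None = None,
    ages: AgeGrid | None = None,
) -> PopulationSurface | dict[str, PopulationSurface]:
    ages = ages or AgeGrid()
    df = _apply_schema(pd.read_csv(path, comment="#"), schema, POP_COLUMNS)
    out: dict[str, PopulationSurface] = {}
    label_index = {lab: i for i, lab in enumerate(ages.labels)}
    for s, grp in df.groupby("sex", sort=True):
        years = np.arange(int(grp["year"].min()), int(grp["year"].max()) + 1)
        py = np.full((ages.n, years.size), np.nan)
        for _, row in grp.iterrows():
            py[label_index[str(row["age_group"])], int(row["year"]) - years[0]] = row["person_years"]
        if np.isnan(py).any():
            raise ValueError(f"population table for sex={s} has missing cells")
        out[str(s)] = PopulationSurface(sex=str(s), years=years, person_years=py, ages=ages)
    if sex is not None:
        return out[sex]
    return out


def write_count_surface(surfaces: CountSurface | Iterable[CountSurface], path: str | Path,
                        header_lines: Iterable[str] = ()) -> None:
    if isinstance(surfaces, CountSurface):
        surfaces = [surfaces]
    df = pd.concat([s.to_frame() for s in surfaces], ignore_index=True)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_population_surface(pop: PopulationSurface, path: str | Path,
                             header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pop.to_frame().to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# Surface algebra


def aggregate_all_sites(
    surfaces: list[CountSurface], catalog: SiteCatalog | None = None
) -> CountSurface:
    """Cellwise sum of site surfaces into the all-sites aggregate.

    All surfaces must share sex, kind and grid; if a catalog is given, the
    summed sites must have mutually disjoint ICD-10 code sets (no double
    counting).
    """
    if not surfaces:
        raise ValueError("no surfaces to aggregate")
    first = surfaces[0]
    label = catalog.aggregate_label if catalog else "all sites (except non-melanoma skin)"
    total = np.zeros_like(np.asarray(first.counts, dtype=float))
    claimed: set[str] = set()
    for s in surfaces:
        if s.sex != first.sex or s.kind != first.kind:
            raise ValueError("aggregating surfaces with mismatched sex or kind")
        if not np.array_equal(s.years, first.years) or s.ages != first.ages:
            raise ValueError("aggregating surfaces with mismatched grids")
        if catalog is not None and s.site in catalog.sites.get(s.sex, {}):
            codes = catalog.sites[s.sex][s.site]
            overlap = claimed & set(codes)
            if overlap:
                raise ValueError(f"overlapping ICD-10 codes in aggregate: {sorted(overlap)}")
            claimed |= set(codes)
        total = total + s.counts
    return CountSurface(
        kind=first.kind, sex=first.sex, site=label,
        years=first.years.copy(), counts=total, ages=first.ages,
    )


def marginal_by_year(surface: CountSurface) -> pd.Series:
    """Yearly totals summed over age groups (feeds the observed series O_i)."""
    return pd.Series(surface.counts.sum(axis=0), index=pd.Index(surface.years, name="year"))
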