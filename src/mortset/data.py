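"""Age x year mortality surfaces and text-format I/O.

The central container is :class:`MortalitySurface`: central death rates
``m[x, t]`` (optionally backed by death counts and exposures) on a
rectangular grid of single-year ages by calendar years.  Readers are
provided for the whitespace table dialect used by the Human Mortality
Database family of sources (columns ``Year Age Female Male Total``, "."
for missing, a trailing open age group such as ``100+``) and for a long
CSV format with columns ``year,age,population,deaths,exposure,rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MortalitySurface",
    "PopulationSet",
    "read_hmd_table",
    "read_long_csv",
    "write_long_csv",
    "derive_rates",
    "restrict_ages",
]


class MortalityDataError(ValueError):
    """Raised for malformed input files or invalid surface operations."""


def _as_matrix(a, k, n, name):
    a = np.asarray(a, dtype=float)
    if a.shape != (k, n):
        raise MortalityDataError(f"{name} has shape {a.shape}, expected {(k, n)}")
    return a


@dataclass
class MortalitySurface:
    """One subpopulation's mortality on an age x year grid.

    Parameters
    ----------
    ages : array of int
        Consecutive integer age labels; the last may represent an
        open-ended group (e.g. 100 standing for "100+"), flagged by
        ``open_ended``.
    years : array of int
        Consecutive calendar years.
    rates : (k, n) array
        Central death rates ``m[x, t]``; NaN marks missing cells.
    deaths, exposures : (k, n) array, optional
        Death counts ``d[x, t] >= 0`` and exposure to risk ``e[x, t] > 0``.
        When both are present, ``rates == deaths / exposures``.
    label : str
        Population identifier (sex, region, ...).
    open_ended : bool
        Whether the last age group is open ("100+").
    """

    ages: np.ndarray
    years: np.ndarray
    rates: np.ndarray
    deaths: np.ndarray | None = None
    exposures: np.ndarray | None = None
    label: str = ""
    open_ended: bool = False
    zero_cells: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        k, n = len(self.ages), len(self.years)
        if k == 0 or n == 0:
            raise MortalityDataError("empty age or year range")
        if not np.all(np.diff(self.ages) == 1):
            raise MortalityDataError("ages must increase in steps of 1")
        if not np.all(np.diff(self.years) == 1):
            raise MortalityDataError("years must increase in steps of 1")
        self.rates = _as_matrix(self.rates, k, n, "rates")
        if self.deaths is not None:
            self.deaths = _as_matrix(self.deaths, k, n, "deaths")
        if self.exposures is not None:
            self.exposures = _as_matrix(self.exposures, k, n, "exposures")
        if self.deaths is not None and self.exposures is not None:
            implied = self.deaths / self.exposures
            ok = np.isnan(self.rates) | np.isnan(implied) | np.isclose(
                self.rates, implied, rtol=1e-12, atol=1e-300
            )
            if not ok.all():
                raise MortalityDataError("rates inconsistent with deaths/exposures")

    # -- basic geometry -------------------------------------------------
    @property
    def n_ages(self) -> int:
        return len(self.ages)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def age_index(self, age: int) -> int:
        idx = np.where(self.ages == age)[0]
        if idx.size == 0:
            raise MortalityDataError(f"age {age} not on grid")
        return int(idx[0])

    def year_index(self, year: int) -> int:
        idx = np.where(self.years == year)[0]
        if idx.size == 0:
            raise MortalityDataError(f"year {year} not on grid")
        return int(idx[0])

    # -- transforms -----------------------------------------------------
    def log_rates(self) -> np.ndarray:
        """Log rates with the zero-cell rule applied.

        Cells with an observed rate of exactly zero (possible at high
        ages when no deaths occurred) are replaced by half the smallest
        positive rate in the same year's column before taking logs, so
        that ordering is preserved without producing -inf.
        """
        r = self.rates.copy()
        for j in range(r.shape[1]):
            col = r[:, j]
            zero = col == 0
            if zero.any():
                pos = col[col > 0]
                if pos.size == 0:
                    raise MortalityDataError(f"no positive rate in year {self.years[j]}")
                col[zero] = 0.5 * pos.min()
        return np.log(r)

    def restrict_years(self, lo: int, hi: int) -> "MortalitySurface":
        """Return the sub-surface with years in [lo, hi]."""
        mask = (self.years >= lo) & (self.years <= hi)
        if not mask.any():
            raise MortalityDataError(f"no years in [{lo}, {hi}]")
        return replace(
            self,
            years=self.years[mask],
            rates=self.rates[:, mask],
            deaths=None if self.deaths is None else self.deaths[:, mask],
            exposures=None if self.exposures is None else self.exposures[:, mask],
            zero_cells=None if self.zero_cells is None else self.zero_cells[:, mask],
        )

    def restrict_ages(self, lo: int, hi: int) -> "MortalitySurface":
        return restrict_ages(self, lo, hi)


@dataclass
class PopulationSet:
    """Mapping of label -> MortalitySurface on a shared age/year grid."""

    surfaces: dict[str, MortalitySurface]

    def __post_init__(self):
        labels = list(self.surfaces)
        if not labels:
            raise MortalityDataError("empty population set")
        ref = self.surfaces[labels[0]]
        for lab in labels[1:]:
            s = self.surfaces[lab]
            if not (np.array_equal(s.ages, ref.ages) and np.array_equal(s.years, ref.years)):
                raise MortalityDataError("populations must share the age/year grid")

    @property
    def labels(self) -> list[str]:
        return list(self.surfaces)

    @property
    def ages(self) -> np.ndarray:
        return self.surfaces[self.labels[0]].ages

    @property
    def years(self) -> np.ndarray:
        return self.surfaces[self.labels[0]].years

    def __getitem__(self, label: str) -> MortalitySurface:
        return self.surfaces[label]

    def __len__(self) -> int:
        return len(self.surfaces)

    def restrict_years(self, lo: int, hi: int) -> "PopulationSet":
        return PopulationSet({l: s.restrict_years(lo, hi) for l, s in self.surfaces.items()})


# ---------------------------------------------------------------------------
# operations


def derive_rates(deaths, exposures):
    """Central rates d/e; zero-death cells give rate 0 and are flagged.

    Returns ``(rates, zero_cells)`` where ``zero_cells`` is a boolean
    matrix marking cells with d == 0.
    """
    d = np.asarray(deaths, dtype=float)
    e = np.asarray(exposures, dtype=float)
    if d.shape != e.shape:
        raise MortalityDataError("deaths and exposures shapes differ")
    if np.any(e <= 0):
        raise MortalityDataError("exposures must be strictly positive")
    rates = d / e
    return rates, d == 0


def restrict_ages(surface: MortalitySurface, lo: int, hi: int) -> MortalitySurface:
    """Slice a surface to ages in [lo, hi], preserving all matrices."""
    mask = (surface.ages >= lo) & (surface.ages <= hi)
    if not mask.any():
        raise MortalityDataError(f"no ages in [{lo}, {hi}]")
    still_open = surface.open_ended and bool(mask[-1])
    return replace(
        surface,
        ages=surface.ages[mask],
        rates=surface.rates[mask],
        deaths=None if surface.deaths is None else surface.deaths[mask],
        exposures=None if surface.exposures is None else surface.exposures[mask],
        zero_cells=None if surface.zero_cells is None else surface.zero_cells[mask],
        open_ended=still_open,
    )


def _parse_age(token: str) -> tuple[int, bool]:
    if token.endswith("+"):
        return int(token[:-1]), True
    return int(token), False


def read_hmd_table(path, column: str) -> MortalitySurface:
    """Read an HMD-dialect whitespace table into a surface.

    The file has a two-line header followed by columns
    ``Year Age Female Male Total``; "." marks missing values and the
    final age group may be open-ended (``100+``).
    """
    columns = {"Female": 2, "Male": 3, "Total": 4}
    if column not in columns:
        raise MortalityDataError(f"unknown column {column!r}; choose from {sorted(columns)}")
    col = columns[column]
    records = []
    open_ended = False
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split()
        if parts[0].lower() == "year":  # column-name row
            continue
        if len(parts) < 5:
            raise MortalityDataError(f"line {lineno}: expected 5 columns, got {len(parts)}")
        try:
            year = int(parts[0])
            age, is_open = _parse_age(parts[1])
            token = parts[col]
            value = np.nan if token == "." else float(token)
        except ValueError as exc:
            raise MortalityDataError(f"line {lineno}: {exc}") from None
        open_ended = open_ended or is_open
        records.append((year, age, value))
    if not records:
        raise MortalityDataError("no data rows")
    df = pd.DataFrame(records, columns=["year", "age", "value"])
    years = np.sort(df["year"].unique())
    ages = np.sort(df["age"].unique())
    if not np.all(np.diff(ages) == 1):
        raise MortalityDataError("non-contiguous ages in file")
    if not np.all(np.diff(years) == 1):
        raise MortalityDataError("non-contiguous years in file")
    mat = df.pivot_table(index="age", columns="year", values="value", dropna=False)
    mat = mat.reindex(index=ages, columns=years)
    return MortalitySurface(
        ages=ages, years=years, rates=mat.to_numpy(), label=column, open_ended=open_ended
    )


def write_long_csv(path, *surfaces: MortalitySurface) -> None:
    """Write surfaces as long CSV: year,age,population,deaths,exposure,rate."""
    frames = []
    for s in surfaces:
        k, n = s.n_ages, s.n_years
        frames.append(
            pd.DataFrame(
                {
                    "year": np.repeat(s.years, k),
                    "age": np.tile(s.ages, n),
                    "population": s.label,
                    "deaths": np.nan if s.deaths is None else s.deaths.T.ravel(),
                    "exposure": np.nan if s.exposures is None else s.exposures.T.ravel(),
                    "rate": s.rates.T.ravel(),
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format="%.17g")


def read_long_csv(path) -> PopulationSet:
    """Read the long CSV format back into a PopulationSet."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"year", "age", "population", "rate"}
    if not required.issubset(df.columns):
        raise MortalityDataError(f"long CSV needs columns {sorted(required)}")
    surfaces = {}
    for label, grp in df.groupby("population", sort=False):
        years = np.sort(grp["year"].unique())
        ages = np.sort(grp["age"].unique())

        def pivot(col):
            if col not in grp or grp[col].isna().all():
                return None
            m = grp.pivot_table(index="age", columns="year", values=col, dropna=False)
            return m.reindex(index=ages, columns=years).to_numpy()

        surfaces[str(label)] = MortalitySurface(
            ages=ages,
            years=years,
            rates=pivot("rate"),
            deaths=pivot("deaths"),
            exposures=pivot("exposure"),
            label=str(label),
            open_ended=bool(ages[-1] >= 100),
        )
    if len(surfaces) == 1:
        return PopulationSet(surfaces)
    return PopulationSet(surfaces)
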