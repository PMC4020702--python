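"""Domain types for joint known-fate / tag-recovery data and model structures.

Three tabular data streams feed the joint model:

* :class:`KnownFateSeries` — monthly radio-telemetry monitoring records
  (at-risk, deaths, censored, staggered entries) used for the Kaplan–Meier
  known-fate component.
* :class:`RecoveryData` — release cohorts of reward-tagged animals and the
  upper-triangular matrix of harvest recoveries by year (the Brownie
  dead-recovery component).
* :class:`RadioHarvestSeries` — counts of transmitter-fitted animals available
  and harvested each season (a binomial harvest component).

A :class:`ModelSpec` describes how each parameter family — monthly survival
``s``, harvest rate ``H``, annual survival ``S``, and radio harvest ``H_r`` —
varies over the design factors (month, year, age, unit, tag type), and
:func:`build_parameter_map` turns a spec plus data into a concrete free
parameter layout with the correct identifiable parameter count ``K``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DataValidationError",
    "SpecError",
    "IdentifiabilityError",
    "KnownFateSeries",
    "RecoveryData",
    "RadioHarvestSeries",
    "Dataset",
    "FamilySpec",
    "ModelSpec",
    "ParamEntry",
    "ParameterLayout",
    "FittedModel",
    "validate_known_fate",
    "validate_recoveries",
    "validate_radio_harvest",
    "build_parameter_map",
]

FACTOR_NAMES = ("month", "year", "age", "unit", "tag_type")

#: parameter families: monthly survival, harvest, annual survival, radio harvest
FAMILIES = ("s", "H", "S", "Hr")


class DataValidationError(ValueError):
    """A data stream violates its bookkeeping invariants."""


class SpecError(ValueError):
    """A model specification is malformed or incompatible with the data."""


class IdentifiabilityError(SpecError):
    """The requested structure leaves parameters structurally non-identifiable."""


# ---------------------------------------------------------------------------
# data streams
# ---------------------------------------------------------------------------

KNOWN_FATE_COLUMNS = ("stratum", "year", "month", "n", "d", "c", "e")
RELEASE_COLUMNS = ("year", "entry_month", "age", "unit", "tag_type", "released")
RECOVERY_COLUMNS = (
    "year_released",
    "entry_month",
    "age",
    "unit",
    "tag_type",
    "year_recovered",
    "count",
)
RADIO_HARVEST_COLUMNS = ("year", "unit", "age", "available", "harvested")


def _require_columns(table: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise DataValidationError(
            f"{what}: missing columns {missing}; expected {list(columns)}, "
            f"found {list(table.columns)}"
        )


def _check_counts(table: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    for col in columns:
        values = table[col].to_numpy()
        as_int = values.astype(np.int64, casting="unsafe")
        if not np.array_equal(as_int, values.astype(np.float64)):
            raise DataValidationError(f"{what}: column '{col}' must hold integers")
        if (as_int < 0).any():
            raise DataValidationError(f"{what}: column '{col}' has negative counts")


@dataclass
class KnownFateSeries:
    """Monthly known-fate monitoring records with staggered entry.

    One row per (stratum, year, month) interval: ``n`` animals at risk at the
    start of the interval, of which ``d`` died and ``c`` were censored, with
    ``e`` new entries at the start of the interval.  Within each
    (stratum, year) group the bookkeeping identity
    ``n[g+1] = n[g] - d[g] - c[g] + e[g+1]`` must hold.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.table, KNOWN_FATE_COLUMNS, "known-fate series")
        self.table = (
            self.table.loc[:, list(KNOWN_FATE_COLUMNS)]
            .sort_values(["stratum", "year", "month"], kind="mergesort")
            .reset_index(drop=True)
        )

    @classmethod
    def empty(cls) -> "KnownFateSeries":
        return cls(pd.DataFrame({c: [] for c in KNOWN_FATE_COLUMNS}))

    @property
    def is_empty(self) -> bool:
        return len(self.table) == 0

    @property
    def total_entries(self) -> int:
        return 0 if self.is_empty else int(self.table["e"].sum())


def validate_known_fate(series: KnownFateSeries) -> KnownFateSeries:
    """Check all :class:`KnownFateSeries` invariants; return the series.

    Raises :class:`DataValidationError` naming the first interval where the
    staggered-entry bookkeeping fails.
    """
    t = series.table
    if len(t) == 0:
        return series
    _check_counts(t, ("n", "d", "c", "e"), "known-fate series")
    bad = t["d"] + t["c"] > t["n"]
    if bad.any():
        row = t.loc[bad].iloc[0]
        raise DataValidationError(
            f"known-fate series: deaths + censored exceed at-risk count in "
            f"stratum={row['stratum']!r} year={row['year']} month={row['month']}"
        )
    for (stratum, year), grp in t.groupby(["stratum", "year"], sort=False):
        months = grp["month"].to_numpy()
        if len(np.unique(months)) != len(months):
            raise DataValidationError(
                f"known-fate series: duplicate month in stratum={stratum!r} year={year}"
            )
        n = grp["n"].to_numpy()
        d = grp["d"].to_numpy()
        c = grp["c"].to_numpy()
        e = grp["e"].to_numpy()
        expected = n[:-1] - d[:-1] - c[:-1] + e[1:]
        mismatch = np.nonzero(n[1:] != expected)[0]
        if mismatch.size:
            g = mismatch[0]
            raise DataValidationError(
                f"known-fate series: at-risk bookkeeping fails in "
                f"stratum={stratum!r} year={year} month={months[g + 1]}: "
                f"n={n[g + 1]} but {n[g]} - {d[g]} - {c[g]} + {e[g + 1]} = {expected[g]}"
            )
    return series


@dataclass
class RecoveryData:
    """Release cohorts and the upper-triangular recovery matrix.

    Cohorts are keyed by (release year, entry month, age, unit, tag type);
    ``releases`` holds one row per cohort with the number released and
    ``recoveries`` holds the recovery counts by recovery year.
    """

    releases: pd.DataFrame
    recoveries: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.releases, RELEASE_COLUMNS, "releases")
        _require_columns(self.recoveries, RECOVERY_COLUMNS, "recoveries")
        self.releases = (
            self.releases.loc[:, list(RELEASE_COLUMNS)]
            .sort_values(list(RELEASE_COLUMNS[:-1]), kind="mergesort")
            .reset_index(drop=True)
        )
        self.recoveries = (
            self.recoveries.loc[:, list(RECOVERY_COLUMNS)]
            .sort_values(list(RECOVERY_COLUMNS[:-1]), kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def years(self) -> list:
        """Sorted distinct release years; recovery years must lie among them."""
        return sorted(self.releases["year"].unique().tolist())

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def total_released(self) -> int:
        return int(self.releases["released"].sum())

    def recovery_matrix(self) -> tuple[pd.DataFrame, np.ndarray]:
        """Return (cohort table, U) with ``U[c, j]`` recoveries of cohort ``c``
        in year ``self.years[j]``."""
        years = self.years
        year_index = {y: j for j, y in enumerate(years)}
        cohorts = self.releases.reset_index(drop=True)
        key_cols = list(RELEASE_COLUMNS[:-1])
        index = {
            tuple(row): i
            for i, row in enumerate(cohorts[key_cols].itertuples(index=False))
        }
        U = np.zeros((len(cohorts), len(years)), dtype=np.int64)
        for row in self.recoveries.itertuples(index=False):
            key = (row.year_released, row.entry_month, row.age, row.unit, row.tag_type)
            U[index[key], year_index[row.year_recovered]] += int(row.count)
        return cohorts, U


def validate_recoveries(data: RecoveryData) -> RecoveryData:
    """Check all :class:`RecoveryData` invariants; return the data."""
    _check_counts(data.releases, ("released",), "releases")
    if len(data.recoveries):
        _check_counts(data.recoveries, ("count",), "recoveries")
    key_cols = list(RELEASE_COLUMNS[:-1])
    if data.releases.duplicated(key_cols).any():
        raise DataValidationError("releases: duplicate cohort keys")
    years = set(data.years)
    release_keys = set(
        tuple(row) for row in data.releases[key_cols].itertuples(index=False)
    )
    for row in data.recoveries.itertuples(index=False):
        key = (row.year_released, row.entry_month, row.age, row.unit, row.tag_type)
        if key not in release_keys:
            raise DataValidationError(
                f"recoveries: recovery for cohort {key} with no matching release"
            )
        if row.year_recovered < row.year_released:
            raise DataValidationError(
                f"recoveries: recovery before release for cohort {key} "
                f"(recovered {row.year_recovered})"
            )
        if row.year_recovered not in years:
            raise DataValidationError(
                f"recoveries: recovery year {row.year_recovered} is not a release "
                f"year; the multinomial covers only years with releases"
            )
    cohorts, U = data.recovery_matrix()
    total = U.sum(axis=1)
    over = total > cohorts["released"].to_numpy()
    if over.any():
        row = cohorts.loc[np.nonzero(over)[0][0]]
        raise DataValidationError(
            f"recoveries: cohort year={row['year']} entry_month={row['entry_month']} "
            f"age={row['age']!r} unit={row['unit']!r} tag_type={row['tag_type']!r} "
            f"has more recoveries than releases"
        )
    return data


@dataclass
class RadioHarvestSeries:
    """Per (year, unit, age): transmitter-fitted animals available (``m``) and
    harvested (``h``) during the season."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _require_columns(self.table, RADIO_HARVEST_COLUMNS, "radio-harvest series")
        self.table = (
            self.table.loc[:, list(RADIO_HARVEST_COLUMNS)]
            .sort_values(["year", "unit", "age"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def is_empty(self) -> bool:
        return len(self.table) == 0

    @property
    def total_available(self) -> int:
        return 0 if self.is_empty else int(self.table["available"].sum())


def validate_radio_harvest(series: RadioHarvestSeries) -> RadioHarvestSeries:
    t = series.table
    if len(t) == 0:
        return series
    _check_counts(t, ("available", "harvested"), "radio-harvest series")
    bad = t["harvested"] > t["available"]
    if bad.any():
        row = t.loc[bad].iloc[0]
        raise DataValidationError(
            f"radio-harvest series: harvested > available in year={row['year']} "
            f"unit={row['unit']!r} age={row['age']!r}"
        )
    if t.duplicated(["year", "unit", "age"]).any():
        raise DataValidationError("radio-harvest series: duplicate (year, unit, age)")
    return series


@dataclass
class Dataset:
    """Bundle of the (optional) three data streams for one analysis."""

    known_fate: KnownFateSeries | None = None
    recoveries: RecoveryData | None = None
    radio_harvest: RadioHarvestSeries | None = None

    def validate(self) -> "Dataset":
        if (
            self.known_fate is None
            and self.recoveries is None
            and self.radio_harvest is None
        ):
            raise DataValidationError("dataset holds no data streams")
        if self.known_fate is not None:
            validate_known_fate(self.known_fate)
        if self.recoveries is not None:
            validate_recoveries(self.recoveries)
        if self.radio_harvest is not None:
            validate_radio_harvest(self.radio_harvest)
        return self


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySpec:
    """Factor structure for one parameter family.

    ``factors`` lists the design factors the family varies over (empty means a
    single constant parameter); ``fixed`` pins every level of the family at a
    known probability instead of estimating it (e.g. monthly survival fixed at
    1.0 gives the classical dead-recovery model that assumes no
    tagging-to-harvest mortality).
    """

    factors: tuple[str, ...] = ()
    fixed: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        for f in self.factors:
            if f not in FACTOR_NAMES:
                raise SpecError(f"unknown factor {f!r}; choose from {FACTOR_NAMES}")
        if len(set(self.factors)) != len(self.factors):
            raise SpecError(f"duplicate factor in {self.factors}")
        if self.fixed is not None and not 0.0 <= self.fixed <= 1.0:
            raise SpecError("fixed value must be a probability in [0, 1]")
        if self.fixed is not None and self.factors:
            raise SpecError("a fixed family cannot also vary by factors")

    def to_dict(self) -> dict:
        if self.fixed is not None:
            return {"fixed": self.fixed}
        return {"factors": list(self.factors)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "FamilySpec":
        unknown = set(d) - {"factors", "fixed"}
        if unknown:
            raise SpecError(f"unknown family-spec keys {sorted(unknown)}")
        return cls(tuple(d.get("factors", ())), d.get("fixed"))


@dataclass(frozen=True)
class ModelSpec:
    """Factor structure of the joint model's four parameter families.

    ``radio_harvest=None`` aliases the radio-harvest rate to the harvest
    family (the H_i = H_ri constraint): radio-harvest cells then resolve in
    the harvest family with ``tag_type="radio"``.  Supplying a
    :class:`FamilySpec` instead gives transmitter-fitted animals their own
    harvest parameters.  ``preseason_end`` is the last pre-season month G, so
    a cohort entering in month ``g0`` accumulates tagging-to-harvest survival
    over months ``g0..G``.
    """

    monthly_survival: FamilySpec = FamilySpec(("month",))
    harvest: FamilySpec = FamilySpec(("year",))
    annual_survival: FamilySpec = FamilySpec(("year",))
    radio_harvest: FamilySpec | None = None
    preseason_end: int = 9

    def __post_init__(self) -> None:
        for name in ("harvest", "annual_survival"):
            fam = getattr(self, name)
            if "month" in fam.factors:
                raise SpecError(f"'month' is only a factor of monthly survival, not {name}")
        if self.radio_harvest is not None and "month" in self.radio_harvest.factors:
            raise SpecError("'month' is only a factor of monthly survival")
        if self.preseason_end < 1:
            raise SpecError("preseason_end must be >= 1")

    @property
    def radio_shares_harvest(self) -> bool:
        return self.radio_harvest is None

    def family(self, name: str) -> FamilySpec:
        if name == "s":
            return self.monthly_survival
        if name == "H":
            return self.harvest
        if name == "S":
            return self.annual_survival
        if name == "Hr":
            if self.radio_harvest is None:
                raise SpecError("radio harvest is shared with the harvest family")
            return self.radio_harvest
        raise SpecError(f"unknown parameter family {name!r}")

    def to_dict(self) -> dict:
        return {
            "monthly_survival": self.monthly_survival.to_dict(),
            "harvest": self.harvest.to_dict(),
            "annual_survival": self.annual_survival.to_dict(),
            "radio_harvest": "shared"
            if self.radio_harvest is None
            else self.radio_harvest.to_dict(),
            "preseason_end": self.preseason_end,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        known = {
            "monthly_survival",
            "harvest",
            "annual_survival",
            "radio_harvest",
            "preseason_end",
        }
        unknown = set(d) - known
        if unknown:
            raise SpecError(f"unknown model-spec keys {sorted(unknown)}")
        radio = d.get("radio_harvest", "shared")
        return cls(
            monthly_survival=FamilySpec.from_dict(d["monthly_survival"]),
            harvest=FamilySpec.from_dict(d["harvest"]),
            annual_survival=FamilySpec.from_dict(d["annual_survival"]),
            radio_harvest=None if radio == "shared" else FamilySpec.from_dict(radio),
            preseason_end=int(d.get("preseason_end", 9)),
        )


# ---------------------------------------------------------------------------
# likelihood cells (shared with the likelihood module)
# ---------------------------------------------------------------------------


@dataclass
class BrownieCohort:
    """One release cohort and its recovery counts over years ``years[first:]``."""

    attrs: dict
    released: int
    first: int  # index of the release year within the study's year list
    counts: np.ndarray  # recoveries in years[first], years[first+1], ..., years[-1]


@dataclass
class CellSet:
    """All likelihood cells implied by a dataset: known-fate intervals,
    Brownie cohorts, and radio-harvest binomial cells."""

    years: list
    km: list  # (attrs, n, d, c)
    cohorts: list  # BrownieCohort
    radio: list  # (attrs, available, harvested)
    preseason_end: int


def enumerate_cells(spec: ModelSpec, data: Dataset) -> CellSet:
    """Map a dataset onto likelihood cells with fully-attributed factor values."""
    years: list = []
    cohorts: list[BrownieCohort] = []
    if data.recoveries is not None:
        years = data.recoveries.years
        table, U = data.recoveries.recovery_matrix()
        year_index = {y: j for j, y in enumerate(years)}
        for c, row in enumerate(table.itertuples(index=False)):
            first = year_index[row.year]
            cohorts.append(
                BrownieCohort(
                    attrs={
                        "year": row.year,
                        "entry_month": int(row.entry_month),
                        "age": row.age,
                        "unit": row.unit,
                        "tag_type": row.tag_type,
                    },
                    released=int(row.released),
                    first=first,
                    counts=U[c, first:].copy(),
                )
            )

    km: list = []
    if data.known_fate is not None and not data.known_fate.is_empty:
        for row in data.known_fate.table.itertuples(index=False):
            attrs = {"month": int(row.month), "year": row.year, "age": row.stratum}
            km.append((attrs, int(row.n), int(row.d), int(row.c)))

    radio: list = []
    if data.radio_harvest is not None and not data.radio_harvest.is_empty:
        for row in data.radio_harvest.table.itertuples(index=False):
            attrs = {
                "year": row.year,
                "unit": row.unit,
                "age": row.age,
                "tag_type": "radio",
            }
            radio.append((attrs, int(row.available), int(row.harvested)))

    return CellSet(
        years=years, km=km, cohorts=cohorts, radio=radio, preseason_end=spec.preseason_end
    )


# ---------------------------------------------------------------------------
# parameter layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamEntry:
    """Resolution of one parameter level: a free-parameter index or a fixed value."""

    index: int | None = None
    fixed: float | None = None

    @property
    def is_free(self) -> bool:
        return self.index is not None


@dataclass
class ParameterLayout:
    """Index map from factor-level keys to free parameters on the link scale."""

    names: list
    factors: dict  # family -> tuple of factor names
    entries: dict  # family -> {level key: ParamEntry}
    family_fixed: dict  # family -> float | None
    K: int
    radio_family: str  # "H" if shared, else "Hr"

    def level_key(self, family: str, attrs: Mapping) -> tuple:
        try:
            return tuple(attrs[f] for f in self.factors[family])
        except KeyError as exc:
            raise SpecError(
                f"family {family!r} varies by factor {exc.args[0]!r} which the data "
                f"stream does not provide"
            ) from None

    def resolve(self, family: str, attrs: Mapping) -> ParamEntry:
        fixed = self.family_fixed.get(family)
        if fixed is not None:
            return ParamEntry(fixed=fixed)
        return self.entries[family][self.level_key(family, attrs)]

    def free_names(self) -> list:
        return list(self.names)


def _format_name(family: str, factors: tuple, key: tuple) -> str:
    if not factors:
        return family
    inner = ",".join(f"{f}={v}" for f, v in zip(factors, key))
    return f"{family}[{inner}]"


def _family_attrs_key(factors: tuple, attrs: Mapping, family: str) -> tuple:
    try:
        return tuple(attrs[f] for f in factors)
    except KeyError as exc:
        raise SpecError(
            f"family {family!r} varies by factor {exc.args[0]!r} which the data "
            f"stream does not provide"
        ) from None


def build_parameter_map(spec: ModelSpec, data: Dataset) -> ParameterLayout:
    """Build the free-parameter layout for ``spec`` applied to ``data``.

    Parameter levels are enumerated from the likelihood cells that use them,
    so structurally non-identifiable parameters (e.g. the final-year annual
    survival, which appears in no expected-recovery cell) never enter the
    count ``K``.  Radio-harvest levels informed only by cells with zero
    availability are fixed at 0 and excluded from ``K``.

    Raises :class:`IdentifiabilityError` when tag-recovery cohorts require
    monthly-survival levels that no known-fate interval informs (the
    cumulative pre-season survival and the recovery rate would be confounded).
    """
    cells = enumerate_cells(spec, data)
    radio_family = "H" if spec.radio_shares_harvest else "Hr"

    fams = {
        "s": spec.monthly_survival,
        "H": spec.harvest,
        "S": spec.annual_survival,
    }
    if not spec.radio_shares_harvest:
        fams["Hr"] = spec.radio_harvest

    used: dict = {f: {} for f in fams}  # family -> key -> usage dict

    def touch(family: str, attrs: Mapping, source: str, m: int = 0) -> None:
        fam = fams[family]
        if fam.fixed is not None:
            return
        key = _family_attrs_key(fam.factors, attrs, family)
        info = used[family].setdefault(key, {"km": False, "brownie": False, "radio_m": 0, "radio": False})
        if source == "km":
            info["km"] = True
        elif source == "brownie":
            info["brownie"] = True
        else:
            info["radio"] = True
            info["radio_m"] += m

    for attrs, _n, _d, _c in cells.km:
        touch("s", attrs, "km")

    G = spec.preseason_end
    years = cells.years
    for coh in cells.cohorts:
        g0 = coh.attrs["entry_month"]
        if g0 > G:
            raise SpecError(
                f"cohort entry month {g0} is after the last pre-season month {G}"
            )
        for g in range(g0, G + 1):
            touch("s", {**coh.attrs, "month": g}, "brownie")
        for j in range(coh.first, len(years)):
            touch("H", {**coh.attrs, "year": years[j]}, "brownie")
            for k in range(coh.first, j):
                touch("S", {**coh.attrs, "year": years[k]}, "brownie")

    for attrs, m, _h in cells.radio:
        touch(radio_family, attrs, "radio", m=m)

    # identifiability: every monthly-survival level entering a cumulative
    # pre-season survival product must be informed by known-fate data
    if fams["s"].fixed is None:
        orphans = [
            key
            for key, info in used["s"].items()
            if info["brownie"] and not info["km"]
        ]
        if orphans:
            names = [_format_name("s", fams["s"].factors, k) for k in sorted(orphans, key=repr)]
            raise IdentifiabilityError(
                "cumulative pre-season survival and the recovery rate are "
                "confounded: no known-fate data inform monthly-survival "
                f"levels {names}; supply known-fate intervals or fix monthly "
                "survival (e.g. at 1.0)"
            )

    names: list = []
    entries: dict = {}
    factors: dict = {}
    family_fixed: dict = {}
    for family, fam in fams.items():
        factors[family] = fam.factors
        family_fixed[family] = fam.fixed
        entries[family] = {}
        if fam.fixed is not None:
            continue
        for key in sorted(used[family].keys(), key=repr):
            info = used[family][key]
            if (
                info["radio"]
                and not info["brownie"]
                and not info["km"]
                and info["radio_m"] == 0
            ):
                # no transmitter-fitted animals ever available at this level:
                # harvest rate constrained to 0, not a free parameter
                entries[family][key] = ParamEntry(fixed=0.0)
                continue
            entries[family][key] = ParamEntry(index=len(names))
            names.append(_format_name(family, fam.factors, key))

    if spec.radio_shares_harvest:
        factors["Hr"] = factors["H"]
        entries["Hr"] = entries["H"]
        family_fixed["Hr"] = family_fixed["H"]

    return ParameterLayout(
        names=names,
        factors=factors,
        entries=entries,
        family_fixed=family_fixed,
        K=len(names),
        radio_family=radio_family,
    )


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


@dataclass
class FittedModel:
    """Result of maximizing the joint log-likelihood under a :class:`ModelSpec`."""

    spec: ModelSpec
    layout: ParameterLayout
    theta: np.ndarray  # free parameters on the logit scale
    loglik: float
    K: int
    n_eff: int
    aicc: float
    converged: bool
    estimates: pd.DataFrame  # family, level, estimate, se, lower95, upper95, ...
    vcov: np.ndarray | None = None  # link-scale variance-covariance, K x K
    se_available: bool = True
    hess_rank: int | None = None
    message: str = ""
    n_restarts: int = 1

    def real_estimates(self) -> np.ndarray:
        from scipy.special import expit

        return expit(self.theta)

    def value(self, family: str, **attrs) -> float:
        """Look up one real-scale parameter value by its factor attributes."""
        entry = self.layout.resolve(family, attrs)
        if not entry.is_free:
            return float(entry.fixed)
        from scipy.special import expit

        return float(expit(self.theta[entry.index]))
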