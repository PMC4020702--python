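"""Monte-Carlo study machinery: scenario generator, allocation grids, metrics.

The shipped scenarios reproduce a two-species design study: three annual
release cohorts, nine pre-season months, constant true rates, and a grid of
transmitter x reward-tag allocations released *each year*.  Species A is a
heavily harvested, short-lived life history (cumulative pre-season survival
0.90, harvest 0.60, annual survival 0.30); species B survives the pre-season
less often and is lightly harvested (0.69, 0.10, 0.60).

For each allocation the engine simulates replicate datasets, fits either the
classical dead-recovery model (monthly survival fixed at 1, used when no
transmitters are allocated) or the joint model (year-specific monthly
survival, year-specific harvest, identifiable annual survival), and summarizes
annual harvest-rate estimates as absolute/relative bias, CV, and CV(RMSE).

Transmitter animals are simulated only through the pre-season months: their
season fates do not feed harvest estimation in these scenarios, so the
radio-harvest binomial component is exercised by the case-study fixtures
(:func:`make_case_study_fixture`), not the grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    Dataset,
    FamilySpec,
    KnownFateSeries,
    ModelSpec,
    RadioHarvestSeries,
    RecoveryData,
    KNOWN_FATE_COLUMNS,
)
from . import estimation

__all__ = [
    "Scenario",
    "SPECIES_A",
    "SPECIES_B",
    "GridResult",
    "simulate_dataset",
    "run_grid",
    "bias_summary",
    "cv",
    "cv_rmse",
    "make_case_study_fixture",
    "simulation_joint_spec",
    "brownie_only_spec",
    "turkey_year_spec",
    "turkey_constant_spec",
    "deer_null_spec",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# model-structure builders
# ---------------------------------------------------------------------------


def simulation_joint_spec(preseason_end: int = 9) -> ModelSpec:
    """Joint model used on simulated grids: monthly survival by month x year,
    harvest by year, annual survival by year (final year not identifiable)."""
    return ModelSpec(
        monthly_survival=FamilySpec(("month", "year")),
        harvest=FamilySpec(("year",)),
        annual_survival=FamilySpec(("year",)),
        preseason_end=preseason_end,
    )


def brownie_only_spec(preseason_end: int = 9) -> ModelSpec:
    """Classical dead-recovery model: pre-season survival assumed to be 1."""
    return ModelSpec(
        monthly_survival=FamilySpec(fixed=1.0),
        harvest=FamilySpec(("year",)),
        annual_survival=FamilySpec(("year",)),
        preseason_end=preseason_end,
    )


def turkey_year_spec() -> ModelSpec:
    """Staggered-entry design with monthly survival by month x age (pooled
    over years) and year-varying harvest and annual survival."""
    return ModelSpec(
        monthly_survival=FamilySpec(("month", "age")),
        harvest=FamilySpec(("year",)),
        annual_survival=FamilySpec(("year",)),
        preseason_end=9,
    )


def turkey_constant_spec() -> ModelSpec:
    """As :func:`turkey_year_spec` but with constant harvest and survival."""
    return ModelSpec(
        monthly_survival=FamilySpec(("month", "age")),
        harvest=FamilySpec(()),
        annual_survival=FamilySpec(()),
        preseason_end=9,
    )


def deer_null_spec() -> ModelSpec:
    """Multi-unit design: monthly survival by age, harvest and annual survival
    by management unit, radio harvest shared with the harvest family."""
    return ModelSpec(
        monthly_survival=FamilySpec(("age",)),
        harvest=FamilySpec(("unit",)),
        annual_survival=FamilySpec(("unit",)),
        radio_harvest=None,
        preseason_end=9,
    )


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """True rates and study design for a simulation grid.

    ``cumulative_preseason_survival`` is the product of the (constant) true
    monthly survival over the ``preseason_months`` pre-season months; the
    monthly truth is its ``1/G`` power.  Allocations are released each year.
    """

    cumulative_preseason_survival: float
    harvest_rate: float
    annual_survival: float
    years: int = 3
    preseason_months: int = 9
    radio_allocations: tuple = (0, 10, 25, 50, 75, 100, 150, 200)
    tag_allocations: tuple = (50, 100, 200, 300, 400, 500, 600)
    n_replicates: int = 1000
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        for value, what in (
            (self.cumulative_preseason_survival, "cumulative pre-season survival"),
            (self.harvest_rate, "harvest rate"),
            (self.annual_survival, "annual survival"),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{what} must be in [0, 1], got {value}")
        if self.years < 1 or self.preseason_months < 1:
            raise ValueError("years and preseason_months must be >= 1")

    @property
    def monthly_survival(self) -> float:
        return self.cumulative_preseason_survival ** (1.0 / self.preseason_months)

    def to_dict(self) -> dict:
        return {
            "cumulative_preseason_survival": self.cumulative_preseason_survival,
            "harvest_rate": self.harvest_rate,
            "annual_survival": self.annual_survival,
            "years": self.years,
            "preseason_months": self.preseason_months,
            "radio_allocations": list(self.radio_allocations),
            "tag_allocations": list(self.tag_allocations),
            "replicates": self.n_replicates,
            "seed": self.seed,
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        reps = d.pop("replicates", d.pop("n_replicates", 1000))
        known = {
            "cumulative_preseason_survival",
            "harvest_rate",
            "annual_survival",
            "years",
            "preseason_months",
            "radio_allocations",
            "tag_allocations",
            "seed",
            "name",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario keys {sorted(unknown)}")
        for key in ("radio_allocations", "tag_allocations"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(n_replicates=int(reps), **d)


SPECIES_A = Scenario(0.90, 0.60, 0.30, name="species_A")
SPECIES_B = Scenario(0.69, 0.10, 0.60, name="species_B")


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------


def simulate_dataset(
    scenario: Scenario, n_tags: int, n_radio: int, rng: np.random.Generator
) -> Dataset:
    """Simulate one study: known-fate monitoring of ``n_radio`` transmitter
    animals per year through the pre-season months, and multinomial recovery
    fates for ``n_tags`` tagged animals per year.

    With ``n_radio=0`` the known-fate stream is empty and downstream fits must
    fix monthly survival (see :func:`brownie_only_spec`).
    """
    G = scenario.preseason_months
    J = scenario.years
    s = scenario.monthly_survival
    H = scenario.harvest_rate
    S = scenario.annual_survival

    km_rows = []
    if n_radio > 0:
        for year in range(1, J + 1):
            alive = n_radio
            for month in range(1, G + 1):
                deaths = int(rng.binomial(alive, 1.0 - s)) if alive > 0 else 0
                km_rows.append(("all", year, month, alive, deaths, 0,
                                n_radio if month == 1 else 0))
                alive -= deaths
    known_fate = (
        KnownFateSeries(pd.DataFrame(km_rows, columns=list(KNOWN_FATE_COLUMNS)))
        if km_rows
        else None
    )

    sg = scenario.cumulative_preseason_survival
    release_rows = []
    recovery_rows = []
    for year in range(1, J + 1):
        probs = [sg * H * S ** (j - year) for j in range(year, J + 1)]
        probs.append(1.0 - sum(probs))
        counts = rng.multinomial(n_tags, probs)
        release_rows.append((year, 1, "all", "all", "tag", n_tags))
        for offset, j in enumerate(range(year, J + 1)):
            if counts[offset] > 0:
                recovery_rows.append((year, 1, "all", "all", "tag", j, counts[offset]))
    recoveries = RecoveryData(
        releases=pd.DataFrame(
            release_rows,
            columns=["year", "entry_month", "age", "unit", "tag_type", "released"],
        ),
        recoveries=pd.DataFrame(
            recovery_rows,
            columns=[
                "year_released",
                "entry_month",
                "age",
                "unit",
                "tag_type",
                "year_recovered",
                "count",
            ],
        ),
    )
    return Dataset(known_fate=known_fate, recoveries=recoveries)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def bias_summary(mean_estimates, truth: float) -> dict:
    """Absolute and relative bias of per-cell mean estimates, with
    mean/min/max/SD summaries across cells.

    ``mean_estimates`` holds one replicate-averaged estimate per
    allocation-year cell.  Relative bias is absolute bias divided by the true
    value; undefined (flagged with NaN) when the truth is 0.
    """
    est = np.asarray(mean_estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates")
    absolute = est - truth
    if truth == 0.0:
        warnings.warn("relative bias undefined for a true value of 0", RuntimeWarning)
        relative = np.full_like(absolute, np.nan)
    else:
        relative = absolute / truth

    def stats(x):
        return {
            "mean": float(np.mean(x)),
            "min": float(np.min(x)),
            "max": float(np.max(x)),
            "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        }

    return {"absolute": stats(absolute), "relative": stats(relative)}


def cv(estimates) -> float:
    """Coefficient of variation of replicate estimates, in percent:
    ``100 * SD / mean``."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("CV needs at least two estimates")
    mean = est.mean()
    if mean == 0.0:
        warnings.warn("CV undefined: mean estimate is 0", RuntimeWarning)
        return float("nan")
    return float(100.0 * est.std(ddof=1) / mean)


def cv_rmse(estimates, truth: float) -> float:
    """Root-mean-squared error relative to the true value, in percent:
    ``100 * sqrt(mean((est - truth)^2)) / truth``.  Combines bias and
    imprecision."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates")
    if truth == 0.0:
        warnings.warn("CV(RMSE) undefined for a true value of 0", RuntimeWarning)
        return float("nan")
    return float(100.0 * np.sqrt(np.mean((est - truth) ** 2)) / truth)


# ---------------------------------------------------------------------------
# grid engine
# ---------------------------------------------------------------------------


@dataclass
class GridResult:
    """Per-allocation-year metrics of a simulation grid.

    ``metrics`` has one row per (n_radio, n_tags, year) with the mean harvest
    estimate, absolute/relative bias, CV, CV(RMSE), and — for joint
    allocations when the grid includes a 0-transmitter baseline — the
    percentage-point CV(RMSE) improvement over that baseline (negative means
    the joint estimator did worse).
    """

    scenario: Scenario
    metrics: pd.DataFrame
    exclusions: pd.DataFrame  # per allocation: replicates fitted/excluded

    def summary(self) -> pd.DataFrame:
        """Bias summaries across allocation-year cells, per estimator.

        Each cell is first averaged over replicates; the rows mirror the
        usual reporting of simulation studies (mean/min/max/SD of absolute
        and relative bias for the 0-transmitter estimator and the joint
        estimator)."""
        rows = []
        truth = self.scenario.harvest_rate
        for model, grp in self.metrics.groupby("model", sort=True):
            b = bias_summary(grp["mean_estimate"].to_numpy(), truth)
            rows.append(
                {
                    "model": model,
                    "abs_bias_mean": b["absolute"]["mean"],
                    "abs_bias_min": b["absolute"]["min"],
                    "abs_bias_max": b["absolute"]["max"],
                    "abs_bias_sd": b["absolute"]["sd"],
                    "rel_bias_mean": b["relative"]["mean"],
                    "rel_bias_min": b["relative"]["min"],
                    "rel_bias_max": b["relative"]["max"],
                    "rel_bias_sd": b["relative"]["sd"],
                    "cv_mean": float(grp["cv"].mean()),
                    "cv_rmse_mean": float(grp["cv_rmse"].mean()),
                }
            )
        return pd.DataFrame(rows)


def _fit_one(dataset: Dataset, joint: bool, G: int, n_restarts: int):
    spec = simulation_joint_spec(G) if joint else brownie_only_spec(G)
    return estimation.fit(
        spec, dataset, n_restarts=n_restarts, compute_se=False
    )


def run_grid(
    scenario: Scenario,
    *,
    n_restarts: int = 2,
    progress: bool = False,
) -> GridResult:
    """Run the full allocation grid for ``scenario``.

    For every (transmitters, tags) allocation, ``scenario.n_replicates``
    datasets are simulated and fitted; replicates whose fit does not converge
    are excluded (a warning is raised if any allocation loses more than 10%).
    Each (allocation, replicate) draws from its own child RNG stream derived
    from the scenario seed, so any cell is reproducible in isolation.
    """
    truth = scenario.harvest_rate
    J = scenario.years
    metric_rows = []
    exclusion_rows = []
    estimates_store: dict = {}

    for ri, n_radio in enumerate(scenario.radio_allocations):
        for ti, n_tags in enumerate(scenario.tag_allocations):
            joint = n_radio > 0
            ests = np.full((scenario.n_replicates, J), np.nan)
            excluded = 0
            for rep in range(scenario.n_replicates):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=scenario.seed, spawn_key=(ri, ti, rep)
                    )
                )
                data = simulate_dataset(scenario, n_tags, n_radio, rng)
                try:
                    fitted = _fit_one(data, joint, scenario.preseason_months, n_restarts)
                except Exception:  # pragma: no cover - defensive
                    log.exception("fit failed for allocation (%s, %s)", n_radio, n_tags)
                    excluded += 1
                    continue
                if not fitted.converged:
                    excluded += 1
                    continue
                years = data.recoveries.years
                ests[rep] = [fitted.value("H", year=y) for y in years]
            ok = ~np.isnan(ests[:, 0])
            n_ok = int(ok.sum())
            exclusion_rows.append(
                {
                    "n_radio": n_radio,
                    "n_tags": n_tags,
                    "n_fitted": n_ok,
                    "n_excluded": excluded,
                    "exclusion_rate": excluded / scenario.n_replicates,
                }
            )
            if excluded / scenario.n_replicates > 0.10:
                warnings.warn(
                    f"allocation (radios={n_radio}, tags={n_tags}): "
                    f"{excluded}/{scenario.n_replicates} replicates excluded "
                    "for non-convergence",
                    RuntimeWarning,
                )
            estimates_store[(n_radio, n_tags)] = ests[ok]
            for j in range(J):
                col = ests[ok, j]
                metric_rows.append(
                    {
                        "model": "joint" if joint else "brownie",
                        "n_radio": n_radio,
                        "n_tags": n_tags,
                        "year": j + 1,
                        "n_fits": n_ok,
                        "mean_estimate": float(col.mean()),
                        "abs_bias": float(col.mean() - truth),
                        "rel_bias": float((col.mean() - truth) / truth)
                        if truth
                        else np.nan,
                        "cv": cv(col) if n_ok > 1 else np.nan,
                        "cv_rmse": cv_rmse(col, truth),
                    }
                )
            if progress:  # pragma: no cover
                log.info("allocation radios=%s tags=%s done", n_radio, n_tags)

    metrics = pd.DataFrame(metric_rows)
    # CV(RMSE) improvement over the 0-transmitter baseline with the same tags
    metrics["cv_rmse_diff_vs_baseline"] = np.nan
    if 0 in scenario.radio_allocations:
        base = (
            metrics[metrics["n_radio"] == 0]
            .set_index(["n_tags", "year"])["cv_rmse"]
        )
        joint_mask = metrics["n_radio"] > 0
        keys = list(zip(metrics.loc[joint_mask, "n_tags"], metrics.loc[joint_mask, "year"]))
        base_vals = np.array([float(base.get(k, np.nan)) for k in keys])
        metrics.loc[joint_mask, "cv_rmse_diff_vs_baseline"] = (
            base_vals - metrics.loc[joint_mask, "cv_rmse"].to_numpy()
        )
    return GridResult(
        scenario=scenario,
        metrics=metrics,
        exclusions=pd.DataFrame(exclusion_rows),
    )


# ---------------------------------------------------------------------------
# case-study fixtures
# ---------------------------------------------------------------------------


def _simulate_staggered_known_fate(
    cohorts, s_lookup, G: int, rng: np.random.Generator
):
    """Simulate staggered-entry monthly monitoring.

    ``cohorts`` is an iterable of (stratum, year, entry_month, n); ``s_lookup``
    maps (stratum, month) to the true monthly survival.  Returns known-fate
    rows plus the per-(stratum, year) survivor counts at the end of month G
    (the animals available for the season).
    """
    entries: dict = {}
    for stratum, year, month, n in cohorts:
        entries.setdefault((stratum, year), {}).setdefault(month, 0)
        entries[(stratum, year)][month] += n
    rows = []
    survivors = {}
    for (stratum, year), by_month in sorted(entries.items(), key=repr):
        first = min(by_month)
        alive = 0
        for month in range(first, G + 1):
            e = by_month.get(month, 0)
            alive += e
            deaths = (
                int(rng.binomial(alive, 1.0 - s_lookup(stratum, month)))
                if alive > 0
                else 0
            )
            rows.append((stratum, year, month, alive, deaths, 0, e))
            alive -= deaths
        survivors[(stratum, year)] = alive
    return rows, survivors


@dataclass(frozen=True)
class _TurkeyDesign:
    years: tuple = (2010, 2011, 2012)
    entry_months: tuple = (1, 2, 3)
    entry_split: tuple = (0.4, 0.35, 0.25)
    banded: dict = field(
        default_factory=lambda: {
            "adult": (162, 167, 169),
            "juvenile": (74, 128, 109),
        }
    )
    radios: dict = field(
        default_factory=lambda: {"adult": (55, 42, 32), "juvenile": (6, 11, 15)}
    )
    preseason_survival: dict = field(
        default_factory=lambda: {"adult": 0.45, "juvenile": 0.51}
    )
    harvest: tuple = (0.054, 0.088, 0.022)
    annual_survival: float = 0.55


@dataclass(frozen=True)
class _DeerDesign:
    years: tuple = (2009, 2010, 2011)
    units: tuple = ("2D", "2G", "3C", "4B")
    entry_month: int = 2
    tagged: dict = field(
        default_factory=lambda: {"adult": 60, "juvenile": 25}
    )
    radios: dict = field(default_factory=lambda: {"adult": 30, "juvenile": 8})
    monthly_survival: dict = field(
        default_factory=lambda: {"adult": 0.9905, "juvenile": 0.9799}
    )
    harvest: dict = field(
        default_factory=lambda: {"2D": 0.138, "2G": 0.116, "3C": 0.111, "4B": 0.133}
    )
    radio_harvest: dict | None = None  # None: same as harvest (no tag effect)
    annual_survival: float = 0.70


def _multinomial_recoveries(
    rng, released, sg, first, years, harvest, annual
):
    """Draw one cohort's recovery fates; returns counts per recovery year."""
    probs = []
    carry = sg
    for j in range(first, len(years)):
        probs.append(carry * harvest[j])
        if j < len(years) - 1:
            carry *= annual[j]
    probs.append(1.0 - sum(probs))
    return rng.multinomial(released, probs)[:-1]


def make_case_study_fixture(
    design: str, rng: np.random.Generator, **overrides
) -> Dataset:
    """Generate a synthetic dataset emulating one of the two case-study
    designs.

    ``design="turkey"``: three years of January–March staggered tagging of two
    age classes, leg bands plus a transmitter subset, an autumn season after
    pre-season month 9 — low pre-season survival (~0.45–0.51), low year-varying
    harvest.  Transmitter birds contribute known-fate data only.

    ``design="deer"``: three years x four management units x two age classes,
    ear tags plus transmitters, high monthly survival, unit-specific harvest
    shared (by default) between tag types, with a radio-harvest series for
    transmitter animals.

    Counts and rates default to magnitudes of the respective field studies and
    can be overridden via keyword arguments of the design dataclasses.
    Identical seeds give identical datasets.
    """
    if design == "turkey":
        d = _TurkeyDesign(**overrides)
        return _turkey_fixture(d, rng)
    if design == "deer":
        d = _DeerDesign(**overrides)
        return _deer_fixture(d, rng)
    raise ValueError(f"unknown design {design!r}; choose 'turkey' or 'deer'")


def _split_counts(total: int, fractions) -> list:
    counts = [int(round(total * f)) for f in fractions]
    counts[0] += total - sum(counts)
    return counts


def _turkey_fixture(d: _TurkeyDesign, rng: np.random.Generator) -> Dataset:
    G = 9
    s_monthly = {
        age: d.preseason_survival[age] ** (1.0 / G) for age in d.preseason_survival
    }

    km_cohorts = []
    tag_cohorts = []  # (year, entry_month, age, released)
    for age in ("adult", "juvenile"):
        for yi, year in enumerate(d.years):
            radio_split = _split_counts(d.radios[age][yi], d.entry_split)
            band_only = d.banded[age][yi] - d.radios[age][yi]
            band_split = _split_counts(band_only, d.entry_split)
            for month, n_radio, n_band in zip(d.entry_months, radio_split, band_split):
                if n_radio:
                    km_cohorts.append((age, year, month, n_radio))
                if n_band:
                    tag_cohorts.append((year, month, age, n_band))

    km_rows, _ = _simulate_staggered_known_fate(
        km_cohorts, lambda age, _m: s_monthly[age], G, rng
    )
    known_fate = KnownFateSeries(
        pd.DataFrame(km_rows, columns=list(KNOWN_FATE_COLUMNS))
    )

    years = list(d.years)
    annual = [d.annual_survival] * len(years)
    release_rows = []
    recovery_rows = []
    for year, month, age, released in tag_cohorts:
        first = years.index(year)
        sg = s_monthly[age] ** (G - month + 1)
        counts = _multinomial_recoveries(
            rng, released, sg, first, years, d.harvest, annual
        )
        release_rows.append((year, month, age, "all", "band", released))
        for offset, count in enumerate(counts):
            if count > 0:
                recovery_rows.append(
                    (year, month, age, "all", "band", years[first + offset], count)
                )
    recoveries = RecoveryData(
        releases=pd.DataFrame(
            release_rows,
            columns=["year", "entry_month", "age", "unit", "tag_type", "released"],
        ),
        recoveries=pd.DataFrame(
            recovery_rows,
            columns=[
                "year_released",
                "entry_month",
                "age",
                "unit",
                "tag_type",
                "year_recovered",
                "count",
            ],
        ),
    )
    return Dataset(known_fate=known_fate, recoveries=recoveries)


def _deer_fixture(d: _DeerDesign, rng: np.random.Generator) -> Dataset:
    G = 9
    years = list(d.years)
    radio_harvest_rates = d.radio_harvest if d.radio_harvest is not None else d.harvest
    annual = [d.annual_survival] * len(years)

    km_cohorts = []
    for age in ("adult", "juvenile"):
        for year in years:
            for unit in d.units:
                km_cohorts.append((age, (year, unit), d.entry_month, d.radios[age]))

    # known-fate rows are pooled over units (stratum = age); simulate per
    # (age, year, unit) so season availability stays unit-specific
    entries_rows, survivors = _simulate_staggered_known_fate(
        km_cohorts, lambda age, _m: d.monthly_survival[age], G, rng
    )
    pooled: dict = {}
    for stratum, (year, _unit), month, n, deaths, c, e in entries_rows:
        key = (stratum, year, month)
        if key not in pooled:
            pooled[key] = [0, 0, 0, 0]
        pooled[key][0] += n
        pooled[key][1] += deaths
        pooled[key][2] += c
        pooled[key][3] += e
    km_rows = [
        (stratum, year, month, *vals)
        for (stratum, year, month), vals in sorted(pooled.items(), key=repr)
    ]
    known_fate = KnownFateSeries(
        pd.DataFrame(km_rows, columns=list(KNOWN_FATE_COLUMNS))
    )

    radio_rows = []
    for (age, (year, unit)), available in sorted(survivors.items(), key=repr):
        harvested = (
            int(rng.binomial(available, radio_harvest_rates[unit]))
            if available > 0
            else 0
        )
        radio_rows.append((year, unit, age, available, harvested))
    radio_harvest = RadioHarvestSeries(
        pd.DataFrame(
            radio_rows, columns=["year", "unit", "age", "available", "harvested"]
        )
    )

    release_rows = []
    recovery_rows = []
    for age in ("adult", "juvenile"):
        sg = d.monthly_survival[age] ** (G - d.entry_month + 1)
        for year in years:
            first = years.index(year)
            for unit in d.units:
                released = d.tagged[age]
                harvest_by_year = [d.harvest[unit]] * len(years)
                counts = _multinomial_recoveries(
                    rng, released, sg, first, years, harvest_by_year, annual
                )
                release_rows.append(
                    (year, d.entry_month, age, unit, "ear", released)
                )
                for offset, count in enumerate(counts):
                    if count > 0:
                        recovery_rows.append(
                            (year, d.entry_month, age, unit, "ear",
                             years[first + offset], count)
                        )
    recoveries = RecoveryData(
        releases=pd.DataFrame(
            release_rows,
            columns=["year", "entry_month", "age", "unit", "tag_type", "released"],
        ),
        recoveries=pd.DataFrame(
            recovery_rows,
            columns=[
                "year_released",
                "entry_month",
                "age",
                "unit",
                "tag_type",
                "year_recovered",
                "count",
            ],
        ),
    )
    return Dataset(
        known_fate=known_fate, recoveries=recoveries, radio_harvest=radio_harvest
    )
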