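"""Log-likelihood kernels for the joint known-fate / tag-recovery model.

Three independent data streams contribute, and because they are independent
the joint log-likelihood is simply their sum:

* Kaplan–Meier known-fate intervals: each monthly interval contributes a
  binomial kernel ``(n - d - c) ln s + d ln(1 - s)`` (censored animals are
  removed before the survival/death split; binomial coefficients are dropped
  throughout, so log-likelihood values are comparable only within a dataset).
* Brownie dead-recovery cohorts: a multinomial over the recovery year with
  cell probabilities ``p_ij = S_Gi * H_j * prod_{k=i..j-1} S_k`` and a final
  never-recovered cell ``1 - sum_j p_ij``.  ``S_Gi`` is the cumulative
  tagging-to-harvest survival — the product of the same monthly rates the
  known-fate kernel estimates, which is what makes ``S_Gi`` and the recovery
  rate separately estimable.
* Radio-harvest binomials: ``h ln H_r + (m - h) ln(1 - H_r)`` per season.

The reporting rate is taken as 1 (reward tags), so the recovery rate equals
the harvest rate; no reporting parameters exist anywhere in the package.

:class:`JointDesign` compiles a :class:`~jointharvest.datamodel.ModelSpec`
plus dataset into flat arrays with an incidence matrix from likelihood cells
to free logit-scale parameters, giving a fast joint log-likelihood with an
analytic gradient for the optimizer.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, xlogy

from .datamodel import (
    CellSet,
    Dataset,
    KnownFateSeries,
    ModelSpec,
    ParameterLayout,
    RadioHarvestSeries,
    RecoveryData,
    build_parameter_map,
    enumerate_cells,
)

__all__ = [
    "km_loglik",
    "cumulative_survival",
    "brownie_expected_recoveries",
    "brownie_cell_probs",
    "brownie_loglik",
    "radio_harvest_loglik",
    "joint_loglik",
    "JointDesign",
]

_TINY = 1e-300
#: floor for the never-recovered tail: keeps the objective finite and the
#: gradient steep-but-bounded when cell probabilities transiently sum past 1
_TAIL_FLOOR = 1e-10


def _flag_impossible(what: str) -> None:
    warnings.warn(f"zero-probability {what} observed: log-likelihood is -inf",
                  RuntimeWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# component kernels
# ---------------------------------------------------------------------------


def km_loglik(monthly_survival, series: KnownFateSeries) -> float:
    """Kaplan–Meier interval log-likelihood kernel.

    ``monthly_survival`` is a scalar or an array aligned with the rows of
    ``series.table``; each row contributes
    ``(n - d - c) * ln(s) + d * ln(1 - s)``.
    """
    t = series.table
    if len(t) == 0:
        return 0.0
    s = np.broadcast_to(np.asarray(monthly_survival, dtype=float), len(t))
    surv = (t["n"] - t["d"] - t["c"]).to_numpy(dtype=float)
    dead = t["d"].to_numpy(dtype=float)
    ll = float(np.sum(xlogy(surv, s)) + np.sum(xlogy(dead, 1.0 - s)))
    if not np.isfinite(ll):
        _flag_impossible("known-fate interval")
        return -np.inf
    return ll


def cumulative_survival(monthly_rates, entry_month: int, end_month: int) -> float:
    """Product of monthly survival rates over months ``entry_month..end_month``.

    ``monthly_rates`` may be a mapping from month number to rate or a sequence
    indexed by month 1..G.  An animal entering in March (month 3) with a
    season opening after month 9 accumulates 7 monthly terms; a January entry
    accumulates 9.
    """
    if entry_month > end_month:
        raise ValueError(
            f"empty month range: entry month {entry_month} after end month {end_month}"
        )
    if isinstance(monthly_rates, Mapping):
        rates = [monthly_rates[g] for g in range(entry_month, end_month + 1)]
    else:
        seq = list(monthly_rates)
        rates = [seq[g - 1] for g in range(entry_month, end_month + 1)]
    return float(np.prod(np.asarray(rates, dtype=float)))


def brownie_expected_recoveries(released, preseason_survival, harvest, annual_survival):
    """Expected recovery matrix for one-cohort-per-year releases.

    ``released[i]``, ``preseason_survival[i]`` (``S_Gi``) per release year,
    ``harvest[j]`` per recovery year, ``annual_survival[k]`` for the first
    ``J - 1`` years (a final-year value, if given, is never used).  Returns the
    upper-triangular ``J x J`` matrix with
    ``E[R_ij] = N_i * S_Gi * H_j * prod_{k=i..j-1} S_k``.
    """
    released = np.asarray(released, dtype=float)
    J = len(released)
    p = brownie_cell_probs(
        preseason_survival, np.arange(J), harvest, annual_survival, J
    )
    return released[:, None] * p


def brownie_cell_probs(preseason_survival, first, harvest, annual_survival, n_years):
    """Recovery-year cell probabilities for arbitrary cohorts.

    ``preseason_survival[c]`` and ``first[c]`` (index of the release year)
    describe cohort ``c``; ``harvest`` has one entry per study year and
    ``annual_survival`` at least ``n_years - 1``.  Returns the ``(C, J)``
    matrix with zeros before each cohort's release year.
    """
    sg = np.asarray(preseason_survival, dtype=float)
    first = np.asarray(first, dtype=int)
    H = np.asarray(harvest, dtype=float)
    S = np.asarray(annual_survival, dtype=float)
    C = len(sg)
    p = np.zeros((C, n_years))
    for c in range(C):
        carry = sg[c]
        for j in range(first[c], n_years):
            p[c, j] = carry * H[j]
            if j < n_years - 1:
                carry *= S[j]
    return p


def brownie_loglik(cell_probs, data: RecoveryData) -> float:
    """Multinomial dead-recovery log-likelihood kernel.

    ``cell_probs[c, j]`` is the probability that an animal from cohort ``c``
    (rows of ``data.recovery_matrix()``) is recovered in study year ``j``; the
    never-recovered cell receives the complement.  Multinomial constants are
    dropped.
    """
    cohorts, U = data.recovery_matrix()
    p = np.asarray(cell_probs, dtype=float)
    a = cohorts["released"].to_numpy(dtype=float)
    never = a - U.sum(axis=1)
    tail = 1.0 - p.sum(axis=1)
    with np.errstate(invalid="ignore"):
        ll = float(
            np.sum(xlogy(U, p)) + np.sum(xlogy(never, np.clip(tail, 0.0, None)))
        )
    if not np.isfinite(ll):
        _flag_impossible("recovery cell")
        return -np.inf
    return ll


def radio_harvest_loglik(radio_harvest_rate, series: RadioHarvestSeries) -> float:
    """Binomial log-likelihood kernel for transmitter-fitted animals.

    ``radio_harvest_rate`` is a scalar or an array aligned with the rows of
    ``series.table``.  Rows with zero availability contribute 0.
    """
    t = series.table
    if len(t) == 0:
        return 0.0
    hr = np.broadcast_to(np.asarray(radio_harvest_rate, dtype=float), len(t))
    h = t["harvested"].to_numpy(dtype=float)
    m = t["available"].to_numpy(dtype=float)
    ll = float(np.sum(xlogy(h, hr)) + np.sum(xlogy(m - h, 1.0 - hr)))
    if not np.isfinite(ll):
        _flag_impossible("radio harvest")
        return -np.inf
    return ll


# ---------------------------------------------------------------------------
# joint evaluation at named real-scale values
# ---------------------------------------------------------------------------


def _resolve_value(values: Mapping, family: str, famspec, attrs: Mapping) -> float:
    if famspec.fixed is not None:
        return famspec.fixed
    v = values[family]
    if np.isscalar(v):
        return float(v)
    key = tuple(attrs[f] for f in famspec.factors)
    if key in v:
        return float(v[key])
    if len(key) == 1 and key[0] in v:
        return float(v[key[0]])
    raise KeyError(f"no value for {family} level {key}")


def joint_loglik(spec: ModelSpec, data: Dataset, values: Mapping) -> float:
    """Joint log-likelihood at real-scale parameter values.

    ``values`` maps family names (``"s"``, ``"H"``, ``"S"`` and, when radio
    harvest is not shared, ``"Hr"``) to either a scalar applied to every level
    or a dict keyed by factor-level tuples.  The cumulative pre-season
    survival inside the dead-recovery term is computed from the same monthly
    rates the known-fate term uses.  Absent data streams contribute 0.
    """
    cells = enumerate_cells(spec, data)
    total = 0.0

    if cells.km:
        s = np.array(
            [_resolve_value(values, "s", spec.monthly_survival, attrs)
             for attrs, *_ in cells.km]
        )
        total += km_loglik(s, data.known_fate)

    if cells.cohorts:
        years = cells.years
        G = spec.preseason_end
        C = len(cells.cohorts)
        p = np.zeros((C, len(years)))
        for c, coh in enumerate(cells.cohorts):
            sg = np.prod(
                [
                    _resolve_value(
                        values, "s", spec.monthly_survival, {**coh.attrs, "month": g}
                    )
                    for g in range(coh.attrs["entry_month"], G + 1)
                ]
            )
            carry = sg
            for j in range(coh.first, len(years)):
                H = _resolve_value(
                    values, "H", spec.harvest, {**coh.attrs, "year": years[j]}
                )
                p[c, j] = carry * H
                if j < len(years) - 1:
                    S = _resolve_value(
                        values, "S", spec.annual_survival,
                        {**coh.attrs, "year": years[j]},
                    )
                    carry *= S
        total += brownie_loglik(p, data.recoveries)

    if cells.radio:
        fam = "H" if spec.radio_shares_harvest else "Hr"
        famspec = spec.harvest if spec.radio_shares_harvest else spec.radio_harvest
        hr = np.array(
            [_resolve_value(values, fam, famspec, attrs) for attrs, *_ in cells.radio]
        )
        total += radio_harvest_loglik(hr, data.radio_harvest)

    return total


# ---------------------------------------------------------------------------
# compiled design for optimization
# ---------------------------------------------------------------------------


class JointDesign:
    """Compiled joint log-likelihood over free logit-scale parameters.

    Each known-fate/radio cell stores the index of its free parameter (or a
    fixed value); each dead-recovery cell stores a multiplicity row over free
    parameters (a month appearing twice in a product simply counts twice) plus
    a log-constant from fixed values, so that
    ``log p_cell = logconst + M @ log(sigmoid(theta))``.
    """

    def __init__(self, spec: ModelSpec, data: Dataset,
                 layout: ParameterLayout | None = None):
        self.spec = spec
        self.data = data
        self.layout = layout if layout is not None else build_parameter_map(spec, data)
        self.K = self.layout.K
        cells = enumerate_cells(spec, data)
        self.cells = cells
        self._compile(cells)

    # -- compilation -------------------------------------------------------

    def _entry_arrays(self, resolved) -> tuple[np.ndarray, np.ndarray]:
        idx = np.array([e.index if e.is_free else -1 for e in resolved], dtype=int)
        fixed = np.array([0.0 if e.is_free else e.fixed for e in resolved])
        return idx, fixed

    def _compile(self, cells: CellSet) -> None:
        lay = self.layout
        # known-fate rows
        self.km_surv = np.array([n - d - c for _a, n, d, c in cells.km], dtype=float)
        self.km_dead = np.array([d for _a, _n, d, _c in cells.km], dtype=float)
        self.km_idx, self.km_fixed = self._entry_arrays(
            [lay.resolve("s", attrs) for attrs, *_ in cells.km]
        )
        # radio rows
        self.r_h = np.array([h for _a, _m, h in cells.radio], dtype=float)
        self.r_m = np.array([m for _a, m, _h in cells.radio], dtype=float)
        self.r_idx, self.r_fixed = self._entry_arrays(
            [lay.resolve("Hr", attrs) for attrs, *_ in cells.radio]
        )
        # dead-recovery cells
        years = cells.years
        G = self.spec.preseason_end
        rows: list[np.ndarray] = []
        logconst: list[float] = []
        cell_U: list[float] = []
        cell_cohort: list[int] = []
        cohort_released = []
        cohort_never = []
        starts: list[int] = []
        for c, coh in enumerate(cells.cohorts):
            cohort_released.append(float(coh.released))
            cohort_never.append(float(coh.released - coh.counts.sum()))
            starts.append(len(cell_U))
            base_row = np.zeros(self.K)
            base_const = 0.0
            structural_zero = False
            for g in range(coh.attrs["entry_month"], G + 1):
                e = lay.resolve("s", {**coh.attrs, "month": g})
                if e.is_free:
                    base_row[e.index] += 1.0
                elif e.fixed == 0.0:
                    structural_zero = True
                else:
                    base_const += np.log(e.fixed)
            row = base_row
            const = base_const
            zero = structural_zero
            for j in range(coh.first, len(years)):
                h_entry = lay.resolve("H", {**coh.attrs, "year": years[j]})
                crow = row.copy()
                cconst = const
                czero = zero
                if h_entry.is_free:
                    crow[h_entry.index] += 1.0
                elif h_entry.fixed == 0.0:
                    czero = True
                else:
                    cconst += np.log(h_entry.fixed)
                U_cj = float(coh.counts[j - coh.first])
                if czero:
                    if U_cj > 0:
                        raise ValueError(
                            "recovery observed in a cell whose probability is "
                            "fixed at 0 by the model specification"
                        )
                    # probability exactly 0: the cell contributes nothing
                else:
                    rows.append(crow)
                    logconst.append(cconst)
                    cell_U.append(U_cj)
                    cell_cohort.append(c)
                if j < len(years) - 1:
                    s_entry = lay.resolve("S", {**coh.attrs, "year": years[j]})
                    if s_entry.is_free:
                        row = row.copy()
                        row[s_entry.index] += 1.0
                    elif s_entry.fixed == 0.0:
                        zero = True
                    else:
                        const = const + np.log(s_entry.fixed)
        self.b_M = (
            np.array(rows) if rows else np.zeros((0, self.K))
        )
        self.b_logconst = np.array(logconst)
        self.b_U = np.array(cell_U)
        self.b_cell_cohort = np.array(cell_cohort, dtype=int)
        self.b_released = np.array(cohort_released)
        self.b_never = np.array(cohort_never)
        self.n_cohorts = len(cells.cohorts)

    # -- evaluation --------------------------------------------------------

    def _km_radio_values(self, x: np.ndarray):
        s = np.where(self.km_idx >= 0, x[np.clip(self.km_idx, 0, None)], self.km_fixed)
        hr = np.where(self.r_idx >= 0, x[np.clip(self.r_idx, 0, None)], self.r_fixed)
        return s, hr

    def cell_probs(self, theta: np.ndarray) -> np.ndarray:
        """Per-cohort recovery-cell probabilities (cells in compile order)."""
        x = expit(np.asarray(theta, dtype=float))
        logx = np.log(np.clip(x, _TINY, None))
        return np.exp(self.b_logconst + self.b_M @ logx)

    def loglik(self, theta: np.ndarray) -> float:
        return self.loglik_and_grad(theta)[0]

    def loglik_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Joint log-likelihood and its analytic gradient on the logit scale.

        A cohort whose cell probabilities sum to >= 1 gets the never-recovered
        tail clipped at a tiny positive value: the value stays finite and the
        gradient still points back into the valid region.
        """
        theta = np.asarray(theta, dtype=float)
        x = expit(theta)
        g = np.zeros(self.K)
        ll = 0.0

        if len(self.km_surv):
            s, _ = self._km_radio_values(x)
            ll += float(np.sum(xlogy(self.km_surv, s)) + np.sum(xlogy(self.km_dead, 1 - s)))
            contrib = self.km_surv * (1 - s) - self.km_dead * s
            free = self.km_idx >= 0
            np.add.at(g, self.km_idx[free], contrib[free])

        if len(self.r_h):
            _, hr = self._km_radio_values(x)
            ll += float(np.sum(xlogy(self.r_h, hr)) + np.sum(xlogy(self.r_m - self.r_h, 1 - hr)))
            contrib = self.r_h - self.r_m * hr
            free = self.r_idx >= 0
            np.add.at(g, self.r_idx[free], contrib[free])

        if self.n_cohorts:
            logx = np.log(np.clip(x, _TINY, None))
            logp = self.b_logconst + self.b_M @ logx
            p = np.exp(logp)
            sump = np.bincount(self.b_cell_cohort, weights=p, minlength=self.n_cohorts)
            tail = np.clip(1.0 - sump, _TAIL_FLOOR, None)
            ll += float(np.sum(self.b_U * logp) + np.sum(xlogy(self.b_never, tail)))
            rest = self.b_never / tail
            w = self.b_U - rest[self.b_cell_cohort] * p
            g += (self.b_M.T @ w) * (1 - x)

        return ll, g

    def negloglik_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        ll, g = self.loglik_and_grad(theta)
        return -ll, -g

    def real_values(self, theta: np.ndarray) -> dict:
        """Real-scale values for every level of every family (fixed included)."""
        x = expit(np.asarray(theta, dtype=float))
        out: dict = {}
        for family in ("s", "H", "S", "Hr"):
            if family not in self.layout.entries:
                continue
            if family == "Hr" and self.layout.radio_family == "H":
                out["Hr"] = out["H"]
                continue
            fixed = self.layout.family_fixed.get(family)
            if fixed is not None:
                out[family] = fixed
                continue
            out[family] = {
                key: (x[e.index] if e.is_free else e.fixed)
                for key, e in self.layout.entries[family].items()
            }
        return out
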