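"""Maximum-likelihood fitting, standard errors, and AICc model comparison.

All probabilities are estimated on the logit scale with a quasi-Newton
optimizer (L-BFGS-B) using the analytic gradient of the joint log-likelihood;
fixed parameters (e.g. monthly survival pinned at 1.0) bypass the link.
Standard errors come from the inverse observed information (the Hessian is a
central-difference Jacobian of the analytic gradient) and are mapped to the
probability scale by the delta method.  Confidence intervals are normal-theory
on the link scale, back-transformed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .datamodel import (
    Dataset,
    FittedModel,
    ModelSpec,
    ParameterLayout,
    SpecError,
    build_parameter_map,
    FamilySpec,
)
from .likelihood import JointDesign

__all__ = [
    "fit",
    "standard_errors",
    "cumulative_survival_se",
    "aicc",
    "compare_models",
    "tag_effect_test",
    "TagEffectResult",
    "effective_sample_size",
]

log = logging.getLogger(__name__)

#: logit bound keeping probabilities strictly inside (0, 1)
_THETA_BOUND = 12.0
#: |theta| beyond this is reported as a boundary estimate
_BOUNDARY = 11.0


def effective_sample_size(data: Dataset) -> int:
    """AICc effective sample size: total individuals released across streams.

    Tagged releases plus known-fate entries; radio-harvest availability is
    added only when no known-fate stream is present, because transmitter
    animals otherwise already entered through the known-fate series.
    """
    n = 0
    if data.recoveries is not None:
        n += data.recoveries.total_released
    if data.known_fate is not None and not data.known_fate.is_empty:
        n += data.known_fate.total_entries
    elif data.radio_harvest is not None:
        n += data.radio_harvest.total_available
    return n


def _initial_theta(design: JointDesign) -> np.ndarray:
    """Closed-form-informed starting values on the logit scale."""
    K = design.K
    x0 = np.full(K, 0.5)
    # monthly survival: pooled interval MLE per level
    if len(design.km_surv):
        surv = np.zeros(K)
        dead = np.zeros(K)
        free = design.km_idx >= 0
        np.add.at(surv, design.km_idx[free], design.km_surv[free])
        np.add.at(dead, design.km_idx[free], design.km_dead[free])
        seen = (surv + dead) > 0
        with np.errstate(invalid="ignore"):
            shat = np.where(seen, surv / np.clip(surv + dead, 1.0, None), 0.9)
    else:
        shat = np.full(K, 0.9)
        seen = np.zeros(K, dtype=bool)
    s_indices = {
        e.index
        for e in design.layout.entries.get("s", {}).values()
        if e.is_free
    }
    for k in range(K):
        if k in s_indices:
            x0[k] = shat[k] if seen[k] else 0.9
    # harvest: crude first-year recovery rate corrected by a crude pre-season survival
    if design.n_cohorts:
        diag = 0.0
        for coh in design.cells.cohorts:
            diag += float(coh.counts[0])
        released = float(design.b_released.sum())
        span = max(
            design.spec.preseason_end - min(
                coh.attrs["entry_month"] for coh in design.cells.cohorts
            ) + 1,
            1,
        )
        if design.layout.family_fixed.get("s") is not None:
            sg_crude = design.layout.family_fixed["s"] ** span
        else:
            pooled = (
                design.km_surv.sum() / max(design.km_surv.sum() + design.km_dead.sum(), 1.0)
                if len(design.km_surv)
                else 0.9
            )
            sg_crude = pooled ** span
        h_crude = diag / max(released, 1.0) / max(sg_crude, 0.05)
        h_crude = float(np.clip(h_crude, 0.02, 0.9))
        for e in design.layout.entries.get("H", {}).values():
            if e.is_free:
                x0[e.index] = h_crude
    # separate radio-harvest family: pooled h/m
    if design.layout.radio_family == "Hr" and len(design.r_m):
        pooled = float(design.r_h.sum()) / max(float(design.r_m.sum()), 1.0)
        pooled = float(np.clip(pooled, 0.02, 0.9))
        for e in design.layout.entries["Hr"].values():
            if e.is_free:
                x0[e.index] = pooled
    theta0 = logit(np.clip(x0, 0.02, 0.98))
    return _repair_start(design, theta0)


def _repair_start(design: JointDesign, theta: np.ndarray) -> np.ndarray:
    """Shrink harvest / annual-survival starts until every cohort's recovery
    cells sum below 1 (the start must lie in the valid multinomial region)."""
    if not design.n_cohorts:
        return theta
    shrink = [
        e.index
        for fam in ("H", "S")
        for e in design.layout.entries.get(fam, {}).values()
        if e.is_free
    ]
    if not shrink:
        return theta
    theta = theta.copy()
    for _ in range(40):
        p = design.cell_probs(theta)
        sums = np.bincount(design.b_cell_cohort, weights=p,
                           minlength=design.n_cohorts)
        if sums.max() <= 0.9:
            break
        theta[shrink] = logit(expit(theta[shrink]) * 0.8)
    return theta


def _numerical_hessian(design: JointDesign, theta: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Observed information: central-difference Jacobian of the analytic
    gradient of the negative log-likelihood, symmetrized."""
    K = len(theta)
    H = np.zeros((K, K))
    for i in range(K):
        tp = theta.copy()
        tp[i] += h
        tm = theta.copy()
        tm[i] -= h
        gp = design.negloglik_and_grad(tp)[1]
        gm = design.negloglik_and_grad(tm)[1]
        H[:, i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def _invert_information(H: np.ndarray) -> tuple[np.ndarray | None, int]:
    """Invert the observed information; return (vcov | None, rank)."""
    if H.size == 0:
        return np.zeros((0, 0)), 0
    eigval, eigvec = np.linalg.eigh(H)
    tol = max(abs(eigval).max(), 1.0) * 1e-9
    rank = int(np.sum(eigval > tol))
    if rank < len(eigval):
        return None, rank
    vcov = (eigvec / eigval) @ eigvec.T
    return vcov, rank


def fit(
    spec: ModelSpec,
    data: Dataset,
    *,
    n_restarts: int = 5,
    compute_se: bool = True,
    n_eff: int | None = None,
    jitter: float = 0.75,
) -> FittedModel:
    """Maximize the joint log-likelihood under ``spec``.

    ``n_restarts`` deterministic jittered starts guard against local optima;
    the best optimum is kept.  ``n_eff`` overrides the effective sample size
    used by AICc.  Non-convergence is flagged on the result, never raised.
    """
    data.validate()
    layout = build_parameter_map(spec, data)
    design = JointDesign(spec, data, layout)
    K = layout.K

    if K == 0:
        theta = np.zeros(0)
        ll = design.loglik(theta)
        best_success = True
        message = "no free parameters"
    else:
        theta0 = _initial_theta(design)
        rng = np.random.default_rng(20260101)
        best = None
        for r in range(max(n_restarts, 1)):
            start = theta0 if r == 0 else _repair_start(
                design, np.clip(theta0 + rng.normal(0.0, jitter, size=K), -4.0, 4.0)
            )
            res = minimize(
                design.negloglik_and_grad,
                start,
                jac=True,
                method="L-BFGS-B",
                bounds=[(-_THETA_BOUND, _THETA_BOUND)] * K,
                options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        ll = -float(best.fun)
        best_success = bool(best.success)
        message = str(best.message)
        if not best_success:
            # line searches occasionally stop "abnormally" at a stationary
            # point; accept the solution when the interior gradient vanishes
            grad = design.loglik_and_grad(theta)[1]
            interior = np.abs(theta) < _BOUNDARY
            if np.all(np.abs(grad[interior]) < 1e-4):
                best_success = True
                message += " (accepted: gradient stationary)"
            else:
                log.warning("optimizer did not report convergence: %s", message)

    n = n_eff if n_eff is not None else effective_sample_size(data)
    try:
        aicc_value = aicc(ll, K, n)
    except ValueError:
        aicc_value = math.nan
        warnings.warn(
            f"AICc undefined: effective sample size {n} <= K + 1 = {K + 1}",
            RuntimeWarning,
        )

    vcov = None
    se_available = False
    hess_rank = None
    boundary = np.abs(theta) >= _BOUNDARY
    if compute_se and K > 0:
        hess = _numerical_hessian(design, theta)
        vcov, hess_rank = _invert_information(hess)
        se_available = vcov is not None
        if not se_available:
            warnings.warn(
                f"observed information is singular (rank {hess_rank} of {K}); "
                "standard errors unavailable",
                RuntimeWarning,
            )
    elif K == 0:
        vcov = np.zeros((0, 0))
        se_available = True
        hess_rank = 0

    estimates = _estimates_table(layout, theta, vcov, boundary)

    return FittedModel(
        spec=spec,
        layout=layout,
        theta=theta,
        loglik=ll,
        K=K,
        n_eff=n,
        aicc=aicc_value,
        converged=best_success,
        estimates=estimates,
        vcov=vcov,
        se_available=se_available,
        hess_rank=hess_rank,
        message=message,
        n_restarts=n_restarts,
    )


def _estimates_table(
    layout: ParameterLayout,
    theta: np.ndarray,
    vcov: np.ndarray | None,
    boundary: np.ndarray,
) -> pd.DataFrame:
    rows = []
    se_link = (
        np.sqrt(np.clip(np.diag(vcov), 0.0, None)) if vcov is not None else None
    )
    for family in ("s", "H", "S", "Hr"):
        if family == "Hr" and layout.radio_family == "H":
            continue
        fixed = layout.family_fixed.get(family)
        if fixed is not None:
            rows.append(
                {
                    "parameter": family,
                    "family": family,
                    "estimate": fixed,
                    "se": np.nan,
                    "lower95": np.nan,
                    "upper95": np.nan,
                    "fixed": True,
                    "boundary": False,
                }
            )
            continue
        factors = layout.factors.get(family, ())
        for key, entry in layout.entries.get(family, {}).items():
            name = family if not factors else (
                f"{family}[" + ",".join(f"{f}={v}" for f, v in zip(factors, key)) + "]"
            )
            if not entry.is_free:
                rows.append(
                    {
                        "parameter": name,
                        "family": family,
                        "estimate": entry.fixed,
                        "se": np.nan,
                        "lower95": np.nan,
                        "upper95": np.nan,
                        "fixed": True,
                        "boundary": False,
                    }
                )
                continue
            k = entry.index
            est = float(expit(theta[k]))
            at_bound = bool(boundary[k])
            if se_link is not None and not at_bound:
                se = est * (1 - est) * se_link[k]
                lo = float(expit(theta[k] - 1.96 * se_link[k]))
                hi = float(expit(theta[k] + 1.96 * se_link[k]))
            else:
                se = np.nan
                lo = np.nan
                hi = np.nan
            rows.append(
                {
                    "parameter": name,
                    "family": family,
                    "estimate": est,
                    "se": se,
                    "lower95": lo,
                    "upper95": hi,
                    "fixed": False,
                    "boundary": at_bound,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "parameter",
            "family",
            "estimate",
            "se",
            "lower95",
            "upper95",
            "fixed",
            "boundary",
        ],
    )


def standard_errors(fitted: FittedModel) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Per-parameter real-scale standard errors and the link-scale vcov.

    SEs are sqrt of the diagonal of the inverse observed information mapped to
    the probability scale by the delta method; fixed parameters have none.
    """
    cols = ["parameter", "family", "estimate", "se", "fixed", "boundary"]
    return fitted.estimates[cols].copy(), fitted.vcov


def cumulative_survival_se(
    fitted: FittedModel, entry_month: int, end_month: int, **attrs
) -> tuple[float, float]:
    """Cumulative pre-season survival over ``entry_month..end_month`` with a
    first-order delta-method standard error.

    Extra keyword attributes (``age=``, ``year=``, ``unit=``...) select the
    stratum when monthly survival varies by those factors.
    """
    if entry_month > end_month:
        raise ValueError("empty month range")
    layout = fitted.layout
    values = []
    grad = np.zeros(fitted.K)
    for g in range(entry_month, end_month + 1):
        entry = layout.resolve("s", {**attrs, "month": g})
        if entry.is_free:
            s = float(expit(fitted.theta[entry.index]))
        else:
            s = float(entry.fixed)
        values.append((s, entry.index))
    sg = float(np.prod([v for v, _ in values]))
    # d S_G / d theta_k = S_G * sum over months at that index of (1 - s_g)
    for s, idx in values:
        if idx is not None:
            grad[idx] += sg * (1.0 - s)
    if fitted.vcov is None:
        return sg, math.nan
    var = float(grad @ fitted.vcov @ grad)
    return sg, math.sqrt(max(var, 0.0))


def aicc(loglik: float, K: int, n: int) -> float:
    """Small-sample Akaike information criterion
    ``-2 ln L + 2K + 2K(K + 1) / (n - K - 1)``."""
    if n <= K + 1:
        raise ValueError(f"AICc undefined for n={n} <= K + 1 = {K + 1}")
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def compare_models(models, names=None) -> pd.DataFrame:
    """AICc comparison table: ΔAICc (best = 0) and Akaike weights.

    Models must be fitted to the same data.  Ties are broken by smaller K,
    then input order.
    """
    models = list(models)
    if not models:
        raise ValueError("no models to compare")
    if names is None:
        names = [f"model_{i + 1}" for i in range(len(models))]
    rows = pd.DataFrame(
        {
            "model": names,
            "K": [m.K for m in models],
            "loglik": [m.loglik for m in models],
            "AICc": [m.aicc for m in models],
            "_order": range(len(models)),
        }
    )
    rows = rows.sort_values(["AICc", "K", "_order"], kind="mergesort").reset_index(drop=True)
    rows["dAICc"] = rows["AICc"] - rows["AICc"].iloc[0]
    rel = np.exp(-0.5 * rows["dAICc"].to_numpy())
    rows["weight"] = rel / rel.sum()
    return rows.drop(columns="_order")


@dataclass
class TagEffectResult:
    """Outcome of the transmitter-effect-on-harvest test."""

    constrained: FittedModel  # harvest shared between tag types (H_i = H_ri)
    unconstrained: FittedModel  # harvest varies by tag type
    table: pd.DataFrame
    prefers_common_harvest: bool


def tag_effect_test(data: Dataset, base_spec: ModelSpec, **fit_kwargs) -> TagEffectResult:
    """Test whether transmitter-fitted animals share the tagged animals'
    harvest rate by comparing models with and without the H_i = H_ri
    constraint via AICc.

    ``base_spec`` is the constrained model (radio harvest shared, no
    ``tag_type`` harvest factor); the unconstrained model adds ``tag_type`` to
    the harvest factors.  Requires both recovery and radio-harvest streams.
    """
    if data.recoveries is None or data.radio_harvest is None:
        raise SpecError(
            "the tag-effect test needs both tag-recovery and radio-harvest data"
        )
    if not base_spec.radio_shares_harvest or "tag_type" in base_spec.harvest.factors:
        raise SpecError(
            "base_spec must share harvest between tag types (radio_harvest shared, "
            "no tag_type harvest factor)"
        )
    free_spec = ModelSpec(
        monthly_survival=base_spec.monthly_survival,
        harvest=FamilySpec(base_spec.harvest.factors + ("tag_type",)),
        annual_survival=base_spec.annual_survival,
        radio_harvest=None,
        preseason_end=base_spec.preseason_end,
    )
    constrained = fit(base_spec, data, **fit_kwargs)
    unconstrained = fit(free_spec, data, **fit_kwargs)
    table = compare_models(
        [constrained, unconstrained], ["common_harvest", "tag_type_harvest"]
    )
    return TagEffectResult(
        constrained=constrained,
        unconstrained=unconstrained,
        table=table,
        prefers_common_harvest=bool(table["model"].iloc[0] == "common_harvest"),
    )
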