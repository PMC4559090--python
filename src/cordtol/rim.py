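"""Logistic BED dose-response model for radiation-induced myelopathy.

Each cohort contributes a binomial outcome (events / total) observed after a
treatment course whose biological dose is summarised by the LQ model:
BED = Σᵢ nᵢ·dᵢ·(1 + dᵢ/(α/β)).  The incidence of myelopathy is modelled by a
three-parameter logistic in BED,

    PRIM(BED) = 1 / [1 + (BED50 / BED)^k],

which is linear on the logit scale: logit(PRIM) = k·(ln BED − ln BED50).
BED50 is the biological dose at 50% incidence and k the (dimensionless)
slope; α/β enters through the BED of every course, so all three parameters
are estimated jointly.

Estimators
----------
``method="logit"`` (default)
    Unweighted least squares of the empirical log-odds on the model logit.
    Cohorts observed at exactly 0% or 100% have no finite log-odds and are
    given half an event (p̃ = 0.5/t, resp. 1 − 0.5/t), the standard dose-plot
    convention.  This is the convention under which the packaged cohort
    tables reproduce the published parameter estimates; see the methods note.
``method="ml"``
    Binomial maximum likelihood — the statistically efficient choice when
    cohort sizes should carry weight (they span 2 to 524 subjects).
``method="ls"``
    Unweighted least squares on the raw proportions.

Confidence intervals are computed by profiling the objective (likelihood
ratio χ²₁ threshold for ML, F-based residual-sum threshold for the
least-squares estimators); profile intervals are naturally asymmetric.
Wald intervals are reported alongside for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats
from scipy.special import xlogy

from .datasets import RIMCohort
from .lq import LQParameters, TreatmentCourse, bed_of_course, dose_for_bed_at_n, total_dose_for_bed

__all__ = [
    "RIMFit",
    "RIMEstimationError",
    "prim_from_bed",
    "predict_prim",
    "fit_rim",
    "bed_for_risk",
    "dose_for_risk",
    "curve_samples",
    "binomial_loglik",
]

_GRID_AB = (1.0, 2.0, 4.0, 8.0)
_GRID_BED50 = (80.0, 110.0, 140.0)
_GRID_K = (5.0, 10.0, 20.0)


class RIMEstimationError(RuntimeError):
    """Raised for unidentifiable designs or non-convergent fits."""


@dataclass(frozen=True)
class RIMFit:
    """Fitted logistic BED dose-response with 95% intervals.

    ``*_ci`` are profile intervals; ``*_ci_wald`` the symmetric asymptotic
    ones.  ``loglik`` is the binomial log-likelihood evaluated at the
    estimate whatever the estimation method, so fits are comparable.
    """

    alpha_beta: float
    bed50: float
    k: float
    alpha_beta_ci: Tuple[float, float]
    bed50_ci: Tuple[float, float]
    k_ci: Tuple[float, float]
    alpha_beta_ci_wald: Tuple[float, float]
    bed50_ci_wald: Tuple[float, float]
    k_ci_wald: Tuple[float, float]
    method: str
    objective: float
    loglik: float
    n_cohorts: int
    group: str = ""

    def __post_init__(self) -> None:
        if not (self.alpha_beta > 0 and self.bed50 > 0 and self.k > 0):
            raise RIMEstimationError("fitted parameters must be positive")

    def params(self) -> LQParameters:
        return LQParameters(self.alpha_beta)


def prim_from_bed(bed: float, bed50: float, k: float) -> float:
    """Logistic incidence at a given BED; returns 0 in the zero-dose limit."""
    if bed < 0:
        raise ValueError("bed must be >= 0")
    if bed == 0.0:
        return 0.0
    return 1.0 / (1.0 + (bed50 / bed) ** k)


def predict_prim(course: TreatmentCourse, fit: RIMFit) -> float:
    """Predicted myelopathy probability for a treatment course."""
    bed = bed_of_course(course, fit.params())
    return prim_from_bed(bed, fit.bed50, fit.k)


def bed_for_risk(p: float, fit: RIMFit) -> float:
    """BED at which the fitted curve crosses incidence ``p`` (closed form).

    BED_p = BED50 · (p/(1−p))^(1/k); p = 0.5 returns BED50 exactly.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"risk level must be in (0, 1), got {p}")
    if p == 0.5:
        return fit.bed50
    return fit.bed50 * (p / (1.0 - p)) ** (1.0 / fit.k)


def dose_for_risk(
    p: float,
    fit: RIMFit,
    dose_per_fraction: Optional[float] = None,
    n_fractions: Optional[int] = None,
) -> float:
    """Physical total dose at risk level ``p`` under the fit's α/β.

    Specify either a fixed dose per fraction (EQD-style conversion) or a
    fixed number of fractions (quadratic-root solve).
    """
    if (dose_per_fraction is None) == (n_fractions is None):
        raise ValueError("specify exactly one of dose_per_fraction or n_fractions")
    bed = bed_for_risk(p, fit)
    if dose_per_fraction is not None:
        return total_dose_for_bed(bed, dose_per_fraction, fit.params())
    return dose_for_bed_at_n(bed, n_fractions, fit.params())


def curve_samples(fit: RIMFit, bed_grid: Sequence[float]) -> List[Tuple[float, float]]:
    """(BED, predicted incidence) samples for plotting the fitted curve."""
    return [(float(b), prim_from_bed(float(b), fit.bed50, fit.k)) for b in bed_grid]


# ---------------------------------------------------------------------------
# internal vectorised design


class _Design:
    """Padded per-cohort regimen arrays for fast BED evaluation."""

    def __init__(self, cohorts: Sequence[RIMCohort]):
        self.events = np.array([c.events for c in cohorts], dtype=float)
        self.total = np.array([c.total for c in cohorts], dtype=float)
        m = max(len(c.course.regimens) for c in cohorts)
        self.d = np.zeros((len(cohorts), m))
        self.n = np.zeros((len(cohorts), m))
        for i, c in enumerate(cohorts):
            for j, r in enumerate(c.course.regimens):
                self.d[i, j] = r.dose_per_fraction
                self.n[i, j] = r.n_fractions
        # empirical log-odds with the half-event rule for degenerate cells
        p = self.events / self.total
        lo_mask = self.events == 0
        hi_mask = self.events == self.total
        p = np.where(lo_mask, 0.5 / self.total, p)
        p = np.where(hi_mask, 1.0 - 0.5 / self.total, p)
        self.logit_obs = np.log(p / (1.0 - p))

    def bed(self, alpha_beta: float) -> np.ndarray:
        return np.sum(self.n * self.d * (1.0 + self.d / alpha_beta), axis=1)


def binomial_loglik(theta: Sequence[float], design: _Design) -> float:
    """Binomial log-likelihood of (α/β, BED50, k) for a cohort design."""
    ab, bed50, k = theta
    if ab <= 0 or bed50 <= 0 or k <= 0:
        return -np.inf
    bed = design.bed(ab)
    p = 1.0 / (1.0 + (bed50 / bed) ** k)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(np.sum(xlogy(design.events, p) + xlogy(design.total - design.events, 1.0 - p)))


def _residuals(theta: np.ndarray, design: _Design, method: str) -> np.ndarray:
    ab, bed50, k = np.abs(theta)
    bed = design.bed(ab)
    if method == "logit":
        return design.logit_obs - k * (np.log(bed) - np.log(bed50))
    # proportion space
    p = 1.0 / (1.0 + (bed50 / bed) ** k)
    return design.events / design.total - p


def _check_identifiable(cohorts: Sequence[RIMCohort]) -> None:
    if len(cohorts) < 4:
        raise RIMEstimationError(
            f"need at least 4 cohorts to fit 3 parameters, got {len(cohorts)}"
        )
    doses = {r.dose_per_fraction for c in cohorts for r in c.course.regimens}
    if len(doses) < 2:
        raise RIMEstimationError(
            "alpha/beta is unidentifiable: all cohorts share a single dose per fraction"
        )


def _optimize_ls(design: _Design, method: str) -> Tuple[np.ndarray, float]:
    best = None
    for ab0 in _GRID_AB:
        for b0 in _GRID_BED50:
            for k0 in _GRID_K:
                res = optimize.least_squares(
                    _residuals,
                    [ab0, b0, k0],
                    args=(design, method),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                    max_nfev=5000,
                )
                if best is None or res.cost < best.cost:
                    best = res
    return np.abs(best.x), 2.0 * best.cost  # SSE


def _optimize_ml(design: _Design) -> Tuple[np.ndarray, float]:
    def nll_log(logtheta: np.ndarray) -> float:
        return -binomial_loglik(np.exp(logtheta), design)

    best = None
    for ab0 in _GRID_AB:
        for b0 in _GRID_BED50:
            for k0 in _GRID_K:
                res = optimize.minimize(
                    nll_log,
                    np.log([ab0, b0, k0]),
                    method="Nelder-Mead",
                    options=dict(xatol=1e-10, fatol=1e-12, maxiter=20000, maxfev=20000),
                )
                if best is None or res.fun < best.fun:
                    best = res
    if not np.isfinite(best.fun):
        raise RIMEstimationError("binomial likelihood maximization failed to converge")
    return np.exp(best.x), best.fun  # negative log-likelihood


def _objective_fixed(
    design: _Design, method: str, index: int, value: float, start: np.ndarray
) -> float:
    """Minimum objective with parameter ``index`` pinned at ``value``."""
    free = [i for i in range(3) if i != index]

    if method == "ml":

        def nll_log(logtheta: np.ndarray) -> float:
            full = np.empty(3)
            full[index] = value
            full[free] = np.exp(logtheta)
            return -binomial_loglik(full, design)

        res = optimize.minimize(
            nll_log,
            np.log(start[free]),
            method="Nelder-Mead",
            options=dict(xatol=1e-9, fatol=1e-11, maxiter=10000, maxfev=10000),
        )
        return res.fun

    def resid(theta2: np.ndarray) -> np.ndarray:
        full = np.empty(3)
        full[index] = value
        full[free] = np.abs(theta2)
        return _residuals(full, design, method)

    res = optimize.least_squares(
        resid, start[free], xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=3000
    )
    return 2.0 * res.cost


def _profile_ci(
    design: _Design,
    method: str,
    theta: np.ndarray,
    objective: float,
    n_obs: int,
    level: float = 0.95,
) -> List[Tuple[float, float]]:
    """Profile interval per parameter: χ²₁ (ML) or F-based SSE threshold (LS)."""
    if method == "ml":
        threshold = objective + stats.chi2.ppf(level, 1) / 2.0
    else:
        dof = n_obs - 3
        threshold = objective * (1.0 + stats.f.ppf(level, 1, dof) / dof)

    cis = []
    for index in range(3):
        center = theta[index]

        def excess(value: float) -> float:
            return _objective_fixed(design, method, index, value, theta) - threshold

        lo = _find_bound(excess, center, direction=-1)
        hi = _find_bound(excess, center, direction=+1)
        cis.append((lo, hi))
    return cis


def _find_bound(excess, center: float, direction: int) -> float:
    """Root of the profile excess on one side of the estimate (nan if open)."""
    step = 0.1 * center
    inner = center
    for _ in range(60):
        outer = inner + direction * step
        if outer <= 0:
            outer = inner / 2.0
        if excess(outer) > 0:
            lo, hi = sorted((inner, outer))
            return float(optimize.brentq(excess, lo, hi, xtol=1e-6 * center, maxiter=200))
        inner = outer
        step *= 1.6
    return float("nan")


def _wald_ci(
    design: _Design, method: str, theta: np.ndarray, objective: float, n_obs: int
) -> List[Tuple[float, float]]:
    z = stats.norm.ppf(0.975)
    if method == "ml":
        # numerical Hessian of the negative log-likelihood
        h = 1e-4 * theta
        hess = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                ei = np.eye(3)[i] * h[i]
                ej = np.eye(3)[j] * h[j]
                fpp = -binomial_loglik(theta + ei + ej, design)
                fpm = -binomial_loglik(theta + ei - ej, design)
                fmp = -binomial_loglik(theta - ei + ej, design)
                fmm = -binomial_loglik(theta - ei - ej, design)
                hess[i, j] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
        cov = np.linalg.pinv(hess)
    else:
        eps = 1e-6 * theta
        base = _residuals(theta, design, method)
        J = np.empty((len(base), 3))
        for i in range(3):
            step = np.zeros(3)
            step[i] = eps[i]
            J[:, i] = (_residuals(theta + step, design, method) - base) / eps[i]
        dof = len(base) - 3
        sigma2 = objective / dof
        cov = sigma2 * np.linalg.pinv(J.T @ J)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return [(float(t - z * s), float(t + z * s)) for t, s in zip(theta, se)]


def fit_rim(
    cohorts: Sequence[RIMCohort],
    method: str = "logit",
    profile: bool = True,
    group: str = "",
) -> RIMFit:
    """Fit the three-parameter logistic BED model to binomial cohorts.

    Only the cohorts passed in are used — callers are expected to have
    filtered exclusions already (``datasets.group_cohorts`` does).  The
    optimizer is a deterministic multi-start (α/β ∈ {1,2,4,8} ×
    BED50 ∈ {80,110,140} × k ∈ {5,10,20}) followed by local refinement.

    ``profile=False`` skips the profile intervals (Wald only) — useful in
    simulation loops.
    """
    cohorts = list(cohorts)
    _check_identifiable(cohorts)
    design = _Design(cohorts)
    n_obs = len(cohorts)

    if method in ("logit", "ls"):
        theta, objective = _optimize_ls(design, method)
    elif method == "ml":
        theta, objective = _optimize_ml(design)
    else:
        raise ValueError(f"unknown method {method!r} (expected 'logit', 'ls' or 'ml')")

    wald = _wald_ci(design, method, theta, objective, n_obs)
    if profile:
        cis = _profile_ci(design, method, theta, objective, n_obs)
    else:
        cis = wald
    return RIMFit(
        alpha_beta=float(theta[0]),
        bed50=float(theta[1]),
        k=float(theta[2]),
        alpha_beta_ci=cis[0],
        bed50_ci=cis[1],
        k_ci=cis[2],
        alpha_beta_ci_wald=wald[0],
        bed50_ci_wald=wald[1],
        k_ci_wald=wald[2],
        method=method,
        objective=float(objective),
        loglik=binomial_loglik(theta, design),
        n_cohorts=n_obs,
        group=group,
    )
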