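"""Fast patient-level safety-profile estimation with fixed patterns.

Given a treatment's already-estimated pattern matrix phi, a new
patient's profile theta (length K, nonnegative) is obtained by
maximizing the Poisson log-likelihood of their cumulative AE counts

    sum_j log Poisson(y_j | C * sum_k exp(theta~_k) phi_kj)

over the unconstrained theta~ (box [-15, 15]).  The study/background
term is omitted: for a new patient it is assumed negligible relative to
the treatment term.  The fitted profile predicts the per-cycle intensity
of every AE type, lambda_j = sum_k theta_k phi_kj, whose largest entries
flag the AE types to monitor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ae_data import AETypeIndex
from .model_core import THETA_BOUND

__all__ = [
    "ProfileEstimate",
    "PredictionTable",
    "StabilityReport",
    "estimate_profile",
    "predict_lambda",
    "rank_ae_types",
    "compare_profiles",
]


@dataclass
class ProfileEstimate:
    theta_hat: np.ndarray  # length K, nonnegative
    log_prob: float
    converged: bool
    exposure_used: float

    @property
    def theta_tilde(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.maximum(np.log(self.theta_hat), -THETA_BOUND)


@dataclass
class PredictionTable:
    """Ranked predicted intensities, one row per AE type."""

    table: pd.DataFrame  # columns: label, severity, lam
    min_severity: int | None
    top_n: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class StabilityReport:
    diff: np.ndarray
    max_abs_deviation: float
    spearman: float


def _profile_objective(
    y: np.ndarray,
    C: float,
    phi: np.ndarray,
    prior: tuple[float, float] | None,
):
    feasible = ~((phi.sum(axis=0) == 0) & (y > 0))

    def fg(tt: np.ndarray) -> tuple[float, np.ndarray]:
        th = np.exp(tt)
        lam = th @ phi
        Cl = C * lam
        ok = feasible & ((Cl > 0) | (y == 0))
        with np.errstate(divide="ignore"):
            ll = float(
                np.sum(np.where(y[ok] > 0, y[ok] * np.log(Cl[ok]), 0.0))
                - Cl[ok].sum()
            )
        g_lam = np.where(
            (lam > 0) & feasible, y / np.where(lam > 0, lam, 1.0), 0.0
        ) - np.where(feasible, C, 0.0)
        grad = th * (phi @ g_lam)
        if prior is not None:
            mu0, s0 = prior
            ll += float(-0.5 * np.sum((tt - mu0) ** 2) / s0**2)
            grad = grad - (tt - mu0) / s0**2
        return -ll, -grad

    return fg, feasible


def estimate_profile(
    y: np.ndarray,
    C: float,
    phi: np.ndarray,
    prior: tuple[float, float] | None = None,
    bound: float = THETA_BOUND,
    warm_start: np.ndarray | None = None,
) -> ProfileEstimate:
    """MAP profile of one patient from cumulative counts under fixed phi.

    ``prior`` is an optional Normal(mu0, sigma0) prior on theta~ given as
    a (mu0, sigma0) tuple; the default is flat (box bounds only).
    ``warm_start`` seeds the optimizer with a previous theta-hat for
    incremental re-estimation as new AEs accrue; it does not change the
    optimum at the solver tolerance.
    """
    y = np.asarray(y, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2 or y.shape[0] != phi.shape[1]:
        raise ValueError(
            f"count vector length {y.shape[0]} does not match phi "
            f"columns {phi.shape[1] if phi.ndim == 2 else '?'}"
        )
    if C <= 0:
        raise ValueError("exposure C must be > 0")
    K = phi.shape[0]
    if np.any((phi.sum(axis=0) == 0) & (y > 0)):
        warnings.warn(
            "counts observed on AE types with zero intensity in every "
            "pattern; those cells are infeasible and were ignored"
        )

    total = float(y.sum())
    if K == 1 and prior is None:
        # closed form: each phi row sums to 1, so the Poisson MLE matches
        # the total count exactly: theta = (sum_j y_j) / C
        theta = np.array([total / C])
        tt = np.clip(
            np.log(theta) if theta[0] > 0 else np.array([-bound]), -bound, bound
        )
        fg, _ = _profile_objective(y, C, phi, None)
        return ProfileEstimate(
            theta_hat=np.exp(tt),
            log_prob=-fg(tt)[0],
            converged=True,
            exposure_used=C,
        )

    fg, _ = _profile_objective(y, C, phi, prior)
    if warm_start is not None:
        with np.errstate(divide="ignore"):
            x0 = np.clip(
                np.log(np.maximum(warm_start, 0.0)), -bound, bound
            )
    else:
        start = max(total, 1e-8) / (C * K)
        x0 = np.full(K, np.clip(np.log(start), -bound, bound))
    res = optimize.minimize(
        fg,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(-bound, bound)] * K,
        options={"maxiter": 1000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return ProfileEstimate(
        theta_hat=np.exp(res.x),
        log_prob=-float(res.fun),
        converged=bool(res.success),
        exposure_used=C,
    )


def predict_lambda(theta_hat: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Predicted per-cycle mean count of each AE type: lambda = theta . phi."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    if theta_hat.shape[0] != phi.shape[0]:
        raise ValueError(
            f"theta length {theta_hat.shape[0]} does not match phi rows "
            f"{phi.shape[0]}"
        )
    return theta_hat @ phi


def rank_ae_types(
    lambda_vec: np.ndarray,
    index: AETypeIndex,
    top_n: int = 10,
    min_severity: int | None = None,
) -> PredictionTable:
    """Rank AE types by predicted intensity (descending; ties broken by
    label).  ``min_severity`` restricts to severe types first, as in the
    usual "top severe AE types" listing."""
    lam = np.asarray(lambda_vec, dtype=float)
    if lam.shape[0] != index.J:
        raise ValueError("lambda length does not match the AE-type index")
    df = pd.DataFrame(
        {
            "label": index.labels,
            "severity": index.severities,
            "lam": lam,
        }
    )
    if min_severity is not None:
        df = df[df["severity"] >= min_severity]
    df = df.sort_values(
        ["lam", "label"], ascending=[False, True], kind="mergesort"
    ).head(top_n)
    return PredictionTable(
        table=df.reset_index(drop=True), min_severity=min_severity, top_n=top_n
    )


def compare_profiles(a: ProfileEstimate, b: ProfileEstimate) -> StabilityReport:
    """Componentwise stability of two profile estimates of one patient
    (e.g. at the end of cycle 2 vs cycle 4): near-zero deviations and a
    rank correlation near 1 indicate a stable profile."""
    if a.theta_hat.shape != b.theta_hat.shape:
        raise ValueError("profiles have different numbers of patterns")
    diff = a.theta_hat - b.theta_hat
    if a.theta_hat.size < 2 or (
        np.all(a.theta_hat == a.theta_hat[0]) or np.all(b.theta_hat == b.theta_hat[0])
    ):
        rho = 1.0 if np.allclose(diff, 0) else np.nan
    else:
        rho = float(stats.spearmanr(a.theta_hat, b.theta_hat).statistic)
    return StabilityReport(
        diff=diff,
        max_abs_deviation=float(np.max(np.abs(diff))) if diff.size else 0.0,
        spearman=rho,
    )
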