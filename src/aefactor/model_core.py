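"""Hierarchical Poisson factorization model for adverse-event counts.

The observation model treats each count Y_ijp as Poisson with mean
C_i * lambda_ijp, where the intensity splits into a treatment part and a
study (disease/background) part:

    lambda = beta + alpha,   beta = theta . phi,   alpha = xi . eta,

with beta = 0 during baseline periods.  Patient loadings theta and xi
are made nonnegative by an exp reparametrization; the pattern matrices
phi (one per treatment, K x J) and eta (one per study, L x J) are
row-wise softmax transforms of unconstrained matrices, so every pattern
is a probability vector of occurrence intensities over AE types.
Treatments sharing a mechanism of action share a mean pattern matrix M
and differ through a treatment random effect R: phi = softmax(M + R)
row-wise.  M, R and S (the study analogue) carry two Gaussian priors:
a random-walk (NDLM) prior linking adjacent severities of the same AE
name, and an anchoring prior pinning each name's lowest severity, which
fixes the softmax translation invariance.

This module holds the parameter containers and computes every term of
the joint log-posterior, plus its analytic gradient for the quasi-Newton
fit.  Loadings theta-tilde / xi-tilde have flat priors and are kept in a
finite box (default [-15, 15]) by the optimizer; exp(-15) ~ 3e-7, i.e. a
profile of zero in practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .ae_data import AdjacencySets, CountData, PeriodMeta

__all__ = [
    "Hyperparams",
    "Registries",
    "ModelParams",
    "LogPosteriorBreakdown",
    "ParamPacker",
    "softmax_rows",
    "compute_phi",
    "compute_eta",
    "compute_lambda",
    "poisson_loglik",
    "ndlm_log_prior",
    "log_posterior",
    "log_posterior_and_grad",
    "build_registries",
    "export_params",
    "import_params",
]

THETA_BOUND = 15.0  # box half-width for the unconstrained loadings

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class Hyperparams:
    """Fixed scales of the model.

    K / L are the numbers of treatment / study patterns.  sigma_G is the
    severity random-walk scale (small, since CTCAE grades span only
    1..4); sigma_M and sigma_S are anchor scales wide enough to express
    any pattern; sigma_R keeps treatment random effects to roughly 10%
    of the mechanism mean effect.
    """

    K: int = 15
    L: int = 2
    sigma_G: float = 1.5
    sigma_M: float = 5.0
    sigma_S: float = 5.0
    sigma_R: float = 0.5

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 0:
            raise ValueError("require K >= 1 and L >= 0")
        for name in ("sigma_G", "sigma_M", "sigma_S", "sigma_R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Registries:
    """Row bookkeeping shared by all periods.

    A patient gets one theta row per treatment ever received (shared
    across periods of that treatment) and one xi row per study (shared
    across that study's baseline and treatment periods, which is what
    lets baseline data identify the study part).
    """

    treatment_patients: dict[int, list[str]]
    study_patients: dict[int, list[str]]
    mech_of: dict[int, int]
    mechanisms: list[int]
    random_effect_set: frozenset[int]
    # per-period row index arrays into theta_tilde[t] / xi_tilde[s]
    theta_rows: dict[int, np.ndarray] = field(default_factory=dict)
    xi_rows: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def treatments(self) -> list[int]:
        return sorted(self.treatment_patients)

    @property
    def studies(self) -> list[int]:
        return sorted(self.study_patients)


def build_registries(
    design: list[PeriodMeta],
    random_effect_treatments: set[int] | None = None,
) -> Registries:
    """Assign parameter rows to (patient, treatment) and (patient, study).

    ``random_effect_treatments`` defaults to every treatment whose
    mechanism is shared by at least two treatments: a mechanism with a
    single treatment cannot separate its mean effect from a random
    effect, so that treatment's phi is softmax(M) alone.
    """
    tp: dict[int, set[str]] = {}
    sp: dict[int, set[str]] = {}
    mech_of: dict[int, int] = {}
    for pm in design:
        sp.setdefault(pm.study_id, set()).update(pm.enrolled_patients)
        if pm.treatment_id is not None:
            tp.setdefault(pm.treatment_id, set()).update(pm.enrolled_patients)
            mech_of[pm.treatment_id] = pm.mechanism_id
    if random_effect_treatments is None:
        by_mech: dict[int, set[int]] = {}
        for t, m in mech_of.items():
            by_mech.setdefault(m, set()).add(t)
        random_effect_treatments = {
            t for t, m in mech_of.items() if len(by_mech[m]) >= 2
        }
    reg = Registries(
        treatment_patients={t: sorted(v) for t, v in tp.items()},
        study_patients={s: sorted(v) for s, v in sp.items()},
        mech_of=mech_of,
        mechanisms=sorted(set(mech_of.values())),
        random_effect_set=frozenset(random_effect_treatments),
    )
    t_row = {
        t: {p: i for i, p in enumerate(pats)}
        for t, pats in reg.treatment_patients.items()
    }
    s_row = {
        s: {p: i for i, p in enumerate(pats)}
        for s, pats in reg.study_patients.items()
    }
    for pm in design:
        pats = sorted(pm.enrolled_patients)
        try:
            reg.xi_rows[pm.period_id] = np.array(
                [s_row[pm.study_id][p] for p in pats], dtype=np.intp
            )
            if pm.treatment_id is not None:
                reg.theta_rows[pm.period_id] = np.array(
                    [t_row[pm.treatment_id][p] for p in pats], dtype=np.intp
                )
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"unregistered patient {exc} in period {pm.period_id}")
    return reg


@dataclass
class ModelParams:
    """Free parameters of the model, keyed by treatment/mechanism/study."""

    theta_tilde: dict[int, np.ndarray]  # t -> (N_t, K)
    M: dict[int, np.ndarray]  # m -> (K, J)
    R: dict[int, np.ndarray]  # t -> (K, J), random-effect treatments only
    xi_tilde: dict[int, np.ndarray]  # s -> (N_s, L)
    S: dict[int, np.ndarray]  # s -> (L, J)

    def copy(self) -> "ModelParams":
        return ModelParams(
            theta_tilde={t: a.copy() for t, a in self.theta_tilde.items()},
            M={m: a.copy() for m, a in self.M.items()},
            R={t: a.copy() for t, a in self.R.items()},
            xi_tilde={s: a.copy() for s, a in self.xi_tilde.items()},
            S={s: a.copy() for s, a in self.S.items()},
        )

    def zeros_like(self) -> "ModelParams":
        return ModelParams(
            theta_tilde={t: np.zeros_like(a) for t, a in self.theta_tilde.items()},
            M={m: np.zeros_like(a) for m, a in self.M.items()},
            R={t: np.zeros_like(a) for t, a in self.R.items()},
            xi_tilde={s: np.zeros_like(a) for s, a in self.xi_tilde.items()},
            S={s: np.zeros_like(a) for s, a in self.S.items()},
        )

    def phi(self, t: int, registries: Registries) -> np.ndarray:
        return compute_phi(self.M[registries.mech_of[t]], self.R.get(t))

    def eta(self, s: int) -> np.ndarray:
        return compute_eta(self.S[s])


class ParamPacker:
    """Flattens a ModelParams into one vector for the optimizer (and back).

    Loadings get box bounds [-bound, bound]; pattern matrices are free.
    """

    def __init__(self, template: ModelParams, bound: float = THETA_BOUND):
        self.bound = bound
        self.blocks: list[tuple[str, int, tuple[int, ...], slice]] = []
        off = 0
        for kind in ("theta_tilde", "M", "R", "xi_tilde", "S"):
            d: dict[int, np.ndarray] = getattr(template, kind)
            for key in sorted(d):
                n = d[key].size
                self.blocks.append((kind, key, d[key].shape, slice(off, off + n)))
                off += n
        self.size = off

    def pack(self, params: ModelParams) -> np.ndarray:
        x = np.empty(self.size)
        for kind, key, _, sl in self.blocks:
            x[sl] = getattr(params, kind)[key].ravel()
        return x

    def unpack(self, x: np.ndarray) -> ModelParams:
        out: dict[str, dict[int, np.ndarray]] = {
            k: {} for k in ("theta_tilde", "M", "R", "xi_tilde", "S")
        }
        for kind, key, shape, sl in self.blocks:
            out[kind][key] = x[sl].reshape(shape).copy()
        return ModelParams(**out)

    def bounds(self) -> list[tuple[float | None, float | None]]:
        b: list[tuple[float | None, float | None]] = [(None, None)] * self.size
        for kind, _, _, sl in self.blocks:
            if kind in ("theta_tilde", "xi_tilde"):
                b[sl.start : sl.stop] = [(-self.bound, self.bound)] * (
                    sl.stop - sl.start
                )
        return b


# ---------------------------------------------------------------------------
# model terms


def softmax_rows(A: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for numerical stability."""
    A = np.asarray(A, dtype=float)
    if A.size and not np.all(np.isfinite(A)):
        raise FloatingPointError("softmax_rows: non-finite input")
    if A.size == 0:
        return A.copy()
    Z = A - A.max(axis=-1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=-1, keepdims=True)


def compute_phi(M_m: np.ndarray, R_t: np.ndarray | None = None) -> np.ndarray:
    """Treatment pattern matrix phi = softmax(M + R) row-wise.

    Treatments outside the random-effect set have no R and use the
    mechanism mean alone.
    """
    if R_t is None:
        return softmax_rows(M_m)
    if R_t.shape != M_m.shape:
        raise ValueError(f"shape mismatch: M {M_m.shape} vs R {R_t.shape}")
    return softmax_rows(M_m + R_t)


def compute_eta(S_s: np.ndarray) -> np.ndarray:
    """Study pattern matrix eta = softmax(S) row-wise (empty when L=0)."""
    return softmax_rows(S_s)


def compute_lambda(
    period: PeriodMeta, params: ModelParams, registries: Registries
) -> np.ndarray:
    """Mean occurrence intensity per patient and AE type for one period.

    Treatment periods: lambda = exp(theta~) phi + exp(xi~) eta; baseline
    periods have no treatment part.
    """
    s = period.study_id
    xi = np.exp(params.xi_tilde[s][registries.xi_rows[period.period_id]])
    eta = params.eta(s)  # (L, J); an empty matmul gives zeros when L = 0
    lam = xi @ eta
    if not period.is_baseline:
        t = period.treatment_id
        th = np.exp(params.theta_tilde[t][registries.theta_rows[period.period_id]])
        lam = lam + th @ params.phi(t, registries)
    return lam


def poisson_loglik(Y: np.ndarray, C: np.ndarray, lam: np.ndarray) -> float:
    """Sum of Poisson log-pmfs: sum_ij [Y log(C lam) - C lam - log(Y!)].

    Cells with lam = 0 contribute 0 when Y = 0 and -inf when Y > 0.
    Includes the log(Y!) constant so the value is a true log-probability.
    """
    Y = np.asarray(Y)
    lam = np.asarray(lam, dtype=float)
    if np.any(Y < 0) or np.any(lam < 0):
        raise ValueError("Y and lambda must be nonnegative")
    Cl = np.asarray(C, dtype=float)[:, None] * lam
    total = float(-Cl.sum() - gammaln(Y + 1.0).sum())
    pos = Y > 0
    if np.any(pos):
        with np.errstate(divide="ignore"):
            total += float(np.sum(Y[pos] * np.log(Cl[pos])))
    return total


def _ndlm_parts(
    A: np.ndarray,
    adjacency: AdjacencySets,
    sigma_G: float,
    sigma_anchor: float,
) -> tuple[float, float]:
    """(anchor term, chain term) of the NDLM + anchoring log-prior."""
    if A.size == 0:
        return 0.0, 0.0
    Kp, J = A.shape
    ja = adjacency.anchor_cols
    if ja.size and ja.max() >= J:
        raise ValueError("anchor column outside matrix")
    anchor = float(
        -0.5 * np.sum(A[:, ja] ** 2) / sigma_anchor**2
        - Kp * ja.size * (np.log(sigma_anchor) + 0.5 * _LOG_2PI)
    )
    lo, hi = adjacency.pair_lo, adjacency.pair_hi
    if lo.size and hi.max() >= J:
        raise ValueError("adjacency column outside matrix")
    d = A[:, hi] - A[:, lo]
    chain = float(
        -0.5 * np.sum(d**2) / sigma_G**2
        - Kp * lo.size * (np.log(sigma_G) + 0.5 * _LOG_2PI)
    )
    return anchor, chain


def ndlm_log_prior(
    A: np.ndarray,
    adjacency: AdjacencySets,
    sigma_G: float,
    sigma_anchor: float,
) -> float:
    """Log-prior of one pattern matrix: Gaussian anchors on each AE
    name's lowest severity plus a Gaussian random walk along adjacent
    severities."""
    if sigma_G <= 0 or sigma_anchor <= 0:
        raise ValueError("scales must be > 0")
    a, c = _ndlm_parts(A, adjacency, sigma_G, sigma_anchor)
    return a + c


@dataclass
class LogPosteriorBreakdown:
    """Joint log-posterior with its additive components."""

    total: float
    poisson_by_period: dict[int, float]
    ndlm_M: float
    ndlm_R: float
    ndlm_S: float
    anchor_M: float
    anchor_R: float
    anchor_S: float


def log_posterior(
    params: ModelParams,
    data: CountData,
    adjacency: AdjacencySets,
    hyper: Hyperparams,
    registries: Registries,
) -> LogPosteriorBreakdown:
    """Evaluate the joint log-posterior term by term.

    Poisson likelihood over all periods plus the NDLM/anchor priors on
    M, R and S.  The loadings theta-tilde and xi-tilde carry no prior.
    """
    pois: dict[int, float] = {}
    for p, pm in sorted(data.periods.items()):
        lam = compute_lambda(pm, params, registries)
        pois[p] = poisson_loglik(data.Y[p], data.C[p], lam)
    aM = cM = aR = cR = aS = cS = 0.0
    for m in sorted(params.M):
        a, c = _ndlm_parts(params.M[m], adjacency, hyper.sigma_G, hyper.sigma_M)
        aM += a
        cM += c
    for t in sorted(params.R):
        a, c = _ndlm_parts(params.R[t], adjacency, hyper.sigma_G, hyper.sigma_R)
        aR += a
        cR += c
    for s in sorted(params.S):
        a, c = _ndlm_parts(params.S[s], adjacency, hyper.sigma_G, hyper.sigma_S)
        aS += a
        cS += c
    total = sum(pois.values()) + aM + cM + aR + cR + aS + cS
    return LogPosteriorBreakdown(
        total=total,
        poisson_by_period=pois,
        ndlm_M=cM,
        ndlm_R=cR,
        ndlm_S=cS,
        anchor_M=aM,
        anchor_R=aR,
        anchor_S=aS,
    )


def _softmax_backprop(P: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Gradient through a row-wise softmax: P = softmax(A), D = dL/dP."""
    return P * (D - np.sum(D * P, axis=1, keepdims=True))


def _ndlm_grad_inplace(
    A: np.ndarray,
    adjacency: AdjacencySets,
    sigma_G: float,
    sigma_anchor: float,
    gA: np.ndarray,
) -> None:
    ja = adjacency.anchor_cols
    np.add.at(gA, (slice(None), ja), -A[:, ja] / sigma_anchor**2)
    lo, hi = adjacency.pair_lo, adjacency.pair_hi
    if lo.size:
        d = (A[:, hi] - A[:, lo]) / sigma_G**2
        np.add.at(gA, (slice(None), hi), -d)
        np.add.at(gA, (slice(None), lo), d)


def log_posterior_and_grad(
    params: ModelParams,
    data: CountData,
    adjacency: AdjacencySets,
    hyper: Hyperparams,
    registries: Registries,
) -> tuple[float, ModelParams]:
    """Joint log-posterior and its analytic gradient.

    The likelihood gradient flows as dL/dlambda = Y / lambda - C, then
    through the exp loadings and the softmax pattern construction; the
    softmax gradients for phi are accumulated per treatment (across its
    periods) before a single backprop into M and R.
    """
    grad = params.zeros_like()
    total = 0.0
    phi_cache: dict[int, np.ndarray] = {}
    eta_cache: dict[int, np.ndarray] = {}
    D_phi: dict[int, np.ndarray] = {}
    D_eta: dict[int, np.ndarray] = {}

    for p, pm in sorted(data.periods.items()):
        Y = data.Y[p]
        C = data.C[p]
        s = pm.study_id
        if s not in eta_cache:
            eta_cache[s] = compute_eta(params.S[s])
        eta = eta_cache[s]
        xi = np.exp(params.xi_tilde[s][registries.xi_rows[p]])
        lam = xi @ eta
        th = phi = None
        if not pm.is_baseline:
            t = pm.treatment_id
            if t not in phi_cache:
                phi_cache[t] = compute_phi(
                    params.M[registries.mech_of[t]], params.R.get(t)
                )
            phi = phi_cache[t]
            th = np.exp(params.theta_tilde[t][registries.theta_rows[p]])
            lam = lam + th @ phi
        total += poisson_loglik(Y, C, lam)
        # dL/dlambda; where lambda = 0 the Y = 0 limit is -C
        with np.errstate(divide="ignore", invalid="ignore"):
            G = np.where(lam > 0, Y / np.where(lam > 0, lam, 1.0), 0.0) - C[:, None]
        if not pm.is_baseline:
            t = pm.treatment_id
            np.add.at(
                grad.theta_tilde[t],
                registries.theta_rows[p],
                th * (G @ phi.T),
            )
            D_phi[t] = D_phi.get(t, 0.0) + th.T @ G
        if eta.size:
            np.add.at(
                grad.xi_tilde[s], registries.xi_rows[p], xi * (G @ eta.T)
            )
            D_eta[s] = D_eta.get(s, 0.0) + xi.T @ G

    for t, D in D_phi.items():
        dA = _softmax_backprop(phi_cache[t], D)
        grad.M[registries.mech_of[t]] += dA
        if t in grad.R:
            grad.R[t] += dA
    for s, D in D_eta.items():
        grad.S[s] += _softmax_backprop(eta_cache[s], D)

    for m in params.M:
        a, c = _ndlm_parts(params.M[m], adjacency, hyper.sigma_G, hyper.sigma_M)
        total += a + c
        _ndlm_grad_inplace(
            params.M[m], adjacency, hyper.sigma_G, hyper.sigma_M, grad.M[m]
        )
    for t in params.R:
        a, c = _ndlm_parts(params.R[t], adjacency, hyper.sigma_G, hyper.sigma_R)
        total += a + c
        _ndlm_grad_inplace(
            params.R[t], adjacency, hyper.sigma_G, hyper.sigma_R, grad.R[t]
        )
    for s in params.S:
        a, c = _ndlm_parts(params.S[s], adjacency, hyper.sigma_G, hyper.sigma_S)
        total += a + c
        _ndlm_grad_inplace(
            params.S[s], adjacency, hyper.sigma_G, hyper.sigma_S, grad.S[s]
        )
    return total, grad


# ---------------------------------------------------------------------------
# export / import


def export_params(
    params: ModelParams,
    registries: Registries,
    hyper: Hyperparams,
    adjacency: AdjacencySets,
    labels: list[str],
) -> dict:
    """Serialize parameters (plus the bookkeeping needed to re-evaluate
    the log-posterior bit-identically) to a JSON-compatible dict."""
    return {
        "hyperparams": {
            "K": hyper.K,
            "L": hyper.L,
            "sigma_G": hyper.sigma_G,
            "sigma_M": hyper.sigma_M,
            "sigma_S": hyper.sigma_S,
            "sigma_R": hyper.sigma_R,
        },
        "ae_type_labels": list(labels),
        "adjacency": {
            "adj_pairs": [list(p) for p in adjacency.adj_pairs],
            "anchors": list(adjacency.anchors),
        },
        "mech_of": {str(t): m for t, m in registries.mech_of.items()},
        "random_effect_set": sorted(registries.random_effect_set),
        "treatment_patients": {
            str(t): v for t, v in registries.treatment_patients.items()
        },
        "study_patients": {str(s): v for s, v in registries.study_patients.items()},
        "theta_tilde": {str(t): a.tolist() for t, a in params.theta_tilde.items()},
        "M": {str(m): a.tolist() for m, a in params.M.items()},
        "R": {str(t): a.tolist() for t, a in params.R.items()},
        "xi_tilde": {str(s): a.tolist() for s, a in params.xi_tilde.items()},
        "S": {str(s): a.tolist() for s, a in params.S.items()},
    }


def import_params(
    blob: dict,
) -> tuple[ModelParams, Hyperparams, AdjacencySets, list[str]]:
    """Inverse of :func:`export_params` (registries are rebuilt from the
    design when needed; the patient lists in the blob are informational)."""
    hp = Hyperparams(**blob["hyperparams"])
    adj = AdjacencySets(
        adj_pairs=[tuple(p) for p in blob["adjacency"]["adj_pairs"]],
        anchors=list(blob["adjacency"]["anchors"]),
    )
    params = ModelParams(
        theta_tilde={int(t): np.array(a) for t, a in blob["theta_tilde"].items()},
        M={int(m): np.array(a) for m, a in blob["M"].items()},
        R={int(t): np.array(a) for t, a in blob["R"].items()},
        xi_tilde={int(s): np.array(a) for s, a in blob["xi_tilde"].items()},
        S={int(s): np.array(a) for s, a in blob["S"].items()},
    )
    return params, hp, adj, list(blob["ae_type_labels"])


def save_params_json(path, blob: dict) -> None:
    with open(path, "w") as fh:
        json.dump(blob, fh)


def load_params_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
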