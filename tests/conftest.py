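"""Shared fixtures and the independent loop-based oracle for the
joint log-posterior, kept deliberately naive (scalar loops, scipy pdfs)
so it shares no code path with the vectorized implementation."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import norm

import aefactor as af


def naive_softmax(v):
    e = [math.exp(x) for x in v]
    s = sum(e)
    return [x / s for x in e]


def naive_log_posterior(params, data, adjacency, hyper, registries) -> float:
    """Term-by-term scalar evaluation of the joint log-posterior."""
    total = 0.0
    for p, pm in data.periods.items():
        pats = sorted(pm.enrolled_patients)
        Y, C = data.Y[p], data.C[p]
        s = pm.study_id
        for i, pat in enumerate(pats):
            si = registries.study_patients[s].index(pat)
            for j in range(data.index.J):
                lam = 0.0
                for l in range(params.S[s].shape[0]):
                    eta_l = naive_softmax(params.S[s][l])
                    lam += math.exp(params.xi_tilde[s][si, l]) * eta_l[j]
                if not pm.is_baseline:
                    t = pm.treatment_id
                    ti = registries.treatment_patients[t].index(pat)
                    for k in range(params.theta_tilde[t].shape[1]):
                        row = params.M[registries.mech_of[t]][k].copy()
                        if t in params.R:
                            row = row + params.R[t][k]
                        phi_k = naive_softmax(row)
                        lam += math.exp(params.theta_tilde[t][ti, k]) * phi_k[j]
                mean = C[i] * lam
                y = int(Y[i, j])
                if mean == 0.0:
                    total += 0.0 if y == 0 else -math.inf
                else:
                    total += y * math.log(mean) - mean - math.lgamma(y + 1)

    def prior(A, sigma_anchor):
        out = 0.0
        for k in range(A.shape[0]):
            for j in adjacency.anchors:
                out += norm.logpdf(A[k, j], 0.0, sigma_anchor)
            for j, jp in adjacency.adj_pairs:
                out += norm.logpdf(A[k, jp], A[k, j], hyper.sigma_G)
        return out

    for m in params.M:
        total += prior(params.M[m], hyper.sigma_M)
    for t in params.R:
        total += prior(params.R[t], hyper.sigma_R)
    for s in params.S:
        total += prior(params.S[s], hyper.sigma_S)
    return total


def random_small_instance(seed: int, with_baseline: bool = True, L: int = 1):
    """A random tiny dataset + parameters for oracle and gradient checks
    (N <= 5, J <= 6, K <= 2, L <= 1)."""
    rng = np.random.default_rng(seed)
    K = int(rng.integers(1, 3))
    n = int(rng.integers(2, 6))
    periods = [af.PeriodSpec(1, 1, 2)]
    if with_baseline:
        periods = [af.PeriodSpec(None, None, None)] + periods
    spec = af.SimSpec(
        arms=(af.ArmSpec(1, n, tuple(periods)),),
        n_names=int(rng.integers(2, 4)),
        grades_per_name=None,
        K=K,
        L=L,
        seed=seed,
        frac_background_names=0.0,
    )
    sim = af.simulate(spec)
    # random parameters (not the simulation truth) to probe generic points
    params = sim.truth.params.copy()
    for d in (params.theta_tilde, params.xi_tilde):
        for key in d:
            d[key] = rng.normal(0, 1, size=d[key].shape)
    for d in (params.M, params.R, params.S):
        for key in d:
            d[key] = rng.normal(0, 1.5, size=d[key].shape)
    return sim, params, spec.hyperparams()


@pytest.fixture(scope="session")
def minimal_sim():
    spec = af.preset("minimal", seed=11)
    return af.simulate(spec)


@pytest.fixture(scope="session")
def recovery_fits():
    """Five seeded recovery experiments: simulate from known truth, fit
    with the true K and L, and match patterns.  Shared by the recovery
    and separation tests (session-scoped: fitting dominates runtime)."""
    import aefactor.map_fit as mf

    out = []
    for seed in range(5):
        spec = af.preset("recovery", seed=seed)
        sim = af.simulate(spec)
        fit = mf.fit_map(
            sim.counts,
            sim.truth.adjacency,
            spec.hyperparams(),
            mf.FitConfig(seed=seed, n_restarts=3),
        )
        out.append((spec, sim, fit))
    return out
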