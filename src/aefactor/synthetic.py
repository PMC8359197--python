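"""Synthetic multi-study adverse-event data with known ground truth.

Real patient-level AE data of the kind this model targets is access
restricted, so the generator emulates its structure: several studies,
each with a baseline period and one or more treatment periods, sparse
per-patient counts whose intensities come from the model's own
generative story.  Pattern matrices are drawn from the NDLM chains
(anchor at each AE name's lowest severity, Gaussian random walk across
adjacent severities); patient loadings come from a sparse point-mass +
lognormal mixture so that, as in real data, most patients load near
zero on most patterns and a few load high.  A configurable fraction of
AE names is "background-only" (driven by the study patterns eta, near
zero in every treatment pattern phi) and the rest are treatment-only,
which makes the treatment/disease separation measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ae_data import (
    AdjacencySets,
    AETypeIndex,
    CountData,
    PeriodMeta,
    build_adjacency,
)
from .model_core import (
    THETA_BOUND,
    Hyperparams,
    ModelParams,
    Registries,
    build_registries,
    compute_lambda,
)

__all__ = [
    "PeriodSpec",
    "ArmSpec",
    "SimSpec",
    "TrueParams",
    "SimResult",
    "make_design",
    "draw_true_params",
    "simulate_counts",
    "simulate",
    "to_event_frames",
    "PRESETS",
]


@dataclass(frozen=True)
class PeriodSpec:
    treatment_id: int | None  # None = baseline
    mechanism_id: int | None
    n_cycles: float | None
    n_patients: int | None = None  # None: thin by the arm dropout fraction


@dataclass(frozen=True)
class ArmSpec:
    study_id: int
    n_patients: int
    periods: tuple[PeriodSpec, ...]
    dropout_frac: float = 0.0  # applied between consecutive periods

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("arm patient counts must be >= 1")
        if not 0 <= self.dropout_frac < 1:
            raise ValueError("dropout fraction must be in [0, 1)")


@dataclass(frozen=True)
class SimSpec:
    """Study design, dimensions and generation scales of one simulation."""

    arms: tuple[ArmSpec, ...]
    n_names: int = 20
    grades_per_name: int | None = 3  # None: sample 1..4 grades per name
    K: int = 3
    L: int = 1
    seed: int = 0
    # pattern-matrix generation (anchors and random-walk steps)
    sigma_M_gen: float = 3.0
    sigma_S_gen: float = 3.0
    sigma_R_gen: float = 0.5
    sigma_G_gen: float = 1.0
    # sparse loading mixture: P(zero), then logN(mu, sd) otherwise
    pi_zero_theta: float = 0.6
    mu_theta: float = 0.4
    sd_theta: float = 0.5
    pi_zero_xi: float = 0.3
    mu_xi: float = -1.2
    sd_xi: float = 0.5
    # treatment/background AE-type separation
    frac_background_names: float = 0.2
    suppress: float = 10.0
    baseline_exposure: float = 1.0
    bound: float = THETA_BOUND

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("at least one arm required")

    def hyperparams(self, **kw) -> Hyperparams:
        return Hyperparams(K=self.K, L=self.L, **kw)

    @property
    def background_names(self) -> list[str]:
        names = _names(self.n_names)
        n_bg = int(round(self.frac_background_names * self.n_names))
        return names[:n_bg]


def _names(n: int) -> list[str]:
    return [f"AE{i:03d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# presets


def _table1_preset(**kw) -> SimSpec:
    """Design shaped like a pooled three-study breast-cancer dataset:
    10 periods (3 baseline), 5 treatments, 2 mechanisms of action."""
    AC, FAC, A, CMF, T = 1, 2, 3, 4, 5
    NUC, MIT = 1, 2
    arms = (
        ArmSpec(  # study 1: baseline, 4 cycles AC, then 4 cycles docetaxel
            study_id=1,
            n_patients=1625,
            periods=(
                PeriodSpec(None, None, None, 1625),
                PeriodSpec(AC, NUC, 4, 1625),
                PeriodSpec(T, MIT, 4, 1583),
            ),
        ),
        ArmSpec(  # study 2: 6 cycles FAC, no baseline data
            study_id=2,
            n_patients=731,
            periods=(PeriodSpec(FAC, NUC, 6, 731),),
        ),
        ArmSpec(
            study_id=3,
            n_patients=480,
            periods=(
                PeriodSpec(None, None, None, 480),
                PeriodSpec(A, NUC, 4, 480),
                PeriodSpec(CMF, NUC, 3, 459),
            ),
        ),
        ArmSpec(
            study_id=3,
            n_patients=481,
            periods=(
                PeriodSpec(None, None, None, 481),
                PeriodSpec(AC, NUC, 4, 481),
                PeriodSpec(CMF, NUC, 3, 472),
            ),
        ),
    )
    defaults = dict(arms=arms, n_names=30, grades_per_name=None, K=15, L=2)
    defaults.update(kw)
    return SimSpec(**defaults)


def _minimal_preset(**kw) -> SimSpec:
    arms = (
        ArmSpec(
            study_id=1,
            n_patients=40,
            periods=(
                PeriodSpec(None, None, None),
                PeriodSpec(1, 1, 4),
            ),
        ),
    )
    defaults = dict(arms=arms, n_names=6, grades_per_name=2, K=2, L=1)
    defaults.update(kw)
    return SimSpec(**defaults)


def _recovery_preset(**kw) -> SimSpec:
    """One study, baseline + one treatment period, 600 patients, 20 AE
    names x 3 grades (J = 60), K = 3 treatment and L = 1 study patterns,
    sparse loadings giving roughly ten AEs per patient."""
    arms = (
        ArmSpec(
            study_id=1,
            n_patients=600,
            periods=(
                PeriodSpec(None, None, None),
                PeriodSpec(1, 1, 4),
            ),
        ),
    )
    defaults = dict(arms=arms, n_names=20, grades_per_name=3, K=3, L=1)
    defaults.update(kw)
    return SimSpec(**defaults)


PRESETS = {
    "table1": _table1_preset,
    "minimal": _minimal_preset,
    "recovery": _recovery_preset,
}


def preset(name: str, **kw) -> SimSpec:
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return PRESETS[name](**kw)


# ---------------------------------------------------------------------------
# design and parameters


def make_design(spec: SimSpec, seed: int | None = None) -> list[PeriodMeta]:
    """Instantiate the design: periods, enrollment and dropout.

    Later periods of an arm enroll a dropout-thinned random subset of
    the arm's initial patients; period ids are assigned consecutively in
    arm order.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    design: list[PeriodMeta] = []
    pid = 1
    for a_i, arm in enumerate(spec.arms):
        pats = [f"S{arm.study_id}A{a_i + 1}P{i:05d}" for i in range(arm.n_patients)]
        current = list(pats)
        for k, ps in enumerate(arm.periods):
            if ps.n_patients is not None:
                n = ps.n_patients
            elif k == 0:
                n = arm.n_patients
            else:
                n = int(round(len(current) * (1 - arm.dropout_frac)))
            if n > len(current):
                raise ValueError(
                    f"period {pid}: {n} patients requested but only "
                    f"{len(current)} remain in the arm"
                )
            if n < len(current):
                keep = rng.choice(len(current), size=n, replace=False)
                current = [current[i] for i in sorted(keep)]
            design.append(
                PeriodMeta(
                    period_id=pid,
                    study_id=arm.study_id,
                    treatment_id=ps.treatment_id,
                    mechanism_id=ps.mechanism_id,
                    n_cycles=ps.n_cycles,
                    is_baseline=ps.treatment_id is None,
                    enrolled_patients=list(current),
                )
            )
            pid += 1
    return design


def _make_index(spec: SimSpec, rng: np.random.Generator) -> AETypeIndex:
    pairs = []
    for name in _names(spec.n_names):
        if spec.grades_per_name is not None:
            k = spec.grades_per_name
        else:
            k = int(rng.integers(1, 5))
        grades = sorted(rng.choice(4, size=k, replace=False) + 1)
        pairs.extend((name, int(g)) for g in grades)
    return AETypeIndex(pairs)


@dataclass
class TrueParams:
    """Ground truth: parameters plus the structures they live on."""

    params: ModelParams
    index: AETypeIndex
    adjacency: AdjacencySets
    registries: Registries
    phi: dict[int, np.ndarray] = field(default_factory=dict)
    eta: dict[int, np.ndarray] = field(default_factory=dict)


def _draw_ndlm_matrix(
    rng: np.random.Generator,
    n_rows: int,
    index: AETypeIndex,
    adjacency: AdjacencySets,
    sigma_anchor: float,
    sigma_step: float,
    anchor_mean: np.ndarray,
) -> np.ndarray:
    """Draw rows anchored at each name's lowest severity and random-walked
    along the adjacency chain (the model priors used generatively)."""
    A = np.zeros((n_rows, index.J))
    ja = adjacency.anchor_cols
    A[:, ja] = anchor_mean[ja] + rng.normal(0, sigma_anchor, size=(n_rows, ja.size))
    for lo, hi in adjacency.adj_pairs:  # pairs are ordered low -> high grade
        A[:, hi] = A[:, lo] + rng.normal(0, sigma_step, size=n_rows)
    return A


def draw_true_params(
    design: list[PeriodMeta],
    spec: SimSpec,
    seed: int | None = None,
    random_effect_treatments: set[int] | None = None,
) -> TrueParams:
    """Draw ground-truth parameters for a design, deterministically."""
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    index = _make_index(spec, rng)
    adjacency = build_adjacency(index)
    registries = build_registries(design, random_effect_treatments)
    bg = set(spec.background_names)
    is_bg = np.array([n in bg for n in index.names])
    # anchor means: background AE names suppressed in treatment patterns,
    # treatment names suppressed in study patterns
    mean_M = np.where(is_bg, -spec.suppress, 0.0)
    mean_S = np.where(is_bg, 0.0, -spec.suppress)

    M = {
        m: _draw_ndlm_matrix(
            rng, spec.K, index, adjacency, spec.sigma_M_gen, spec.sigma_G_gen, mean_M
        )
        for m in registries.mechanisms
    }
    R = {
        t: _draw_ndlm_matrix(
            rng,
            spec.K,
            index,
            adjacency,
            spec.sigma_R_gen,
            spec.sigma_G_gen,
            np.zeros(index.J),
        )
        for t in sorted(registries.random_effect_set)
    }
    S = {
        s: _draw_ndlm_matrix(
            rng, spec.L, index, adjacency, spec.sigma_S_gen, spec.sigma_G_gen, mean_S
        )
        for s in registries.studies
    }

    def _sparse_loadings(n: int, k: int, pi0: float, mu: float, sd: float):
        vals = rng.normal(mu, sd, size=(n, k))
        zero = rng.random((n, k)) < pi0
        return np.where(zero, -spec.bound, np.clip(vals, -spec.bound, spec.bound))

    theta_tilde = {
        t: _sparse_loadings(
            len(pats), spec.K, spec.pi_zero_theta, spec.mu_theta, spec.sd_theta
        )
        for t, pats in registries.treatment_patients.items()
    }
    xi_tilde = {
        s: _sparse_loadings(
            len(pats), spec.L, spec.pi_zero_xi, spec.mu_xi, spec.sd_xi
        )
        for s, pats in registries.study_patients.items()
    }
    params = ModelParams(
        theta_tilde=theta_tilde, M=M, R=R, xi_tilde=xi_tilde, S=S
    )
    tp = TrueParams(
        params=params, index=index, adjacency=adjacency, registries=registries
    )
    tp.phi = {t: params.phi(t, registries) for t in registries.treatments}
    tp.eta = {s: params.eta(s) for s in registries.studies}
    return tp


def simulate_counts(
    true_params: TrueParams,
    design: list[PeriodMeta],
    seed: int | None = None,
    baseline_exposure: float = 1.0,
) -> CountData:
    """Draw Y_ijp ~ Poisson(C_i lambda_ijp) independently per period."""
    rng = np.random.default_rng(0 if seed is None else seed)
    Y: dict[int, np.ndarray] = {}
    C: dict[int, np.ndarray] = {}
    for pm in design:
        pats = sorted(pm.enrolled_patients)
        c = baseline_exposure if pm.is_baseline else float(pm.n_cycles)
        Cp = np.full(len(pats), c)
        lam = compute_lambda(pm, true_params.params, true_params.registries)
        mean = Cp[:, None] * lam
        if not np.all(np.isfinite(mean)) or np.any(mean > 1e12):
            raise OverflowError("simulated Poisson mean exceeds 1e12")
        Y[pm.period_id] = rng.poisson(mean).astype(np.int64)
        C[pm.period_id] = Cp
    return CountData(
        Y=Y,
        C=C,
        periods={pm.period_id: pm for pm in design},
        index=true_params.index,
    )


@dataclass
class SimResult:
    spec: SimSpec
    design: list[PeriodMeta]
    truth: TrueParams
    counts: CountData


def simulate(spec: SimSpec, seed: int | None = None) -> SimResult:
    """End-to-end: design, ground truth, counts — all from one seed."""
    base = spec.seed if seed is None else seed
    design = make_design(spec, seed=base)
    truth = draw_true_params(design, spec, seed=base)
    counts = simulate_counts(
        truth, design, seed=base + 2, baseline_exposure=spec.baseline_exposure
    )
    return SimResult(spec=spec, design=design, truth=truth, counts=counts)


# ---------------------------------------------------------------------------
# export in the CSV dialects the ingestion layer consumes


def to_event_frames(
    counts: CountData,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Long-format events, design and enrollment tables (round-trips
    through the ingestion layer back to the same count matrices)."""
    ev_rows = []
    en_rows = []
    de_rows = []
    for p, pm in sorted(counts.periods.items()):
        pats = sorted(pm.enrolled_patients)
        de_rows.append(
            {
                "period_id": p,
                "study_id": pm.study_id,
                "treatment_id": "" if pm.treatment_id is None else pm.treatment_id,
                "mechanism_id": "" if pm.mechanism_id is None else pm.mechanism_id,
                "n_cycles": "" if pm.n_cycles is None else pm.n_cycles,
                "is_baseline": pm.is_baseline,
            }
        )
        Yp = counts.Y[p]
        for i, pat in enumerate(pats):
            en_rows.append({"period_id": p, "patient_id": pat})
            for j in np.nonzero(Yp[i])[0]:
                name, sev = counts.index.pairs[j]
                ev_rows.append(
                    {
                        "patient_id": pat,
                        "period_id": p,
                        "ae_name": name,
                        "severity": sev,
                        "count": int(Yp[i, j]),
                    }
                )
    events = pd.DataFrame(
        ev_rows, columns=["patient_id", "period_id", "ae_name", "severity", "count"]
    )
    design = pd.DataFrame(de_rows)
    enrollment = pd.DataFrame(en_rows, columns=["period_id", "patient_id"])
    return events, design, enrollment


def write_dataset(counts: CountData, outdir) -> dict[str, str]:
    """Write events/design/enrollment CSVs; returns the file paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    events, design, enrollment = to_event_frames(counts)
    paths = {
        "events": os.path.join(outdir, "events.csv"),
        "design": os.path.join(outdir, "design.csv"),
        "enrollment": os.path.join(outdir, "enrollment.csv"),
    }
    events.to_csv(paths["events"], index=False)
    design.to_csv(paths["design"], index=False)
    enrollment.to_csv(paths["enrollment"], index=False)
    return paths
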