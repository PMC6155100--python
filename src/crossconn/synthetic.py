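"""Synthetic multi-paradigm cohort generator.

Emulates the statistical structure the cross-paradigm analysis assumes: a
cohort of ordered outcome groups (lowest risk first), each subject scanned
under K paradigms, with

* a shared per-subject latent connectivity architecture (a low-rank factor
  model whose loadings carry a global strength factor plus structured
  factors), so that per-subject PCA across paradigms finds a dominant first
  component;
* paradigm-specific deviations (factor-loading perturbations), whose size
  relative to the shared part is set by ``shared_variance_fraction``;
* a planted subnetwork whose edges receive a graded group shift on the
  Fisher-z scale (control < intermediate < highest-risk group), standardized
  so the realized between-group Cohen's d on mean planted-edge connectivity
  matches the configured ``effect_sizes``;
* covariate confounding (age, head motion, antipsychotic dose modulate the
  global connectivity factor) and phenotypes coupled to planted-network
  strength (positively for symptoms, negatively for months to conversion).

All subject- and paradigm-level connectivity variation is generated through
factor loadings, which keeps every target matrix positive semi-definite by
construction; only the (small) planted-edge shift is injected directly on the
Fisher-z edge scale, followed by an eigenvalue-clipping repair in the rare
case it pushes a matrix marginally outside the PSD cone. A severely
non-PSD assembly raises :class:`ConstructionError`.

Effect standardization is self-calibrating: before drawing the cohort, the
generator simulates a fixed-seed pilot population at the latent edge level
(cheap: no time series) to measure the within-group standard deviation of the
mean planted-edge value, and scales the group shifts by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .connectivity import (
    ScanTimeSeries,
    devectorize_edges,
    edge_pairs,
    n_edges,
)
from .design import CohortDesign, PhenotypeTable
from .exceptions import ConstructionError, ParameterError
from .nbs import NetworkMask

__all__ = [
    "CovariateModel",
    "SynthConfig",
    "SyntheticCohort",
    "plant_network",
    "plant_connected_network",
    "generate_cohort",
]

_GROUP_NAME_SETS = {
    2: ("control", "case"),
    3: ("control", "non-converter", "converter"),
    4: ("control", "adhd", "bipolar", "schizophrenia"),
}


@dataclass(frozen=True)
class CovariateModel:
    """Slopes linking covariates to the (log) global connectivity factor.

    Units: change in log global-factor weight per covariate unit. Head motion
    inflating apparent connectivity is the classic confound; dose and age
    effects are kept small.
    """

    age: float = -0.004        # per year from the reference age
    mean_fd: float = 2.0       # per mm of mean frame-wise displacement
    dose: float = 2.0e-4       # per chlorpromazine-equivalent mg
    age_ref: float = 21.0
    fd_ref: float = 0.10


@dataclass
class SynthConfig:
    """Study conditions for one synthetic cohort.

    The defaults are the desk-scale study conditions used throughout the test
    battery: 60 nodes, 3 paradigms (one resting-state, two task), three
    ordered outcome groups of 30, a 30-edge connected planted subnetwork with
    graded standardized shifts (0, 0.5, 1.0), and a shared-variance fraction
    calibrated so the first cross-paradigm PC explains roughly 70% of the
    variance.
    """

    n_nodes: int = 60
    n_paradigms: int = 3
    group_sizes: tuple[int, ...] = (30, 30, 30)
    group_names: tuple[str, ...] | None = None
    timepoints_per_paradigm: int | tuple[int, ...] | None = None
    planted_edge_count: int = 30
    effect_sizes: tuple[float, ...] = (0.0, 0.5, 1.0)
    graded: bool = True
    planted_topology: str = "connected"   # or "uniform"
    shared_variance_fraction: float = 0.58
    noise_sd: float = 0.0
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    phenotype_coupling: float = 0.5
    paradigm_dropout: float = 0.0
    paradigm_classes: tuple[str, ...] | None = None
    sampling_interval: float = 2.0
    # latent-architecture knobs (see docs/methods.md for rationale)
    n_factors: int = 4
    factor_strength: float = 0.65
    base_global_weight: float = 0.45
    subject_global_log_sd: float = 0.8
    subject_factor_sd: float = 0.12
    network_strength_sd: float = 0.06
    nuisance_amplitude: float = 0.15
    n_nuisance: int = 8
    seed: int = 0
    # fixes the planted network + base architecture independently of the
    # subject draws, so independent cohorts can share the same ground truth
    # (e.g. discovery/transfer pairs); None means "derive from seed"
    architecture_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ParameterError("n_nodes must be >= 3")
        if self.n_paradigms < 2:
            raise ParameterError("n_paradigms must be >= 2")
        if len(self.group_sizes) < 2 or any(g < 2 for g in self.group_sizes):
            raise ParameterError("need >= 2 groups with >= 2 subjects each")
        if self.planted_edge_count < 0 or self.planted_edge_count > n_edges(self.n_nodes):
            raise ParameterError("planted_edge_count exceeds N(N-1)/2")
        if not 0 <= self.shared_variance_fraction <= 1:
            raise ParameterError("shared_variance_fraction must be in [0, 1]")
        if len(self.effect_sizes) != len(self.group_sizes):
            raise ParameterError("one effect size per group required")
        if self.graded and np.any(np.diff(self.effect_sizes) < 0):
            raise ParameterError("graded mode requires non-decreasing effect_sizes")
        if not 0 <= self.paradigm_dropout < 1:
            raise ParameterError("paradigm_dropout must be in [0, 1)")
        if self.planted_topology not in ("connected", "uniform"):
            raise ParameterError("planted_topology must be 'connected' or 'uniform'")
        if self.paradigm_classes is None:
            self.paradigm_classes = ("rest",) + ("task",) * (self.n_paradigms - 1)
        self.paradigm_classes = tuple(self.paradigm_classes)
        if len(self.paradigm_classes) != self.n_paradigms or any(
            c not in ("rest", "task") for c in self.paradigm_classes
        ):
            raise ParameterError("paradigm_classes must be 'rest'/'task', one per paradigm")
        if self.timepoints_per_paradigm is None:
            # rest scans run longer: the narrow band-pass leaves fewer
            # effective degrees of freedom per volume than task high-pass
            self.timepoints_per_paradigm = tuple(
                240 if c == "rest" else 160 for c in self.paradigm_classes
            )
        if isinstance(self.timepoints_per_paradigm, int):
            self.timepoints_per_paradigm = (self.timepoints_per_paradigm,) * self.n_paradigms
        self.timepoints_per_paradigm = tuple(int(t) for t in self.timepoints_per_paradigm)
        if len(self.timepoints_per_paradigm) != self.n_paradigms:
            raise ParameterError("one timepoint count per paradigm required")
        if any(t < 4 * (self.n_nuisance + 1) for t in self.timepoints_per_paradigm):
            raise ParameterError("too few timepoints for the nuisance model")
        if self.group_names is None:
            self.group_names = _GROUP_NAME_SETS.get(
                len(self.group_sizes),
                tuple(f"group{k}" for k in range(len(self.group_sizes))),
            )
        self.group_names = tuple(self.group_names)
        if len(self.group_names) != len(self.group_sizes):
            raise ParameterError("one group name per group required")


@dataclass
class SyntheticCohort:
    """A generated cohort: scans, design, phenotypes, and ground truth."""

    scans: dict[tuple[str, str], ScanTimeSeries]
    subject_ids: list[str]
    paradigm_ids: list[str]
    design: CohortDesign
    phenotypes: PhenotypeTable
    truth: NetworkMask
    true_effect_sizes: tuple[float, ...]
    config: SynthConfig
    calibration: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid in self.subject_ids:
            if len(self.subject_paradigms(sid)) < 2:
                raise ConstructionError(f"subject {sid} has fewer than 2 paradigms")

    def subject_paradigms(self, subject_id: str) -> list[str]:
        return [p for (s, p) in self.scans if s == subject_id]

    def scan(self, subject_id: str, paradigm_id: str) -> ScanTimeSeries:
        return self.scans[(subject_id, paradigm_id)]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


# ---------------------------------------------------------------------------
# planted-network samplers
# ---------------------------------------------------------------------------

def _uniform_edges(rng: np.random.Generator, n_nodes: int, m: int) -> np.ndarray:
    total = n_edges(n_nodes)
    picks = rng.choice(total, size=m, replace=False)
    iu, ju = edge_pairs(n_nodes)
    return np.stack([iu[picks], ju[picks]], axis=1)


def plant_network(n_nodes: int, m_edges: int, seed: int | None = None) -> NetworkMask:
    """Uniformly sampled edge set: ``m_edges`` distinct undirected pairs i < j."""
    if m_edges < 0 or m_edges > n_edges(n_nodes):
        raise ParameterError(
            f"cannot place {m_edges} edges among {n_nodes} nodes "
            f"(max {n_edges(n_nodes)})"
        )
    rng = np.random.default_rng(seed)
    if m_edges == 0:
        return NetworkMask(edges=np.empty((0, 2), dtype=int), n_nodes=n_nodes)
    return NetworkMask(edges=_uniform_edges(rng, n_nodes, m_edges), n_nodes=n_nodes)


def plant_connected_network(
    n_nodes: int,
    m_edges: int,
    seed: int | None = None,
    edges_per_node: float = 1.355,
) -> NetworkMask:
    """Random *connected* subnetwork on a node subset.

    Samples a node subset sized so the edge/node ratio is about
    ``edges_per_node`` (the density regime of sparse circuit-level findings),
    builds a random spanning tree over it, then adds the remaining edges
    uniformly among the subset. The result is a single connected component,
    the shape a component-based statistic is designed to recover.
    """
    if m_edges < 1 or m_edges > n_edges(n_nodes):
        raise ParameterError("m_edges out of range")
    rng = np.random.default_rng(seed)
    m_nodes = int(round(m_edges / edges_per_node)) + 1
    m_nodes = max(2, min(m_nodes, n_nodes, m_edges + 1))
    while n_edges(m_nodes) < m_edges:
        m_nodes += 1
    if m_nodes > n_nodes:
        raise ParameterError("m_edges too large for a connected subnetwork")
    nodes = rng.choice(n_nodes, size=m_nodes, replace=False)
    # random spanning tree (random attachment order)
    order = rng.permutation(m_nodes)
    edges = set()
    for k in range(1, m_nodes):
        anchor = order[rng.integers(0, k)]
        a, b = int(nodes[anchor]), int(nodes[order[k]])
        edges.add((min(a, b), max(a, b)))
    pool = [
        (int(min(a, b)), int(max(a, b)))
        for ix, a in enumerate(nodes)
        for b in nodes[ix + 1 :]
        if (min(a, b), max(a, b)) not in edges
    ]
    extra = m_edges - len(edges)
    if extra > 0:
        picks = rng.choice(len(pool), size=extra, replace=False)
        edges.update(pool[p] for p in picks)
    return NetworkMask(edges=np.asarray(sorted(edges)), n_nodes=n_nodes)


# ---------------------------------------------------------------------------
# latent model pieces
# ---------------------------------------------------------------------------

_UNIQUE_VAR = 1.0
_R_CLIP = 0.995


def _edge_z_from_loadings(lam: np.ndarray) -> np.ndarray:
    """Fisher-z edge vector of cov2corr(lam @ lam.T + I)."""
    s = lam @ lam.T
    var = np.diag(s) + _UNIQUE_VAR
    d = 1.0 / np.sqrt(var)
    r = s * d[:, None] * d[None, :]
    iu, ju = edge_pairs(lam.shape[0])
    return np.arctanh(np.clip(r[iu, ju], -_R_CLIP, _R_CLIP))


def _ensure_psd_correlation(r: np.ndarray) -> np.ndarray:
    """Cholesky fast path; eigenvalue clip + renormalize when marginally non-PSD."""
    try:
        np.linalg.cholesky(r + 1e-10 * np.eye(r.shape[0]))
        return r
    except np.linalg.LinAlgError:
        pass
    evals, evecs = np.linalg.eigh(r)
    # planted shifts push a target matrix at most marginally outside the PSD
    # cone; "marginal" is judged by the negative eigenvalue mass against the
    # trace (= N for a correlation matrix). Deeper degeneracy means the
    # requested perturbations are incompatible with a correlation matrix.
    neg_mass = float(-evals[evals < 0].sum())
    if neg_mass > 0.05 * r.shape[0]:
        raise ConstructionError(
            "assembled connectivity matrix is severely non-positive-semi-definite "
            f"(negative eigenvalue mass {neg_mass:.3f} vs trace {r.shape[0]}); "
            "reduce planted shifts or network_strength_sd"
        )
    evals = np.clip(evals, 1e-8, None)
    fixed = (evecs * evals) @ evecs.T
    d = 1.0 / np.sqrt(np.diag(fixed))
    fixed = fixed * d[:, None] * d[None, :]
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _ar1(rng: np.random.Generator, t: int, phi: float = 0.9) -> np.ndarray:
    x = np.empty(t)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(t - 1) * np.sqrt(1 - phi**2)
    for k in range(1, t):
        x[k] = phi * x[k - 1] + innov[k - 1]
    return x


def _estimation_noise_var(cfg: SynthConfig) -> float:
    """Predicted Fisher-z sampling variance of one edge, averaged over paradigms."""
    nyq = 0.5 / cfg.sampling_interval
    out = []
    for t, cls in zip(cfg.timepoints_per_paradigm, cfg.paradigm_classes):
        if cls == "rest":
            frac = (0.1 - 0.008) / nyq
        else:
            frac = (nyq - 0.008) / nyq
        t_eff = max(t * frac - (cfg.n_nuisance + 1), 12)
        out.append(1.0 / (t_eff - 3))
    return float(np.mean(out))


def _draw_covariates(
    rng: np.random.Generator, codes: np.ndarray, cfg: SynthConfig
) -> pd.DataFrame:
    n = codes.shape[0]
    age = np.clip(rng.normal(21.0, 4.0, n), 14.0, 40.0)
    sex = rng.choice(["F", "M"], size=n)
    iq = rng.normal(105.0, 12.0, n)
    site = rng.choice([f"site{k}" for k in range(1, 5)], size=n)
    mean_fd = 0.06 + rng.gamma(3.0, 0.015, n) + 0.01 * codes
    dose = np.zeros(n)
    med = (codes > 0) & (rng.random(n) < 0.25 + 0.15 * codes)
    dose[med] = rng.gamma(2.0, 75.0, int(med.sum()))
    return pd.DataFrame(
        {"age": age, "sex": sex, "iq": iq, "site": site, "mean_fd": mean_fd, "dose": dose}
    )


_SQRT3 = float(np.sqrt(3.0))


def _global_draw(rng: np.random.Generator) -> float:
    """Standardized (unit-variance, zero-mean) bounded draw for global strength.

    Uniform rather than Gaussian: a bounded distribution keeps per-cohort
    standard deviations stable, so standardized effect sizes are not distorted
    by rare extreme-connectivity subjects.
    """
    return float(rng.uniform(-_SQRT3, _SQRT3))


def _global_log_weight(
    rng_draw: float, cov_row: pd.Series, cfg: SynthConfig
) -> float:
    cm = cfg.covariate_model
    return (
        cfg.subject_global_log_sd * rng_draw
        + cm.age * (cov_row["age"] - cm.age_ref)
        + cm.mean_fd * (cov_row["mean_fd"] - cm.fd_ref)
        + cm.dose * cov_row["dose"]
    )


# ---------------------------------------------------------------------------
# pilot calibration
# ---------------------------------------------------------------------------

def _calibrate(
    cfg: SynthConfig,
    lam_base: np.ndarray,
    mask_idx: np.ndarray,
    rng: np.random.Generator,
) -> dict:
    """Pilot simulation standardizing paradigm noise and the planted effect.

    Three measurements on a fixed-seed pilot population (latent level, no
    time series):

    * ``sigma_b`` - paradigm loading-perturbation scale realizing the
      configured shared-variance fraction after accounting for the predicted
      finite-scan sampling noise;
    * ``sigma_m`` - within-group SD of the mean planted-edge connectivity
      (correlation scale, paradigm-averaged, after PSD repair);
    * ``gain`` - realized correlation-scale response of that mean to a unit
      Fisher-z planted shift, absorbing both tanh compression and the
      (small) eigenvalue-clipping repair.

    Group shifts are then ``delta_g = effect_size_g * sigma_m / gain`` on the
    Fisher-z scale, so the realized between-group Cohen's d on mean
    planted-edge connectivity matches the configured effect sizes.
    """
    n = cfg.n_nodes
    r = cfg.n_factors
    w0 = cfg.base_global_weight

    # stage 1: across-edge variance of the subject trait (shared part) and the
    # per-unit edge variance of a loading perturbation
    n1 = 48
    cov1 = _draw_covariates(rng, np.zeros(n1, dtype=int), cfg)
    z_list, probe_var = [], []
    for i in range(n1):
        w = w0 * np.exp(_global_log_weight(_global_draw(rng), cov1.iloc[i], cfg))
        a = rng.normal(0.0, cfg.subject_factor_sd, (n, r))
        lam = np.column_stack([np.full(n, w), lam_base + a])
        z = _edge_z_from_loadings(lam)
        z_list.append(z)
        eps = 0.1
        pert = rng.standard_normal((n, r + 1)) * eps
        probe_var.append(np.mean((_edge_z_from_loadings(lam + pert) - z) ** 2) / eps**2)
    v_shared = float(np.mean(np.var(np.vstack(z_list), axis=1, ddof=1)))
    v_unit = float(np.mean(probe_var))

    s = max(cfg.shared_variance_fraction, 0.01)
    v_para_target = v_shared * (1 - s) / s
    v_factor = max(v_para_target - _estimation_noise_var(cfg), 0.0)
    sigma_b = float(np.sqrt(v_factor / v_unit)) if v_factor > 0 else 0.0

    out = {
        "sigma_b": sigma_b,
        "v_shared": v_shared,
        "v_para_target": v_para_target,
        "estimation_noise_var": _estimation_noise_var(cfg),
        "sigma_m": float("nan"),
    }
    max_eff = float(np.max(np.abs(cfg.effect_sizes)))
    if mask_idx.size == 0 or max_eff == 0:
        return out

    # stage 2: iterative effect standardization through the exact
    # matrix-assembly path used for real subjects. The correlation scale is
    # mildly nonlinear in the Fisher-z shift (tanh compression, PSD repair),
    # and the within-group spread itself compresses as the shift grows, so
    # the Cohen's d realized by a trial shift is measured on pilot subjects
    # and the shift rescaled until the pilot d matches the requested one.
    k = cfg.n_paradigms
    n2 = 96
    iu, ju = edge_pairs(n)

    def _mask_mean(z_vec: np.ndarray, shift: float) -> float:
        z2 = z_vec.copy()
        z2[mask_idx] += shift
        r_t = _ensure_psd_correlation(devectorize_edges(np.tanh(z2)))
        return float(r_t[iu[mask_idx], ju[mask_idx]].mean())

    effects = sorted({abs(float(e)) for e in cfg.effect_sizes if e != 0})
    trial = {e: 0.0 for e in effects}
    for it in range(3):
        cov2 = _draw_covariates(rng, np.zeros(n2, dtype=int), cfg)
        m0 = np.zeros(n2)
        me = {e: np.zeros(n2) for e in effects}
        for i in range(n2):
            w = w0 * np.exp(_global_log_weight(_global_draw(rng), cov2.iloc[i], cfg))
            a = rng.normal(0.0, cfg.subject_factor_sd, (n, r))
            c = rng.normal(0.0, cfg.network_strength_sd)
            lam = np.column_stack([np.full(n, w), lam_base + a])
            for _ in range(k):
                lam_k = lam + rng.normal(0.0, sigma_b, (n, r + 1)) if sigma_b > 0 else lam
                z = _edge_z_from_loadings(lam_k)
                m0[i] += _mask_mean(z, c)
                for e in effects:
                    if it > 0:
                        me[e][i] += _mask_mean(z, c + trial[e])
        m0 /= k
        if it == 0:
            # initial linear guess from the no-shift spread
            out["sigma_m"] = float(m0.std(ddof=1))
            trial = {e: e * out["sigma_m"] for e in effects}
            continue
        done = True
        for e in effects:
            me[e] /= k
            pooled = np.sqrt((m0.var(ddof=1) + me[e].var(ddof=1)) / 2)
            realized = float((me[e].mean() - m0.mean()) / pooled)
            if realized > 0:
                trial[e] *= e / realized
                done = done and abs(realized - e) < 0.02 * e
        if done:
            break
    out["shift_per_effect"] = dict(trial)
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SynthConfig) -> SyntheticCohort:
    """Draw one cohort under the configured study conditions.

    Fully reproducible: identical config + seed give a bit-identical cohort.
    """
    cfg = config
    n = cfg.n_nodes
    arch_seed = cfg.seed if cfg.architecture_seed is None else cfg.architecture_seed
    rng_mask, rng_base = (
        np.random.default_rng(s) for s in np.random.SeedSequence(arch_seed).spawn(2)
    )
    ss = np.random.SeedSequence(cfg.seed)
    _, _, rng_cov, rng_pilot, rng_subj, rng_pheno = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )

    # planted subnetwork (ground truth)
    if cfg.planted_edge_count == 0:
        truth = NetworkMask(edges=np.empty((0, 2), dtype=int), n_nodes=n)
    elif cfg.planted_topology == "uniform":
        truth = NetworkMask(edges=_uniform_edges(rng_mask, n, cfg.planted_edge_count), n_nodes=n)
    else:
        truth = plant_connected_network(
            n, cfg.planted_edge_count, seed=int(rng_mask.integers(2**31 - 1))
        )
    mask_idx = truth.edge_indices()

    # base architecture shared by the whole cohort
    lam_base = rng_base.normal(0.0, np.sqrt(cfg.factor_strength / cfg.n_factors), (n, cfg.n_factors))

    # design
    codes = np.repeat(np.arange(len(cfg.group_sizes)), cfg.group_sizes)
    n_subj = codes.shape[0]
    subject_ids = [f"sub{k:04d}" for k in range(n_subj)]
    covariates = _draw_covariates(rng_cov, codes, cfg)
    design = CohortDesign(
        subject_ids=subject_ids,
        group=np.asarray(cfg.group_names, dtype=object)[codes],
        group_levels=cfg.group_names,
        covariates=covariates,
    )

    calib = _calibrate(cfg, lam_base, mask_idx, rng_pilot)
    sigma_b = calib["sigma_b"]
    shift_map = calib.get("shift_per_effect", {})
    deltas = np.array(
        [
            float(np.sign(e)) * shift_map.get(abs(float(e)), 0.0) if e != 0 else 0.0
            for e in cfg.effect_sizes
        ]
    )

    degenerate_replicates = cfg.shared_variance_fraction >= 1.0 and cfg.noise_sd == 0.0
    paradigm_ids = [f"par{k}" for k in range(cfg.n_paradigms)]
    w0 = cfg.base_global_weight

    scans: dict[tuple[str, str], ScanTimeSeries] = {}
    strength = np.empty(n_subj)
    for i, sid in enumerate(subject_ids):
        w = w0 * np.exp(
            _global_log_weight(_global_draw(rng_subj), covariates.iloc[i], cfg)
        )
        a = rng_subj.normal(0.0, cfg.subject_factor_sd, (n, cfg.n_factors))
        c = rng_subj.normal(0.0, cfg.network_strength_sd)
        shift = deltas[codes[i]] + c
        strength[i] = shift
        lam_subj = np.column_stack([np.full(n, w), lam_base + a])

        # paradigm availability (>= 2 kept)
        keep = np.ones(cfg.n_paradigms, dtype=bool)
        if cfg.paradigm_dropout > 0:
            keep = rng_subj.random(cfg.n_paradigms) >= cfg.paradigm_dropout
            if keep.sum() < 2:
                keep[:] = False
                keep[:2] = True

        shared_draws: tuple | None = None
        for k, pid in enumerate(paradigm_ids):
            t = cfg.timepoints_per_paradigm[k]
            if degenerate_replicates:
                if shared_draws is None:
                    shared_draws = (
                        rng_subj.standard_normal((t, n)),
                        _nuisance_block(rng_subj, t, cfg, covariates.iloc[i]["mean_fd"]),
                        rng_subj.normal(0.0, cfg.nuisance_amplitude, (cfg.n_nuisance, n)),
                    )
                white, q, gamma = shared_draws
                lam_k = lam_subj
            else:
                b = rng_subj.normal(0.0, sigma_b, (n, cfg.n_factors + 1)) if sigma_b > 0 else None
                lam_k = lam_subj + b if b is not None else lam_subj
                white = rng_subj.standard_normal((t, n))
                q = _nuisance_block(rng_subj, t, cfg, covariates.iloc[i]["mean_fd"])
                gamma = rng_subj.normal(0.0, cfg.nuisance_amplitude, (cfg.n_nuisance, n))
            if not keep[k]:
                continue
            z = _edge_z_from_loadings(lam_k)
            if mask_idx.size:
                z[mask_idx] += shift
            r_target = devectorize_edges(np.tanh(z))
            r_target = _ensure_psd_correlation(r_target)
            chol = np.linalg.cholesky(r_target + 1e-10 * np.eye(n))
            x = white @ chol.T + q @ gamma
            if cfg.noise_sd > 0:
                x = x + cfg.noise_sd * rng_subj.standard_normal((t, n))
            scans[(sid, pid)] = ScanTimeSeries(
                subject_id=sid,
                paradigm_id=pid,
                data=x.T,
                sampling_interval=cfg.sampling_interval,
                nuisance=q,
                paradigm_class=cfg.paradigm_classes[k],
            )

    phenotypes = _draw_phenotypes(rng_pheno, strength, codes, cfg, subject_ids)
    return SyntheticCohort(
        scans=scans,
        subject_ids=subject_ids,
        paradigm_ids=paradigm_ids,
        design=design,
        phenotypes=phenotypes,
        truth=truth,
        true_effect_sizes=tuple(cfg.effect_sizes),
        config=cfg,
        calibration=calib,
    )


def _nuisance_block(
    rng: np.random.Generator, t: int, cfg: SynthConfig, mean_fd: float
) -> np.ndarray:
    """Motion-like AR(1) regressors (scaled by the subject's motion level) + tissue signals."""
    q = np.column_stack([_ar1(rng, t) for _ in range(cfg.n_nuisance)])
    n_motion = min(6, cfg.n_nuisance)
    q[:, :n_motion] *= mean_fd / 0.10
    return q


def _draw_phenotypes(
    rng: np.random.Generator,
    strength: np.ndarray,
    codes: np.ndarray,
    cfg: SynthConfig,
    subject_ids: list[str],
) -> PhenotypeTable:
    n = strength.shape[0]
    sd = strength.std()
    nu = (strength - strength.mean()) / sd if sd > 1e-12 else np.zeros(n)
    coup = cfg.phenotype_coupling
    disorganization = 6.0 + 2.0 * (coup * nu + rng.standard_normal(n))
    positive = 8.0 + 2.0 * (0.4 * coup * nu + rng.standard_normal(n))
    follow_up = rng.uniform(12.0, 36.0, n)
    months = np.full(n, np.nan)
    top = codes == codes.max()
    # conversion speed varies among converters with *their* network strength,
    # so the coupling is standardized within the converter group
    s_top = strength[top]
    sd_top = s_top.std()
    nu_top = (s_top - s_top.mean()) / sd_top if sd_top > 1e-12 else np.zeros(s_top.size)
    latent = -coup * nu_top + rng.standard_normal(int(top.sum()))
    months[top] = 36.0 / (1.0 + np.exp(-0.8 * latent))
    follow_up[top] = np.maximum(follow_up[top], months[top] + 1.0)
    return PhenotypeTable(
        table=pd.DataFrame(
            {
                "subject_id": subject_ids,
                "positive": positive,
                "disorganization": disorganization,
                "months_to_conversion": months,
                "follow_up_months": follow_up,
            }
        )
    )
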