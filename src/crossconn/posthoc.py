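"""Post-hoc battery applied to a discovered network mask.

Everything downstream of network discovery lives here: per-subject network
means, covariate-adjusted group tests (omnibus ANCOVA and ordered-group
linear trend), pairwise post-hoc t-tests, Cohen's d, Spearman/Pearson
phenotype correlations, the random-edge specificity permutation, and the
ROC/AUC transfer test with its permutation null. Subset analyses (matched
subsamples, minimum follow-up) are plain re-runs on a filtered design; no
special code path exists for them.

All resampling operations are reproducible given a seed and use the +1
permutation correction, so a permutation p is never exactly zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import ConnectivityMatrix, vectorize_edges
from .design import CohortDesign, PhenotypeTable, build_design_matrices
from .exceptions import ParameterError
from .nbs import NetworkMask, _fstats_from_bases, _orthonormal_basis, edgewise_glm
from .trait import TraitMatrix

__all__ = [
    "StatReport",
    "PhenotypeTable",
    "network_mean",
    "ancova_group_test",
    "paradigm_wise_group_tests",
    "correlate",
    "cohens_d",
    "edge_specificity_test",
    "roc_transfer",
    "pairwise_posthoc",
]


@dataclass
class StatReport:
    """One reported statistic with its provenance."""

    name: str
    value: float
    p: float
    n: int
    p_corrected: float | None = None
    correction: str | None = None
    groups: tuple[str, ...] | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for q in (self.p, self.p_corrected):
            if q is not None and not (0 <= q <= 1 or np.isnan(q)):
                raise ParameterError(f"p-value {q} outside [0, 1]")


def bonferroni(p: float, n_tests: int) -> float:
    """Family-wise corrected p: min(1, n_tests * p)."""
    return float(min(1.0, n_tests * p))


# ---------------------------------------------------------------------------
# network mean
# ---------------------------------------------------------------------------

def network_mean(
    values: np.ndarray | TraitMatrix | ConnectivityMatrix,
    mask: NetworkMask,
) -> np.ndarray | float:
    """Arithmetic mean over the mask's edges.

    ``values`` may be a single edge vector, a ``(n_subjects, E)`` matrix
    (returns one scalar per row), a :class:`TraitMatrix` or a
    :class:`ConnectivityMatrix`.
    """
    if mask.size == 0:
        raise ParameterError("empty network mask")
    if isinstance(values, TraitMatrix):
        vec = values.pc_scores
    elif isinstance(values, ConnectivityMatrix):
        vec = vectorize_edges(values)
    else:
        vec = np.asarray(values, dtype=float)
    idx = mask.edge_indices()
    if vec.ndim == 1:
        if idx.max() >= vec.shape[0]:
            raise ParameterError("mask edges outside the edge vector")
        return float(vec[idx].mean())
    if idx.max() >= vec.shape[1]:
        raise ParameterError("mask edges outside the edge matrix")
    return vec[:, idx].mean(axis=1)


# ---------------------------------------------------------------------------
# covariate-adjusted group tests
# ---------------------------------------------------------------------------

def ancova_group_test(
    y: np.ndarray,
    design: CohortDesign,
    contrast: str = "omnibus",
) -> StatReport:
    """Group test on a per-subject scalar after covariate adjustment.

    ``contrast="omnibus"`` is the G-level ANCOVA F (one-way ANOVA when the
    design has no covariates); ``contrast="linear_trend"`` is the two-sided
    t-test on an ordered-group linear score (codes 0..G-1, centered) after
    covariates, testing for a graded monotone relationship across the risk
    ordering.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != design.n_subjects:
        raise ParameterError("y length does not match design")
    if contrast == "omnibus":
        f, p = edgewise_glm(y[:, None], design)
        return StatReport(
            name="ancova_omnibus_F",
            value=float(f[0]),
            p=float(p[0]),
            n=design.n_subjects,
            groups=design.group_levels,
        )
    if contrast != "linear_trend":
        raise ParameterError("contrast must be 'omnibus' or 'linear_trend'")
    _, x_red, *_ = build_design_matrices(design)
    score = design.group_codes().astype(float)
    score -= score.mean()
    x = np.column_stack([x_red, score])
    n, p_cols = x.shape
    df = n - p_cols
    if df < 1:
        raise ParameterError("no residual degrees of freedom for the trend test")
    xtx_inv = np.linalg.pinv(x.T @ x)
    beta = xtx_inv @ (x.T @ y)
    resid = y - x @ beta
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(max(sigma2 * xtx_inv[-1, -1], 0.0)))
    if se == 0:
        tval, pval = 0.0, 1.0
    else:
        tval = float(beta[-1] / se)
        pval = float(2 * stats.t.sf(abs(tval), df))
    return StatReport(
        name="ancova_linear_trend_t",
        value=tval,
        p=pval,
        n=n,
        groups=design.group_levels,
        extra={"slope": float(beta[-1]), "df": df},
    )


def paradigm_wise_group_tests(
    paradigm_means: np.ndarray,
    design: CohortDesign,
    paradigm_ids: tuple[str, ...] | None = None,
    contrast: str = "omnibus",
) -> list[StatReport]:
    """Per-paradigm ANCOVA on network means, Bonferroni over paradigms.

    ``paradigm_means`` is ``(n_subjects, K)``: the network mean extracted from
    each paradigm's original connectivity matrix.
    """
    m = np.atleast_2d(np.asarray(paradigm_means, dtype=float))
    if m.shape[0] != design.n_subjects:
        raise ParameterError("paradigm_means must be (n_subjects, K)")
    k = m.shape[1]
    ids = paradigm_ids or tuple(f"p{i}" for i in range(k))
    reports = []
    for j in range(k):
        r = ancova_group_test(m[:, j], design, contrast=contrast)
        r.name = f"network_mean[{ids[j]}]"
        r.p_corrected = bonferroni(r.p, k)
        r.correction = f"bonferroni({k})"
        reports.append(r)
    return reports


# ---------------------------------------------------------------------------
# correlations and effect sizes
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / np.sqrt(np.sum((rx - rx.mean()) ** 2))
    ry = ry - ry.mean()
    ry /= np.sqrt(np.sum(ry**2))
    n = len(rx)
    count = 0
    total = 0
    perm_iter = itertools.permutations(range(n))
    chunk: list[tuple] = []
    for perm in perm_iter:
        chunk.append(perm)
        if len(chunk) == 40320:
            pm = np.asarray(chunk)
            rhos = ry[pm] @ rx
            count += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
            total += pm.shape[0]
            chunk = []
    if chunk:
        pm = np.asarray(chunk)
        rhos = ry[pm] @ rx
        count += int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        total += pm.shape[0]
    return count / total


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "spearman",
    fwe_n: int | None = None,
    name: str = "correlation",
) -> StatReport:
    """Spearman (average ranks on ties) or Pearson correlation with two-sided p.

    For Spearman with n <= 10 the p-value is an exact permutation p; above
    that, the usual t approximation. ``fwe_n`` applies a Bonferroni correction
    for a family of that many correlations.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.shape[0]
    if n < 4:
        raise ParameterError("need >= 4 paired complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("constant vector; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
        if n <= 10:
            p = _spearman_exact_p(x, y, r)
    else:
        raise ParameterError("method must be 'spearman' or 'pearson'")
    report = StatReport(name=f"{name}[{method}]", value=float(r), p=float(p), n=n)
    if fwe_n is not None:
        report.p_corrected = bonferroni(report.p, fwe_n)
        report.correction = f"bonferroni({fwe_n})"
    return report


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference (mean(a) - mean(b)) / pooled SD (n-2 denominator)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = a.shape[0], b.shape[0]
    if na + nb < 3 or min(na, nb) < 1:
        raise ParameterError("need at least 3 observations across the two groups")
    ss = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
    pooled = np.sqrt(ss / (na + nb - 2))
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


# ---------------------------------------------------------------------------
# specificity permutation
# ---------------------------------------------------------------------------

def edge_specificity_test(
    trait_edges: np.ndarray,
    design: CohortDesign,
    mask: NetworkMask,
    n_draws: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> StatReport:
    """Is the observed network's group effect specific, or whole-brain generic?

    Draws ``n_draws`` uniformly random edge sets of the same size as ``mask``
    (from all edges, the observed network not excluded), computes the
    covariate-adjusted omnibus p on each set's mean, and reports (a) the
    observed network's p, (b) whether any random draw survives Bonferroni
    correction over the draws, (c) the observed network's rank among the
    draws (1 = smaller p than every draw).
    """
    y = np.asarray(trait_edges, dtype=float)
    n, e = y.shape
    m = mask.size
    if m == 0 or m > e:
        raise ParameterError("mask size must be in [1, total edges]")
    rng = np.random.default_rng(seed)
    x_full, x_red, *_ = build_design_matrices(design)
    qf = _orthonormal_basis(x_full)
    qr = _orthonormal_basis(x_red)
    df1, df2 = qf.shape[1] - qr.shape[1], n - qf.shape[1]

    obs_mean = y[:, mask.edge_indices()].mean(axis=1)
    f_obs = _fstats_from_bases(obs_mean[:, None], qf, qr, df1, df2)[0]
    p_obs = float(stats.f.sf(f_obs, df1, df2))

    draw_means = np.empty((n, n_draws))
    for d in range(n_draws):
        idx = rng.choice(e, size=m, replace=False)
        draw_means[:, d] = y[:, idx].mean(axis=1)
    f_draws = _fstats_from_bases(draw_means, qf, qr, df1, df2)
    p_draws = stats.f.sf(f_draws, df1, df2)

    rank = int(1 + np.sum(p_draws < p_obs))
    return StatReport(
        name="edge_specificity",
        value=float(rank),
        p=p_obs,
        n=n,
        p_corrected=bonferroni(p_obs, n_draws),
        correction=f"bonferroni({n_draws})",
        seed=seed,
        extra={
            "n_draws": n_draws,
            "rank_among_draws": rank,
            "any_draw_survives_bonferroni": bool(np.any(p_draws * n_draws <= alpha)),
            "observed_survives_bonferroni": bool(p_obs * n_draws <= alpha),
            "draw_p_values": p_draws,
        },
    )


# ---------------------------------------------------------------------------
# ROC transfer
# ---------------------------------------------------------------------------

def _auc_from_ranks(ranks: np.ndarray, case: np.ndarray) -> float:
    n1 = int(case.sum())
    n0 = case.size - n1
    return float((ranks[case].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_transfer(
    scores: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> StatReport:
    """AUC of network scores for case/control discrimination + permutation p.

    AUC is the rank statistic (Mann-Whitney; ties contribute 1/2). The
    one-sided permutation p is the +1-corrected fraction of label shuffles
    with AUC >= observed.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    case = np.asarray(labels).astype(bool).ravel()
    if scores.shape != case.shape:
        raise ParameterError("scores and labels must align")
    n1 = int(case.sum())
    n0 = case.size - n1
    if n1 == 0 or n0 == 0:
        raise ParameterError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = _auc_from_ranks(ranks, case)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm_case = np.zeros(case.size, dtype=bool)
        perm_case[rng.choice(case.size, size=n1, replace=False)] = True
        if _auc_from_ranks(ranks, perm_case) >= auc - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return StatReport(
        name="roc_auc",
        value=auc,
        p=float(p),
        n=case.size,
        seed=seed,
        extra={"n_cases": n1, "n_controls": n0, "n_permutations": n_permutations},
    )


# ---------------------------------------------------------------------------
# pairwise post-hoc tests
# ---------------------------------------------------------------------------

def pairwise_posthoc(
    y: np.ndarray,
    design: CohortDesign,
    correction: str = "bonferroni",
) -> list[StatReport]:
    """Covariate-adjusted pairwise group t-tests within the full model.

    All groups are fit jointly (shared covariate adjustment and shared error
    variance); each pair is a contrast between group coefficients, with
    Bonferroni correction over the G(G-1)/2 pairs.
    """
    if correction != "bonferroni":
        raise ParameterError("only bonferroni correction is implemented")
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != design.n_subjects:
        raise ParameterError("y length does not match design")
    x_full, _, names, _ = build_design_matrices(design)
    n, p_cols = x_full.shape
    df = n - p_cols
    xtx_inv = np.linalg.pinv(x_full.T @ x_full)
    beta = xtx_inv @ (x_full.T @ y)
    resid = y - x_full @ beta
    sigma2 = float(resid @ resid) / df
    # group coefficient positions: reference level has implicit coefficient 0
    g = design.n_groups
    coef_pos = {0: None}
    offset = p_cols - (g - 1)
    for k in range(1, g):
        coef_pos[k] = offset + (k - 1)
    pairs = list(itertools.combinations(range(g), 2))
    reports = []
    for a, b in pairs:
        # contrast: later (higher-risk) group minus earlier group
        c = np.zeros(p_cols)
        if coef_pos[b] is not None:
            c[coef_pos[b]] = 1.0
        if coef_pos[a] is not None:
            c[coef_pos[a]] -= 1.0
        est = float(c @ beta)
        se = float(np.sqrt(max(sigma2 * (c @ xtx_inv @ c), 0.0)))
        if se == 0:
            tval, pval = 0.0, 1.0
        else:
            tval = est / se
            pval = float(2 * stats.t.sf(abs(tval), df))
        la, lb = design.group_levels[a], design.group_levels[b]
        reports.append(
            StatReport(
                name=f"pairwise_t[{lb} vs {la}]",
                value=float(tval),
                p=pval,
                n=n,
                p_corrected=bonferroni(pval, len(pairs)),
                correction=f"bonferroni({len(pairs)})",
                groups=(la, lb),
                extra={"difference": est, "df": df},
            )
        )
    return reports
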