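"""Network-based statistic (NBS) on edge-wise trait matrices.

The procedure: (1) at every edge, an F-test of the group factor after
covariate adjustment (extra sum of squares between the covariate-only and the
covariate+group model); (2) edges whose F exceeds a primary threshold are
assembled into connected components over the shared node set; (3) the
family-wise-error-corrected p-value of each observed component is the
fraction of permutations whose *maximum* component statistic matches or
exceeds it. Because group labels are not exchangeable in the presence of
covariates, permutation follows the Freedman-Lane scheme: residuals of the
reduced (covariate-only) model are row-permuted and the full model is refit.

Component statistic: "extent" (edge count) by default, "intensity"
(sum of F - F_critical over the component's edges) optionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components as _cc

from .connectivity import edge_index, edge_pairs, n_edges
from .design import CohortDesign, build_design_matrices
from .exceptions import ParameterError

__all__ = ["NetworkMask", "NBSResult", "edgewise_glm", "threshold_and_components", "nbs_test"]


# ---------------------------------------------------------------------------
# NetworkMask
# ---------------------------------------------------------------------------

@dataclass
class NetworkMask:
    """A set of undirected edges (i < j) over the atlas nodes."""

    edges: np.ndarray  # (m, 2) int, i < j
    n_nodes: int
    system_labels: dict[int, str] | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if e.size:
            lo = np.minimum(e[:, 0], e[:, 1])
            hi = np.maximum(e[:, 0], e[:, 1])
            e = np.stack([lo, hi], axis=1)
            if np.any(lo == hi) or lo.min() < 0 or hi.max() >= self.n_nodes:
                raise ParameterError("mask edges must be valid node pairs i < j")
            # canonical order, distinct
            order = np.lexsort((e[:, 1], e[:, 0]))
            e = e[order]
            if np.any(np.all(e[1:] == e[:-1], axis=1)):
                raise ParameterError("mask edges must be distinct")
        self.edges = e

    @property
    def size(self) -> int:
        """Number of edges ("extent")."""
        return self.edges.shape[0]

    @property
    def node_ids(self) -> np.ndarray:
        return np.unique(self.edges)

    def edge_indices(self) -> np.ndarray:
        """Positions of the mask edges in the canonical edge vector."""
        if self.size == 0:
            return np.empty(0, dtype=np.int64)
        return edge_index(self.edges[:, 0], self.edges[:, 1], self.n_nodes)

    def jaccard(self, other: "NetworkMask") -> float:
        """Edge-set Jaccard similarity."""
        a = set(map(tuple, self.edges))
        b = set(map(tuple, other.edges))
        if not a and not b:
            return 1.0
        return len(a & b) / len(a | b)

    def union(self, other: "NetworkMask") -> "NetworkMask":
        if self.n_nodes != other.n_nodes:
            raise ParameterError("cannot combine masks over different atlases")
        return NetworkMask(
            edges=np.vstack([self.edges, other.edges]) if self.size or other.size
            else np.empty((0, 2), dtype=int),
            n_nodes=self.n_nodes,
        )


# ---------------------------------------------------------------------------
# edge-wise covariate-adjusted group F-test
# ---------------------------------------------------------------------------

def _orthonormal_basis(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def _fstats_from_bases(
    y: np.ndarray,
    q_full: np.ndarray,
    q_red: np.ndarray,
    df1: int,
    df2: int,
) -> np.ndarray:
    """Vectorized extra-sum-of-squares F over the columns of ``y``."""
    ssq = np.einsum("ij,ij->j", y, y)
    fit_f = q_full.T @ y
    fit_r = q_red.T @ y
    rss_f = ssq - np.einsum("ij,ij->j", fit_f, fit_f)
    rss_r = ssq - np.einsum("ij,ij->j", fit_r, fit_r)
    num = np.maximum(rss_r - rss_f, 0.0) / df1
    den = np.maximum(rss_f, 0.0) / df2
    scale = np.maximum(ssq, 1.0)
    f = np.zeros_like(num)
    degenerate = den <= 1e-14 * scale
    ok = ~degenerate
    f[ok] = num[ok] / den[ok]
    # den ~ 0: perfect full-model fit; F is 0 if the group adds nothing, inf otherwise
    f[degenerate & (num > 1e-14 * scale)] = np.inf
    return f


def edgewise_glm(
    trait_edges: np.ndarray,
    design: CohortDesign,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge group F (after covariate adjustment) and parametric p.

    Parameters
    ----------
    trait_edges:
        ``(n_subjects, n_edges)`` matrix of edge scores (cross-paradigm PC
        scores, or any per-subject edge values).
    design:
        Cohort design; the group factor is tested, covariates are adjusted for.
    """
    y = np.atleast_2d(np.asarray(trait_edges, dtype=float))
    if y.ndim != 2 or y.shape[0] != design.n_subjects:
        raise ParameterError("trait_edges must be (n_subjects, n_edges)")
    x_full, x_red, *_ = build_design_matrices(design)
    qf = _orthonormal_basis(x_full)
    qr = _orthonormal_basis(x_red)
    df1 = qf.shape[1] - qr.shape[1]
    df2 = y.shape[0] - qf.shape[1]
    if df1 < 1 or df2 < 1:
        raise ParameterError("design leaves no degrees of freedom for the group test")
    f = _fstats_from_bases(y, qf, qr, df1, df2)
    p = stats.f.sf(f, df1, df2)
    return f, p


# ---------------------------------------------------------------------------
# suprathreshold components
# ---------------------------------------------------------------------------

def _component_labels(iu: np.ndarray, ju: np.ndarray, n_nodes: int) -> np.ndarray:
    """Connected-component label per edge for the graph (iu[k], ju[k])."""
    nodes = np.unique(np.concatenate([iu, ju]))
    remap = np.empty(n_nodes, dtype=np.int64)
    remap[nodes] = np.arange(nodes.size)
    a, b = remap[iu], remap[ju]
    g = sparse.csr_matrix(
        (np.ones(a.size), (a, b)), shape=(nodes.size, nodes.size)
    )
    _, node_labels = _cc(g, directed=False)
    return node_labels[a]


def threshold_and_components(
    edge_stats: np.ndarray,
    f_critical: float,
    n_nodes: int,
) -> list[NetworkMask]:
    """Connected components of the suprathreshold graph, largest first.

    ``edge_stats`` is the canonical edge vector of F statistics; an edge is
    suprathreshold when its statistic strictly exceeds ``f_critical``. Returns
    one :class:`NetworkMask` per component (edge sets are disjoint; each
    component is connected through shared nodes). Empty suprathreshold set
    gives an empty list.
    """
    edge_stats = np.asarray(edge_stats, dtype=float)
    if edge_stats.shape[0] != n_edges(n_nodes):
        raise ParameterError("edge_stats length does not match n_nodes")
    supra = np.flatnonzero(edge_stats > f_critical)
    if supra.size == 0:
        return []
    iu_all, ju_all = edge_pairs(n_nodes)
    iu, ju = iu_all[supra], ju_all[supra]
    labels = _component_labels(iu, ju, n_nodes)
    comps = []
    for lab in np.unique(labels):
        sel = labels == lab
        comps.append(NetworkMask(edges=np.stack([iu[sel], ju[sel]], axis=1), n_nodes=n_nodes))
    comps.sort(key=lambda c: c.size, reverse=True)
    return comps


def _max_component_stat(
    fvals: np.ndarray,
    f_critical: float,
    iu_all: np.ndarray,
    ju_all: np.ndarray,
    n_nodes: int,
    statistic: str,
) -> float:
    supra = np.flatnonzero(fvals > f_critical)
    if supra.size == 0:
        return 0.0
    if supra.size == 1:
        return 1.0 if statistic == "extent" else float(fvals[supra[0]] - f_critical)
    iu, ju = iu_all[supra], ju_all[supra]
    labels = _component_labels(iu, ju, n_nodes)
    if statistic == "extent":
        return float(np.bincount(labels).max())
    mass = np.zeros(labels.max() + 1)
    np.add.at(mass, labels, fvals[supra] - f_critical)
    return float(mass.max())


# ---------------------------------------------------------------------------
# full NBS with Freedman-Lane permutation FWE
# ---------------------------------------------------------------------------

@dataclass
class NBSResult:
    """Outcome of one NBS run."""

    f_stats: np.ndarray
    p_values: np.ndarray
    primary_threshold_p: float
    f_critical: float
    components: list[NetworkMask]
    component_stats: np.ndarray
    observed_max_stat: float
    null_max_stats: np.ndarray
    fwe_p: np.ndarray
    winning_mask: NetworkMask
    n_permutations: int
    seed: int | None
    alpha: float
    statistic: str
    n_nodes: int

    @property
    def min_fwe_p(self) -> float:
        """FWE p of the strongest component; NaN when nothing survived the threshold."""
        return float(self.fwe_p.min()) if self.fwe_p.size else float("nan")


def nbs_test(
    trait_edges: np.ndarray,
    design: CohortDesign,
    primary_threshold_p: float = 0.001,
    n_permutations: int = 1000,
    seed: int | None = None,
    statistic: str = "extent",
    alpha: float = 0.05,
) -> NBSResult:
    """Connectome-wide NBS: edge-wise ANCOVA F, components, permutation FWE.

    The null distribution of the maximum component statistic is obtained by
    Freedman-Lane permutation: residuals of the reduced (covariate-only)
    model are row-permuted and the identical threshold/component procedure is
    applied. Per-component FWE p uses the +1 correction,
    ``(1 + #{null >= observed}) / (1 + n_permutations)``, and is therefore
    never exactly zero. ``winning_mask`` is the union of components with
    ``fwe_p <= alpha`` (empty when none survive). Fully reproducible given
    ``seed``.
    """
    if n_permutations < 100:
        raise ParameterError("n_permutations must be >= 100")
    if not 0 < primary_threshold_p < 1:
        raise ParameterError("primary_threshold_p must be in (0, 1)")
    if statistic not in ("extent", "intensity"):
        raise ParameterError("statistic must be 'extent' or 'intensity'")
    y = np.asarray(trait_edges, dtype=float)
    n, e = y.shape
    nn = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n_edges(nn) != e:
        raise ParameterError("trait_edges column count is not N(N-1)/2")

    x_full, x_red, *_ = build_design_matrices(design)
    qf = _orthonormal_basis(x_full)
    qr = _orthonormal_basis(x_red)
    df1 = qf.shape[1] - qr.shape[1]
    df2 = n - qf.shape[1]
    f_crit = float(stats.f.isf(primary_threshold_p, df1, df2))

    f_obs = _fstats_from_bases(y, qf, qr, df1, df2)
    p_obs = stats.f.sf(f_obs, df1, df2)
    comps = threshold_and_components(f_obs, f_crit, nn)
    iu_all, ju_all = edge_pairs(nn)
    if statistic == "extent":
        comp_stats = np.array([c.size for c in comps], dtype=float)
    else:
        comp_stats = np.array(
            [float(np.sum(f_obs[c.edge_indices()] - f_crit)) for c in comps]
        )

    # Freedman-Lane: permute reduced-model residuals, refit the full model.
    resid = y - qr @ (qr.T @ y)
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        f_b = _fstats_from_bases(resid[perm], qf, qr, df1, df2)
        null_max[b] = _max_component_stat(f_b, f_crit, iu_all, ju_all, nn, statistic)

    if comp_stats.size:
        fwe = (1 + (null_max[None, :] >= comp_stats[:, None]).sum(axis=1)) / (
            1 + n_permutations
        )
    else:
        fwe = np.empty(0)
    winners = [c for c, p in zip(comps, fwe) if p <= alpha]
    winning = NetworkMask(edges=np.empty((0, 2), dtype=int), n_nodes=nn)
    for w in winners:
        winning = winning.union(w)

    return NBSResult(
        f_stats=f_obs,
        p_values=p_obs,
        primary_threshold_p=primary_threshold_p,
        f_critical=f_crit,
        components=comps,
        component_stats=comp_stats,
        observed_max_stat=float(comp_stats.max()) if comp_stats.size else 0.0,
        null_max_stats=null_max,
        fwe_p=fwe,
        winning_mask=winning,
        n_permutations=n_permutations,
        seed=seed,
        alpha=alpha,
        statistic=statistic,
        n_nodes=nn,
    )
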