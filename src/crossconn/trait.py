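"""Per-subject PCA across paradigm connectivity matrices ("cross-paradigm connectivity").

For one subject the edge vectors of the K available paradigm connectivity
matrices are arranged as an E x K matrix (edges are the observations,
paradigms the variables). Columns are mean-centered (covariance PCA, no
scaling) and the principal axes come from the eigendecomposition of the K x K
covariance. The first-PC score per edge is the subject's state-independent
connectivity trait; the per-paradigm loadings say how much each paradigm
contributes to it, and the leading variance-explained fraction quantifies how
paradigm-independent the subject's connectome is.

Sign convention: the component is oriented so that the correlation between
the PC scores and the across-paradigm mean edge value is non-negative, making
"higher score = stronger shared connectivity" interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import CohortDesign
from .exceptions import ParameterError

__all__ = ["TraitMatrix", "fit_cross_paradigm_pca", "summarize_pca_by_group", "stack_traits"]


@dataclass
class TraitMatrix:
    """First-PC edge scores of one subject across paradigms."""

    subject_id: str
    pc_scores: np.ndarray            # (E,) first-PC score per edge, mean 0
    loadings: np.ndarray             # (K,) unit-norm paradigm coefficients
    variance_explained: np.ndarray   # (K,) fractions, descending, sum 1
    n_paradigms_used: int
    paradigm_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pc_scores = np.asarray(self.pc_scores, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.variance_explained = np.asarray(self.variance_explained, dtype=float)
        if abs(self.variance_explained.sum() - 1.0) > 1e-9:
            raise ParameterError("variance_explained must sum to 1")
        if self.variance_explained[0] < self.variance_explained.max() - 1e-12:
            raise ParameterError("variance_explained must lead with the maximum")
        if abs(np.linalg.norm(self.loadings) - 1.0) > 1e-9:
            raise ParameterError("loadings must have unit Euclidean norm")


def fit_cross_paradigm_pca(
    edge_vectors: np.ndarray | list[np.ndarray],
    subject_id: str = "",
    paradigm_ids: tuple[str, ...] = (),
    standardize: bool = False,
) -> TraitMatrix:
    """Covariance PCA over one subject's paradigm edge vectors.

    Parameters
    ----------
    edge_vectors:
        ``(E, K)`` array or list of K canonical edge vectors, one per
        available paradigm (K >= 2).
    standardize:
        If True, columns are scaled to unit variance before the
        eigendecomposition (correlation PCA). Default is covariance PCA,
        which keeps paradigms' amplitude differences meaningful.
    """
    if isinstance(edge_vectors, (list, tuple)):
        m = np.column_stack([np.asarray(v, dtype=float) for v in edge_vectors])
    else:
        m = np.asarray(edge_vectors, dtype=float)
    if m.ndim != 2:
        raise ParameterError("edge_vectors must be 2-D (edges x paradigms)")
    e, k = m.shape
    if k < 2:
        raise ParameterError("need >= 2 paradigms for cross-paradigm PCA")
    if e < 2:
        raise ParameterError("need >= 2 edges")
    centered = m - m.mean(axis=0, keepdims=True)
    if standardize:
        sd = centered.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ParameterError("zero-variance paradigm column; cannot standardize")
        centered = centered / sd
    cov = centered.T @ centered / (e - 1)
    total = np.trace(cov)
    if total <= 0:
        raise ParameterError("zero total variance across paradigms")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    loadings = evecs[:, 0]
    loadings = loadings / np.linalg.norm(loadings)
    scores = centered @ loadings
    # orient: non-negative correlation with the across-paradigm mean edge value
    mean_edge = m.mean(axis=1)
    orient = scores @ (mean_edge - mean_edge.mean())
    if orient < 0:
        loadings = -loadings
        scores = -scores
    return TraitMatrix(
        subject_id=subject_id,
        pc_scores=scores,
        loadings=loadings,
        variance_explained=evals / evals.sum(),
        n_paradigms_used=k,
        paradigm_ids=tuple(paradigm_ids) or tuple(f"p{i}" for i in range(k)),
    )


def stack_traits(traits: list[TraitMatrix]) -> np.ndarray:
    """Stack per-subject PC scores into a (n_subjects, E) matrix."""
    if not traits:
        raise ParameterError("no trait matrices given")
    return np.vstack([t.pc_scores for t in traits])


def summarize_pca_by_group(
    traits: list[TraitMatrix],
    design: CohortDesign,
) -> dict:
    """Group means + one-way ANOVA of variance explained and paradigm loadings.

    Returns a dict with per-group means of the leading variance-explained
    fraction and of each paradigm's loading, along with unadjusted one-way
    ANOVA reports (the same GLM engine as the edge-wise test, with no
    covariates), mirroring the question "do the groups share the same
    cross-paradigm structure?".
    """
    from .posthoc import ancova_group_test  # late import avoids a cycle

    if len(traits) != design.n_subjects:
        raise ParameterError("one TraitMatrix per design row required")
    kmax = max(t.n_paradigms_used for t in traits)
    if any(t.n_paradigms_used != kmax for t in traits):
        raise ParameterError("group summaries require a common paradigm count")
    bare = CohortDesign(
        subject_ids=design.subject_ids,
        group=design.group,
        group_levels=design.group_levels,
        covariates=None,
    )
    ve1 = np.array([t.variance_explained[0] for t in traits])
    loadings = np.vstack([t.loadings for t in traits])
    codes = bare.group_codes()
    out: dict = {
        "group_levels": design.group_levels,
        "variance_explained_mean": {
            g: float(ve1[codes == k].mean()) for k, g in enumerate(design.group_levels)
        },
        "loadings_mean": {
            g: loadings[codes == k].mean(axis=0) for k, g in enumerate(design.group_levels)
        },
        "variance_explained_test": ancova_group_test(ve1, bare, contrast="omnibus"),
        "loading_tests": [
            ancova_group_test(loadings[:, j], bare, contrast="omnibus")
            for j in range(kmax)
        ],
    }
    return out
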