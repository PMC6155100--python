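"""Cohort metadata: group structure, covariates, phenotypes, design matrices.

The group factor is an *ordered* categorical (e.g. control < non-converter <
converter), reflecting graded psychosis risk; the ordering is what the
linear-trend contrast downstream acts on. Covariates may be numeric (age, IQ,
mean FD, antipsychotic dose) or categorical (sex, site); categorical columns
are dummy-coded with the first level as reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError

__all__ = ["CohortDesign", "PhenotypeTable", "build_design_matrices"]


@dataclass
class CohortDesign:
    """Per-subject group labels and nuisance covariates.

    Parameters
    ----------
    subject_ids:
        Unique subject identifiers, in row order.
    group:
        Group label per subject.
    group_levels:
        Ordered group levels, lowest risk first. Every level must appear with
        at least two subjects.
    covariates:
        Optional dataframe (one row per subject, same order). ``None`` or an
        empty frame means "no covariate adjustment".
    """

    subject_ids: list[str]
    group: np.ndarray
    group_levels: tuple[str, ...]
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ParameterError("subject_ids must be unique")
        self.group = np.asarray(self.group, dtype=object)
        if self.group.shape[0] != len(self.subject_ids):
            raise ParameterError("group length does not match subject_ids")
        self.group_levels = tuple(str(g) for g in self.group_levels)
        if len(self.group_levels) < 2:
            raise ParameterError("need at least 2 groups")
        unknown = set(map(str, self.group)) - set(self.group_levels)
        if unknown:
            raise ParameterError(f"group labels not in group_levels: {sorted(unknown)}")
        counts = {g: int(np.sum(self.group == g)) for g in self.group_levels}
        small = [g for g, c in counts.items() if c < 2]
        if small:
            raise ParameterError(f"every group needs >= 2 subjects; too small: {small}")
        if self.covariates is not None:
            if len(self.covariates) != len(self.subject_ids):
                raise ParameterError("covariates row count does not match subjects")
            self.covariates = self.covariates.reset_index(drop=True)
            num = self.covariates.select_dtypes(include=[np.number])
            if num.isna().any().any():
                raise ParameterError("covariates contain missing values; impute upstream")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_groups(self) -> int:
        return len(self.group_levels)

    def group_codes(self) -> np.ndarray:
        """Ordinal group codes 0..G-1 following ``group_levels`` order."""
        lut = {g: k for k, g in enumerate(self.group_levels)}
        return np.asarray([lut[str(g)] for g in self.group], dtype=int)

    def subset(self, mask: np.ndarray) -> "CohortDesign":
        """Row-subset (e.g. matched subsample, >=24-month follow-up re-runs)."""
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = np.zeros(self.n_subjects, dtype=bool)
            idx[mask] = True
            mask = idx
        levels = tuple(g for g in self.group_levels if np.any(self.group[mask] == g))
        return CohortDesign(
            subject_ids=[s for s, m in zip(self.subject_ids, mask) if m],
            group=self.group[mask],
            group_levels=levels,
            covariates=None if self.covariates is None else self.covariates.loc[mask],
        )


@dataclass
class PhenotypeTable:
    """Symptom scores and conversion timing, one row per subject.

    Columns: ``subject_id``, symptom scores (e.g. ``positive``,
    ``disorganization``), ``months_to_conversion`` (NaN except converters,
    strictly positive where present) and ``follow_up_months``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "subject_id" not in self.table.columns:
            raise ParameterError("phenotype table needs a subject_id column")
        self.table = self.table.reset_index(drop=True)
        if "months_to_conversion" in self.table.columns:
            m = self.table["months_to_conversion"]
            if (m.dropna() <= 0).any():
                raise ParameterError("months_to_conversion must be > 0 where present")

    def aligned(self, subject_ids: list[str]) -> pd.DataFrame:
        t = self.table.set_index("subject_id")
        missing = [s for s in subject_ids if s not in t.index]
        if missing:
            raise ParameterError(f"phenotypes missing for subjects: {missing[:5]}")
        return t.loc[subject_ids]


def _encode_covariates(cov: pd.DataFrame | None) -> tuple[np.ndarray, list[str]]:
    if cov is None or cov.shape[1] == 0:
        return np.empty((0 if cov is None else len(cov), 0)), []
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for col in cov.columns:
        s = cov[col]
        if pd.api.types.is_numeric_dtype(s):
            blocks.append(s.to_numpy(dtype=float)[:, None])
            names.append(str(col))
        else:
            d = pd.get_dummies(s.astype(str), prefix=str(col), drop_first=True)
            blocks.append(d.to_numpy(dtype=float))
            names.extend(d.columns.astype(str))
    return np.hstack(blocks), names


def build_design_matrices(
    design: CohortDesign,
    include_covariates: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Full and reduced GLM design matrices.

    Returns ``(X_full, X_reduced, names_full, names_reduced)`` where the
    reduced model contains intercept + covariates and the full model adds
    G-1 group indicator columns (first level is the reference). Raises
    :class:`ParameterError` naming collinear columns if the full design is
    rank deficient.
    """
    n = design.n_subjects
    parts: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    if include_covariates and design.covariates is not None:
        cmat, cnames = _encode_covariates(design.covariates)
        if cmat.shape[1]:
            parts.append(cmat)
            names.extend(cnames)
    x_reduced = np.hstack(parts)
    names_reduced = list(names)
    codes = design.group_codes()
    for g in range(1, design.n_groups):
        parts.append((codes == g).astype(float)[:, None])
        names.append(f"group[{design.group_levels[g]}]")
    x_full = np.hstack(parts)
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        from .connectivity import _independent_columns

        keep = set(_independent_columns(x_full).tolist())
        bad = [names[k] for k in range(x_full.shape[1]) if k not in keep]
        raise ParameterError(f"design matrix is rank deficient; collinear columns: {bad}")
    return x_full, x_reduced, names, names_reduced
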