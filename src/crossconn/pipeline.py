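"""End-to-end orchestration: simulate -> connect -> pca -> nbs -> posthoc.

`compute_cohort_traits` is the workhorse bridging the scan level and the
group level: it runs each scan through nuisance regression, temporal
filtering (band chosen by paradigm class) and Pearson correlation, then fits
the per-subject cross-paradigm PCA, returning both the trait (first-PC) edge
matrix and the per-paradigm connectivity edge matrices.

`run_pipeline` executes the full study on a synthetic cohort and emits the
artifacts (trait table, NBS result, post-hoc reports, provenance record).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connectivity import compute_connectivity, n_edges, regress_nuisance, temporal_filter, vectorize_edges
from .design import CohortDesign
from .exceptions import ParameterError
from .nbs import NBSResult, nbs_test
from .posthoc import (
    StatReport,
    ancova_group_test,
    cohens_d,
    correlate,
    edge_specificity_test,
    network_mean,
    pairwise_posthoc,
    paradigm_wise_group_tests,
    roc_transfer,
)
from .synthetic import SynthConfig, SyntheticCohort, generate_cohort
from .trait import TraitMatrix, fit_cross_paradigm_pca, stack_traits

__all__ = ["DEFAULT_FILTER_BANDS", "CohortTraits", "RunConfig", "compute_cohort_traits", "process_scan", "run_pipeline"]

# rest: band-pass; task: high-pass (upper edge open)
DEFAULT_FILTER_BANDS: dict[str, tuple[float, float]] = {
    "rest": (0.008, 0.1),
    "task": (0.008, float("inf")),
}


def process_scan(ts, filter_bands: dict[str, tuple[float, float]] | None = None):
    """Nuisance regression, temporal filtering, connectivity for one scan."""
    bands = filter_bands or DEFAULT_FILTER_BANDS
    low, high = bands[ts.paradigm_class]
    clean = regress_nuisance(ts)
    filtered = temporal_filter(clean, low, high)
    return compute_connectivity(filtered)


@dataclass
class CohortTraits:
    """Cohort-level result of the scan-to-trait stage."""

    subject_ids: list[str]
    traits: list[TraitMatrix]
    trait_edges: np.ndarray                      # (n_subjects, E) first-PC scores
    paradigm_edges: dict[str, np.ndarray]        # paradigm -> (n_subjects, E), NaN if missing
    n_nodes: int


def compute_cohort_traits(
    cohort: SyntheticCohort,
    filter_bands: dict[str, tuple[float, float]] | None = None,
    fisher_z: bool = False,
    standardize_pca: bool = False,
) -> CohortTraits:
    """Scan processing + per-subject cross-paradigm PCA for a whole cohort."""
    n_nodes = next(iter(cohort.scans.values())).n_nodes
    e = n_edges(n_nodes)
    n = cohort.n_subjects
    paradigm_edges = {p: np.full((n, e), np.nan) for p in cohort.paradigm_ids}
    traits: list[TraitMatrix] = []
    for i, sid in enumerate(cohort.subject_ids):
        vecs, pids = [], []
        for pid in cohort.paradigm_ids:
            key = (sid, pid)
            if key not in cohort.scans:
                continue
            cm = process_scan(cohort.scans[key], filter_bands)
            vec = vectorize_edges(cm)
            if fisher_z:
                vec = np.arctanh(np.clip(vec, -0.999999, 0.999999))
            paradigm_edges[pid][i] = vec
            vecs.append(vec)
            pids.append(pid)
        traits.append(
            fit_cross_paradigm_pca(
                np.column_stack(vecs),
                subject_id=sid,
                paradigm_ids=tuple(pids),
                standardize=standardize_pca,
            )
        )
    return CohortTraits(
        subject_ids=list(cohort.subject_ids),
        traits=traits,
        trait_edges=stack_traits(traits),
        paradigm_edges=paradigm_edges,
        n_nodes=n_nodes,
    )


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration for one full pipeline run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    filter_bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FILTER_BANDS)
    )
    fisher_z: bool = False
    standardize_pca: bool = False
    nbs_threshold_p: float = 0.001
    nbs_permutations: int = 1000
    nbs_statistic: str = "extent"
    alpha: float = 0.05
    specificity_draws: int = 1000
    roc_permutations: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.nbs_threshold_p < 1:
            raise ParameterError(f"invalid NBS threshold p {self.nbs_threshold_p}")
        if self.nbs_permutations < 100:
            raise ParameterError("nbs_permutations must be >= 100")
        if self.nbs_statistic not in ("extent", "intensity"):
            raise ParameterError("nbs_statistic must be 'extent' or 'intensity'")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must be in (0, 1)")
        for cls, (lo, hi) in self.filter_bands.items():
            if cls not in ("rest", "task") or lo < 0 or hi <= lo:
                raise ParameterError(f"invalid filter band for '{cls}': ({lo}, {hi})")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self.synth).items()
        }
        d["filter_bands"] = {k: list(v) for k, v in self.filter_bands.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .io import _config_from_dict

        d = dict(d)
        if "synth" in d:
            d["synth"] = _config_from_dict(d["synth"])
        if "filter_bands" in d:
            d["filter_bands"] = {
                k: (float(v[0]), float(v[1])) for k, v in d["filter_bands"].items()
            }
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _report_dict(r: StatReport) -> dict:
    return {
        "name": r.name,
        "value": float(r.value),
        "p": float(r.p),
        "p_corrected": None if r.p_corrected is None else float(r.p_corrected),
        "correction": r.correction,
        "n": r.n,
        "groups": None if r.groups is None else list(r.groups),
        "seed": r.seed,
    }


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute simulate -> connect -> pca -> nbs -> posthoc; return a result bundle.

    When ``out_dir`` is given, artifacts (trait table, winning-mask edge list,
    NBS JSON, post-hoc JSON, provenance record) are written there. The run is
    deterministic given the config: re-running the same config yields
    identical artifacts.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(4)]
    synth = dataclasses.replace(config.synth, seed=seeds[0])

    cohort = generate_cohort(synth)
    ct = compute_cohort_traits(
        cohort,
        filter_bands=config.filter_bands,
        fisher_z=config.fisher_z,
        standardize_pca=config.standardize_pca,
    )
    nbs_result = nbs_test(
        ct.trait_edges,
        cohort.design,
        primary_threshold_p=config.nbs_threshold_p,
        n_permutations=config.nbs_permutations,
        seed=seeds[1],
        statistic=config.nbs_statistic,
        alpha=config.alpha,
    )
    mask = nbs_result.winning_mask if nbs_result.winning_mask.size else cohort.truth
    mask_source = "nbs" if nbs_result.winning_mask.size else "planted_truth"

    bundle: dict = {
        "cohort": cohort,
        "traits": ct,
        "nbs": nbs_result,
        "mask_source": mask_source,
        "posthoc": {},
    }
    ph = bundle["posthoc"]
    if mask.size:
        scores = network_mean(ct.trait_edges, mask)
        ph["ancova_omnibus"] = ancova_group_test(scores, cohort.design, "omnibus")
        ph["linear_trend"] = ancova_group_test(scores, cohort.design, "linear_trend")
        ph["pairwise"] = pairwise_posthoc(scores, cohort.design)
        pm = np.column_stack(
            [
                np.where(
                    np.isnan(ct.paradigm_edges[p]).all(axis=1),
                    np.nan,
                    np.nanmean(
                        np.take(ct.paradigm_edges[p], mask.edge_indices(), axis=1), axis=1
                    ),
                )
                for p in cohort.paradigm_ids
            ]
        )
        if not np.isnan(pm).any():
            ph["paradigm_wise"] = paradigm_wise_group_tests(
                pm, cohort.design, tuple(cohort.paradigm_ids)
            )
        codes = cohort.design.group_codes()
        ph["cohens_d_extremes"] = cohens_d(
            scores[codes == codes.max()], scores[codes == 0]
        )
        pheno = cohort.phenotypes.aligned(cohort.subject_ids)
        ph["symptom_disorganization"] = correlate(
            scores, pheno["disorganization"].to_numpy(), "spearman", name="disorganization"
        )
        ph["symptom_positive"] = correlate(
            scores, pheno["positive"].to_numpy(), "spearman", name="positive"
        )
        conv = np.isfinite(pheno["months_to_conversion"].to_numpy())
        if conv.sum() >= 4:
            ph["months_to_conversion"] = correlate(
                scores[conv],
                pheno["months_to_conversion"].to_numpy()[conv],
                "spearman",
                name="months_to_conversion",
            )
        if cohort.design.covariates is not None and "mean_fd" in cohort.design.covariates:
            ph["head_motion"] = correlate(
                scores,
                cohort.design.covariates["mean_fd"].to_numpy(),
                "spearman",
                name="mean_fd",
            )
        ph["specificity"] = edge_specificity_test(
            ct.trait_edges,
            cohort.design,
            mask,
            n_draws=config.specificity_draws,
            seed=seeds[2],
        )
        ph["roc"] = roc_transfer(
            scores[(codes == codes.max()) | (codes == 0)],
            (codes[(codes == codes.max()) | (codes == 0)] == codes.max()),
            n_permutations=config.roc_permutations,
            seed=seeds[3],
        )
        ph["truth_jaccard"] = mask.jaccard(cohort.truth)

    if out_dir is not None:
        _write_bundle(config, bundle, mask, Path(out_dir))
    return bundle


def _write_bundle(config: RunConfig, bundle: dict, mask, out: Path) -> None:
    from .io import write_edge_list, write_nbs_result, write_trait_table

    out.mkdir(parents=True, exist_ok=True)
    write_trait_table(bundle["traits"].traits, out / "traits.tsv")
    write_nbs_result(bundle["nbs"], out / "nbs.json")
    write_edge_list(mask, out / "network_mask.tsv")
    posthoc_json = {}
    for key, val in bundle["posthoc"].items():
        if isinstance(val, StatReport):
            posthoc_json[key] = _report_dict(val)
        elif isinstance(val, list):
            posthoc_json[key] = [_report_dict(v) for v in val]
        else:
            posthoc_json[key] = val
    posthoc_json["mask_source"] = bundle["mask_source"]
    with open(out / "posthoc.json", "w") as fh:
        json.dump(posthoc_json, fh, indent=1, default=float)
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    provenance = {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "crossconn": __version__,
            "numpy": np.__version__,
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)
    with open(out / "config.yaml", "w") as fh:
        fh.write(cfg_yaml)
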