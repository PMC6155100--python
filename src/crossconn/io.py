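"""Plain-text interchange formats (TSV/YAML/JSON) and schema validation.

TSV is the interchange default: inspectable and language-neutral. Every
reader validates its schema and reports offending columns/rows; every
write-then-read round trip restores the structure exactly (floats are written
with 17 significant digits).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectivity import ScanTimeSeries
from .design import CohortDesign, PhenotypeTable
from .exceptions import SchemaError
from .nbs import NBSResult, NetworkMask
from .synthetic import CovariateModel, SynthConfig, SyntheticCohort
from .trait import TraitMatrix

__all__ = [
    "write_sample_sheet",
    "read_sample_sheet",
    "write_timeseries",
    "read_timeseries",
    "write_matrix",
    "read_matrix",
    "write_edge_list",
    "read_edge_list",
    "write_phenotypes",
    "read_phenotypes",
    "write_cohort",
    "read_cohort",
    "write_trait_table",
    "write_nbs_result",
]

_FLOAT_FMT = "%.17g"


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file does not exist")
    try:
        return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip", **kw)
    except Exception as exc:  # noqa: BLE001 - rewrap with path context
        raise SchemaError(f"{path}: cannot parse TSV ({exc})") from exc


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

def write_sample_sheet(design: CohortDesign, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame({"subject_id": design.subject_ids, "group": design.group})
    if design.covariates is not None:
        df = pd.concat([df, design.covariates.reset_index(drop=True)], axis=1)
    with open(path, "w") as fh:
        fh.write("# group_levels: " + ",".join(design.group_levels) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_sample_sheet(
    path: str | Path,
    required_covariates: tuple[str, ...] = (),
    group_levels: tuple[str, ...] | None = None,
) -> CohortDesign:
    path = Path(path)
    if group_levels is None and path.exists():
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# group_levels:"):
            group_levels = tuple(first.split(":", 1)[1].strip().split(","))
    df = _read_tsv(path, dtype={"subject_id": str})
    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise SchemaError(f"{path}: sample sheet is missing required column '{col}'")
    for col in required_covariates:
        if col not in df.columns:
            raise SchemaError(f"{path}: sample sheet is missing covariate column '{col}'")
    cov_cols = [c for c in df.columns if c not in ("subject_id", "group")]
    cov = df[cov_cols] if cov_cols else None
    if cov is not None:
        bad = cov.select_dtypes(include=[np.number]).isna()
        if bad.any().any():
            rows = (np.flatnonzero(bad.any(axis=1)) + 2).tolist()  # header is line 1
            raise SchemaError(f"{path}: missing covariate values at line(s) {rows[:10]}")
    if group_levels is None:
        group_levels = tuple(pd.unique(df["group"]))
    return CohortDesign(
        subject_ids=df["subject_id"].tolist(),
        group=df["group"].to_numpy(dtype=object),
        group_levels=group_levels,
        covariates=cov,
    )


# ---------------------------------------------------------------------------
# matrices and time series
# ---------------------------------------------------------------------------

def write_timeseries(data: np.ndarray, path: str | Path) -> None:
    """Write a nodes x timepoints (or timepoints x regressors) real matrix."""
    np.savetxt(path, np.asarray(data, dtype=float), delimiter="\t", fmt=_FLOAT_FMT)


def read_timeseries(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file does not exist")
    try:
        out = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise SchemaError(f"{path}: malformed numeric row ({exc})") from exc
    if not np.all(np.isfinite(out)):
        rows = (np.flatnonzero(~np.isfinite(out).all(axis=1)) + 1).tolist()
        raise SchemaError(f"{path}: non-finite values at line(s) {rows[:10]}")
    return out


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    write_timeseries(matrix, path)


def read_matrix(path: str | Path, atol: float = 1e-8) -> np.ndarray:
    m = read_timeseries(path)
    if m.shape[0] != m.shape[1]:
        raise SchemaError(f"{path}: matrix is not square {m.shape}")
    asym = np.abs(m - m.T)
    if asym.max() > atol:
        i, j = np.unravel_index(int(asym.argmax()), asym.shape)
        raise SchemaError(
            f"{path}: asymmetric entry at ({i},{j}): {m[i, j]!r} vs {m[j, i]!r}"
        )
    return m


# ---------------------------------------------------------------------------
# edge lists / masks
# ---------------------------------------------------------------------------

def write_edge_list(mask: NetworkMask, path: str | Path, weights: np.ndarray | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"node_i": mask.edges[:, 0], "node_j": mask.edges[:, 1]})
    if weights is not None:
        df["weight"] = np.asarray(weights, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# n_nodes: {mask.n_nodes}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_edge_list(path: str | Path, n_nodes: int | None = None) -> NetworkMask:
    path = Path(path)
    if n_nodes is None and path.exists():
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("# n_nodes:"):
            n_nodes = int(first.split(":", 1)[1])
    if n_nodes is None:
        raise SchemaError(f"{path}: n_nodes not recorded and not supplied")
    df = _read_tsv(path)
    for col in ("node_i", "node_j"):
        if col not in df.columns:
            raise SchemaError(f"{path}: edge list is missing column '{col}'")
    edges = df[["node_i", "node_j"]].to_numpy(dtype=int)
    return NetworkMask(edges=edges.reshape(-1, 2), n_nodes=n_nodes)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = _read_tsv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: phenotype table is missing column 'subject_id'")
    return PhenotypeTable(table=df)


# ---------------------------------------------------------------------------
# whole cohorts
# ---------------------------------------------------------------------------

def _config_to_dict(cfg: SynthConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _config_from_dict(d: dict) -> SynthConfig:
    d = dict(d)
    cm = d.get("covariate_model")
    if isinstance(cm, dict):
        d["covariate_model"] = CovariateModel(**cm)
    for k, v in d.items():
        if isinstance(v, list):
            d[k] = tuple(v)
    return SynthConfig(**d)


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    write_sample_sheet(cohort.design, out / "sample_sheet.tsv")
    write_phenotypes(cohort.phenotypes, out / "phenotypes.tsv")
    write_edge_list(cohort.truth, out / "truth_edges.tsv")
    meta = {
        "config": _config_to_dict(cohort.config),
        "paradigm_ids": list(cohort.paradigm_ids),
        "true_effect_sizes": list(cohort.true_effect_sizes),
        "calibration": {
            k: ({str(kk): float(vv) for kk, vv in v.items()} if isinstance(v, dict) else float(v))
            for k, v in cohort.calibration.items()
        },
        "scans": [
            {
                "subject_id": s,
                "paradigm_id": p,
                "paradigm_class": cohort.scans[(s, p)].paradigm_class,
                "sampling_interval": cohort.scans[(s, p)].sampling_interval,
            }
            for (s, p) in sorted(cohort.scans)
        ],
    }
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    for (s, p), ts in cohort.scans.items():
        write_timeseries(ts.data, out / "scans" / f"{s}_{p}_ts.tsv")
        if ts.nuisance is not None:
            write_timeseries(ts.nuisance, out / "scans" / f"{s}_{p}_nuisance.tsv")


def read_cohort(in_dir: str | Path) -> SyntheticCohort:
    src = Path(in_dir)
    with open(src / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    cfg = _config_from_dict(meta["config"])
    design = read_sample_sheet(src / "sample_sheet.tsv")
    pheno = read_phenotypes(src / "phenotypes.tsv")
    truth = read_edge_list(src / "truth_edges.tsv")
    scans: dict[tuple[str, str], ScanTimeSeries] = {}
    for rec in meta["scans"]:
        s, p = rec["subject_id"], rec["paradigm_id"]
        data = read_timeseries(src / "scans" / f"{s}_{p}_ts.tsv")
        nuis_path = src / "scans" / f"{s}_{p}_nuisance.tsv"
        nuis = read_timeseries(nuis_path) if nuis_path.exists() else None
        scans[(s, p)] = ScanTimeSeries(
            subject_id=s,
            paradigm_id=p,
            data=data,
            sampling_interval=float(rec["sampling_interval"]),
            nuisance=nuis,
            paradigm_class=rec["paradigm_class"],
        )
    return SyntheticCohort(
        scans=scans,
        subject_ids=design.subject_ids,
        paradigm_ids=list(meta["paradigm_ids"]),
        design=design,
        phenotypes=pheno,
        truth=truth,
        true_effect_sizes=tuple(meta["true_effect_sizes"]),
        config=cfg,
        calibration=dict(meta.get("calibration", {})),
    )


# ---------------------------------------------------------------------------
# analysis outputs
# ---------------------------------------------------------------------------

def write_trait_table(traits: list[TraitMatrix], path: str | Path) -> None:
    rows = []
    for t in traits:
        row = {
            "subject_id": t.subject_id,
            "n_paradigms_used": t.n_paradigms_used,
            "variance_explained_1": t.variance_explained[0],
        }
        for pid, lo in zip(t.paradigm_ids, t.loadings):
            row[f"loading_{pid}"] = lo
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_nbs_result(result: NBSResult, path: str | Path) -> None:
    payload = {
        "primary_threshold_p": result.primary_threshold_p,
        "f_critical": result.f_critical,
        "statistic": result.statistic,
        "n_permutations": result.n_permutations,
        "seed": result.seed,
        "alpha": result.alpha,
        "n_nodes": result.n_nodes,
        "observed_max_stat": result.observed_max_stat,
        "component_stats": result.component_stats.tolist(),
        "fwe_p": result.fwe_p.tolist(),
        "null_max_stats": result.null_max_stats.tolist(),
        "winning_edges": result.winning_mask.edges.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
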