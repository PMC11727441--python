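"""Pipeline configuration, readers/writers and the end-to-end driver.

Entry point of the analysis is a directory of parcellated ROI time-series
TSVs plus a cohort manifest CSV and a node/partition table; the pipeline
runs connectome construction -> sparsity thresholding -> global/nodal
metrics (with rewired-null normalization) -> AUC integration -> modular
connectivity -> covariate-adjusted group statistics.  Every CSV written
carries a metadata header (config hash, seed, package version) and a fixed
config + seed reproduces all outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import (DEFAULT_GRID, ConnectivityMatrix, binarize_at_sparsity,
                         largest_component_size, pearson_matrix, rank_edges)
from .integration import MetricCurve, auc
from .metrics import global_metrics, nodal_metrics
from .modules import ModulePartition, module_connectivity
from .null_models import NullConfig, small_world
from .stats import (DEFAULT_COVARIATES, bonferroni, omnibus_and_pairwise,
                    stats_table)
from .synthetic_cohort import GROUPS, SubjectRecord

logger = logging.getLogger(__name__)

GLOBAL_METRICS = ("Cp", "Lp", "Eglob", "Eloc")
SMALL_WORLD_METRICS = ("Gamma", "Lambda", "Sigma")
NODAL_METRICS = ("BC", "DC", "NCp", "NLp", "Ne", "Nle")


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run."""

    manifest: str = ""
    timeseries_dir: str = ""
    partition: str | None = None  # None -> shipped AAL-90 table
    outdir: str = "results"
    s_min: float = 0.05
    s_max: float = 0.18
    s_step: float = 0.01
    edge_ranking: str = "absolute"  # "absolute" | "positive"
    log_base: float = math.e
    n_rand: int = 100
    swaps_per_edge: int = 10
    alpha: float = 0.05
    quadrature: str = "trapezoid"
    covariates: tuple = DEFAULT_COVARIATES
    compute_small_world: bool = True
    compute_nodal: bool = True
    compute_modules: bool = True
    seed: int = 0

    def grid(self) -> tuple[float, ...]:
        n = int(round((self.s_max - self.s_min) / self.s_step)) + 1
        grid = tuple(round(self.s_min + k * self.s_step, 10) for k in range(n))
        if len(grid) < 1 or grid[-1] > 1 or grid[0] <= 0:
            raise ValueError(f"malformed sparsity grid: {grid}")
        return grid

    def null_config(self) -> NullConfig:
        return NullConfig(n_rand=self.n_rand, swaps_per_edge=self.swaps_per_edge,
                          seed=self.seed)

    def config_hash(self) -> str:
        data = asdict(self)
        data.pop("outdir")  # where results land does not change what they are
        payload = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "covariates" in data:
            data["covariates"] = tuple(data["covariates"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["covariates"] = list(data["covariates"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_timeseries(path: str | Path, expected_rois: list[str] | None = None) -> pd.DataFrame:
    """Read one subject's T x N time-series TSV (header row = ROI names)."""
    df = pd.read_csv(path, sep="\t")
    bad = df.columns[~df.dtypes.apply(lambda d: np.issubdtype(d, np.number))]
    if len(bad):
        for col in bad:
            nonnum = pd.to_numeric(df[col], errors="coerce")
            row = int(nonnum.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at data row {row}")
    if expected_rois is not None and list(df.columns) != list(expected_rois):
        raise ValueError(
            f"{path}: ROI columns do not match the node table "
            f"({len(df.columns)} vs {len(expected_rois)} expected)")
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the cohort manifest CSV."""
    df = pd.read_csv(path)
    required = {"subject_id", "group", "age", "sex", "avg_ht", "ht_8k", "timeseries"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in manifest: {dupes}")
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group label(s) in manifest: {sorted(bad_groups)}; "
                         f"expected one of {GROUPS}")
    return df


def read_partition(path: str | Path | None) -> ModulePartition:
    from .modules import load_partition

    return load_partition(path, require_six=path is None)


def read_node_table(path: str | Path) -> pd.DataFrame:
    """Node table: roi, MNI x/y/z (mm), module."""
    df = pd.read_csv(path, sep="\t")
    required = {"roi", "x", "y", "z", "module"}
    if not required.issubset(df.columns):
        raise ValueError(f"node table must have columns {sorted(required)}")
    if df["roi"].duplicated().any():
        raise ValueError("duplicate ROI names in node table")
    if not np.isfinite(df[["x", "y", "z"]].to_numpy(dtype=float)).all():
        raise ValueError("non-finite MNI coordinate in node table")
    return df


def load_subjects(cfg: PipelineConfig) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Read the manifest and all per-subject time series."""
    manifest = read_manifest(cfg.manifest)
    ts_dir = Path(cfg.timeseries_dir)
    part = read_partition(cfg.partition)
    subjects = []
    for _, row in manifest.iterrows():
        try:
            df = read_timeseries(ts_dir / row["timeseries"],
                                 expected_rois=list(part.roi_names))
            subjects.append(SubjectRecord(
                subject_id=str(row["subject_id"]), group=str(row["group"]),
                timeseries=df.to_numpy(dtype=float), age=float(row["age"]),
                sex=str(row["sex"]), avg_ht=float(row["avg_ht"]),
                ht_8k=float(row["ht_8k"]),
                duration=float(row["duration"]) if pd.notna(row.get("duration")) else None))
        except Exception as exc:  # noqa: BLE001 - annotate with stage context
            raise RuntimeError(
                f"stage=load subject={row['subject_id']}: {exc}") from exc
    return subjects, manifest


# ---------------------------------------------------------------------------
# Metadata-stamped CSV output
# ---------------------------------------------------------------------------

def write_csv(df: pd.DataFrame, path: str | Path, cfg: PipelineConfig,
              index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# braingraph v{__version__} config={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=index)
    return path


def read_output_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def subject_metric_curves(record: SubjectRecord, grid, part: ModulePartition,
                          cfg: PipelineConfig):
    """All metric curves for one subject across the sparsity grid.

    Returns ``(global_rows, nodal_rows, module_rows, component_sizes)``
    where each rows object is a list of dicts keyed by threshold.
    """
    conn = pearson_matrix(record.timeseries, roi_names=part.roi_names)
    ranked = rank_edges(conn, mode=cfg.edge_ranking)
    null_cfg = cfg.null_config()
    g_rows, n_rows, m_rows, comp = [], [], [], []
    for s in grid:
        net = binarize_at_sparsity(conn, s, ranked=ranked)
        gm = global_metrics(net)
        row = {"subject_id": record.subject_id, "threshold": s, **gm.as_dict()}
        if cfg.compute_small_world:
            sw = small_world(net, null_cfg)
            row.update(sw.as_dict())
            row.update(null_cp_mean=sw.null_cp_mean, null_cp_sd=sw.null_cp_sd,
                       null_lp_mean=sw.null_lp_mean, null_lp_sd=sw.null_lp_sd)
        g_rows.append(row)
        comp.append({"subject_id": record.subject_id, "threshold": s,
                     "largest_component": largest_component_size(net),
                     "unreachable_pairs": gm.unreachable_pairs})
        if cfg.compute_nodal:
            nm = nodal_metrics(net)
            for k, roi in enumerate(part.roi_names):
                n_rows.append({"subject_id": record.subject_id, "threshold": s,
                               "roi": roi,
                               **{name: arr[k] for name, arr in nm.as_dict().items()}})
        if cfg.compute_modules:
            dens = module_connectivity(net, part)
            m_rows.append({"subject_id": record.subject_id, "threshold": s,
                           **dens.to_dict()})
    return g_rows, n_rows, m_rows, comp


def _auc_wide(df: pd.DataFrame, id_cols: list[str], metric_cols: list[str],
              grid, method: str) -> pd.DataFrame:
    """Collapse threshold curves to one AUC row per id-combination."""
    out = []
    for key, sub in df.groupby(id_cols, sort=False):
        key = key if isinstance(key, tuple) else (key,)
        sub = sub.sort_values("threshold")
        row = dict(zip(id_cols, key))
        for mcol in metric_cols:
            curve = MetricCurve(tuple(sub["threshold"]), tuple(sub[mcol]),
                                metric_name=mcol, subject_id=str(key[0]))
            try:
                row[f"a{mcol}"] = auc(curve, method=method).value
            except ValueError:
                # e.g. NLp of a node isolated across the grid: the curve has
                # no usable points; mark missing, group stats will drop it
                row[f"a{mcol}"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


def run_pipeline(cfg: PipelineConfig, subjects: list[SubjectRecord] | None = None,
                 write: bool = True) -> dict:
    """Execute the full pipeline; returns the result bundle as DataFrames.

    ``subjects`` may be passed directly (e.g. a freshly simulated cohort);
    otherwise they are read from ``cfg.manifest`` / ``cfg.timeseries_dir``.
    """
    t0 = time.time()
    grid = cfg.grid()
    part = read_partition(cfg.partition)
    if subjects is None:
        subjects, _ = load_subjects(cfg)
    if not subjects:
        raise ValueError("no subjects to analyse")

    g_all, n_all, m_all, comp_all = [], [], [], []
    for rec in subjects:
        try:
            g, n, m, comp = subject_metric_curves(rec, grid, part, cfg)
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(f"stage=metrics subject={rec.subject_id}: {exc}") from exc
        g_all += g
        n_all += n
        m_all += m
        comp_all += comp
        logger.info("subject %s done (%.1fs elapsed)", rec.subject_id, time.time() - t0)

    global_curves = pd.DataFrame(g_all)
    component_report = pd.DataFrame(comp_all)
    gcols = [c for c in (*GLOBAL_METRICS, *SMALL_WORLD_METRICS) if c in global_curves]
    global_auc = _auc_wide(global_curves, ["subject_id"], gcols, grid, cfg.quadrature)

    covar_df = pd.DataFrame([{**{"subject_id": r.subject_id, "group": r.group},
                              **r.covariates()} for r in subjects])
    global_auc = covar_df.merge(global_auc, on="subject_id")

    results: dict = {"global_curves": global_curves, "global_auc": global_auc,
                     "component_report": component_report}

    cov_cols = [c for c in cfg.covariates if c in covar_df.columns]
    constant = [c for c in cov_cols if covar_df[c].nunique() <= 1]
    if constant:
        logger.warning("dropping zero-variance covariate(s): %s", ", ".join(constant))
        cov_cols = [c for c in cov_cols if c not in constant]
    cov = global_auc[cov_cols] if cov_cols else None
    rows = []
    for mcol in [f"a{m}" for m in gcols]:
        row = omnibus_and_pairwise(global_auc[mcol], global_auc["group"],
                                   covariates=cov, metric=mcol, alpha=cfg.alpha)
        rows.append(row)
    results["global_stats"] = stats_table(rows)

    if cfg.compute_nodal:
        nodal_curves = pd.DataFrame(n_all)
        nodal_auc = _auc_wide(nodal_curves, ["subject_id", "roi"],
                              list(NODAL_METRICS), grid, cfg.quadrature)
        nodal_auc = covar_df.merge(nodal_auc, on="subject_id")
        results["nodal_curves"] = nodal_curves
        results["nodal_auc"] = nodal_auc
        n_nodes = len(part.roi_names)
        nrows = []
        for mname in NODAL_METRICS:
            col = f"a{mname}"
            for roi, sub in nodal_auc.groupby("roi", sort=False):
                if not np.isfinite(sub[col]).all():
                    continue  # isolated-node NLp left out of group statistics
                row = omnibus_and_pairwise(
                    sub[col], sub["group"], covariates=sub[cov_cols] if cov_cols else None,
                    metric=f"{col}[{roi}]", correction="bonferroni",
                    family_size=n_nodes, alpha=cfg.alpha)
                nrows.append(row)
        results["nodal_stats"] = stats_table(nrows)

    if cfg.compute_modules:
        module_curves = pd.DataFrame(m_all)
        measure_cols = [c for c in module_curves.columns
                        if c not in ("subject_id", "threshold")]
        module_auc = _auc_wide(module_curves, ["subject_id"], measure_cols,
                               grid, cfg.quadrature)
        module_auc.columns = ["subject_id"] + measure_cols  # densities keep names
        module_auc = covar_df.merge(module_auc, on="subject_id")
        results["module_curves"] = module_curves
        results["module_auc"] = module_auc
        mrows = []
        for mcol in measure_cols:
            row = omnibus_and_pairwise(module_auc[mcol], module_auc["group"],
                                       covariates=module_auc[cov_cols] if cov_cols else None,
                                       metric=mcol, family_size=len(measure_cols),
                                       alpha=cfg.alpha)
            mrows.append(row)
        mtab = stats_table(mrows)
        mtab["p_bonferroni"] = [bonferroni(p, len(measure_cols)) for p in mtab["p"]]
        results["module_stats"] = mtab

    if write:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg.to_yaml(outdir / "config.yaml")
        for name, df in results.items():
            write_csv(df, outdir / f"{name}.csv", cfg)
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    return results
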