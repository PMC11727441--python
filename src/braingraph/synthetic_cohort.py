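"""Synthetic multi-subject cohorts of ROI time series with planted effects.

No raw imaging data ships with the package, so every downstream stage is
exercised on simulated cohorts that reproduce the *structure* of a parcel
time-series study: N-ROI Gaussian time series (default 90 ROIs x 240 time
points) whose population correlation is block-modular over the six
anatomical modules, three groups (ROT / PT / HC), and demographic/clinical
covariates with group offsets (tinnitus groups get elevated hearing
thresholds).

A planted *segregation deficit* is expressed through ``effect_map``: a
per-group multiplicative factor on the within-module correlation.  The
default (factor 0.5 for ROT) halves the ROT group's within-module coupling,
which the pipeline should recover as lower clustering / local efficiency —
the qualitative signature the group statistics are built to detect.

Time series are plain multivariate Gaussians: the pipeline consumes only
Pearson correlations, which this model controls exactly.  An optional
moving-average smoother emulates band-limited noise; correlation targets
are defined pre-smoothing and the smoother is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .modules import MODULE_ORDER, ModulePartition, default_partition

GROUPS = ("ROT", "PT", "HC")

#: Default per-group covariate distributions (means/SDs), mirroring the
#: direction of a typical tinnitus cohort: patients have higher hearing
#: thresholds; ROT durations are under 6 months, PT durations above.
DEFAULT_COVARIATE_MODEL = {
    "ROT": {"age": (37.0, 11.0), "avg_ht": (19.0, 8.0), "ht_8k": (26.0, 10.0)},
    "PT": {"age": (41.0, 12.0), "avg_ht": (18.0, 8.0), "ht_8k": (25.0, 10.0)},
    "HC": {"age": (40.0, 12.0), "avg_ht": (12.0, 4.0), "ht_8k": (13.0, 5.0)},
}

DEFAULT_SEX_PROB = {"ROT": 0.65, "PT": 0.72, "HC": 0.62}

DEFAULT_EFFECT_MAP = {"ROT": 0.5, "PT": 1.0, "HC": 1.0}

TFI_SUBSCALES = ("I", "SC", "C", "SL", "A", "R", "Q", "E")


@dataclass(frozen=True)
class CohortSpec:
    """Generator parameters for one synthetic cohort."""

    n_per_group: int = 25
    n_rois: int = 90
    t_len: int = 240
    module_sizes: tuple[int, ...] | None = None
    r_within: float = 0.3
    r_between: float = 0.1
    effect_map: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_MAP))
    covariate_model: dict = field(default_factory=lambda: {g: dict(v) for g, v in DEFAULT_COVARIATE_MODEL.items()})
    sex_prob: dict = field(default_factory=lambda: dict(DEFAULT_SEX_PROB))
    smooth_window: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not 0.0 <= self.r_between <= self.r_within < 1.0:
            raise ValueError(
                f"require 0 <= r_between <= r_within < 1, got "
                f"r_between={self.r_between}, r_within={self.r_within}"
            )
        if self.module_sizes is not None:
            sizes = tuple(int(k) for k in self.module_sizes)
            if sum(sizes) != self.n_rois:
                raise ValueError(f"module_sizes sum to {sum(sizes)}, expected {self.n_rois}")
            object.__setattr__(self, "module_sizes", sizes)
        for g, f in self.effect_map.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group in effect_map: {g!r}")
            if not 0.0 < f <= 1.0:
                raise ValueError(f"effect factor for {g} must be in (0, 1], got {f}")

    def module_labels(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """(roi_names, module label per ROI) for this spec.

        The default 90-ROI layout uses the shipped AAL-90 six-module table;
        explicit ``module_sizes`` produce contiguous blocks.
        """
        if self.module_sizes is None:
            if self.n_rois == 90:
                part = default_partition()
                return part.roi_names, part.labels
            raise ValueError("module_sizes must be given when n_rois != 90")
        names = tuple(f"ROI{k + 1:03d}" for k in range(self.n_rois))
        block_names = (MODULE_ORDER if len(self.module_sizes) == 6
                       else tuple(f"M{k + 1}" for k in range(len(self.module_sizes))))
        labels: list[str] = []
        for bname, size in zip(block_names, self.module_sizes):
            labels.extend([bname] * size)
        return names, tuple(labels)

    def partition(self) -> ModulePartition:
        names, labels = self.module_labels()
        return ModulePartition(names, labels)


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: ROI time series plus covariates and group label."""

    subject_id: str
    group: str
    timeseries: np.ndarray  # T x N
    age: float
    sex: str  # "male" | "female"
    avg_ht: float
    ht_8k: float
    duration: float | None = None  # months; None for HC
    pm: float | None = None  # pitch match, Hz
    lm: float | None = None  # loudness match, dB HL
    tfi_total: float | None = None
    tfi_subscales: dict | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        ts = np.asarray(self.timeseries, dtype=float)
        if ts.ndim != 2:
            raise ValueError("timeseries must be T x N")
        if np.any(ts.std(axis=0) == 0):
            raise ValueError("timeseries has a constant column")
        object.__setattr__(self, "timeseries", ts)

    def covariates(self) -> dict[str, float]:
        return {"age": self.age, "sex": 1.0 if self.sex == "male" else 0.0,
                "avg_ht": self.avg_ht, "ht_8k": self.ht_8k}


def build_block_covariance(spec: CohortSpec, group: str) -> np.ndarray:
    """Unit-diagonal block covariance for one group.

    Entries are ``r_within * effect_map[group]`` for ROI pairs sharing a
    module and ``r_between`` across modules.  The matrix is checked for
    positive semidefiniteness; a non-PSD configuration is rejected with the
    smallest eigenvalue in the message.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group: {group!r}")
    _, labels = spec.module_labels()
    lab = np.asarray(labels)
    within = spec.r_within * spec.effect_map.get(group, 1.0)
    same = lab[:, None] == lab[None, :]
    cov = np.where(same, within, spec.r_between)
    np.fill_diagonal(cov, 1.0)
    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig < -1e-10:
        raise ValueError(
            f"covariance for group {group} is not positive semidefinite "
            f"(smallest eigenvalue {min_eig:.3e})"
        )
    return cov


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(100):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


def _sample_covariates(rng: np.random.Generator, spec: CohortSpec, group: str) -> dict:
    cm = spec.covariate_model[group]
    out = {
        "age": _truncated_normal(rng, *cm["age"], 18.0, 75.0),
        "avg_ht": _truncated_normal(rng, *cm["avg_ht"], 0.0, 90.0),
        "ht_8k": _truncated_normal(rng, *cm["ht_8k"], 0.0, 95.0),
        "sex": "male" if rng.random() < spec.sex_prob[group] else "female",
    }
    if group == "HC":
        out.update(duration=None, pm=None, lm=None, tfi_total=None, tfi_subscales=None)
        return out
    if group == "ROT":  # recent onset: under 6 months
        out["duration"] = float(rng.uniform(0.25, 5.9))
    else:  # persistent: 6 months and beyond
        out["duration"] = float(6.0 + rng.lognormal(mean=3.0, sigma=0.9))
    out["pm"] = float(np.round(rng.choice([2000, 3000, 4000, 5000, 6000, 8000])
                               * rng.uniform(0.9, 1.1)))
    out["lm"] = _truncated_normal(rng, 41.0, 19.0, 0.0, 100.0)
    subs = {k: _truncated_normal(rng, 12.0, 6.0, 0.0, 30.0) for k in TFI_SUBSCALES}
    out["tfi_subscales"] = subs
    out["tfi_total"] = float(np.clip(sum(subs.values()) / len(subs) * 2.9
                                     + rng.normal(0, 4), 0.0, 100.0))
    return out


def _smooth(ts: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return ts
    kernel = np.ones(window) / window
    out = np.empty_like(ts)
    for j in range(ts.shape[1]):
        out[:, j] = np.convolve(ts[:, j], kernel, mode="same")
    return out


def sample_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw the full three-group cohort described by ``spec``.

    Each subject has an independent RNG substream keyed by
    ``(spec.seed, subject index)``, so the same spec and seed reproduce the
    cohort bit-identically and enlarging a group never reshuffles existing
    subjects.
    """
    if spec.t_len < 2 * spec.n_rois:
        warnings.warn(
            f"t_len={spec.t_len} < 2*n_rois={2 * spec.n_rois}: "
            "sample correlation estimates will be unstable", stacklevel=2)
    chols = {g: np.linalg.cholesky(
        build_block_covariance(spec, g) + 1e-12 * np.eye(spec.n_rois))
        for g in GROUPS}
    cohort: list[SubjectRecord] = []
    idx = 0
    for group in GROUPS:
        for k in range(spec.n_per_group):
            rng = np.random.default_rng(np.random.SeedSequence((spec.seed, idx)))
            z = rng.standard_normal((spec.t_len, spec.n_rois))
            ts = _smooth(z @ chols[group].T, spec.smooth_window)
            cov = _sample_covariates(rng, spec, group)
            sex = cov.pop("sex")
            cohort.append(SubjectRecord(
                subject_id=f"{group}{k + 1:03d}", group=group,
                timeseries=ts, sex=sex, **cov))
            idx += 1
    return cohort


def with_effect(spec: CohortSpec, group: str, factor: float) -> CohortSpec:
    """Copy of ``spec`` with one group's within-module effect factor replaced."""
    em = dict(spec.effect_map)
    em[group] = factor
    return replace(spec, effect_map=em)


# ---------------------------------------------------------------------------
# Plain-text writers consumed by the I/O layer
# ---------------------------------------------------------------------------

def write_cohort(cohort: list[SubjectRecord], outdir: str | Path,
                 spec: CohortSpec) -> dict[str, Path]:
    """Write per-subject time-series TSVs, a manifest CSV and a node table.

    Returns the paths written: ``manifest``, ``nodes``, ``partition`` and
    the time-series directory.  Node MNI coordinates in the synthetic node
    table are zeros (placeholders: simulated parcels have no location).
    """
    outdir = Path(outdir)
    ts_dir = outdir / "timeseries"
    ts_dir.mkdir(parents=True, exist_ok=True)
    roi_names, labels = spec.module_labels()

    rows = []
    for rec in cohort:
        fname = ts_dir / f"{rec.subject_id}.tsv"
        pd.DataFrame(rec.timeseries, columns=list(roi_names)).to_csv(
            fname, sep="\t", index=False, float_format="%.6f")
        row = {"subject_id": rec.subject_id, "group": rec.group, "age": rec.age,
               "sex": rec.sex, "avg_ht": rec.avg_ht, "ht_8k": rec.ht_8k,
               "duration": rec.duration, "pm": rec.pm, "lm": rec.lm,
               "tfi_total": rec.tfi_total,
               "timeseries": fname.name}
        if rec.tfi_subscales:
            for k, v in rec.tfi_subscales.items():
                row[f"tfi_{k}"] = v
        rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)

    nodes = outdir / "nodes.tsv"
    pd.DataFrame({"roi": list(roi_names), "x": 0.0, "y": 0.0, "z": 0.0,
                  "module": list(labels)}).to_csv(nodes, sep="\t", index=False)
    partition = outdir / "partition.tsv"
    pd.DataFrame({"roi": list(roi_names), "module": list(labels)}).to_csv(
        partition, sep="\t", index=False)
    return {"manifest": manifest, "nodes": nodes, "partition": partition,
            "timeseries_dir": ts_dir}
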