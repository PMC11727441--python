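"""Modular (intra/inter-module) connectivity over an anatomical parcellation.

The 90 AAL regions are grouped into six anatomical modules — frontal,
prefrontal, parietal, temporal, occipital and subcortical.  For each
binarized network the intra-module strength of a module is the edge density
among its ROIs, and the inter-module strength of a module pair is the
density of edges crossing between them; with six modules this gives
6 + 15 = 21 values per subject per threshold, each in [0, 1].

The shipped ROI-to-module table (``data/aal90_modules.tsv``) is an editable
reconstruction from AAL region nomenclature; all module results are defined
relative to the loaded mapping, whose content hash is recorded in output
metadata.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import BinaryNetwork

#: Canonical module ordering used for the 21 connectivity measures.
MODULE_ORDER = ("frontal", "prefrontal", "subcortical", "parietal", "temporal", "occipital")


@dataclass(frozen=True)
class ModulePartition:
    """Assignment of every ROI to exactly one module."""

    roi_names: tuple[str, ...]
    labels: tuple[str, ...]  # module label per ROI, parallel to roi_names

    def __post_init__(self) -> None:
        if len(self.roi_names) != len(self.labels):
            raise ValueError("roi_names and labels must have equal length")
        if len(set(self.roi_names)) != len(self.roi_names):
            raise ValueError("duplicate ROI names in partition")
        sizes = self.sizes
        singletons = [m for m, k in sizes.items() if k < 2]
        if singletons:
            raise ValueError(f"module(s) with fewer than 2 ROIs: {', '.join(singletons)}")

    @property
    def modules(self) -> tuple[str, ...]:
        known = [m for m in MODULE_ORDER if m in set(self.labels)]
        extra = sorted(set(self.labels) - set(MODULE_ORDER))
        return tuple(known + extra)

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    def indices(self, module: str) -> np.ndarray:
        idx = np.array([k for k, lab in enumerate(self.labels) if lab == module], dtype=int)
        if idx.size == 0:
            raise KeyError(f"unknown module: {module!r}")
        return idx

    def content_hash(self) -> str:
        payload = "\n".join(f"{r}\t{m}" for r, m in zip(self.roi_names, self.labels))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_partition(path: str | Path | None = None, require_six: bool = True) -> ModulePartition:
    """Read a partition TSV (columns ``roi``, ``module``).

    ``path=None`` loads the shipped AAL-90 six-module table.  With
    ``require_six`` the table must carry exactly the six canonical labels.
    """
    if path is None:
        with resources.files("braingraph.data").joinpath("aal90_modules.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    if not {"roi", "module"}.issubset(df.columns):
        raise ValueError("partition table must have columns 'roi' and 'module'")
    part = ModulePartition(tuple(df["roi"].astype(str)), tuple(df["module"].astype(str)))
    if require_six:
        found = set(part.labels)
        if found != set(MODULE_ORDER):
            raise ValueError(
                f"expected the six module labels {sorted(MODULE_ORDER)}, got {sorted(found)}"
            )
    return part


def default_partition() -> ModulePartition:
    return load_partition(None, require_six=True)


def intra_module_strength(net: BinaryNetwork, part: ModulePartition, module: str) -> float:
    """Edge density among the ROIs of one module."""
    idx = part.indices(module)
    if idx.size < 2:
        raise ValueError(f"module {module!r} has fewer than 2 ROIs")
    a = net.adjacency()
    sub = a[np.ix_(idx, idx)]
    n_edges = int(np.triu(sub, k=1).sum())
    possible = idx.size * (idx.size - 1) // 2
    return n_edges / possible


def inter_module_strength(net: BinaryNetwork, part: ModulePartition, m1: str, m2: str) -> float:
    """Density of edges crossing between two distinct modules."""
    if m1 == m2:
        raise ValueError("inter-module strength requires two distinct modules")
    i1, i2 = part.indices(m1), part.indices(m2)
    a = net.adjacency()
    n_edges = int(a[np.ix_(i1, i2)].sum())
    return n_edges / (i1.size * i2.size)


def module_edge_counts(net: BinaryNetwork, part: ModulePartition) -> dict[str, int]:
    """Raw intra/inter edge counts (audit companion to the densities)."""
    a = net.adjacency()
    out: dict[str, int] = {}
    for m in part.modules:
        idx = part.indices(m)
        out[m] = int(np.triu(a[np.ix_(idx, idx)], k=1).sum())
    for m1, m2 in combinations(part.modules, 2):
        out[f"{m1}-{m2}"] = int(a[np.ix_(part.indices(m1), part.indices(m2))].sum())
    return out


def module_connectivity(net: BinaryNetwork, part: ModulePartition) -> pd.Series:
    """All 21 module-connectivity densities of one network.

    Ordered as the 15 inter-module pairs followed by the 6 intra-module
    strengths, both in canonical module order.
    """
    values: dict[str, float] = {}
    mods = part.modules
    for m1, m2 in combinations(mods, 2):
        values[f"{m1}-{m2}"] = inter_module_strength(net, part, m1, m2)
    for m in mods:
        values[m] = intra_module_strength(net, part, m)
    return pd.Series(values, name="density")
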