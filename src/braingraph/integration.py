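"""AUC integration of metric curves across the sparsity grid.

Comparing networks at a single threshold makes every downstream statistic a
function of that arbitrary choice; integrating each metric's curve over the
whole sparsity grid (composite trapezoidal rule by default) yields one
threshold-independent scalar per subject per metric — the ``a``-prefixed
quantities (aCp, aGamma, ...) the group statistics consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricCurve:
    """One metric's values across the sparsity grid for one subject (/node)."""

    thresholds: tuple[float, ...]
    values: tuple[float, ...]
    metric_name: str = ""
    subject_id: str = ""
    node_id: str | None = None
    missing: tuple[bool, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("thresholds and values must be 1-D and equal length")
        if len(t) >= 2:
            steps = np.diff(t)
            if np.any(steps <= 0):
                raise ValueError("thresholds must be strictly ascending")
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
                raise ValueError("thresholds must have constant step")
        if self.missing is None:
            miss = ~np.isfinite(v)
            object.__setattr__(self, "missing", tuple(bool(x) for x in miss))
        elif len(self.missing) != len(t):
            raise ValueError("missing mask length mismatch")
        mask = np.asarray(self.missing, dtype=bool)
        if np.any(~mask & ~np.isfinite(v)):
            raise ValueError("non-finite value not flagged as missing")


@dataclass(frozen=True)
class AUCScalar:
    value: float
    metric_name: str = ""
    subject_id: str = ""
    node_id: str | None = None
    n_points: int = 0
    skipped_panels: int = 0


def auc(curve: MetricCurve, method: str = "trapezoid") -> AUCScalar:
    """Integrate a metric curve over its sparsity grid.

    ``method="trapezoid"`` is the composite trapezoidal rule;
    ``method="rectangle"`` is the left-rectangle sum (for sensitivity
    analysis).  Panels adjacent to a missing grid point are skipped and
    counted in ``skipped_panels``.
    """
    if method not in ("trapezoid", "rectangle"):
        raise ValueError(f"unknown quadrature method: {method!r}")
    t = np.asarray(curve.thresholds, dtype=float)
    v = np.asarray(curve.values, dtype=float)
    ok = ~np.asarray(curve.missing, dtype=bool)
    if ok.sum() < 2:
        raise ValueError(
            f"curve {curve.metric_name!r} for {curve.subject_id!r} has "
            f"{int(ok.sum())} usable points; need at least 2"
        )
    total = 0.0
    skipped = 0
    for a, b in zip(range(len(t) - 1), range(1, len(t))):
        if not (ok[a] and ok[b]):
            skipped += 1
            continue
        if method == "trapezoid":
            total += 0.5 * (v[a] + v[b]) * (t[b] - t[a])
        else:
            total += v[a] * (t[b] - t[a])
    if skipped:
        logger.info("AUC for %s/%s skipped %d panel(s) with missing points",
                    curve.subject_id, curve.metric_name, skipped)
    return AUCScalar(value=float(total), metric_name=curve.metric_name,
                     subject_id=curve.subject_id, node_id=curve.node_id,
                     n_points=int(ok.sum()), skipped_panels=skipped)
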