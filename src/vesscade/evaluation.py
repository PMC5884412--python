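"""Segmentation metrics and report assembly.

Dice overlap (DOC, percent) and average symmetric surface distance (ASD, mm)
are the volume- and surface-based accuracy measures; a paired t-test compares
method variants case by case. Reports bundle per-case metrics with cascade
bookkeeping (per-layer kinds and weak-classifier counts, feature queues,
rear-layer feature utilization).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .cascade import CascadeModel, feature_utilization
from .volume import Volume

__all__ = ["dice", "asd", "paired_t", "PairedTResult", "EvalReport", "make_report"]


def _as_bool(vol: Volume | np.ndarray) -> np.ndarray:
    data = vol.data if isinstance(vol, Volume) else vol
    return np.asarray(data) > 0.5


def dice(pred: Volume | np.ndarray, ref: Volume | np.ndarray) -> float:
    """Dice overlap coefficient in percent: 100 · 2|A∩B| / (|A|+|B|).

    Two empty masks count as perfect agreement (100, with a warning-free
    fast path); shape mismatch is an error.
    """
    a, b = _as_bool(pred), _as_bool(ref)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 100.0
    return 100.0 * 2.0 * np.logical_and(a, b).sum() / denom


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _surface(mask: np.ndarray, connectivity: int = 1) -> np.ndarray:
    struct = ndimage.generate_binary_structure(3, connectivity)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def asd(pred: Volume | np.ndarray, ref: Volume | np.ndarray,
        spacing: tuple[float, float, float] | None = None, *,
        connectivity: int = 1) -> float:
    """Average symmetric surface distance in mm.

    Surfaces are mask voxels with at least one background neighbor
    (face-connectivity by default); directed distances use a spacing-aware
    Euclidean distance transform and the two directed means are averaged.
    Undefined (error) when either mask is empty.
    """
    a, b = _as_bool(pred), _as_bool(ref)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if spacing is None:
        spacing = pred.spacing if isinstance(pred, Volume) else (1.0, 1.0, 1.0)
    if not a.any() or not b.any():
        raise ValueError("undefined surface distance: empty mask")
    surf_a = _surface(a, connectivity)
    surf_b = _surface(b, connectivity)
    dt_a = ndimage.distance_transform_edt(~surf_a, sampling=spacing)
    dt_b = ndimage.distance_transform_edt(~surf_b, sampling=spacing)
    d_ab = dt_b[surf_a]
    d_ba = dt_a[surf_b]
    return 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    significant: bool
    degenerate: bool = False


def paired_t(values_a: np.ndarray, values_b: np.ndarray,
             alpha: float = 0.05) -> PairedTResult:
    """Classical two-sided paired t-test on case-matched metric values.

    All-zero differences give (t=0, p=1); nonzero constant differences have
    no finite t statistic and are returned with the degenerate flag set
    (difference direction still certain, so marked significant).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1D arrays with n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return PairedTResult(0.0, 1.0, False)
        return PairedTResult(float(np.inf) * np.sign(diff.mean()), 0.0,
                             True, degenerate=True)
    from scipy import stats

    t, p = stats.ttest_rel(a, b)
    return PairedTResult(float(t), float(p), bool(p < alpha))


@dataclass
class EvalReport:
    """Per-case metrics plus cascade bookkeeping, serializable to JSON/CSV."""

    cases: pd.DataFrame  # columns: case id fields + doc_percent, asd_mm
    layer_table: pd.DataFrame  # layer, kind, n_weaks, achieved_d, achieved_e
    feature_queues: list[list[tuple[int, int]]]
    utilization: np.ndarray  # percent per feature, sums to 100
    overall_rates: tuple[float, float]  # (D, E)
    config: dict = field(default_factory=dict)
    t_tests: dict = field(default_factory=dict)

    def summary(self, by: str = "noise_variance") -> pd.DataFrame:
        """Mean ± SD of DOC and ASD grouped by a case column."""
        grp = self.cases.groupby(by)
        out = grp.agg(doc_mean=("doc_percent", "mean"),
                      doc_sd=("doc_percent", "std"),
                      asd_mean=("asd_mm", "mean"),
                      asd_sd=("asd_mm", "std"),
                      n=("doc_percent", "size"))
        return out.reset_index()

    def to_dict(self) -> dict:
        return {
            "cases": self.cases.to_dict(orient="list"),
            "layer_table": self.layer_table.to_dict(orient="list"),
            "feature_queues": [[list(c) for c in q] for q in self.feature_queues],
            "utilization": self.utilization.tolist(),
            "overall_rates": list(self.overall_rates),
            "config": self.config,
            "t_tests": self.t_tests,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "EvalReport":
        return cls(
            cases=pd.DataFrame(obj["cases"]),
            layer_table=pd.DataFrame(obj["layer_table"]),
            feature_queues=[[tuple(c) for c in q] for q in obj["feature_queues"]],
            utilization=np.asarray(obj["utilization"]),
            overall_rates=tuple(obj["overall_rates"]),
            config=obj.get("config", {}),
            t_tests=obj.get("t_tests", {}),
        )

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "EvalReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def write_csvs(self, prefix: str) -> None:
        self.cases.to_csv(f"{prefix}_cases.csv", index=False)
        self.layer_table.to_csv(f"{prefix}_layers.csv", index=False)


def make_report(cases: pd.DataFrame, cascade: CascadeModel,
                config: dict | None = None) -> EvalReport:
    """Assemble per-case metrics and cascade bookkeeping into a report."""
    rows = []
    for i, layer in enumerate(cascade.layers):
        n_weaks = layer.n_weaks if layer.kind == "adaboost" else len(layer.channels)
        rows.append({"layer": i + 1, "kind": layer.kind, "n_weaks": n_weaks,
                     "achieved_d": layer.achieved_d,
                     "achieved_e": layer.achieved_e})
    layer_table = pd.DataFrame(rows, columns=["layer", "kind", "n_weaks",
                                              "achieved_d", "achieved_e"])
    return EvalReport(
        cases=cases.reset_index(drop=True),
        layer_table=layer_table,
        feature_queues=[list(l.queue) for l in cascade.layers],
        utilization=feature_utilization(cascade) if cascade.layers else np.array([]),
        overall_rates=cascade.overall_rates(),
        config=config or {},
    )
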