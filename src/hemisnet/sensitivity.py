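"""Robustness analyses: sparsity sweep with AUC, and model variants.

The sparsity sweep re-thresholds each subject's cached weighted
networks at every threshold from 0.25 to 0.50 in steps of 0.01 (26
values; edge sets are nested across the sweep because thresholding is
by rank), integrates each metric over the range by the trapezoidal
rule, and reruns the case-control models on the hemispheric difference
of the AUC. HD is linear in the hemispheres, so the HD of the AUC
equals the AUC of the HD curve.

Model variants rerun the main models with a quadratic centred-age term,
or with the subject's mean cortical thickness over all 68 regions as an
extra fixed effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .inference import (
    MetricPanel,
    _finalize_tier,
    _one_test,
    compute_metric_panel,
    run_node_level_analysis,
)
from .io import Subject, TestResult, ThicknessTable
from .metrics import NODE_METRICS, compute_node_metrics
from .networks import binarize_by_sparsity
from .regions import DK_REGIONS, N_REGIONS

__all__ = ["SparsityCurves", "run_sparsity_sweep", "run_model_variants", "trapezoid_auc"]


def trapezoid_auc(values: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Trapezoidal integral of metric curves over the sparsity axis.

    ``values``' last axis must index the thresholds. A constant curve m
    integrates to m * (range width); a linear curve from a to b to
    (a + b) / 2 * width.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return np.trapezoid(values, x=thresholds, axis=-1)


@dataclass
class SparsityCurves:
    """Metric values across the threshold sweep, per subject/hemisphere.

    ``node_values[metric][hemi]`` has shape (n_subjects, 34, n_thresholds).
    """

    subject_ids: list[str]
    thresholds: np.ndarray
    node_values: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def auc(self, metric: str, hemi: str) -> np.ndarray:
        """(n_subjects, 34) trapezoid AUC over the sweep."""
        return trapezoid_auc(self.node_values[metric][hemi], self.thresholds)

    def auc_hd(self, metric: str, region_idx: int) -> np.ndarray:
        return self.auc(metric, "L")[:, region_idx] - self.auc(metric, "R")[:, region_idx]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: subject, hemisphere, metric, node, S, value."""
        rows = []
        for metric, by_hemi in self.node_values.items():
            for hemi, vals in by_hemi.items():
                for si, sid in enumerate(self.subject_ids):
                    for ri, region in enumerate(DK_REGIONS):
                        for ti, s in enumerate(self.thresholds):
                            rows.append(
                                (sid, hemi, metric, region, float(s), vals[si, ri, ti])
                            )
        return pd.DataFrame(
            rows, columns=["subject_id", "hemisphere", "metric", "node", "S", "value"]
        )


def compute_sparsity_curves(
    table: ThicknessTable,
    subjects: list[Subject],
    config: AnalysisConfig | None = None,
    node_metrics: tuple[str, ...] = NODE_METRICS,
    panel: MetricPanel | None = None,
) -> SparsityCurves:
    """Metric values at every threshold, from cached weighted networks."""
    config = config or AnalysisConfig()
    if panel is None or not panel.weighted:
        panel = compute_metric_panel(
            table, subjects, config,
            node_metrics=(), hemisphere_level=False, keep_weighted=True,
        )
    thresholds = config.sparsity_grid
    nt = len(thresholds)
    n = len(panel.subject_ids)
    curves = SparsityCurves(
        subject_ids=panel.subject_ids,
        thresholds=thresholds,
        node_values={m: {} for m in node_metrics},
    )
    need_slow = any(m != "degree_centrality" for m in node_metrics)
    for hemi in ("L", "R"):
        weighted = panel.weighted[hemi]
        store = {m: np.empty((n, N_REGIONS, nt)) for m in node_metrics}
        for ti, s in enumerate(thresholds):
            binary = binarize_by_sparsity(weighted, float(s))
            if "degree_centrality" in node_metrics:
                store["degree_centrality"][:, :, ti] = binary.sum(axis=2)
            if need_slow:
                for i in range(n):
                    nm = compute_node_metrics(binary[i]).as_dict()
                    for m in node_metrics:
                        if m != "degree_centrality":
                            store[m][i, :, ti] = nm[m]
        for m in node_metrics:
            curves.node_values[m][hemi] = store[m]
    return curves


def run_sparsity_sweep(
    table: ThicknessTable,
    subjects: list[Subject],
    config: AnalysisConfig | None = None,
    node_metrics: tuple[str, ...] = NODE_METRICS,
    panel: MetricPanel | None = None,
    curves: SparsityCurves | None = None,
) -> tuple[SparsityCurves, list[TestResult]]:
    """AUC-HD case-control tests across the sparsity range."""
    config = config or AnalysisConfig()
    if curves is None:
        curves = compute_sparsity_curves(table, subjects, config, node_metrics, panel)
    results: list[TestResult] = []
    for mi, m in enumerate(curves.node_values):
        metric_results = []
        for i, region in enumerate(DK_REGIONS):
            hd = curves.auc_hd(m, i)
            seed = int(
                np.random.SeedSequence((config.rng_seed, 4, mi, i)).generate_state(1)[0]
                % (2**31)
            )
            metric_results.append(
                _one_test(
                    hd, subjects, config, "node", f"{m}_auc", region, seed,
                )
            )
        _finalize_tier(metric_results, "node", config)
        results.extend(metric_results)
    return curves, results


def run_model_variants(
    table: ThicknessTable,
    subjects: list[Subject],
    config: AnalysisConfig | None = None,
    panel: MetricPanel | None = None,
    node_metrics: tuple[str, ...] = NODE_METRICS,
    hemisphere_level: bool = True,
    variants: tuple[str, ...] = ("nonlinear_age", "global_thickness"),
) -> dict[str, list[TestResult]]:
    """Rerun the main case-control models under each variant."""
    config = config or AnalysisConfig()
    if panel is None:
        panel = compute_metric_panel(
            table, subjects, config,
            node_metrics=node_metrics, hemisphere_level=hemisphere_level,
        )
    return {
        v: run_node_level_analysis(
            table, subjects, config, panel=panel,
            node_metrics=node_metrics, hemisphere_level=hemisphere_level,
            variant=v, follow_up_unilateral=False,
        )
        for v in variants
    }
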