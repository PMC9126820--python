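"""Descriptive edge-level asymmetry analysis.

For a seed region whose degree-centrality asymmetry differs between
cases and controls, each of the 33 edges linking the seed to the other
regions is tested for asymmetry, using the *unthresholded* weighted
networks: per subject, edge HD = w_L(seed, j) - w_R(seed, j). The same
mixed model and permutation scheme as the main analysis apply, with
BH-FDR at 0.05 over the 33 edges of each seed.

Unlike the binarized topology, raw edge HDs depend on the similarity
kernel's functional form; signs, ranks and the calibration of the
inference are kernel-robust, raw magnitudes are not.
"""

from __future__ import annotations

import numpy as np

from .config import AnalysisConfig
from .inference import (
    MetricPanel,
    _finalize_tier,
    _one_test,
    compute_metric_panel,
)
from .io import Subject, TestResult, ThicknessTable
from .regions import DK_REGIONS, region_index

__all__ = ["extract_seed_edge_hd", "run_edge_level_analysis", "seeds_from_results"]


def extract_seed_edge_hd(
    weighted_left: np.ndarray, weighted_right: np.ndarray, seed: str
) -> tuple[list[str], np.ndarray]:
    """(partner names, 33 HD values) for one subject's seed edges."""
    i = region_index(seed)
    wl = np.asarray(weighted_left, dtype=float)
    wr = np.asarray(weighted_right, dtype=float)
    partners = [r for r in DK_REGIONS if r != seed]
    idx = [region_index(r) for r in partners]
    return partners, wl[i, idx] - wr[i, idx]


def seeds_from_results(results: list[TestResult]) -> list[str]:
    """Regions with significant node-tier degree-centrality asymmetry."""
    return [
        r.node
        for r in results
        if r.tier == "node" and r.metric == "degree_centrality" and r.significant
    ]


def run_edge_level_analysis(
    table: ThicknessTable,
    subjects: list[Subject],
    config: AnalysisConfig | None = None,
    seeds: list[str] | None = None,
    panel: MetricPanel | None = None,
    main_results: list[TestResult] | None = None,
) -> list[TestResult]:
    """Edge-HD mixed models for every seed; BH over 33 edges per seed.

    ``seeds`` may be given explicitly; otherwise they are auto-selected
    from ``main_results``. An empty seed list returns an empty result.
    """
    config = config or AnalysisConfig()
    if seeds is None:
        seeds = seeds_from_results(main_results or [])
    if not seeds:
        return []
    if panel is None or not panel.weighted:
        panel = compute_metric_panel(
            table, subjects, config,
            node_metrics=(), hemisphere_level=False, keep_weighted=True,
        )
    wl, wr = panel.weighted["L"], panel.weighted["R"]

    out: list[TestResult] = []
    for seed in seeds:
        i = region_index(seed)
        partners = [r for r in DK_REGIONS if r != seed]
        seed_results = []
        for r in partners:
            j = region_index(r)
            hd = wl[:, i, j] - wr[:, i, j]
            perm_seed = int(
                np.random.SeedSequence(
                    (config.rng_seed, 3, i, j)
                ).generate_state(1)[0]
                % (2**31)
            )
            seed_results.append(
                _one_test(
                    hd, subjects, config, "edge", "edge_weight",
                    f"{seed}->{r}", perm_seed,
                )
            )
        _finalize_tier(seed_results, "edge", config)
        out.extend(seed_results)
    return out
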