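"""Case-control inference on hemispheric asymmetries.

Every topological metric yields, per subject, a hemispheric difference
``HD = Left - Right`` (positive = leftward asymmetry). Case-control
differences in HD are tested with a random-intercept linear mixed model

    HD ~ diagnosis + age + sex + (1 | dataset),

the diagnosis t converted to Cohen's d, and significance assessed by
label-swapping permutations (two-tailed, add-one smoothed). Multiplicity
is corrected per analysis tier: Bonferroni over the 3 hemisphere-level
metrics, Benjamini-Hochberg over the 34 nodes of each node-level metric
(threshold 0.05/4 for the four metrics tested), BH over the 33 edges of
a seed region, and no correction for the post hoc unilateral and
within-case follow-ups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import Subject, TestResult, ThicknessTable
from .lmm import batched_diagnosis_t, fit_random_intercept
from .metrics import (
    HEMISPHERE_METRICS,
    NODE_METRICS,
    compute_node_metrics,
    compute_small_world,
)
from .networks import (
    binarize_by_sparsity,
    build_weighted_networks,
    compute_control_reference,
    standardize,
)
from .regions import DK_REGIONS, N_REGIONS, hemisphere_columns

logger = logging.getLogger(__name__)

MODEL_VARIANTS = (
    "main",
    "nonlinear_age",
    "global_thickness",
    "unilateral_left",
    "unilateral_right",
)


def compute_hd(left, right):
    """Hemispheric difference, Left - Right. Positive = leftward.

    Non-finite inputs propagate as NaN (counted and logged), so a
    subject with an undefined metric drops out of the model fit rather
    than poisoning it.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    hd = left - right
    n_bad = int(np.sum(~np.isfinite(hd)))
    if n_bad:
        logger.warning("%d non-finite HD value(s) propagated as missing", n_bad)
    return hd


def cohens_d_from_t(t: float, n1: int, n2: int, df: float) -> float:
    """Two-group Cohen's d from a model t-statistic.

    d = t (n1 + n2) / (sqrt(n1 n2) sqrt(df)), with df the residual
    degrees of freedom of the fixed-effects design.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    if df <= 0:
        raise ValueError(f"df must be positive, got {df}")
    return float(t * (n1 + n2) / (np.sqrt(n1 * n2) * np.sqrt(df)))


@dataclass
class _Design:
    """Model-ready arrays for one outcome, with missingness handled."""

    y: np.ndarray
    diag: np.ndarray  # focal 0/1 column
    F: np.ndarray  # covariates incl. intercept
    groups: np.ndarray
    n_cases: int
    n_controls: int


def _build_design(
    y: np.ndarray,
    subjects: list[Subject],
    variant: str = "main",
    global_thickness: np.ndarray | None = None,
    focal: np.ndarray | None = None,
    drop_covariate: str | None = None,
) -> _Design:
    """Assemble outcome/design arrays, excluding subjects with missing data.

    ``focal`` overrides the diagnosis indicator (used by within-case
    models, where the focal predictor is a clinical variable);
    ``drop_covariate`` removes ``age`` or ``sex`` from the covariates
    when it is itself the focal predictor.
    """
    if variant not in MODEL_VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}")
    y = np.asarray(y, dtype=float)
    if len(y) != len(subjects):
        raise ValueError("outcome length does not match subject list")

    age = np.array([s.age for s in subjects], dtype=float)
    sex = np.array(
        [np.nan if s.sex is None else float(s.sex == "M") for s in subjects]
    )
    diag = np.array([float(s.is_case) for s in subjects])
    groups = np.array([s.dataset_id for s in subjects])
    if focal is None:
        focal = diag
    focal = np.asarray(focal, dtype=float)

    keep = np.isfinite(y) & np.isfinite(focal)
    if drop_covariate != "age":
        keep &= np.isfinite(age)
    if drop_covariate != "sex":
        keep &= np.isfinite(sex)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d subject(s) with missing outcome/covariates", n_dropped)

    cols = [np.ones(keep.sum())]
    if drop_covariate != "age":
        cols.append(age[keep])
    if drop_covariate != "sex":
        cols.append(sex[keep])
    if variant == "nonlinear_age":
        a = age[keep]
        cols.append((a - a.mean()) ** 2)
    if variant == "global_thickness":
        if global_thickness is None:
            raise ValueError("variant 'global_thickness' needs the thickness table")
        gt = np.asarray(global_thickness, dtype=float)[keep]
        cols.append(gt)
    F = np.column_stack(cols)

    d = diag[keep]
    return _Design(
        y=y[keep],
        diag=focal[keep],
        F=F,
        groups=groups[keep],
        n_cases=int(d.sum()),
        n_controls=int((1 - d).sum()),
    )


def fit_case_control_model(
    hd: np.ndarray,
    subjects: list[Subject],
    variant: str = "main",
    global_thickness: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """(diagnosis coefficient, t, residual df) of the HD mixed model.

    ``unilateral_left`` / ``unilateral_right`` variants are fit by the
    caller passing the raw unilateral metric as ``hd``; the model
    structure is identical.
    """
    des = _build_design(hd, subjects, variant, global_thickness)
    if des.n_cases == 0 or des.n_controls == 0:
        raise ValueError("both diagnosis groups must be present")
    fit = fit_random_intercept(
        np.column_stack([des.diag, des.F]), des.y, des.groups
    )
    return float(fit.beta[0]), float(fit.t[0]), fit.df


def _permuted_columns(
    focal: np.ndarray,
    groups: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    within_dataset: bool,
) -> np.ndarray:
    """(n, n_perm) label-swapped versions of the focal column."""
    n = len(focal)
    D = np.empty((n, n_perm))
    if within_dataset:
        for g in np.unique(groups):
            idx = np.flatnonzero(groups == g)
            keys = rng.random((len(idx), n_perm))
            order = np.argsort(keys, axis=0)
            D[idx, :] = focal[idx][order]
    else:
        keys = rng.random((n, n_perm))
        order = np.argsort(keys, axis=0)
        D[:, :] = focal[order]
    return D


def permutation_pvalue(
    hd: np.ndarray,
    subjects: list[Subject],
    variant: str = "main",
    n_perm: int = 10_000,
    rng_seed: int = 0,
    within_dataset: bool = True,
    global_thickness: np.ndarray | None = None,
    focal: np.ndarray | None = None,
    drop_covariate: str | None = None,
) -> tuple[float, float]:
    """Two-tailed empirical p for the focal coefficient, and its t.

    p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perm); labels are swapped
    within dataset by default (each dataset's case/control counts are
    preserved, matching exchangeability under the random-intercept
    model). The observed t is computed by the same batched estimator as
    the permuted ones, so the comparison is like-with-like.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    des = _build_design(hd, subjects, variant, global_thickness, focal, drop_covariate)
    rng = np.random.default_rng(rng_seed)
    D = _permuted_columns(des.diag, des.groups, n_perm, rng, within_dataset)
    t_all = batched_diagnosis_t(des.F, np.column_stack([des.diag, D]), des.y, des.groups)
    t_obs, t_perm = t_all[0], t_all[1:]
    n_failed = int(np.sum(~np.isfinite(t_perm)))
    if not np.isfinite(t_obs):
        raise ValueError("observed mixed-model fit failed")
    if n_failed > 0.01 * n_perm:
        raise ValueError(
            f"{n_failed}/{n_perm} permutation fits failed; the design is "
            "likely degenerate (unreplicated datasets or constant outcome)"
        )
    p = (1.0 + np.sum(np.abs(t_perm) >= np.abs(t_obs))) / (1.0 + n_perm)
    return float(p), float(t_obs)


def adjust_pvalues(
    p: np.ndarray, tier: str, config: AnalysisConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(adjusted p, significance flags) for one analysis tier.

    hemisphere: Bonferroni, significant iff raw p < 0.05/3.
    node: BH over the vector (34 nodes of one metric), iff adjusted < 0.05/4.
    edge: BH over the vector (33 edges of one seed), iff adjusted < 0.05.
    unilateral / within-case: no correction, nominal 0.05.
    """
    config = config or AnalysisConfig()
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if tier == "hemisphere":
        adj = np.minimum(p * len(p), 1.0)
        sig = p < config.alpha_hemisphere
    elif tier == "node":
        adj = stats.false_discovery_control(p, method="bh")
        sig = adj < config.alpha_node
    elif tier == "edge":
        adj = stats.false_discovery_control(p, method="bh")
        sig = adj < config.alpha_edge
    elif tier in ("unilateral", "within-case"):
        adj = p.copy()
        sig = p < 0.05
    else:
        raise ValueError(f"unknown tier {tier!r}")
    return adj, sig


# ---------------------------------------------------------------------------
# metric panel
# ---------------------------------------------------------------------------


@dataclass
class MetricPanel:
    """Per-subject topological metrics for both hemispheres.

    ``node_values[metric][hemi]`` is (n_subjects, 34);
    ``hemi_values[metric][hemi]`` is (n_subjects,) for gamma/lambda/sigma.
    """

    subject_ids: list[str]
    node_values: dict[str, dict[str, np.ndarray]]
    hemi_values: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    weighted: dict[str, np.ndarray] = field(default_factory=dict)  # (n, 34, 34)

    def node_hd(self, metric: str, region_idx: int) -> np.ndarray:
        v = self.node_values[metric]
        return compute_hd(v["L"][:, region_idx], v["R"][:, region_idx])

    def hemi_hd(self, metric: str) -> np.ndarray:
        v = self.hemi_values[metric]
        return compute_hd(v["L"], v["R"])


def compute_metric_panel(
    table: ThicknessTable,
    subjects: list[Subject],
    config: AnalysisConfig | None = None,
    node_metrics: tuple[str, ...] = NODE_METRICS,
    hemisphere_level: bool = True,
    keep_weighted: bool = False,
    sparsity: float | None = None,
) -> MetricPanel:
    """Standardize, build and threshold networks, compute all metrics.

    ``node_metrics`` may be restricted (e.g. degree only) to skip the
    more expensive shortest-path metrics; ``keep_weighted`` retains the
    unthresholded weighted networks for edge-level analysis.
    """
    config = config or AnalysisConfig()
    if sparsity is None:
        sparsity = config.sparsity
    if [s.subject_id for s in subjects] != table.subject_ids:
        raise ValueError("subjects and thickness table are not index-aligned")
    ref = compute_control_reference(table, subjects, pooled=config.pooled_reference)
    z = standardize(table, subjects, ref)

    panel = MetricPanel(
        subject_ids=table.subject_ids,
        node_values={m: {} for m in node_metrics},
        hemi_values={m: {} for m in HEMISPHERE_METRICS} if hemisphere_level else {},
    )
    need_slow = any(
        m in node_metrics
        for m in ("nodal_global_efficiency", "nodal_local_efficiency")
    ) or ("clustering_coefficient" in node_metrics)
    # one null-model seed per subject, shared by both hemispheres, so that
    # relabeling L<->R swaps the hemisphere metrics exactly
    null_seeds = np.random.SeedSequence((config.rng_seed, 7)).generate_state(
        table.n_subjects
    )

    for hi, hemi in enumerate(("L", "R")):
        zh = z.loc[:, hemisphere_columns(hemi)].to_numpy()
        weighted = build_weighted_networks(zh)
        if keep_weighted:
            panel.weighted[hemi] = weighted
        binary = binarize_by_sparsity(weighted, sparsity)
        n = binary.shape[0]

        if "degree_centrality" in node_metrics:
            panel.node_values["degree_centrality"][hemi] = binary.sum(axis=2)
        if need_slow:
            per_metric = {m: np.empty((n, N_REGIONS)) for m in node_metrics if m != "degree_centrality"}
            for i in range(n):
                nm = compute_node_metrics(binary[i]).as_dict()
                for m in per_metric:
                    per_metric[m][i] = nm[m]
            for m, vals in per_metric.items():
                panel.node_values[m][hemi] = vals

        if hemisphere_level:
            gamma = np.empty(n)
            lam = np.empty(n)
            sigma = np.empty(n)
            for i in range(n):
                sw = compute_small_world(
                    binary[i],
                    n_null=config.n_null_networks,
                    rng_seed=int(null_seeds[i] % (2**31)),
                )
                gamma[i], lam[i], sigma[i] = sw.gamma, sw.lambda_, sw.sigma
            panel.hemi_values["gamma"][hemi] = gamma
            panel.hemi_values["lambda"][hemi] = lam
            panel.hemi_values["sigma"][hemi] = sigma
    return panel


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _one_test(
    y: np.ndarray,
    subjects: list[Subject],
    config: AnalysisConfig,
    tier: str,
    metric: str,
    node: str,
    seed: int,
    variant: str = "main",
    global_thickness: np.ndarray | None = None,
) -> TestResult:
    coef, t, df = fit_case_control_model(y, subjects, variant, global_thickness)
    p, _ = permutation_pvalue(
        y,
        subjects,
        variant,
        n_perm=config.n_permutations,
        rng_seed=seed,
        within_dataset=config.within_dataset_permutation,
        global_thickness=global_thickness,
    )
    des = _build_design(y, subjects, variant, global_thickness)
    d = cohens_d_from_t(t, des.n_cases, des.n_controls, df)
    return TestResult(
        tier=tier,
        metric=metric,
        node=node,
        n_cases=des.n_cases,
        n_controls=des.n_controls,
        coefficient=coef,
        t=t,
        cohens_d=d,
        p_empirical=p,
    )


def _finalize_tier(results: list[TestResult], tier: str, config: AnalysisConfig) -> None:
    adj, sig = adjust_pvalues(
        np.array([r.p_empirical for r in results]), tier, config
    )
    for r, a, s in zip(results, adj, sig):
        r.p_adjusted = float(a)
        r.significant = bool(s)


def run_node_level_analysis(
    table: ThicknessTable,
    subjects: list[Subject],
    config: AnalysisConfig | None = None,
    panel: MetricPanel | None = None,
    node_metrics: tuple[str, ...] = NODE_METRICS,
    hemisphere_level: bool = True,
    variant: str = "main",
    follow_up_unilateral: bool = True,
) -> list[TestResult]:
    """The main analysis: 3 hemisphere-level + 4 x 34 node-level HD tests.

    Returns main-tier results (139 with all metrics) followed by
    uncorrected unilateral follow-up fits for every significant HD.
    """
    config = config or AnalysisConfig()
    if panel is None:
        panel = compute_metric_panel(
            table, subjects, config,
            node_metrics=node_metrics, hemisphere_level=hemisphere_level,
        )
    global_thickness = (
        table.global_mean() if variant == "global_thickness" else None
    )
    ss = np.random.SeedSequence(config.rng_seed)
    # one deterministic permutation seed per (metric, node) label
    seed_for = {}
    labels = [("hemisphere", m, "hemisphere") for m in HEMISPHERE_METRICS] + [
        ("node", m, r) for m in NODE_METRICS for r in DK_REGIONS
    ]
    for (tier, m, r), s in zip(labels, ss.generate_state(len(labels))):
        seed_for[(m, r)] = int(s % (2**31))

    results: list[TestResult] = []
    if hemisphere_level:
        hemi_results = [
            _one_test(
                panel.hemi_hd(m), subjects, config, "hemisphere", m, "hemisphere",
                seed_for[(m, "hemisphere")], variant, global_thickness,
            )
            for m in HEMISPHERE_METRICS
        ]
        _finalize_tier(hemi_results, "hemisphere", config)
        results.extend(hemi_results)

    for m in node_metrics:
        node_results = [
            _one_test(
                panel.node_hd(m, i), subjects, config, "node", m, region,
                seed_for[(m, region)], variant, global_thickness,
            )
            for i, region in enumerate(DK_REGIONS)
        ]
        _finalize_tier(node_results, "node", config)
        results.extend(node_results)

    if follow_up_unilateral:
        results.extend(
            run_unilateral_followup(panel, subjects, config, results, variant, global_thickness)
        )
    return results


def run_unilateral_followup(
    panel: MetricPanel,
    subjects: list[Subject],
    config: AnalysisConfig,
    main_results: list[TestResult],
    variant: str = "main",
    global_thickness: np.ndarray | None = None,
) -> list[TestResult]:
    """Uncorrected left-only / right-only models for significant HDs."""
    out = []
    counter = 0
    for r in main_results:
        if not r.significant or r.tier not in ("hemisphere", "node"):
            continue
        for hemi, label in (("L", "left"), ("R", "right")):
            if r.tier == "hemisphere":
                y = panel.hemi_values[r.metric][hemi]
            else:
                y = panel.node_values[r.metric][hemi][:, DK_REGIONS.index(r.node)]
            ss = np.random.SeedSequence((config.rng_seed, 1, counter))
            counter += 1
            seed = int(ss.generate_state(1)[0] % (2**31))
            res = _one_test(
                y, subjects, config, "unilateral", f"{r.metric}_{label}", r.node,
                seed, variant, global_thickness,
            )
            out.append(res)
    if out:
        _finalize_tier(out, "unilateral", config)
    return out


WITHIN_CASE_VARIABLES = ("ados", "medication", "iq", "age", "sex", "handedness")


def run_within_case_models(
    panel: MetricPanel,
    subjects: list[Subject],
    config: AnalysisConfig,
    significant: list[TestResult],
    variables: tuple[str, ...] = WITHIN_CASE_VARIABLES,
    min_n: int = 20,
) -> tuple[list[TestResult], list[str]]:
    """Clinical-variable models among cases for the significant HDs.

    For each significant HD and each variable: HD ~ variable + age + sex
    + (1 | dataset) among cases only, the variable's own term dropped
    from the covariates when it is age or sex. Variables with fewer than
    ``min_n`` non-missing cases are skipped with a logged reason (second
    return value).
    """
    case_idx = [i for i, s in enumerate(subjects) if s.is_case]
    cases = [subjects[i] for i in case_idx]
    results: list[TestResult] = []
    skipped: list[str] = []
    counter = 0

    def get_var(name: str) -> np.ndarray:
        pull = {
            "ados": lambda s: s.ados_total,
            "medication": lambda s: s.medication,
            "iq": lambda s: s.iq,
            "age": lambda s: s.age,
            "sex": lambda s: None if s.sex is None else float(s.sex == "M"),
            "handedness": lambda s: None if s.handedness is None else float(s.handedness == "R"),
        }[name]
        return np.array(
            [np.nan if pull(s) is None else float(pull(s)) for s in cases]
        )

    for r in significant:
        if r.tier == "hemisphere":
            hd = panel.hemi_hd(r.metric)[case_idx]
        else:
            hd = panel.node_hd(r.metric, DK_REGIONS.index(r.node))[case_idx]
        for var in variables:
            focal = get_var(var)
            ok = np.isfinite(focal) & np.isfinite(hd)
            if ok.sum() < min_n:
                reason = (
                    f"{var} for {r.metric}/{r.node}: only {int(ok.sum())} "
                    f"non-missing cases (< {min_n})"
                )
                logger.info("skipping within-case model: %s", reason)
                skipped.append(reason)
                continue
            drop = var if var in ("age", "sex") else None
            seed = int(
                np.random.SeedSequence((config.rng_seed, 2, counter)).generate_state(1)[0]
                % (2**31)
            )
            counter += 1
            des = _build_design(hd, cases, "main", focal=focal, drop_covariate=drop)
            fit = fit_random_intercept(
                np.column_stack([des.diag, des.F]), des.y, des.groups
            )
            p, t_obs = permutation_pvalue(
                hd, cases, "main",
                n_perm=config.n_permutations, rng_seed=seed,
                within_dataset=config.within_dataset_permutation,
                focal=focal, drop_covariate=drop,
            )
            binary_var = set(np.unique(focal[np.isfinite(focal)])) <= {0.0, 1.0}
            if binary_var:
                n1 = int(np.nansum(focal == 1))
                n0 = int(np.nansum(focal == 0))
                d = cohens_d_from_t(t_obs, n1, n0, fit.df) if n1 and n0 else float("nan")
            else:
                d = float("nan")
            results.append(
                TestResult(
                    tier="within-case",
                    metric=f"{r.metric}~{var}",
                    node=r.node,
                    n_cases=int(ok.sum()),
                    n_controls=0,
                    coefficient=float(fit.beta[0]),
                    t=t_obs,
                    cohens_d=d,
                    p_empirical=p,
                )
            )
    if results:
        _finalize_tier(results, "within-case", config)
    return results, skipped
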