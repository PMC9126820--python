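"""Synthetic multi-site cohort generator.

Emulates the statistical structure the asymmetry analysis assumes:
several datasets of heterogeneous size acquired on different scanners
(per-dataset additive offsets), control-defined regional means and SDs,
bilateral age and sex effects, a shared within-subject factor that
creates positive inter-regional thickness covariance, and an injectable
group difference in inter-regional coupling for chosen regions of one
hemisphere.

The coupling mechanism is a convex pull of a region's thickness toward
the subject's own hemispheric mean: ``t' = (1 - alpha) * t + alpha *
mean_h(t)``. Pulling a region toward the hemisphere mean shrinks its
standardized distance to every other region, which raises the similarity
rank of its edges and hence its degree once networks are thresholded, so
an injected effect must survive the entire pipeline (standardization ->
similarity -> sparsity -> graph metrics) to be detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import Subject, ThicknessTable
from .regions import DK_REGIONS, N_REGIONS, all_region_columns, region_index

import pandas as pd

#: map (region base name, hemisphere, diagnosis group) -> coupling alpha
CouplingMap = Mapping[tuple[str, str, str], float]


@dataclass
class SimConfig:
    """Parameters of the cohort generator.

    ``n_cases`` / ``n_controls`` may be a single int (every dataset the
    same size) or one int per dataset. All thickness-scale parameters are
    in mm; ``age_slope`` is mm per year and applies bilaterally, as do
    the sex effect and the dataset offsets, so none of them induces
    asymmetry on their own.
    """

    n_datasets: int = 5
    n_cases: int | Sequence[int] = 12
    n_controls: int | Sequence[int] = 12
    region_mean_range: tuple[float, float] = (1.8, 3.2)
    region_sd: float = 0.15
    dataset_offset_sd: float = 0.10
    subject_global_sd: float = 0.12
    age_range: tuple[float, float] = (6.0, 30.0)
    age_ref: float = 15.0
    age_slope: float = -0.01
    sex_effect: float = 0.03
    coupling_alpha: CouplingMap = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("region_sd", "dataset_offset_sd", "subject_global_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for key, alpha in self.coupling_alpha.items():
            if not 0 <= alpha <= 1:
                raise ValueError(f"coupling alpha must be in [0, 1], got {alpha} for {key}")
            region, hemi, group = key
            region_index(region)  # raises on unknown region
            if hemi not in ("L", "R") or group not in ("case", "control"):
                raise ValueError(f"bad coupling key {key}")

    def per_dataset(self, value: int | Sequence[int]) -> list[int]:
        if isinstance(value, int):
            return [value] * self.n_datasets
        value = list(value)
        if len(value) != self.n_datasets:
            raise ValueError(
                f"need {self.n_datasets} per-dataset sizes, got {len(value)}"
            )
        return value


def generate_cohort(config: SimConfig) -> tuple[ThicknessTable, list[Subject]]:
    """Simulate one multi-site cohort. Deterministic given ``rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    n_cases = config.per_dataset(config.n_cases)
    n_controls = config.per_dataset(config.n_controls)
    if any(n < 2 for n in n_controls):
        raise ValueError(
            "every dataset needs >= 2 controls (control SD is otherwise undefined)"
        )

    lo, hi = config.region_mean_range
    # One mean per region, shared by hemispheres and datasets: homotopic
    # regions are exchangeable unless a coupling is injected.
    mu = rng.uniform(lo, hi, size=N_REGIONS)

    rows, subjects = [], []
    for d in range(config.n_datasets):
        dataset_id = f"site{d + 1:02d}"
        offset = rng.normal(0.0, config.dataset_offset_sd)
        groups = ["case"] * n_cases[d] + ["control"] * n_controls[d]
        for k, group in enumerate(groups):
            sid = f"{dataset_id}_{'p' if group == 'case' else 'c'}{k + 1:03d}"
            age = rng.uniform(*config.age_range)
            sex = "M" if rng.random() < 0.5 else "F"
            g_k = rng.normal(0.0, config.subject_global_sd)
            base = (
                mu
                + offset
                + config.age_slope * (age - config.age_ref)
                + (config.sex_effect if sex == "M" else 0.0)
                + g_k
            )
            hemis = {
                h: base + rng.normal(0.0, config.region_sd, size=N_REGIONS)
                for h in ("L", "R")
            }
            # Convex coupling toward the subject's pre-coupling hemispheric
            # mean *profile*: regional baselines mu differ by up to ~1 mm,
            # so the pull acts on deviations from mu (otherwise it would
            # mostly relocate the region rather than couple it).
            for h in ("L", "R"):
                dev = hemis[h] - mu
                dev_mean = dev.mean()
                for (region, hemi, grp), alpha in config.coupling_alpha.items():
                    if hemi == h and grp == group and alpha > 0:
                        i = region_index(region)
                        hemis[h][i] = mu[i] + (1 - alpha) * dev[i] + alpha * dev_mean
            rows.append(np.concatenate([hemis["L"], hemis["R"]]))

            clinical = {}
            if group == "case":
                clinical = dict(
                    ados_total=float(max(0.0, rng.normal(12.0, 4.0))),
                    medication=int(rng.random() < 0.4),
                    iq=float(rng.normal(105.0, 15.0)),
                    handedness="R" if rng.random() < 0.9 else "L",
                )
            subjects.append(
                Subject(
                    subject_id=sid,
                    dataset_id=dataset_id,
                    diagnosis=group,
                    age=float(age),
                    sex=sex,
                    **clinical,
                )
            )

    frame = pd.DataFrame(
        np.asarray(rows),
        index=pd.Index([s.subject_id for s in subjects], name="subject_id"),
        columns=all_region_columns(),
    )
    return ThicknessTable(frame), subjects


FIXTURE_SEED = 20_220_208  # frozen; fixtures are versioned by this seed

_FIXTURES = {
    "tiny": dict(n_datasets=2, n_cases=3, n_controls=3),
    "null": dict(n_datasets=5, n_cases=6, n_controls=6),
    "effect": dict(
        n_datasets=5,
        n_cases=40,
        n_controls=40,
        coupling_alpha={("fusiform", "R", "case"): 0.6},
    ),
}


def make_fixture(
    name: str, rng_seed: int = FIXTURE_SEED
) -> tuple[ThicknessTable, list[Subject]]:
    """Canned cohorts for tests and demos.

    ``tiny``: 2 datasets x 6 subjects for smoke tests. ``null``: 5
    datasets, 60 subjects, no injected coupling. ``effect``: 5 datasets,
    200 cases + 200 controls, right-fusiform coupling alpha = 0.6 in
    cases only.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    return generate_cohort(SimConfig(rng_seed=rng_seed, **_FIXTURES[name]))
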