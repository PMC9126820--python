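"""Per-subject hemispheric structural covariance network construction.

Each subject contributes two 34-node networks, one per hemisphere. The
subject's regional thickness values are first standardized against the
mean and sample SD of the *controls of the subject's own dataset* (so
scanner and protocol differences cancel within dataset); the edge weight
between regions ``i`` and ``j`` is then a similarity of the two
standardized values,

    w_ij = exp(-(z_i - z_j)^2 / 2),

a Gaussian kernel on the z-difference. Networks are binarized by keeping
the ``floor(S * 561)`` strongest edges (224 at the default sparsity
S = 0.4); because thresholding only uses the *ranks* of the weights, any
strictly decreasing function of |z_i - z_j| yields the identical binary
topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .io import Subject, ThicknessTable
from .regions import DK_REGIONS, N_EDGES, N_REGIONS, all_region_columns

__all__ = [
    "ControlReference",
    "HemiNetwork",
    "compute_control_reference",
    "standardize",
    "gaussian_similarity",
    "build_weighted_network",
    "build_weighted_networks",
    "binarize_by_sparsity",
    "retained_edges",
    "triu_pairs",
]

POOLED_KEY = "__pooled__"


@dataclass
class ControlReference:
    """Per-dataset control mean and sample SD for each of the 68 regions.

    ``means`` and ``sds`` are DataFrames indexed by ``dataset_id`` with
    the 68 canonical region columns. A pooled reference stores a single
    row under :data:`POOLED_KEY`.
    """

    means: pd.DataFrame
    sds: pd.DataFrame
    pooled: bool = False

    def for_dataset(self, dataset_id: str) -> tuple[np.ndarray, np.ndarray]:
        key = POOLED_KEY if self.pooled else dataset_id
        if key not in self.means.index:
            raise KeyError(f"no control reference for dataset {dataset_id!r}")
        return self.means.loc[key].to_numpy(), self.sds.loc[key].to_numpy()


@dataclass
class HemiNetwork:
    """One subject's 34-node network for one hemisphere."""

    subject_id: str
    hemisphere: str
    weights: np.ndarray
    binary: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (N_REGIONS, N_REGIONS):
            raise ValueError(f"weights must be {N_REGIONS}x{N_REGIONS}, got {w.shape}")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        self.weights = w


def compute_control_reference(
    table: ThicknessTable, subjects: list[Subject], pooled: bool = False
) -> ControlReference:
    """Control-only mean and sample SD (ddof=1) per dataset and region.

    Raises if any dataset has fewer than 2 controls or any region whose
    controls are all identical (SD would be 0 and z undefined).
    """
    cols = all_region_columns()
    frame = table.data
    is_control = pd.Series(
        [s.diagnosis == "control" for s in subjects],
        index=[s.subject_id for s in subjects],
    )
    dataset = pd.Series(
        [s.dataset_id for s in subjects], index=[s.subject_id for s in subjects]
    )
    controls = frame.loc[is_control.reindex(frame.index).fillna(False)]
    if pooled:
        groups = {POOLED_KEY: controls}
    else:
        groups = dict(iter(controls.groupby(dataset.reindex(controls.index))))
        for ds in dataset.unique():
            if ds not in groups:
                raise ValueError(f"dataset {ds!r} has no controls")

    means, sds = {}, {}
    for ds, sub in groups.items():
        if len(sub) < 2:
            raise ValueError(
                f"dataset {ds!r} has {len(sub)} control(s); need >= 2 for a sample SD"
            )
        m = sub.mean(axis=0)
        s = sub.std(axis=0, ddof=1)
        zero = s[s == 0]
        if len(zero):
            raise ValueError(
                f"control SD is zero in dataset {ds!r} for region(s): "
                f"{', '.join(zero.index[:5])}"
            )
        means[ds], sds[ds] = m, s
    return ControlReference(
        means=pd.DataFrame(means).T[cols],
        sds=pd.DataFrame(sds).T[cols],
        pooled=pooled,
    )


def standardize(
    table: ThicknessTable, subjects: list[Subject], ref: ControlReference
) -> pd.DataFrame:
    """z = (t - control_mean) / control_sd, per subject's own dataset."""
    dataset = {s.subject_id: s.dataset_id for s in subjects}
    out = np.empty_like(table.data.to_numpy())
    for i, sid in enumerate(table.subject_ids):
        mean, sd = ref.for_dataset(dataset[sid])
        out[i] = (table.data.iloc[i].to_numpy() - mean) / sd
    return pd.DataFrame(out, index=table.data.index, columns=table.data.columns)


def gaussian_similarity(absdiff: np.ndarray) -> np.ndarray:
    """Similarity kernel on |z_i - z_j|; 1 at zero difference."""
    return np.exp(-(absdiff**2) / 2.0)


def build_weighted_network(
    z_row: np.ndarray,
    kernel: Callable[[np.ndarray], np.ndarray] = gaussian_similarity,
) -> np.ndarray:
    """34x34 symmetric similarity matrix from one hemisphere's 34 z-values."""
    z = np.asarray(z_row, dtype=float)
    if z.shape != (N_REGIONS,):
        raise ValueError(f"expected {N_REGIONS} z-values, got shape {z.shape}")
    if not np.all(np.isfinite(z)):
        raise ValueError("z-values must be finite")
    w = kernel(np.abs(z[:, None] - z[None, :]))
    np.fill_diagonal(w, 0.0)
    return w


def build_weighted_networks(
    z: np.ndarray,
    kernel: Callable[[np.ndarray], np.ndarray] = gaussian_similarity,
) -> np.ndarray:
    """(n, 34, 34) stack of weighted networks from an (n, 34) z-array."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("z-values must be finite")
    w = kernel(np.abs(z[:, :, None] - z[:, None, :]))
    idx = np.arange(z.shape[1])
    w[:, idx, idx] = 0.0
    return w


_TRIU = np.triu_indices(N_REGIONS, k=1)


def triu_pairs(n: int = N_REGIONS) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle node pairs in lexicographic order."""
    return np.triu_indices(n, k=1)


def retained_edges(sparsity: float, n_nodes: int = N_REGIONS) -> int:
    """Number of edges kept at a sparsity threshold: floor(S * pairs)."""
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(sparsity * n_pairs))


def binarize_by_sparsity(weights: np.ndarray, sparsity: float) -> np.ndarray:
    """Keep the strongest ``floor(S * n_pairs)`` edges of one network.

    Ties are broken deterministically: stable sort by weight descending,
    then lexicographic node-pair order. Accepts a single (N, N) matrix or
    an (n, N, N) stack.
    """
    w = np.asarray(weights, dtype=float)
    single = w.ndim == 2
    if single:
        w = w[None]
    n_nodes = w.shape[-1]
    m = retained_edges(sparsity, n_nodes)
    iu, ju = triu_pairs(n_nodes)
    flat = w[:, iu, ju]  # (n, n_pairs), lexicographic pair order
    order = np.argsort(-flat, axis=1, kind="stable")
    keep = order[:, :m]
    binary = np.zeros_like(w)
    rows = np.repeat(np.arange(w.shape[0]), m)
    binary[rows, iu[keep.ravel()], ju[keep.ravel()]] = 1.0
    binary += np.transpose(binary, (0, 2, 1))
    return binary[0] if single else binary
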