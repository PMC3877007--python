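"""Ward clustering of compound potency fingerprints.

Compounds are clustered by their IC50 profile across the cell-line panel,
on a log10 scale by default, using Ward agglomeration (each merge minimizes
the increase in total within-cluster sum of squared deviations) over
Euclidean distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

__all__ = [
    "PotencyMatrix",
    "LinkageTree",
    "transform_potency",
    "ward_cluster",
    "cluster_assignments",
    "to_newick",
]


@dataclass(frozen=True)
class PotencyMatrix:
    """Compounds x cell-lines IC50 grid (µM) with censoring flags.

    ``values`` holds IC50s; censored entries hold their bounding
    concentration (the ">X" bound) with ``censored`` True; missing entries
    are NaN.
    """

    values: pd.DataFrame
    censored: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.censored.shape:
            raise ValueError("values and censored must have identical shape")
        if not self.values.index.equals(self.censored.index) or not (
            self.values.columns.equals(self.censored.columns)
        ):
            raise ValueError("values and censored must share labels")
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise ValueError("IC50s and censoring bounds must be positive")

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_values(cls, values: pd.DataFrame) -> "PotencyMatrix":
        """Uncensored matrix from a plain numeric frame."""
        censored = pd.DataFrame(
            False, index=values.index, columns=values.columns
        )
        return cls(values=values.astype(float), censored=censored)


@dataclass(frozen=True)
class LinkageTree:
    """Agglomeration result: a scipy-format merge list plus leaf labels.

    Each merge row is (cluster id, cluster id, height, new size); leaves
    are ids 0..n-1 in label order, internal nodes n, n+1, ...
    """

    merges: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.merges.shape != (n - 1, 4):
            raise ValueError("merge list must have n-1 rows of 4 columns")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("Ward merge heights must be non-decreasing")


def transform_potency(
    pm: PotencyMatrix,
    log10: bool = True,
    censor_policy: str = "impute_at_bound",
    standardize: bool = False,
) -> pd.DataFrame:
    """Numeric clustering input from a potency matrix.

    Censored entries are either imputed at their bound (default) or the
    whole cell line is dropped for all compounds; lines with missing
    entries are always dropped (complete cases only).
    """
    if censor_policy not in ("impute_at_bound", "drop_line"):
        raise ValueError(f"unknown censor_policy {censor_policy!r}")
    values = pm.values.copy()
    if censor_policy == "drop_line":
        keep = ~pm.censored.any(axis=0)
        values = values.loc[:, keep]
    values = values.dropna(axis=1, how="any")
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError(
            "need >= 2 compounds and >= 2 complete cell lines after the "
            "censoring policy"
        )
    out = np.log10(values) if log10 else values
    if standardize:
        out = out.sub(out.mean(axis=1), axis=0).div(out.std(axis=1, ddof=0), axis=0)
    return out


def ward_cluster(matrix: pd.DataFrame) -> LinkageTree:
    """Ward linkage over Euclidean distances between compound profiles."""
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 compounds to cluster")
    if np.isnan(X).any():
        raise ValueError("clustering input must not contain missing values")
    Z = hierarchy.linkage(X, method="ward")
    return LinkageTree(merges=Z, labels=tuple(str(i) for i in matrix.index))


def cluster_assignments(tree: LinkageTree, k: int) -> dict[str, int]:
    """Flat clusters from cutting the tree into k groups."""
    if not 1 <= k <= len(tree.labels):
        raise ValueError("k must be between 1 and the number of leaves")
    flat = hierarchy.fcluster(tree.merges, t=k, criterion="maxclust")
    return {label: int(c) for label, c in zip(tree.labels, flat)}


def _escape(label: str) -> str:
    return label.replace(" ", "_").replace("(", "").replace(")", "").replace(",", "_").replace(":", "_").replace(";", "_")


def to_newick(tree: LinkageTree) -> str:
    """Newick serialization; branch length = parent height - child height."""
    n = len(tree.labels)
    reps: dict[int, str] = {i: _escape(lab) for i, lab in enumerate(tree.labels)}
    heights: dict[int, float] = {i: 0.0 for i in range(n)}
    node = n - 1
    for j, (a, b, h, _) in enumerate(tree.merges):
        a, b = int(a), int(b)
        node = n + j
        bl_a = h - heights[a]
        bl_b = h - heights[b]
        reps[node] = f"({reps[a]}:{bl_a:.10g},{reps[b]}:{bl_b:.10g})"
        heights[node] = h
    return reps[node] + ";"
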