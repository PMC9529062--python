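"""Clonal inference from longitudinal VAF trajectories.

Mutations whose VAFs move together across timepoints are taken to reside in
the same clone: trajectories are log10-transformed (with a pseudocount so
absent calls at 1e-4-scale VAFs stay on scale), clustered hierarchically and
cut at a configurable height. Clusters need at least two member mutations to
count as a clone. Clone prevalence is twice the mean member VAF
(heterozygous diploid); ancestry is then read off by containment — an
ancestor's prevalence must cover its descendant's at every timepoint the
descendant exists — and a formerly minor clone that ends dominant is flagged
as a selective sweep.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch

from .simulate import Clone, CloneTree, CloneTreeError

__all__ = [
    "TrajectoryMatrix",
    "InferredClone",
    "ClusterResult",
    "TreeResult",
    "SweepEvent",
    "RelativeFraction",
    "cluster_trajectories",
    "build_clone_tree",
    "detect_sweeps",
    "relative_subclone_fraction",
]


class TrajectoryMatrix:
    """Mutations x timepoints VAF table (NaN = missing, imputed as 0 on use).

    ``tiers`` optionally annotates each cell with its evidence tier
    ("DCS" or "SSCS_rescue") for bookkeeping of low-coverage timepoints.
    """

    def __init__(self, frame: pd.DataFrame, tiers: Optional[pd.DataFrame] = None):
        if frame.shape[1] < 2:
            raise ValueError("at least 2 timepoints required")
        vals = frame.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("VAFs must lie in [0, 1]")
        self.frame = frame.astype(float)
        if tiers is not None and (tiers.shape != frame.shape):
            raise ValueError("tier annotation shape mismatch")
        self.tiers = tiers

    @property
    def mutations(self) -> List[str]:
        return list(self.frame.index)

    @property
    def timepoints(self) -> List[Hashable]:
        return list(self.frame.columns)

    def imputed(self) -> Tuple[pd.DataFrame, pd.DataFrame]:
        """(VAFs with NaN as 0, boolean mask of imputed cells)."""
        mask = self.frame.isna()
        return self.frame.fillna(0.0), mask

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="mutation")

    @classmethod
    def from_tsv(cls, path) -> "TrajectoryMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="mutation")
        return cls(frame)


@dataclass
class InferredClone:
    id: str
    members: List[str]
    prevalence: Dict[Hashable, float]  # 2 x mean member VAF, clipped to [0, 1]
    parent: Optional[str] = None

    def mean_prevalence(self) -> float:
        return float(np.mean(list(self.prevalence.values())))


@dataclass
class ClusterResult:
    clones: List[InferredClone]
    unassigned: List[str]
    assignments: Dict[str, Optional[str]]
    linkage: Optional[np.ndarray] = None
    imputed_cells: Optional[pd.DataFrame] = None


def cluster_trajectories(
    matrix: TrajectoryMatrix,
    *,
    cut_height: float = 0.8,
    pseudocount: float = 1e-5,
    metric: str = "euclidean",
    method: str = "average",
    min_members: int = 2,
    prevalence_stat: str = "mean",
    timepoint_weights: Optional[Mapping[Hashable, float]] = None,
) -> ClusterResult:
    """Cluster mutation trajectories into clones.

    Average-linkage hierarchical clustering on Euclidean distance between
    log10(VAF + pseudocount) trajectories, cut at ``cut_height``. Clusters
    smaller than ``min_members`` are reported as unassigned, never as clones.
    ``timepoint_weights`` down-weights low-confidence timepoints (e.g. VAFs
    sourced from SSCS rescue at a low-coverage sample) by scaling their
    column before the distance computation.
    """
    vafs, mask = matrix.imputed()
    muts = matrix.mutations
    X = np.log10(vafs.to_numpy() + pseudocount)
    if timepoint_weights is not None:
        w = np.array([float(timepoint_weights.get(t, 1.0)) for t in matrix.timepoints])
        if (w < 0).any():
            raise ValueError("timepoint weights must be >= 0")
        X = X * np.sqrt(w)[None, :]

    if len(muts) == 1:
        labels = np.array([1])
        Z = None
    else:
        Z = sch.linkage(X, method=method, metric=metric)
        labels = sch.fcluster(Z, t=cut_height, criterion="distance")

    groups: Dict[int, List[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)

    stat = {"mean": np.mean, "median": np.median}[prevalence_stat]
    clones: List[InferredClone] = []
    unassigned: List[str] = []
    assignments: Dict[str, Optional[str]] = {}
    kept = []
    for lab, idxs in groups.items():
        if len(idxs) < min_members:
            for i in idxs:
                unassigned.append(muts[i])
                assignments[muts[i]] = None
            continue
        kept.append(idxs)

    # stable clone naming: C1 = highest mean prevalence
    def clone_prev(idxs: List[int]) -> Dict[Hashable, float]:
        sub = vafs.iloc[idxs]
        return {t: float(min(2.0 * stat(sub[t].to_numpy()), 1.0)) for t in matrix.timepoints}

    kept.sort(key=lambda idxs: -float(np.mean(list(clone_prev(idxs).values()))))
    for rank, idxs in enumerate(kept, start=1):
        cid = f"C{rank}"
        members = [muts[i] for i in idxs]
        clones.append(InferredClone(cid, members, clone_prev(idxs)))
        for m in members:
            assignments[m] = cid
    return ClusterResult(clones=clones, unassigned=sorted(unassigned),
                         assignments=assignments, linkage=Z, imputed_cells=mask)


@dataclass
class TreeResult:
    tree: CloneTree
    violations: List[str]


def build_clone_tree(
    clones: Sequence[InferredClone],
    tolerance: float = 0.05,
    presence_threshold: float = 0.0,
) -> TreeResult:
    """Assemble inferred clones into a rooted tree by prevalence containment.

    X is a candidate ancestor of Y iff prevalence(X) >= prevalence(Y) -
    tolerance at every timepoint where Y is present; among candidates the one
    with minimal mean prevalence becomes the parent. Sibling prevalence sums
    exceeding the parent are reported as violations, not repaired. Raises
    :class:`CloneTreeError` when no single root exists.
    """
    if not clones:
        raise CloneTreeError("no clones to build a tree from")
    timepoints = list(clones[0].prevalence)

    def is_ancestor(x: InferredClone, y: InferredClone) -> bool:
        for t in timepoints:
            if y.prevalence[t] > presence_threshold:
                if x.prevalence[t] < y.prevalence[t] - tolerance:
                    return False
        return True

    ancestors: Dict[str, List[InferredClone]] = {c.id: [] for c in clones}
    for x in clones:
        for y in clones:
            if x.id == y.id:
                continue
            if is_ancestor(x, y):
                if is_ancestor(y, x):
                    # mutual containment within tolerance: the larger clone
                    # (ties broken lexicographically) is treated as ancestor
                    mx, my = x.mean_prevalence(), y.mean_prevalence()
                    if mx < my or (mx == my and x.id > y.id):
                        continue
                ancestors[y.id].append(x)

    parents: Dict[str, Optional[str]] = {}
    for c in clones:
        cand = ancestors[c.id]
        parents[c.id] = (min(cand, key=lambda a: (a.mean_prevalence(), a.id)).id
                         if cand else None)
    roots = [cid for cid, p in parents.items() if p is None]
    if len(roots) != 1:
        raise CloneTreeError(
            f"no single root: {len(roots)} clones have no containing ancestor")

    tree_clones = [
        Clone(c.id, parents[c.id], dict(c.prevalence), mutations=list(c.members))
        for c in clones
    ]
    tree = CloneTree(tree_clones, timepoints, validate=False)
    violations = tree.nesting_violations(tol=tolerance)
    for c in clones:
        c.parent = parents[c.id]
    return TreeResult(tree=tree, violations=violations)


@dataclass
class SweepEvent:
    """A clone rising from minor to dominant: the selective-sweep signature."""

    clone: str
    start: Hashable  # last timepoint still below the minor threshold
    end: Hashable    # first timepoint above the dominance threshold
    prevalence_before: float
    prevalence_after: float


def detect_sweeps(
    tree: CloneTree,
    matrix: Optional[TrajectoryMatrix] = None,
    minor_threshold: float = 0.05,
    dominance_threshold: float = 0.5,
) -> List[SweepEvent]:
    """Report clones below ``minor_threshold`` at every timepoint up to some
    point that later exceed ``dominance_threshold``.

    Prevalences come from the tree; ``matrix`` optionally recomputes a
    clone's trajectory as twice the mean member VAF when supplied.
    """
    if dominance_threshold <= minor_threshold:
        raise ValueError("dominance threshold must exceed the minor threshold")
    events: List[SweepEvent] = []
    for cid, clone in tree.clones.items():
        traj = [clone.prevalence[t] for t in tree.timepoints]
        if matrix is not None and clone.mutations:
            members = [m for m in clone.mutations if m in matrix.frame.index]
            if members:
                vafs, _ = matrix.imputed()
                traj = [float(min(2.0 * vafs.loc[members, t].mean(), 1.0))
                        for t in tree.timepoints]
        # longest initial run strictly below the minor threshold
        m = 0
        while m < len(traj) and traj[m] < minor_threshold:
            m += 1
        if m == 0 or m == len(traj):
            continue
        later = [j for j in range(m, len(traj)) if traj[j] > dominance_threshold]
        if not later:
            continue
        j = later[0]
        events.append(SweepEvent(
            clone=cid, start=tree.timepoints[m - 1], end=tree.timepoints[j],
            prevalence_before=traj[m - 1], prevalence_after=traj[j]))
    return events


@dataclass
class RelativeFraction:
    """A subclone's size expressed as percent of the major clone."""

    pct: Optional[float]
    defined: bool


def relative_subclone_fraction(subclone_prevalence: float,
                               major_prevalence: float) -> RelativeFraction:
    """Subclone prevalence as a percentage of the major clone's prevalence.

    Division by a zero major clone is flagged undefined, not raised.
    """
    if subclone_prevalence < 0 or major_prevalence < 0:
        raise ValueError("prevalences must be >= 0")
    if major_prevalence == 0:
        return RelativeFraction(pct=None, defined=False)
    return RelativeFraction(pct=100.0 * subclone_prevalence / major_prevalence, defined=True)
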