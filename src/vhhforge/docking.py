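"""Docked-pose ensemble analysis for epitope inference.

Per-pose interface extraction at a strict < 4 A atom-atom cutoff, two-stage
CDR-contact filtering, pairwise interface RMSD after antigen superposition,
density clustering on the precomputed distance matrix (eps = 9 A,
min_samples = 3 by default) with core/reachable/outlier status, and cluster
composition summaries.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .annotation import AntibodyAnnotation
from .structure import StructureModel, kabsch

__all__ = [
    "ComplexPose",
    "DomainDefinition",
    "InteractionSummary",
    "DistanceMatrix",
    "ClusteringResult",
    "interacting_residues",
    "filter_poses",
    "irmsd_matrix",
    "dbscan_precomputed",
    "summarize_clusters",
    "embed_2d",
]


@dataclass
class ComplexPose:
    """One docked antibody-antigen complex (distinct chains, one structure)."""

    pose_id: str
    model: StructureModel
    antibody_chain: str
    antigen_chain: str

    def __post_init__(self) -> None:
        chains = set(self.model.chains)
        if self.antibody_chain == self.antigen_chain:
            raise ValueError("antibody and antigen chains must differ")
        for c in (self.antibody_chain, self.antigen_chain):
            if c not in chains:
                raise ValueError(f"pose {self.pose_id}: chain {c!r} absent")


@dataclass
class DomainDefinition:
    """Ordered labels with author-numbered inclusive residue ranges on the
    antigen chain; ranges must not overlap."""

    domains: list  # [(label, start, end)] inclusive

    def __post_init__(self) -> None:
        self.domains = [(str(l), int(s), int(e)) for l, s, e in self.domains]
        for label, s, e in self.domains:
            if s > e:
                raise ValueError(f"domain {label}: start > end")
        spans = sorted((s, e) for _, s, e in self.domains)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("domain ranges must not overlap")

    @property
    def labels(self) -> list:
        return [l for l, _, _ in self.domains]

    def label_of(self, resnum: int) -> str | None:
        for label, s, e in self.domains:
            if s <= resnum <= e:
                return label
        return None


@dataclass
class InteractionSummary:
    pose_id: str
    antibody_residues: frozenset
    cdr_residues: frozenset
    antigen_residues: frozenset
    domain_counts: dict
    domain_class: str

    def __post_init__(self) -> None:
        if not self.cdr_residues <= self.antibody_residues:
            raise ValueError("CDR residues must be a subset of antibody residues")

    @property
    def n_cdr(self) -> int:
        return len(self.cdr_residues)


@dataclass
class DistanceMatrix:
    pose_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.pose_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match pose ids")
        if np.abs(self.values - self.values.T).max() > 1e-6:
            raise ValueError("matrix must be symmetric to 1e-6")
        if np.abs(np.diag(self.values)).max() != 0.0:
            raise ValueError("diagonal must be exactly zero")
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.pose_ids, columns=self.pose_ids)


@dataclass
class ClusteringResult:
    pose_ids: list
    labels: np.ndarray           # >= 0 or -1 for outliers
    status: list                 # "core" | "reachable" | "outlier"
    eps: float
    min_samples: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        for lab, st in zip(self.labels, self.status):
            if (lab >= 0) != (st in ("core", "reachable")):
                raise ValueError("status must be core/reachable iff label >= 0")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0

    def label_of(self, pose_id: str) -> int:
        return int(self.labels[self.pose_ids.index(pose_id)])


# ---------------------------------------------------------------------------
# Interface extraction


def _chain_residue_order(model: StructureModel, chain: str) -> list[int]:
    return [rn for _, rn, _, _, _ in model.residues(chain)]


def _cdr_resnum_set(pose: ComplexPose, annotation: AntibodyAnnotation) -> set[int]:
    """Map 0-based annotation span indices onto the antibody chain
    positionally (span index i <-> i-th residue of the chain)."""
    order = _chain_residue_order(pose.model, pose.antibody_chain)
    idx = annotation.cdr_index_set()
    if max(idx, default=-1) >= len(order):
        raise ValueError(
            f"pose {pose.pose_id}: annotation spans exceed antibody chain "
            f"length {len(order)}")
    return {order[i] for i in idx}


def interacting_residues(
    pose: ComplexPose,
    annotation: AntibodyAnnotation,
    domains: DomainDefinition,
    cutoff: float = 4.0,
) -> InteractionSummary:
    """Residue-level interface at a strict ``< cutoff`` all-atom criterion.

    An antibody residue interacts iff any of its atoms is at less than
    ``cutoff`` from any antigen atom (and symmetrically for the antigen);
    interacting antigen residues are tallied per annotated domain.
    """
    model = pose.model
    ab_mask = model.chain_mask(pose.antibody_chain)
    ag_mask = model.chain_mask(pose.antigen_chain)
    if not ab_mask.any() or not ag_mask.any():
        raise ValueError(f"pose {pose.pose_id}: empty chain")
    d = cdist(model.xyz[ab_mask], model.xyz[ag_mask])
    contact = d < cutoff  # strict
    ab_resnums = model.resnums[ab_mask]
    ag_resnums = model.resnums[ag_mask]
    ab_hit = frozenset(int(r) for r in ab_resnums[contact.any(axis=1)])
    ag_hit = frozenset(int(r) for r in ag_resnums[contact.any(axis=0)])
    cdr_set = _cdr_resnum_set(pose, annotation)
    cdr_hit = frozenset(r for r in ab_hit if r in cdr_set)

    counts = {label: 0 for label in domains.labels}
    for r in ag_hit:
        label = domains.label_of(r)
        if label is not None:
            counts[label] += 1
    hit_labels = [l for l in domains.labels if counts[l] > 0]
    if not hit_labels:
        domain_class = "none"
    elif len(hit_labels) == len(domains.labels):
        domain_class = "both"
    elif len(hit_labels) == 1:
        domain_class = "first" if hit_labels[0] == domains.labels[0] else "second"
    else:
        domain_class = "+".join(hit_labels)
    return InteractionSummary(pose.pose_id, ab_hit, cdr_hit, ag_hit, counts,
                              domain_class)


def filter_poses(summaries, min_cdr_contacts: int = 10) -> tuple[list, dict]:
    """Two-stage filter: drop poses whose CDRs make no antigen contact, then
    poses with fewer than ``min_cdr_contacts`` interacting CDR residues
    (the default mirrors the "less than ten" rule: 9 fails, 10 passes)."""
    summaries = list(summaries)
    report = {"input": len(summaries), "stage1_dropped": 0,
              "stage2_dropped": 0, "kept": 0}
    kept = []
    for s in summaries:
        if s.n_cdr == 0:
            report["stage1_dropped"] += 1
            continue
        if s.n_cdr < min_cdr_contacts:
            report["stage2_dropped"] += 1
            continue
        kept.append(s.pose_id)
    report["kept"] = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# Interface RMSD matrix


def _pose_arrays(pose: ComplexPose, annotation: AntibodyAnnotation):
    model = pose.model
    ag_ca = model.atom_coords(pose.antigen_chain, "CA")
    order = _chain_residue_order(model, pose.antibody_chain)
    idx = sorted(annotation.cdr_index_set())
    lookup = {}
    for i in range(model.n_atoms):
        if model.chains[i] == pose.antibody_chain and model.atom_names[i] == "CA":
            lookup[int(model.resnums[i])] = model.xyz[i]
    cdr_ca = []
    for i in idx:
        rn = order[i]
        if rn not in lookup:
            raise ValueError(
                f"pose {pose.pose_id}: CDR residue {pose.antibody_chain}:{rn} "
                f"missing CA atom")
        cdr_ca.append(lookup[rn])
    return ag_ca, np.array(cdr_ca)


def irmsd_matrix(poses, annotation: AntibodyAnnotation) -> DistanceMatrix:
    """Pairwise interface RMSD: superimpose pose j's antigen CA set onto pose
    i's, carry the antibody along, then RMSD over the CA atoms of all CDR
    residues.  Residue correspondence across poses is positional."""
    poses = list(poses)
    arrays = [_pose_arrays(p, annotation) for p in poses]
    n_ag = {a[0].shape[0] for a in arrays}
    n_cdr = {a[1].shape[0] for a in arrays}
    if len(n_ag) > 1 or len(n_cdr) > 1:
        raise ValueError("poses must share identical chain compositions")
    n = len(poses)
    mat = np.zeros((n, n))
    for i in range(n):
        ag_i, cdr_i = arrays[i]
        for j in range(i + 1, n):
            ag_j, cdr_j = arrays[j]
            transform, _ = kabsch(ag_j, ag_i)
            moved = transform.apply(cdr_j)
            diff = moved - cdr_i
            val = float(np.sqrt((diff ** 2).sum(axis=1).mean()))
            mat[i, j] = mat[j, i] = val
    return DistanceMatrix([p.pose_id for p in poses], mat)


# ---------------------------------------------------------------------------
# DBSCAN on a precomputed matrix


def dbscan_precomputed(matrix: DistanceMatrix, eps: float = 9.0,
                       min_samples: int = 3) -> ClusteringResult:
    """DBSCAN with the point counting itself towards min_samples.

    Core poses have >= min_samples poses within eps; clusters are connected
    components of cores under mutual <= eps reachability; non-core poses
    within eps of a core join as "reachable" (ties break to the lowest final
    cluster label).  Labels are renumbered 0..K-1 by decreasing cluster
    size, ties by smallest member index.
    """
    d = matrix.values
    n = d.shape[0]
    within = d <= eps
    core = within.sum(axis=1) >= min_samples  # diagonal counts the point itself

    labels = np.full(n, -1, dtype=int)
    comp = 0
    for start in range(n):
        if not core[start] or labels[start] >= 0:
            continue
        queue = deque([start])
        labels[start] = comp
        while queue:
            i = queue.popleft()
            for j in np.nonzero(within[i] & core)[0]:
                if labels[j] < 0:
                    labels[j] = comp
                    queue.append(int(j))
        comp += 1

    # renumber by decreasing size, ties by smallest member index
    sizes = [(int((labels == c).sum()), int(np.nonzero(labels == c)[0][0]), c)
             for c in range(comp)]
    sizes.sort(key=lambda t: (-t[0], t[1]))
    remap = {old: new for new, (_, _, old) in enumerate(sizes)}
    labels = np.array([remap[l] if l >= 0 else -1 for l in labels])

    status = ["outlier"] * n
    for i in range(n):
        if core[i]:
            status[i] = "core"
    for i in range(n):
        if core[i]:
            continue
        nbr_labels = {int(labels[j]) for j in np.nonzero(within[i] & core)[0]}
        if nbr_labels:
            labels[i] = min(nbr_labels)
            status[i] = "reachable"
    return ClusteringResult(list(matrix.pose_ids), labels, status, eps, min_samples)


# ---------------------------------------------------------------------------
# Summaries and embedding


def summarize_clusters(clustering: ClusteringResult, summaries) -> tuple[pd.DataFrame, dict]:
    """Cluster table (size, domain-class counts, core count) and an overall
    report including the ratio of both-domain poses among clustered poses
    outside the largest cluster."""
    by_id = {s.pose_id: s for s in summaries}
    classes = ("first", "second", "both", "none")
    rows = []
    labels = clustering.labels
    for c in range(clustering.n_clusters):
        member_ids = [pid for pid, l in zip(clustering.pose_ids, labels) if l == c]
        counts = {cls: 0 for cls in classes}
        other = 0
        for pid in member_ids:
            cls = by_id[pid].domain_class if pid in by_id else "none"
            if cls in counts:
                counts[cls] += 1
            else:
                other += 1
        core_n = sum(1 for pid, st, l in zip(clustering.pose_ids, clustering.status, labels)
                     if l == c and st == "core")
        rows.append({"cluster": c, "size": len(member_ids), "n_core": core_n,
                     **{f"class_{k}": v for k, v in counts.items()},
                     "class_other": other})
    table = pd.DataFrame(rows, columns=["cluster", "size", "n_core",
                                        *[f"class_{k}" for k in classes],
                                        "class_other"])

    n_outliers = int((labels == -1).sum())
    overall = {"n_poses": len(labels), "n_clusters": clustering.n_clusters,
               "n_outliers": n_outliers}
    if clustering.n_clusters > 0:
        largest = 0  # labels already sorted by decreasing size
        outside = [pid for pid, l in zip(clustering.pose_ids, labels)
                   if l >= 0 and l != largest]
        n_both = sum(1 for pid in outside
                     if pid in by_id and by_id[pid].domain_class == "both")
        overall.update({
            "largest_cluster": largest,
            "n_outside_largest": len(outside),
            "n_both_outside_largest": n_both,
            "both_fraction_outside_largest":
                (n_both / len(outside)) if outside else float("nan"),
        })
    return table, overall


def embed_2d(matrix: DistanceMatrix, seed: int = 0) -> np.ndarray:
    """Optional 2D layout of the distance matrix (t-SNE, fixed seed).

    Plotting plumbing only; nothing downstream may depend on it.
    """
    from sklearn.manifold import TSNE

    n = len(matrix.pose_ids)
    if n < 3:
        raise ValueError("need at least 3 poses to embed")
    perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
    tsne = TSNE(n_components=2, metric="precomputed", init="random",
                random_state=seed, perplexity=perplexity)
    return tsne.fit_transform(matrix.values)
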