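"""Proposing new conformer classes from unassigned steps.

Unassigned steps are clustered by complete-linkage agglomeration on
the circular Euclidean distance over the nine torsions; sufficiently
populated flat clusters are turned into *draft* class definitions for
manual curation. Drafts are never merged automatically into a shipped
reference.

The agglomeration is implemented directly (O(n^3), adequate for the
curation-scale inputs this is meant for) so that the merge order is
fully deterministic: when two pairs are equidistant the pair whose
(sorted) member-id tuple is lexicographically smallest merges first,
which makes the labelling invariant under permutation of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import circular_euclidean_distance
from .reference import GoldenSetMember, compute_class_statistics


@dataclass(frozen=True)
class ClusterResult:
    labels: dict[str, int]          # step id -> flat cluster index
    merge_heights: tuple[float, ...]  # complete-linkage height per merge
    cut_threshold: float


@dataclass(frozen=True)
class ClusterRejection:
    size: int
    min_size: int
    reason: str


def _distance_matrix(vectors) -> np.ndarray:
    n = len(vectors)
    angles = [v.angles() for v in vectors]
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = circular_euclidean_distance(angles[i],
                                                              angles[j])
    return dm


def cluster_steps(torsion_vectors, cut_threshold: float = 60.0,
                  ids=None) -> ClusterResult:
    """Complete-linkage clustering of step torsion vectors.

    Agglomerates until every inter-cluster complete-linkage distance
    exceeds ``cut_threshold``; the resulting flat clusters are numbered
    0.. in order of their smallest member id.
    """
    n = len(torsion_vectors)
    if n < 2:
        raise ValueError("need at least 2 torsion vectors to cluster")
    ids = list(ids) if ids is not None else [f"s{i:04d}" for i in range(n)]
    dm = _distance_matrix(torsion_vectors)

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    # complete linkage between current clusters
    link = dm.copy()
    heights: list[float] = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ai, a in enumerate(keys):
            for b in keys[ai + 1:]:
                d = link[a, b]
                tie_key = tuple(sorted(ids[i] for i in
                                       clusters[a] + clusters[b]))
                cand = (d, tie_key, a, b)
                if best is None or cand < best:
                    best = cand
        d, _, a, b = best
        if d > cut_threshold:
            break
        heights.append(float(d))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        for c in clusters:
            if c != a:
                link[a, c] = link[c, a] = max(link[a, c], link[b, c])

    ordered = sorted(clusters.values(), key=lambda idxs: min(ids[i]
                                                             for i in idxs))
    labels = {ids[i]: k for k, idxs in enumerate(ordered) for i in idxs}
    return ClusterResult(labels=labels, merge_heights=tuple(heights),
                         cut_threshold=float(cut_threshold))


def complete_linkage_heights(torsion_vectors) -> tuple[float, ...]:
    """All n-1 merge heights of the full dendrogram (cut at infinity)."""
    return cluster_steps(torsion_vectors,
                         cut_threshold=float("inf")).merge_heights


def propose_class(cluster_members, min_size: int = 10,
                  draft_id: str = "DRFT"):
    """Draft an NtcClassDefinition from a cluster, or reject it by size.

    The draft's statistics come from the same machinery that builds
    reference classes; its CANA letter is left as NAN since draft
    classes are not part of the alphabet until curated.
    """
    members = list(cluster_members)
    if len(members) < min_size:
        return ClusterRejection(size=len(members), min_size=min_size,
                                reason=f"cluster size {len(members)} below "
                                       f"minimum {min_size}")
    gsm = [GoldenSetMember(member_id=f"{draft_id}_{i:03d}",
                           ntc_class=draft_id, torsions=t)
           for i, t in enumerate(members)]
    stats = compute_class_statistics({draft_id: gsm},
                                     cana_map={draft_id: "NAN"})
    return stats[draft_id]
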