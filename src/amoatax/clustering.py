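"""Average-neighbour OTU clustering over the common coding frame.

Distances are column mismatch fractions over the shared frame; columns gapped
in either sequence are excluded from numerator and denominator (a mothur-like
one-gap simplification).  Clustering is agglomerative average linkage
(UPGMA-style) cut at 1 - identity, i.e. clusters keep merging while the mean
inter-cluster distance stays within the cutoff.  Representatives are medoids —
the member minimising mean distance to its co-members, ties broken by
lexicographically smallest id — which makes OTU picks reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .records import AlignedGene


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray  # square, symmetric, zero diagonal

    def __post_init__(self):
        self.index = {g: i for i, g in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.index[a], self.index[b]])


def _encoded(genes: list[AlignedGene]) -> np.ndarray:
    cols = {len(g.aligned_seq) for g in genes}
    if len(cols) > 1:
        raise ValueError(f"genes do not share a common frame: column counts {sorted(cols)}")
    return np.frombuffer("".join(g.aligned_seq for g in genes).encode(), dtype=np.uint8).reshape(
        len(genes), cols.pop()
    )


def sequence_identity(a: str, b: str) -> float:
    """Pairwise identity over shared columns, gap columns excluded."""
    if len(a) != len(b):
        raise ValueError("sequences must share the column frame")
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    gap = np.uint8(ord("-"))
    keep = (xa != gap) & (xb != gap)
    n = int(keep.sum())
    if n == 0:
        return 0.0
    return float((xa[keep] == xb[keep]).sum() / n)


def pairwise_distances(genes: list[AlignedGene], gap_policy: str = "exclude") -> DistanceMatrix:
    """Distance = 1 - matching/compared columns for every pair.

    ``exclude`` drops columns gapped in either sequence from the comparison;
    ``count`` treats a gap as a mismatching character.
    """
    if len(genes) < 2:
        warnings.warn("fewer than 2 genes: degenerate distance matrix", stacklevel=2)
    enc = _encoded(genes)
    n = len(genes)
    gap = np.uint8(ord("-"))
    mat = np.zeros((n, n), dtype=float)
    nongap = enc != gap
    for i in range(n):
        eq = enc[i + 1 :] == enc[i]
        if gap_policy == "exclude":
            keep = nongap[i + 1 :] & nongap[i]
            compared = keep.sum(axis=1)
            matches = (eq & keep).sum(axis=1)
        elif gap_policy == "count":
            compared = np.full(n - i - 1, enc.shape[1])
            matches = (eq & nongap[i + 1 :] & nongap[i]).sum(axis=1)
        else:
            raise ValueError(f"unknown gap_policy {gap_policy!r}")
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(compared > 0, 1.0 - matches / np.maximum(compared, 1), 1.0)
        mat[i, i + 1 :] = d
        mat[i + 1 :, i] = d
    return DistanceMatrix([g.id for g in genes], mat)


@dataclass(frozen=True)
class OtuCluster:
    otu_id: str
    representative: str
    members: tuple[str, ...]
    threshold: float


def _medoid(ids: list[str], dm: DistanceMatrix) -> str:
    idx = [dm.index[i] for i in ids]
    sub = dm.matrix[np.ix_(idx, idx)]
    means = sub.mean(axis=1)
    best = min(range(len(ids)), key=lambda k: (means[k], ids[k]))
    return ids[best]


def average_neighbour(dm: DistanceMatrix, threshold_identity: float) -> list[OtuCluster]:
    """Average-linkage clustering cut at distance 1 - threshold_identity."""
    cutoff = 1.0 - threshold_identity
    n = len(dm.ids)
    if n == 0:
        return []
    if n == 1:
        return [OtuCluster("OTU_0001", dm.ids[0], (dm.ids[0],), threshold_identity)]
    z = linkage(squareform(dm.matrix, checks=False), method="average")
    labels = fcluster(z, t=cutoff, criterion="distance")
    groups: dict[int, list[str]] = {}
    for gid, lab in zip(dm.ids, labels):
        groups.setdefault(int(lab), []).append(gid)
    # stable OTU numbering: by lexicographically smallest member
    ordered = sorted(groups.values(), key=lambda ms: min(ms))
    out = []
    for k, members in enumerate(ordered, start=1):
        rep = _medoid(sorted(members), dm)
        out.append(OtuCluster(f"OTU_{k:04d}", rep, tuple(sorted(members)), threshold_identity))
    return out


def assign_to_otus(
    new_genes: list[AlignedGene],
    otus: list[OtuCluster],
    representatives: dict[str, AlignedGene],
    min_identity: float = 0.96,
) -> tuple[dict[str, str], float]:
    """Map each new gene to the best-matching OTU representative.

    Returns (gene id -> otu id or "unassigned", assignable fraction).
    """
    if not otus:
        raise ValueError("no OTUs to assign against")
    reps = [(o.otu_id, representatives[o.representative]) for o in otus]
    assignment: dict[str, str] = {}
    n_ok = 0
    for g in new_genes:
        best_otu, best_ident = None, -1.0
        for otu_id, rep in reps:
            ident = sequence_identity(g.aligned_seq, rep.aligned_seq)
            if ident > best_ident:
                best_otu, best_ident = otu_id, ident
        if best_ident >= min_identity:
            assignment[g.id] = best_otu
            n_ok += 1
        else:
            assignment[g.id] = "unassigned"
    frac = n_ok / len(new_genes) if new_genes else float("nan")
    return assignment, frac


def otu_membership_map(otus: list[OtuCluster]) -> dict[str, str]:
    return {m: o.otu_id for o in otus for m in o.members}
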