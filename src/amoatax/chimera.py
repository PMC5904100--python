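"""Reference-based two-parent (bimera) chimera screening.

A trusted reference set is assembled from the curated corpus by abundance and
identity-corroboration rules (abundant sequences are unlikely to be PCR
artefacts because chimeras rarely recur across independent Sanger libraries),
then clustered at 97% identity.  Each query is scored against chimeric models
Q ~ A[1..b] + B[b+1..L] built from its top reference candidates; the verdict
combines a divergence gain ``d`` (how much better the best two-parent model
explains the query than the best single parent, in percent of columns) with a
per-side vote score ``h`` that demands both sides of the breakpoint carry
chimera-supporting signal.  A query is called chimeric iff d >= mindiv and
h >= minh (defaults 1.7 and 0.10).

Vote score: on each side of the breakpoint the model's source parent is
compared against the other parent — a column where the query matches the
side's own parent but not the other is a "yes" vote, the reverse a "no" vote,
all else abstains; each side scores Y / (Y + beta*N + gamma*A) with beta=8,
gamma=0.5, and h is the minimum of the two sides, so both halves must carry
independent chimeric signal before minh can fire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import DistanceMatrix, average_neighbour, pairwise_distances, sequence_identity
from .curation import _kmer_set
from .records import AlignedGene


@dataclass(frozen=True)
class ChimeraParams:
    mindiv: float = 1.7  # minimum divergence gain, percent of columns
    minh: float = 0.10  # minimum vote score
    top_k_parents: int = 8
    beta: float = 8.0  # weight of "no" votes
    gamma: float = 0.5  # weight of abstain votes
    candidate_min_identity: float = 0.80


@dataclass(frozen=True)
class ChimeraVerdict:
    query_id: str
    parent_a: str | None
    parent_b: str | None
    breakpoint: int | None  # last column (1-based) taken from parent A
    d: float
    h: float
    decision: str  # chimeric | clean | no-parents


@dataclass
class ReferenceDB:
    members: list[AlignedGene]
    provenance: dict[str, str] = field(default_factory=dict)  # id -> admitting rule

    def __post_init__(self):
        self.by_id = {g.id: g for g in self.members}


def build_reference_db(
    genes: list[AlignedGene],
    multiplicity: dict[str, int],
    study_of: dict[str, str],
    genome_ids: set[str] | None = None,
    min_abundance: int = 5,
    corroborate_identity: float = 0.99,
    cluster_identity: float = 0.97,
) -> ReferenceDB:
    """Admit abundant, identity-corroborated and genome-derived sequences, then
    cluster the admitted set at ``cluster_identity`` (average neighbour) and
    keep one representative per cluster."""
    genome_ids = genome_ids or set()
    admitted: dict[str, str] = {}
    by_id = {g.id: g for g in genes}
    for g in genes:
        if g.id in genome_ids:
            admitted[g.id] = "genome"
        elif multiplicity.get(g.id, 1) >= min_abundance:
            admitted[g.id] = "abundance"
    # identity corroboration: >= 2 matches at >= corroborate_identity, at
    # least one from an independent study
    remaining = [g for g in genes if g.id not in admitted]
    for g in remaining:
        matches = []
        for other in genes:
            if other.id == g.id:
                continue
            if sequence_identity(g.aligned_seq, other.aligned_seq) >= corroborate_identity:
                matches.append(other)
        if len(matches) >= 2 and any(
            study_of.get(m.id, "") != study_of.get(g.id, "") for m in matches
        ):
            admitted[g.id] = "identity-corroborated"
    if not admitted:
        raise ValueError("no-reference: no sequence satisfies any admission rule")
    members = sorted((by_id[i] for i in admitted), key=lambda g: g.id)
    if len(members) > 1:
        clusters = average_neighbour(pairwise_distances(members), cluster_identity)
        members = sorted((g for g in members if g.id in {c.representative for c in clusters}), key=lambda g: g.id)
    return ReferenceDB(members, {g.id: admitted[g.id] for g in members})


def _match_profile(q: np.ndarray, p: np.ndarray, valid: np.ndarray) -> np.ndarray:
    return (q == p) & valid


def score_query(query: AlignedGene, db: ReferenceDB, params: ChimeraParams = ChimeraParams()) -> ChimeraVerdict:
    """Best two-parent model over top-k candidates x all breakpoints.

    Ties in the best model resolve to the smallest breakpoint, then the
    lexicographically smallest ordered (A, B) pair.
    """
    if not db.members:
        raise ValueError("empty reference database")
    L_cols = len(query.aligned_seq)
    if any(len(m.aligned_seq) != L_cols for m in db.members):
        raise ValueError("query and references must share the column frame")

    # candidate gate: top-k by shared k-mers, must clear the identity floor
    qk = _kmer_set(query.coding_seq)
    scored = sorted(
        db.members,
        key=lambda m: (-len(qk & _kmer_set(m.coding_seq)), m.id),
    )
    candidates = [
        m
        for m in scored[: params.top_k_parents]
        if sequence_identity(query.aligned_seq, m.aligned_seq) >= params.candidate_min_identity
    ]
    if len(candidates) < 2:
        return ChimeraVerdict(query.id, None, None, None, 0.0, 0.0, "no-parents")

    gap = np.uint8(ord("-"))
    q = np.frombuffer(query.aligned_seq.encode(), dtype=np.uint8)
    seqs = {m.id: np.frombuffer(m.aligned_seq.encode(), dtype=np.uint8) for m in candidates}
    valid = {m.id: (q != gap) & (seqs[m.id] != gap) for m in candidates}

    # best single parent: most matching columns (tie -> smallest id)
    parent_matches = {mid: int(_match_profile(q, seqs[mid], valid[mid]).sum()) for mid in seqs}
    best_parent = min(parent_matches, key=lambda mid: (-parent_matches[mid], mid))
    m_qt = parent_matches[best_parent]

    ids = sorted(seqs)
    best = None  # (-(m_qm), b, a_id, b_id)
    for a_id in ids:
        ma = _match_profile(q, seqs[a_id], valid[a_id])
        ca = np.concatenate(([0], np.cumsum(ma)))
        for b_id in ids:
            if b_id == a_id:
                continue
            mb = _match_profile(q, seqs[b_id], valid[b_id])
            tot_b = int(mb.sum())
            cb = np.concatenate(([0], np.cumsum(mb)))
            # model matches for breakpoint b (1..L-1): prefix from A + suffix from B
            bs = np.arange(1, L_cols)
            m_qm = ca[bs] + (tot_b - cb[bs])
            k = int(np.argmax(m_qm))  # first (smallest b) maximum
            cand = (-int(m_qm[k]), int(bs[k]), a_id, b_id)
            if best is None or cand < best:
                best = cand
    m_qm = -best[0]
    b_col, a_id, b_id = best[1], best[2], best[3]
    d = 100.0 * (m_qm - m_qt) / L_cols

    # vote score: each side compares its own parent against the other parent
    ma = _match_profile(q, seqs[a_id], valid[a_id])
    mb = _match_profile(q, seqs[b_id], valid[b_id])

    def side_score(sel: np.ndarray, own: np.ndarray, other: np.ndarray) -> float:
        y = int((own & ~other)[sel].sum())
        n = int((~own & other)[sel].sum())
        a = int(sel.sum()) - y - n
        denom = y + params.beta * n + params.gamma * a
        return y / denom if denom > 0 else 0.0

    left = np.arange(L_cols) < b_col
    h = min(side_score(left, ma, mb), side_score(~left, mb, ma))

    decision = "chimeric" if (d >= params.mindiv and h >= params.minh) else "clean"
    return ChimeraVerdict(query.id, a_id, b_id, b_col, float(d), float(h), decision)


@dataclass
class ScreenResult:
    verdicts: list[ChimeraVerdict]
    kept: list[AlignedGene]
    removed: list[str]
    whitelisted: list[str]


def screen_all(
    genes: list[AlignedGene],
    db: ReferenceDB,
    params: ChimeraParams = ChimeraParams(),
    whitelist: set[str] | None = None,
) -> ScreenResult:
    """Score every gene; drop chimeras except whitelisted ids."""
    whitelist = whitelist or set()
    verdicts, kept, removed, white = [], [], [], []
    for g in genes:
        v = score_query(g, db, params)
        verdicts.append(v)
        if v.decision == "chimeric" and g.id not in whitelist:
            removed.append(g.id)
        else:
            if v.decision == "chimeric":
                white.append(g.id)
            kept.append(g)
    return ScreenResult(verdicts, kept, removed, white)


def branch_length_outlier_report(tree, z_threshold: float = 3.0) -> list[tuple[str, float, float]]:
    """Leaves on unusually long terminal branches (judgement aid, no removal).

    Returns (leaf id, branch length, z-score) for terminal branches whose
    length exceeds ``z_threshold`` standard deviations above the mean.
    """
    leaves = [(lf.taxon.label, lf.edge.length or 0.0) for lf in tree.tree.leaf_node_iter()]
    lengths = np.array([l for _, l in leaves])
    mu, sd = lengths.mean(), lengths.std()
    if sd == 0:
        return []
    return [(n, l, float((l - mu) / sd)) for n, l in leaves if (l - mu) / sd > z_threshold]
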