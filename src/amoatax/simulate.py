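"""Synthetic marker-gene corpus generator with known ground truth.

Emulates the structure of a curated protein-coding marker-gene corpus:
clade-structured codon usage and GC heterogeneity, OTU-level sequence
clusters, two-parent PCR chimeras with known breakpoints, corrupted raw reads
(frameshifts, premature stops, truncations, ambiguity codes, reverse
complements) and multi-level habitat annotations.  Every stochastic choice
flows from a single integer seed through one numpy Generator, so a fixed seed
fixes every output byte-identically.

The tree is rooted and bifurcating: order-level clades sit on long,
well-supported stems; within-clade branches receive either high support
(UFBoot ~ U[95,100], SH-aLRT ~ U[85,100]) or sub-threshold support in one or
both measures, drawn independently so each threshold is exercised on its own.
Each clade evolves from its own ancestral sequence drawn from clade-specific
codon weights that are biased toward a per-clade GC target; mutation is
synonymous-biased so clades keep distinct compositional signatures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .records import AlignedGene, RawRecord, STOP_CODONS, revcomp
from .signatures import SYNONYMOUS_FAMILIES
from .taxonomy import LineageSeed, RankedTaxon, SupportTree, assign_ranks, leaf_lineages

ORDER_PREFIXES = ("NC", "NS", "NT", "NP")

AMINO_ACIDS = tuple(SYNONYMOUS_FAMILIES)  # 20 amino acids, standard code


@dataclass
class CorruptionSpec:
    frameshift: float = 0.03
    stop: float = 0.03
    truncation: float = 0.03
    ambiguous: float = 0.02
    revcomp_fraction: float = 0.2

    def total(self) -> float:
        return self.frameshift + self.stop + self.truncation + self.ambiguous


@dataclass
class SimConfig:
    seed: int = 0
    n_clades: int = 4
    otus_per_clade: int = 15
    seqs_per_otu: int = 8
    rep_copies: int = 5  # exact duplicates of each OTU representative
    frame_length_codons: int = 197
    per_clade_gc_target: tuple[float, ...] | None = None
    mutation_rate: float = 1.0  # substitutions/site per branch-length unit
    synonymous_fraction: float = 0.9
    otu_noise: tuple[float, float] = (0.004, 0.015)  # per-site divergence of OTU members
    chimera_fraction: float = 0.1
    min_parent_divergence: float = 0.05
    max_parent_divergence: float = 0.25
    breakpoint_window: tuple[float, float] = (0.2, 0.8)  # central 60% of columns
    unsupported_fraction: float = 0.3
    n_studies: int = 6
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)

    def __post_init__(self):
        if self.n_clades < 2:
            raise ValueError("n_clades must be >= 2")
        if self.otus_per_clade < 2:
            raise ValueError("otus_per_clade must be >= 2")
        for f in (self.chimera_fraction, self.unsupported_fraction, self.synonymous_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
        for r in (self.corruption.frameshift, self.corruption.stop, self.corruption.truncation,
                  self.corruption.ambiguous, self.corruption.revcomp_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("corruption rates must be in [0, 1]")
        if self.corruption.total() > 1.0:
            raise ValueError("corruption rates must sum to <= 1")
        if self.per_clade_gc_target is None:
            self.per_clade_gc_target = tuple(
                float(t) for t in np.linspace(0.40, 0.58, self.n_clades)
            )
        if len(self.per_clade_gc_target) != self.n_clades:
            raise ValueError("per_clade_gc_target must have one entry per clade")
        if any(not 0.0 <= t <= 1.0 for t in self.per_clade_gc_target):
            raise ValueError("GC targets must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        data = json.loads(text)
        data["corruption"] = CorruptionSpec(**data.get("corruption", {}))
        for key in ("per_clade_gc_target", "otu_noise", "breakpoint_window"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    true_tree: SupportTree
    true_taxonomy: dict[str, str]  # leaf -> most specific rank name
    true_taxa: list[RankedTaxon]
    seeds: LineageSeed
    clade_of_leaf: dict[str, int]
    true_otu_of_seq: dict[str, str] = field(default_factory=dict)  # seq id -> leaf (OTU rep) id
    chimera_registry: list[tuple[str, str, str, int]] = field(default_factory=list)
    corruption_registry: dict[str, str] = field(default_factory=dict)  # seq id -> type
    revcomped: set[str] = field(default_factory=set)
    habitat_of_seq: dict[str, str] = field(default_factory=dict)


def _gc_counts() -> tuple[dict[str, np.ndarray], np.ndarray]:
    g_codon = {
        aa: np.array([sum(c in "GC" for c in codon) for codon in fam], dtype=float)
        for aa, fam in SYNONYMOUS_FAMILIES.items()
    }
    g12 = np.array(
        [np.mean([sum(c in "GC" for c in codon[:2]) for codon in SYNONYMOUS_FAMILIES[aa]]) for aa in AMINO_ACIDS]
    )
    return g_codon, g12


def _tilted(beta: float) -> tuple[dict[str, np.ndarray], np.ndarray, float]:
    """Codon and amino-acid probabilities under an exponential GC tilt beta,
    plus the resulting expected per-codon G+C count."""
    g_codon, g12 = _gc_counts()
    codon_p = {}
    exp_g_by_aa = np.empty(len(AMINO_ACIDS))
    for i, aa in enumerate(AMINO_ACIDS):
        w = np.exp(beta * g_codon[aa])
        w /= w.sum()
        codon_p[aa] = w
        exp_g_by_aa[i] = float(w @ g_codon[aa])
    aa_w = np.exp(beta * g12)
    aa_p = aa_w / aa_w.sum()
    return codon_p, aa_p, float(aa_p @ exp_g_by_aa)


def solve_gc_tilt(gc_target: float) -> float:
    """Tilt beta whose expected GC equals the target (bisection).

    Amino-acid choice and within-family codon choice share one tilt, so GC
    heterogeneity shows up in both protein composition and synonymous usage,
    and realised GC is unbiased around the target by construction.
    """
    want = 3.0 * min(max(gc_target, 0.05), 0.95)
    lo, hi = -8.0, 8.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if _tilted(mid)[2] < want:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def clade_codon_weights(gc_target: float) -> dict[str, np.ndarray]:
    """Within-family codon probabilities calibrated to the clade GC target."""
    return _tilted(solve_gc_tilt(gc_target))[0]


def clade_aa_weights(gc_target: float) -> np.ndarray:
    """Amino-acid probabilities under the same calibrated GC tilt."""
    return _tilted(solve_gc_tilt(gc_target))[1]


def _random_bifurcating(leaf_names: list[str], rng: np.random.Generator, taxon_ns,
                        blen_lo: float = 0.03, blen_hi: float = 0.08):
    """Random rooted bifurcating subtree over the given leaves (dendropy nodes)."""
    nodes = []
    for name in leaf_names:
        n = dendropy.Node()
        n.taxon = taxon_ns.require_taxon(label=name)
        n.edge.length = float(rng.uniform(blen_lo, blen_hi))
        nodes.append(n)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(blen_lo, blen_hi))
        parent.add_child(a)
        parent.add_child(b)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def _draw_support(rng: np.random.Generator, supported: bool) -> tuple[float, float]:
    if supported:
        return round(float(rng.uniform(95.0, 100.0)), 1), round(float(rng.uniform(85.0, 100.0)), 1)
    mode = rng.integers(0, 3)  # 0: low ufboot, 1: low sh-alrt, 2: both low
    uf = round(float(rng.uniform(50.0, 94.9)), 1) if mode in (0, 2) else round(float(rng.uniform(95.0, 100.0)), 1)
    sha = round(float(rng.uniform(40.0, 84.9)), 1) if mode in (1, 2) else round(float(rng.uniform(85.0, 100.0)), 1)
    return uf, sha


def simulate_tree(config: SimConfig) -> tuple[SupportTree, GroundTruth]:
    """Rooted bifurcating support tree plus its rule-derived true taxonomy.

    Clade stems are always supported; a configurable fraction of other
    internal branches draws sub-threshold support.  The true taxonomy is
    obtained by contracting exactly the branches *flagged* unsupported at
    generation time (not by thresholding) and applying the rank-assignment
    rules, so recovery tests compare two independent routes to the labels.
    """
    rng = np.random.default_rng(config.seed)
    ns = dendropy.TaxonNamespace()
    clade_roots = []
    clade_of_leaf: dict[str, int] = {}
    for ci in range(config.n_clades):
        leaves = [f"cl{ci}_otu{k:03d}" for k in range(config.otus_per_clade)]
        for lf in leaves:
            clade_of_leaf[lf] = ci
        root = _random_bifurcating(leaves, rng, ns)
        root.edge.length = float(rng.uniform(0.15, 0.25))  # long, distinct stems
        clade_roots.append(root)

    # caterpillar skeleton joining the clade stems
    spine = clade_roots[0]
    for nxt in clade_roots[1:]:
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.05, 0.15))
        parent.add_child(spine)
        parent.add_child(nxt)
        spine = parent
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = spine
    tree.seed_node.edge.length = None
    tree.is_rooted = True

    # internal nodes strictly inside a clade may draw sub-threshold support;
    # clade stems and the skeleton above them are always supported
    within_clade = set()
    for root in clade_roots:
        for n in root.preorder_iter():
            if n is not root and not n.is_leaf():
                within_clade.add(id(n))
    for node in tree.preorder_node_iter():
        node.clade_name = None
        if node.is_leaf():
            continue
        if node is tree.seed_node:
            node.truly_supported = True
            node.ufboot, node.shalrt = 100.0, 100.0
            continue
        if id(node) in within_clade:
            node.truly_supported = bool(rng.random() >= config.unsupported_fraction)
        else:
            node.truly_supported = True
        node.ufboot, node.shalrt = _draw_support(rng, node.truly_supported)

    support_tree = SupportTree(tree)

    # true collapsed tree: contract exactly the flagged branches
    truth_tree = SupportTree.from_newick(support_tree.to_newick())
    flagged = {
        frozenset(lf.taxon.label for lf in n.leaf_iter())
        for n in tree.preorder_node_iter()
        if not n.is_leaf() and n.parent_node is not None and not n.truly_supported
    }
    to_collapse = [
        n
        for n in truth_tree.tree.preorder_node_iter()
        if not n.is_leaf()
        and n.parent_node is not None
        and frozenset(lf.taxon.label for lf in n.leaf_iter()) in flagged
    ]
    for n in to_collapse:
        n.edge.collapse()

    seeds = _default_seeds(clade_roots, config)
    true_taxa = assign_ranks(truth_tree, seeds)
    gt = GroundTruth(
        true_tree=truth_tree,
        true_taxonomy=leaf_lineages(true_taxa),
        true_taxa=true_taxa,
        seeds=seeds,
        clade_of_leaf=clade_of_leaf,
    )
    return support_tree, gt


def _default_seeds(clade_roots, config: SimConfig) -> LineageSeed:
    anchors = {}
    for ci, root in enumerate(clade_roots):
        prefix = ORDER_PREFIXES[ci] if ci < len(ORDER_PREFIXES) else f"NO{ci + 1}"
        children = root.child_nodes()
        # one anchor under each child of the clade root pins the MRCA to the root
        for child in children[:2]:
            leaf = next(child.leaf_iter())
            anchors[leaf.taxon.label] = prefix
    return LineageSeed(anchors)


def _draw_codon(rng: np.random.Generator, weights: dict[str, np.ndarray], aa: str) -> str:
    family = SYNONYMOUS_FAMILIES[aa]
    return family[int(rng.choice(len(family), p=weights[aa]))]


def _ancestral_sequence(
    rng: np.random.Generator,
    weights: dict[str, np.ndarray],
    aa_probs: np.ndarray,
    n_codons: int,
    gc_target: float | None = None,
    gc_tolerance: float = 0.01,
) -> list[str]:
    """Ancestral codon sequence; with a GC target, rejection-sampled until the
    realised GC lands within the tolerance so clade means stay ordered."""
    for _ in range(400):
        aas = ["M"] + [AMINO_ACIDS[int(i)] for i in rng.choice(len(AMINO_ACIDS), n_codons - 1, p=aa_probs)]
        codons = [_draw_codon(rng, weights, aa) for aa in aas]
        if gc_target is None:
            return codons
        seq = "".join(codons)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        if abs(gc - gc_target) <= gc_tolerance:
            return codons
    return codons  # pathological target: keep the last draw


def _aa_of(codon: str) -> str:
    from .signatures import FAMILY_OF_CODON

    return FAMILY_OF_CODON[codon]


def _mutate_codons(
    codons: list[str],
    p_codon: float,
    rng: np.random.Generator,
    weights: dict[str, np.ndarray],
    aa_probs: np.ndarray,
    synonymous_fraction: float,
) -> list[str]:
    out = list(codons)
    hits = np.nonzero(rng.random(len(out)) < p_codon)[0]
    for i in hits:
        aa = _aa_of(out[i])
        if rng.random() >= synonymous_fraction:
            aa = AMINO_ACIDS[int(rng.choice(len(AMINO_ACIDS), p=aa_probs))]
        out[i] = _draw_codon(rng, weights, aa)
    return out


def evolve_sequences(
    tree: SupportTree, config: SimConfig, ground_truth: GroundTruth
) -> list[AlignedGene]:
    """One gene per tree leaf (OTU representative), evolved along the tree.

    Each clade gets its own ancestral sequence drawn from its GC-biased codon
    weights; every branch mutates codons with probability
    3 * mutation_rate * branch_length, mostly synonymously, so realised
    per-clade GC tracks the target and clean sequences stay stop-free.
    """
    if len(tree.leaf_ids()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    weights_by_clade = [clade_codon_weights(t) for t in config.per_clade_gc_target]
    aa_by_clade = [clade_aa_weights(t) for t in config.per_clade_gc_target]

    clade_nodes: dict[int, object] = {}
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        clades = {ground_truth.clade_of_leaf[l] for l in leaves}
        if len(clades) == 1:
            ci = clades.pop()
            if ci not in clade_nodes:
                clade_nodes[ci] = node  # first pure node in preorder = clade root
    # single-leaf clades cannot happen (otus_per_clade >= 2)

    genes: list[AlignedGene] = []
    for ci in sorted(clade_nodes):
        w, aa_p = weights_by_clade[ci], aa_by_clade[ci]
        root = clade_nodes[ci]
        seqs: dict[int, list[str]] = {
            id(root): _ancestral_sequence(
                rng, w, aa_p, config.frame_length_codons, gc_target=config.per_clade_gc_target[ci]
            )
        }
        for node in root.preorder_iter():
            if node is root:
                continue
            parent_codons = seqs[id(node.parent_node)]
            p = min(1.0, 3.0 * config.mutation_rate * (node.edge.length or 0.0))
            seqs[id(node)] = _mutate_codons(parent_codons, p, rng, w, aa_p, config.synonymous_fraction)
        for lf in root.leaf_iter():
            seq = "".join(seqs[id(lf)])
            assert not any(c in STOP_CODONS for c in (seq[i:i + 3] for i in range(0, len(seq), 3)))
            genes.append(AlignedGene(lf.taxon.label, seq))
    genes.sort(key=lambda g: g.id)
    return genes


def expand_otus(reps: list[AlignedGene], config: SimConfig, ground_truth: GroundTruth) -> list[AlignedGene]:
    """Per-OTU sequence pool: exact duplicates of the representative plus
    noisy members, each tagged with a random study."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    out: list[AlignedGene] = []
    bases = "ACGT"
    for rep in reps:
        study_pool = [f"study{int(s)}" for s in rng.integers(0, config.n_studies, config.seqs_per_otu + config.rep_copies)]
        for j in range(config.rep_copies):
            sid = f"{rep.id}_d{j}"
            out.append(AlignedGene(sid, rep.coding_seq, study=study_pool[j]))
            ground_truth.true_otu_of_seq[sid] = rep.id
        n_members = max(0, config.seqs_per_otu - config.rep_copies)
        for j in range(n_members):
            rate = float(rng.uniform(*config.otu_noise))
            seq = list(rep.coding_seq)
            # substitute sites, then repair any stop codon by reverting it
            for pos in np.nonzero(rng.random(len(seq)) < rate)[0]:
                seq[pos] = bases[int(rng.integers(0, 4))]
            for i in range(0, len(seq) - 2, 3):
                if "".join(seq[i:i + 3]) in STOP_CODONS:
                    seq[i:i + 3] = rep.coding_seq[i:i + 3]
            sid = f"{rep.id}_m{j}"
            out.append(AlignedGene(sid, "".join(seq), study=study_pool[config.rep_copies + j]))
            ground_truth.true_otu_of_seq[sid] = rep.id
    return out


def make_chimeras(
    pool: list[AlignedGene],
    fraction: float,
    min_parent_divergence: float,
    seed: int,
    max_parent_divergence: float = 0.25,
    breakpoint_window: tuple[float, float] = (0.2, 0.8),
) -> tuple[list[AlignedGene], list[tuple[str, str, str, int]]]:
    """Two-parent chimeras with breakpoints in a central codon-aligned window.

    Breakpoints sit on codon boundaries so chimeras stay in frame (a PCR
    jump between homologous templates preserves the reading frame).
    """
    if len(pool) < 2:
        raise ValueError("need at least 2 potential parents")
    rng = np.random.default_rng(seed)
    n_chim = int(round(fraction * len(pool)))
    registry: list[tuple[str, str, str, int]] = []
    chimeras: list[AlignedGene] = []
    if n_chim == 0:
        return chimeras, registry

    def divergence(a: str, b: str) -> float:
        return sum(x != y for x, y in zip(a, b)) / len(a)

    L = len(pool[0].coding_seq)
    lo = int(np.ceil(breakpoint_window[0] * L / 3.0))
    hi = int(np.floor(breakpoint_window[1] * L / 3.0))
    for k in range(n_chim):
        pair = None
        for _ in range(200):
            i, j = rng.integers(0, len(pool), 2)
            if i == j:
                continue
            d = divergence(pool[i].coding_seq, pool[j].coding_seq)
            if min_parent_divergence <= d <= max_parent_divergence:
                pair = (pool[i], pool[j])
                break
        if pair is None:
            eligible = [
                (a, b)
                for ai, a in enumerate(pool)
                for b in pool[ai + 1 :]
                if min_parent_divergence <= divergence(a.coding_seq, b.coding_seq) <= max_parent_divergence
            ]
            if not eligible:
                raise ValueError("no eligible parent pair above min_parent_divergence")
            pair = eligible[int(rng.integers(0, len(eligible)))]
        a, b = pair
        bcol = 3 * int(rng.integers(lo, hi + 1))
        seq = a.coding_seq[:bcol] + b.coding_seq[bcol:]
        cid = f"chim{k:04d}"
        chimeras.append(AlignedGene(cid, seq, study=a.study))
        registry.append((cid, a.id, b.id, bcol))
    return chimeras, registry


def corrupt_sequences(
    pool: list[AlignedGene], corruption: CorruptionSpec, seed: int
) -> tuple[list[RawRecord], dict[str, str], set[str]]:
    """Raw FASTA-ready records with logged corruption types.

    Each input yields one output record that is clean or carries exactly one
    corruption (frameshift indel, premature stop, truncation below 582 nt, or
    an ambiguity code); an independent fraction is emitted reverse-complemented
    (logged, not a corruption — curation must recover it).
    """
    rng = np.random.default_rng(seed)
    records: list[RawRecord] = []
    registry: dict[str, str] = {}
    revcomped: set[str] = set()
    cuts = np.cumsum([corruption.frameshift, corruption.stop, corruption.truncation, corruption.ambiguous])
    for g in pool:
        u = rng.random()
        seq = g.coding_seq
        if u < cuts[0]:
            kind = "frameshift"
            pos = int(rng.integers(30, len(seq) - 30))
            width = int(rng.integers(1, 3))
            if rng.random() < 0.5:
                seq = seq[:pos] + seq[pos + width :]
            else:
                ins = "".join("ACGT"[int(x)] for x in rng.integers(0, 4, width))
                seq = seq[:pos] + ins + seq[pos:]
        elif u < cuts[1]:
            kind = "stop"
            codon_i = int(rng.integers(3, len(seq) // 3 - 3))
            stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
            seq = seq[: 3 * codon_i] + stop + seq[3 * codon_i + 3 :]
        elif u < cuts[2]:
            kind = "short"
            seq = seq[: int(rng.integers(420, 582))]
        elif u < cuts[3]:
            kind = "ambiguous"
            pos = int(rng.integers(0, len(seq)))
            seq = seq[:pos] + "N" + seq[pos + 1 :]
        else:
            kind = "clean"
        if rng.random() < corruption.revcomp_fraction:
            seq = revcomp(seq)
            revcomped.add(g.id)
        records.append(RawRecord(g.id, seq, g.study))
        registry[g.id] = kind
    return records, registry, revcomped


DEFAULT_HABITAT_PATHS = (
    "marine/water/epipelagic",
    "marine/water/below-epipelagic",
    "marine/sediment",
    "soils-sediments/acidic",
    "soils-sediments/neutral",
    "soils-sediments/alkaline",
    "freshwater/water",
    "freshwater/sediment",
    "estuarine-coastal",
    "hot springs",
)


def default_habitat_tree():
    from .habitats import HabitatTree

    tree = HabitatTree()
    for path in DEFAULT_HABITAT_PATHS:
        tree.add_path(path.split("/"))
    return tree


def default_clade_distribution(n_clades: int) -> dict[int, dict[str, float]]:
    """Clade-specific habitat preferences over the default category leaves."""
    presets = [
        {"marine/water/epipelagic": 0.5, "marine/water/below-epipelagic": 0.3, "marine/sediment": 0.2},
        {"soils-sediments/acidic": 0.3, "soils-sediments/neutral": 0.5, "soils-sediments/alkaline": 0.2},
        {"freshwater/water": 0.6, "freshwater/sediment": 0.3, "estuarine-coastal": 0.1},
        {"hot springs": 0.8, "soils-sediments/neutral": 0.2},
    ]
    return {ci: presets[ci % len(presets)] for ci in range(n_clades)}


def make_metadata(
    seqs: list[AlignedGene],
    habitat_tree,
    per_clade_distribution: dict[int, dict[str, float]],
    seed: int,
    broader_only_fraction: float = 0.1,
    clade_of_seq: dict[str, int] | None = None,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """(seq id, category path) rows drawn from per-clade habitat distributions.

    A ``broader_only_fraction`` of assignments is truncated to the parent
    category to exercise the level-exclusion rule downstream.
    """
    for ci, dist in per_clade_distribution.items():
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clade {ci} distribution sums to {total}, not 1")
        for path in dist:
            if path not in habitat_tree.parent:
                raise ValueError(f"unknown category {path!r}")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str]] = []
    habitat_of: dict[str, str] = {}
    for g in seqs:
        if clade_of_seq is not None:
            ci = clade_of_seq[g.id]
        else:
            ci = int(g.id.split("_")[0].removeprefix("cl"))
        dist = per_clade_distribution[ci]
        paths = sorted(dist)
        path = paths[int(rng.choice(len(paths), p=np.array([dist[p] for p in paths])))]
        if "/" in path and rng.random() < broader_only_fraction:
            path = "/".join(path.split("/")[:-1])
        rows.append((g.id, path))
        habitat_of[g.id] = path
    return rows, habitat_of


@dataclass
class SimulatedDataset:
    config: SimConfig
    tree: SupportTree
    ground_truth: GroundTruth
    otu_representatives: list[AlignedGene]
    clean_pool: list[AlignedGene]  # OTU members incl. duplicates, pre-corruption
    chimeras: list[AlignedGene]
    raw_records: list[RawRecord]
    metadata_rows: list[tuple[str, str]]


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full corpus: tree, clean pool, chimeras, corrupted raw records, metadata."""
    tree, gt = simulate_tree(config)
    reps = evolve_sequences(tree, config, gt)
    pool = expand_otus(reps, config, gt)
    chimeras, chim_registry = make_chimeras(
        pool,
        config.chimera_fraction,
        config.min_parent_divergence,
        int(np.random.SeedSequence([config.seed, 3]).generate_state(1)[0] % 2**31),
        config.max_parent_divergence,
        config.breakpoint_window,
    )
    gt.chimera_registry = chim_registry
    raw, corr_registry, revcomped = corrupt_sequences(
        pool, config.corruption, int(np.random.SeedSequence([config.seed, 4]).generate_state(1)[0] % 2**31)
    )
    for c in chimeras:  # chimeras enter the raw pool uncorrupted
        raw.append(RawRecord(c.id, c.coding_seq, c.study))
        corr_registry[c.id] = "chimera"
    gt.corruption_registry = corr_registry
    gt.revcomped = revcomped
    clade_of_seq = {g.id: gt.clade_of_leaf[gt.true_otu_of_seq[g.id]] for g in pool}
    for cid, pa, _, _ in chim_registry:
        clade_of_seq[cid] = gt.clade_of_leaf[gt.true_otu_of_seq[pa]]
    rows, habitat_of = make_metadata(
        pool + chimeras,
        default_habitat_tree(),
        default_clade_distribution(config.n_clades),
        int(np.random.SeedSequence([config.seed, 5]).generate_state(1)[0] % 2**31),
        clade_of_seq=clade_of_seq,
    )
    gt.habitat_of_seq = habitat_of
    return SimulatedDataset(config, tree, gt, reps, pool, chimeras, raw, rows)
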