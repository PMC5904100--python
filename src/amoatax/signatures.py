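"""Nucleobase composition and synonymous codon-usage signatures.

Per-gene statistics: GC and purine content (%), Wright's effective number of
codons (Nc) and a codon adaptation index scored against the dominant codon
bias of a reference set (gCAI).  Per-OTU signatures are expressed as the
deviation of the OTU mean from the global average, where the global average is
the unweighted mean over OTU means so that large OTUs do not dominate.

Nc quantifies how evenly a gene spreads its synonymous codon choices: it is 20
when each amino acid uses a single codon and 61 (after capping) when every
synonymous codon of every amino acid is used equally.  gCAI is the geometric
mean of per-codon relative adaptiveness weights, in (0, 1]; weights are fitted
either from the pooled reference counts ("fixed") or by iteratively narrowing
the reference to its most bias-conforming half ("iterative"), which recovers a
dominant bias even when the reference set is a mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .records import AlignedGene, STOP_CODONS, codons_of

# Standard genetic code grouped into synonymous families, keyed by amino acid.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {
    "F": ("TTT", "TTC"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "I": ("ATT", "ATC", "ATA"),
    "M": ("ATG",),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "Y": ("TAT", "TAC"),
    "H": ("CAT", "CAC"),
    "Q": ("CAA", "CAG"),
    "N": ("AAT", "AAC"),
    "K": ("AAA", "AAG"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "C": ("TGT", "TGC"),
    "W": ("TGG",),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
}

FAMILY_OF_CODON: dict[str, str] = {
    c: aa for aa, codons in SYNONYMOUS_FAMILIES.items() for c in codons
}

#: Redundancy classes of the standard code and their multiplicities in Wright's
#: estimator: Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.
REDUNDANCY_CLASSES: dict[int, tuple[str, ...]] = {
    2: ("F", "Y", "H", "Q", "N", "K", "D", "E", "C"),
    3: ("I",),
    4: ("V", "P", "T", "A", "G"),
    6: ("L", "S", "R"),
}

NC_MIN, NC_MAX = 20.0, 61.0


def base_composition(gene: AlignedGene | str) -> tuple[float, float]:
    """GC and purine content (%) of the degapped coding strand."""
    seq = gene.coding_seq if isinstance(gene, AlignedGene) else gene
    seq = seq.replace("-", "").upper()
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    gc = 100.0 * (seq.count("G") + seq.count("C")) / n
    purine = 100.0 * (seq.count("A") + seq.count("G")) / n
    return gc, purine


def codon_counts(seq: str) -> dict[str, int]:
    """Counts of sense codons in an in-frame degapped sequence (stops skipped)."""
    counts: dict[str, int] = {}
    for c in codons_of(seq.replace("-", "").upper()):
        if c in FAMILY_OF_CODON:
            counts[c] = counts.get(c, 0) + 1
    return counts


def _family_homozygosity(counts: dict[str, int], family: tuple[str, ...]) -> tuple[int, float] | None:
    """Wright's F-hat = (n*sum(p_i^2) - 1)/(n - 1) for one family; None if n < 2."""
    ns = [counts.get(c, 0) for c in family]
    n = sum(ns)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in ns)
    f_hat = (n * sum_p2 - 1.0) / (n - 1.0)
    return n, f_hat


def effective_number_of_codons(gene: AlignedGene | str) -> float:
    """Wright's Nc, capped to [20, 61].

    Families with fewer than two observed codons do not contribute; families
    with F-hat = 0 are excluded from their class mean (they would otherwise
    make the class term infinite).  An empty 3-codon class (Ile unobserved)
    falls back to the mean of the 2- and 4-fold class homozygosities, Wright's
    interpolation; any other empty class falls back to the uniform-usage
    expectation 1/k.
    """
    seq = gene.coding_seq if isinstance(gene, AlignedGene) else gene
    counts = codon_counts(seq)
    if not counts:
        raise ValueError("no sense codons in sequence")

    class_means: dict[int, float | None] = {}
    for k, aas in REDUNDANCY_CLASSES.items():
        fs = []
        for aa in aas:
            res = _family_homozygosity(counts, SYNONYMOUS_FAMILIES[aa])
            if res is not None and res[1] > 0:
                fs.append(res[1])
        class_means[k] = float(np.mean(fs)) if fs else None

    if class_means[3] is None:
        if class_means[2] is not None and class_means[4] is not None:
            class_means[3] = (class_means[2] + class_means[4]) / 2.0
    for k in REDUNDANCY_CLASSES:
        if class_means[k] is None:
            class_means[k] = 1.0 / k

    nc = 2.0 + 9.0 / class_means[2] + 1.0 / class_means[3] + 5.0 / class_means[4] + 3.0 / class_means[6]
    return float(min(NC_MAX, max(NC_MIN, nc)))


@dataclass
class CaiWeights:
    """Relative adaptiveness w_c per codon (max 1 within each family)."""

    weights: dict[str, float]
    mode: str = "fixed"
    reference_size: int = 0
    iteration_trace: list[int] = field(default_factory=list)

    def __getitem__(self, codon: str) -> float:
        return self.weights[codon]


def _fixed_weights(pooled: dict[str, int], pseudo_factor: float = 0.5) -> dict[str, float]:
    weights: dict[str, float] = {}
    for aa, family in SYNONYMOUS_FAMILIES.items():
        counts = {c: pooled.get(c, 0) for c in family}
        mx = max(counts.values())
        if mx == 0:
            # Family absent from the reference: uninformative, weight 1 so it
            # does not penalise queries.
            for c in family:
                weights[c] = 1.0
            continue
        for c in family:
            if counts[c] > 0:
                weights[c] = counts[c] / mx
            else:
                weights[c] = pseudo_factor / mx  # pseudo-weight, avoids log(0)
    return weights


def fit_cai_weights(
    reference_genes: list[AlignedGene | str],
    mode: str = "iterative",
    pseudo_factor: float = 0.5,
    tolerance: float = 1e-4,
) -> CaiWeights:
    """Fit relative-adaptiveness weights from a reference gene set.

    ``fixed``: weights from the pooled codon counts of the whole reference.
    ``iterative``: repeatedly score the references against the current weights
    and keep the best-scoring half, until the set shrinks to
    max(1% of references, 5) genes or the weights stop changing; this isolates
    the dominant codon bias of a heterogeneous reference set.
    """
    if not reference_genes:
        raise ValueError("empty reference set")
    seqs = [g.coding_seq if isinstance(g, AlignedGene) else g for g in reference_genes]

    def pooled_counts(subset: list[str]) -> dict[str, int]:
        pooled: dict[str, int] = {}
        for s in subset:
            for c, n in codon_counts(s).items():
                pooled[c] = pooled.get(c, 0) + n
        return pooled

    if mode == "fixed":
        w = _fixed_weights(pooled_counts(seqs), pseudo_factor)
        return CaiWeights(w, "fixed", len(seqs))
    if mode != "iterative":
        raise ValueError(f"unknown mode {mode!r}")

    floor = max(int(math.ceil(0.01 * len(seqs))), 5)
    subset = list(seqs)
    weights = _fixed_weights(pooled_counts(subset), pseudo_factor)
    trace = [len(subset)]
    while len(subset) > floor:
        scored = sorted(subset, key=lambda s: -gcai(s, CaiWeights(weights)))
        subset = scored[: max(floor, len(subset) // 2)]
        new_weights = _fixed_weights(pooled_counts(subset), pseudo_factor)
        trace.append(len(subset))
        delta = max(abs(new_weights[c] - weights[c]) for c in new_weights)
        weights = new_weights
        if delta < tolerance:
            break
    return CaiWeights(weights, "iterative", len(seqs), trace)


def gcai(gene: AlignedGene | str, weights: CaiWeights) -> float:
    """Geometric-mean codon adaptation index over degenerate sense codons.

    Single-codon families (Met, Trp) and stop codons are excluded, as usual
    for CAI: they carry no synonymous choice.
    """
    seq = gene.coding_seq if isinstance(gene, AlignedGene) else gene
    logs = []
    for c in codons_of(seq.replace("-", "").upper()):
        if c in STOP_CODONS or c not in FAMILY_OF_CODON:
            continue
        if len(SYNONYMOUS_FAMILIES[FAMILY_OF_CODON[c]]) == 1:
            continue
        logs.append(math.log(weights[c]))
    if not logs:
        raise ValueError("no scorable codons")
    return float(math.exp(sum(logs) / len(logs)))


@dataclass(frozen=True)
class SignatureRecord:
    gene_id: str
    gc: float
    purine: float
    nc: float
    gcai: float


def signature_table(genes: list[AlignedGene], weights: CaiWeights) -> list[SignatureRecord]:
    out = []
    for g in genes:
        gc, pur = base_composition(g)
        out.append(SignatureRecord(g.id, gc, pur, effective_number_of_codons(g), gcai(g, weights)))
    return out


@dataclass(frozen=True)
class OtuSignature:
    otu_id: str
    deviations: dict[str, float]  # metric -> OTU mean minus global average
    sds: dict[str, float]  # metric -> SD of gene deviations within the OTU


METRICS = ("gc", "purine", "nc", "gcai")


def otu_deviations(records: list[SignatureRecord], otu_of: dict[str, str]) -> list[OtuSignature]:
    """Per-OTU mean deviation (± SD) from the global average of OTU means.

    The global average per metric is the unweighted arithmetic mean of the OTU
    means, so duplicating genes within one OTU cannot shift it.  Genes without
    an OTU mapping raise; empty OTUs simply never appear.
    """
    by_otu: dict[str, list[SignatureRecord]] = {}
    for rec in records:
        try:
            otu = otu_of[rec.gene_id]
        except KeyError:
            raise KeyError(f"gene {rec.gene_id} has no OTU mapping") from None
        by_otu.setdefault(otu, []).append(rec)

    otu_means = {
        otu: {m: float(np.mean([getattr(r, m) for r in recs])) for m in METRICS}
        for otu, recs in by_otu.items()
    }
    global_avg = {m: float(np.mean([mm[m] for mm in otu_means.values()])) for m in METRICS}

    out = []
    for otu in sorted(by_otu):
        recs = by_otu[otu]
        devs = {m: otu_means[otu][m] - global_avg[m] for m in METRICS}
        sds = {
            m: float(np.std([getattr(r, m) - global_avg[m] for r in recs], ddof=0))
            for m in METRICS
        }
        out.append(OtuSignature(otu, devs, sds))
    return out


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    residuals: tuple[float, ...]


def gene_vs_genome_regression(pairs: list[tuple[float, float]]) -> RegressionResult:
    """OLS of gene-level values (y) on genome-level values (x)."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    residuals = tuple((y - (res.intercept + res.slope * x)).tolist())
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue), len(pairs), residuals
    )
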