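"""Hierarchical habitat categories and level-wise fraction profiles.

Sequences carry a category path of arbitrary depth ("marine/water/epipelagic")
that may stop at any level.  The level-fraction rule: the fraction of a group
falling in each child of a node is computed over the sequences of the group
assigned at or below *some* child — sequences whose annotation stops exactly
at the node ("broader-only") are excluded from the denominator, so partial
annotations never dilute the profile.

Numeric helpers bin ocean depth at 200 m (epipelagic boundary) and soil pH at
6.5 / 7.5 (acidic / neutral / alkaline); range-valued pH reports map to the
explicit sibling categories "acidic-neutral" and "neutral-alkaline".
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_ROOTS = (
    "marine",
    "soils-sediments",
    "freshwater",
    "estuarine-coastal",
    "salt lakes",
    "hot springs",
    "host-associated",
)


@dataclass
class HabitatTree:
    """Forest of habitat categories; node -> parent (roots map to None)."""

    parent: dict[str, str | None] = field(default_factory=dict)

    def add_path(self, path: list[str]) -> None:
        prev: str | None = None
        for i, name in enumerate(path):
            key = "/".join(path[: i + 1])
            if key in self.parent and self.parent[key] != prev:
                raise ValueError(f"category {key!r} already attached elsewhere")
            self.parent[key] = prev
            prev = key

    def children(self, node: str | None) -> list[str]:
        return sorted(k for k, p in self.parent.items() if p == node)

    def roots(self) -> list[str]:
        return self.children(None)

    def validate(self) -> None:
        for node in self.parent:
            seen, cur = set(), node
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle at category {cur!r}")
                seen.add(cur)
                nxt = self.parent.get(cur, "missing")
                if nxt == "missing":
                    raise ValueError(f"orphan category {cur!r}")
                cur = nxt


@dataclass
class HabitatAssignment:
    """seq id -> deepest known category path (slash-joined key)."""

    path_of: dict[str, str] = field(default_factory=dict)


def load_categories(
    rows: list[tuple[str, str]], known_tree: HabitatTree | None = None
) -> tuple[HabitatTree, HabitatAssignment]:
    """Build tree + assignments from (seq id, slash path) rows.

    With ``known_tree`` given, paths must already exist in it; offenders are
    collected into a single error.  Conflicting duplicate annotations keep the
    first and log the conflict.
    """
    tree = known_tree or HabitatTree()
    assign = HabitatAssignment()
    conflicts: list[str] = []
    unknown: list[str] = []
    for seq_id, path in rows:
        parts = [p.strip() for p in path.strip("/").split("/") if p.strip()]
        if not parts:
            continue
        key = "/".join(parts)
        if known_tree is not None:
            if key not in tree.parent:
                unknown.append(key)
                continue
        else:
            tree.add_path(parts)
        if seq_id in assign.path_of:
            if assign.path_of[seq_id] != key:
                conflicts.append(seq_id)  # first-wins
            continue
        assign.path_of[seq_id] = key
    if unknown:
        raise ValueError(f"unknown categories: {sorted(set(unknown))}")
    tree.validate()
    assign.conflicts = conflicts
    return tree, assign


def _at_or_below(path: str, node: str) -> bool:
    return path == node or path.startswith(node + "/")


def level_fractions(
    group: set[str], tree: HabitatTree, assignments: HabitatAssignment, at_node: str | None
) -> dict[str, float] | None:
    """Fractions of ``group`` per child of ``at_node`` (None for the root level).

    Denominator counts group sequences assigned at or below any child;
    broader-only sequences (path stops exactly at ``at_node``) are excluded.
    Returns None when the denominator is empty (undefined, not zero).
    """
    children = tree.children(at_node)
    if not children:
        raise ValueError(f"category {at_node!r} has no children")
    counts = {c: 0 for c in children}
    denom = 0
    for seq in group:
        path = assignments.path_of.get(seq)
        if path is None:
            continue
        for c in children:
            if _at_or_below(path, c):
                counts[c] += 1
                denom += 1
                break
    if denom == 0:
        return None
    return {c: counts[c] / denom for c in children}


def clade_frequency_table(
    lineage_of: dict[str, str],
    taxon_parent: dict[str, str | None],
    assignments: HabitatAssignment,
    multiplicity: dict[str, int] | None = None,
    seq_to_leaf: dict[str, str] | None = None,
) -> dict[tuple[str, str], int]:
    """Multiplicity-weighted counts per (taxon, habitat path) pair.

    ``lineage_of`` maps leaf/OTU id -> most specific taxon; counts propagate
    up both hierarchies, so a parent's count is the sum over its children plus
    its direct members.  ``seq_to_leaf`` maps sequence ids to tree leaves when
    assignments are per sequence rather than per leaf.
    """
    multiplicity = multiplicity or {}
    counts: dict[tuple[str, str], int] = {}
    for seq, path in assignments.path_of.items():
        leaf = seq_to_leaf.get(seq, seq) if seq_to_leaf else seq
        taxon = lineage_of.get(leaf)
        if taxon is None:
            continue
        w = multiplicity.get(seq, 1)
        # propagate along the taxonomy
        t: str | None = taxon
        while t is not None:
            # propagate along the habitat hierarchy
            parts = path.split("/")
            for i in range(len(parts)):
                key = "/".join(parts[: i + 1])
                counts[(t, key)] = counts.get((t, key), 0) + w
            t = taxon_parent.get(t)
    return counts


def habitat_fraction(counts: dict[tuple[str, str], int], taxon: str, habitat: str) -> float:
    """Fraction of a taxon's habitat-annotated sequences found in ``habitat``,
    relative to its siblings at the same habitat level."""
    parent = "/".join(habitat.split("/")[:-1])
    total = sum(
        n for (t, h), n in counts.items() if t == taxon and "/".join(h.split("/")[:-1]) == parent and h.count("/") == habitat.count("/")
    )
    if total == 0:
        return float("nan")
    return counts.get((taxon, habitat), 0) / total


def export_krona(
    counts: dict[tuple[str, str], int], taxon_parent: dict[str, str | None]
) -> str:
    """Krona-style text: one row per (leaf taxon, leaf habitat path):
    count TAB taxon TAB habitat level1 TAB level2 ...  Re-import reproduces
    the leaf counts."""
    header = "count\ttaxon\thabitat_path"
    taxa_with_children = set(filter(None, taxon_parent.values()))
    rows = []
    keys = sorted(counts)
    deepest = {
        (t, h)
        for (t, h) in keys
        if t not in taxa_with_children and not any(h2 != h and h2.startswith(h + "/") and t2 == t for (t2, h2) in keys)
    }
    for t, h in keys:
        if (t, h) in deepest:
            rows.append(f"{counts[(t, h)]}\t{t}\t" + "\t".join(h.split("/")))
    return header + "\n" + "\n".join(rows) + ("\n" if rows else "\n")


def import_krona(text: str) -> dict[tuple[str, str], int]:
    out: dict[tuple[str, str], int] = {}
    lines = text.strip().splitlines()
    for line in lines[1:]:
        parts = line.split("\t")
        count, taxon, habitat = int(parts[0]), parts[1], "/".join(parts[2:])
        out[(taxon, habitat)] = out.get((taxon, habitat), 0) + count
    return out


def bin_depth(depth_m: float) -> str:
    """Ocean water-column zone at the 200 m epipelagic boundary."""
    return "epipelagic" if depth_m <= 200 else "below-epipelagic"


def bin_ph(low: float, high: float | None = None) -> str:
    """Soil pH class; a range spanning classes maps to an explicit range category."""
    high = low if high is None else high
    lo_cls = "acidic" if low < 6.5 else ("neutral" if low <= 7.5 else "alkaline")
    hi_cls = "acidic" if high < 6.5 else ("neutral" if high <= 7.5 else "alkaline")
    if lo_cls == hi_cls:
        return lo_cls
    if {lo_cls, hi_cls} == {"acidic", "neutral"}:
        return "acidic-neutral"
    if {lo_cls, hi_cls} == {"neutral", "alkaline"}:
        return "neutral-alkaline"
    return "acidic-alkaline"
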