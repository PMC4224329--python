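"""Hotspot-masked genome comparison, haplogroup classification and NJ trees.

All genomes live in one reference coordinate frame (substitution-only
model), so columns line up by construction and no multiple alignment is
needed.  Comparisons exclude hotspot-masked positions and positions that
are N in either genome.

Haplogroup classification walks a defining-variant tree from the root,
entering a child when the genome carries at least a configurable fraction
of the child's assessable defining variants (masked and genome-N sites are
excluded from the denominator, tolerating incomplete consensus genomes).

Tree building is classic neighbor joining (Saitou–Nei Q criterion with the
standard limb-length and distance-update formulas), which is exact on
additive distance matrices and fully deterministic here: ties are broken
by the lexicographically smallest leaf label in each subtree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    ConfigError,
    MissingTaxonError,
    ParseError,
    TreeError,
    UndefinedEstimateError,
    ValidationError,
)
from .reference import (
    CODING_REGION,
    GenomeRecord,
    RegionMask,
    Variant,
    parse_variant,
)

__all__ = [
    "PairwiseComparison",
    "pairwise_comparison",
    "private_variants",
    "HaplogroupNode",
    "HaplogroupCall",
    "classify_haplogroup",
    "read_haplogroup_tree_tsv",
    "write_haplogroup_tree_tsv",
    "DistanceMatrix",
    "p_distance_matrix",
    "nj_tree",
]


# ---------------------------------------------------------------------------
# pairwise comparison and private variants


@dataclass
class PairwiseComparison:
    n_compared: int
    n_diff: int
    similarity: float
    differences: List[Variant]  # oriented a -> b


def _comparable(
    a: np.ndarray, b: np.ndarray, mask: RegionMask, window: Optional[Tuple[int, int]]
) -> np.ndarray:
    ok = (a < 4) & (b < 4) & ~mask.bool_array(len(a))
    if window is not None:
        w = np.zeros(len(a), dtype=bool)
        w[window[0] - 1 : window[1]] = True
        ok &= w
    return ok


def pairwise_comparison(
    a: GenomeRecord,
    b: GenomeRecord,
    mask: RegionMask = RegionMask(),
    window: Optional[Tuple[int, int]] = None,
) -> PairwiseComparison:
    """Masked p-distance style comparison of two same-frame genomes.

    Positions masked, outside the optional window, or N in either genome
    are excluded; ``similarity = 1 - n_diff / n_compared``.
    """
    if a.length != b.length:
        raise ValidationError("genomes are not in the same coordinate frame")
    ca, cb = a.codes(), b.codes()
    ok = _comparable(ca, cb, mask, window)
    n_compared = int(ok.sum())
    if n_compared == 0:
        raise UndefinedEstimateError("no comparable positions between genomes")
    diff_idx = np.flatnonzero(ok & (ca != cb))
    diffs = [
        Variant(int(i) + 1, "ACGT"[ca[i]], "ACGT"[cb[i]]) for i in diff_idx
    ]
    n_diff = len(diffs)
    return PairwiseComparison(
        n_compared=n_compared,
        n_diff=n_diff,
        similarity=1.0 - n_diff / n_compared,
        differences=diffs,
    )


def private_variants(
    clade: Sequence[GenomeRecord],
    focal: str,
    mask: RegionMask = RegionMask(),
) -> List[Variant]:
    """Unmasked positions where the focal genome differs from every other
    clade member while the others agree with one another.

    Variants are oriented shared-base → focal-base.  Hotspot-masked sites
    are never reported.
    """
    ids = [g.id for g in clade]
    if focal not in ids:
        raise MissingTaxonError(f"focal genome {focal!r} not in clade {ids}")
    if len(clade) < 2:
        raise ConfigError("private variants need at least two genomes")
    focal_g = clade[ids.index(focal)]
    others = [g for g in clade if g.id != focal]
    fc = focal_g.codes()
    oc = np.stack([g.codes() for g in others])
    masked = mask.bool_array(focal_g.length)
    agree = (oc == oc[0]).all(axis=0) & (oc[0] < 4)
    informative = agree & (fc < 4) & ~masked
    private = informative & (fc != oc[0])
    return [
        Variant(int(i) + 1, "ACGT"[oc[0][i]], "ACGT"[fc[i]])
        for i in np.flatnonzero(private)
    ]


# ---------------------------------------------------------------------------
# haplogroup classification


@dataclass
class HaplogroupNode:
    """A clade in a defining-variant tree (root may define nothing)."""

    name: str
    defining_variants: List[Variant]
    children: List["HaplogroupNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()

    def validate(self) -> None:
        names = [n.name for n in self.walk()]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TreeError(f"duplicate node names in haplogroup tree: {sorted(dupes)}")


@dataclass
class HaplogroupCall:
    """Result of a greedy root-to-tip descent."""

    call: str
    path: List[str]
    node_support: Dict[str, Tuple[int, int]]  # name -> (matched, assessable)
    ambiguous: bool
    ambiguous_children: List[str]


def _variant_support(
    genome_codes: np.ndarray,
    node: HaplogroupNode,
    masked: np.ndarray,
) -> Tuple[int, int]:
    matched = assessable = 0
    for v in node.defining_variants:
        i = v.position - 1
        if masked[i] or genome_codes[i] >= 4:
            continue
        assessable += 1
        if "ACGT"[genome_codes[i]] == v.alt_base:
            matched += 1
    return matched, assessable


def classify_haplogroup(
    genome: GenomeRecord,
    tree: HaplogroupNode,
    root_ref: GenomeRecord,
    mask: RegionMask = RegionMask(),
    match_fraction: float = 0.8,
    exact: bool = False,
) -> HaplogroupCall:
    """Greedy descent: enter a child when the genome carries enough of its
    unmasked, non-N defining variants; the deepest node reached is the call.

    With ``exact=True`` a child is entered only if every defining variant
    is assessable and matched.  If two children qualify at a node, both are
    reported and the call is flagged ambiguous (the call stays at the
    parent).
    """
    tree.validate()
    if genome.length != root_ref.length:
        raise ValidationError("genome and root reference frames differ")
    codes = genome.codes()
    masked = mask.bool_array(genome.length)

    node = tree
    path = [tree.name]
    support: Dict[str, Tuple[int, int]] = {}
    ambiguous = False
    ambiguous_children: List[str] = []
    while True:
        qualifying = []
        for child in node.children:
            matched, assessable = _variant_support(codes, child, masked)
            support[child.name] = (matched, assessable)
            if exact:
                ok = assessable == len(child.defining_variants) and matched == assessable and assessable > 0
            else:
                ok = assessable > 0 and matched / assessable >= match_fraction
            if ok:
                qualifying.append(child)
        if len(qualifying) == 1:
            node = qualifying[0]
            path.append(node.name)
        elif len(qualifying) > 1:
            ambiguous = True
            ambiguous_children = [c.name for c in qualifying]
            break
        else:
            break
    return HaplogroupCall(
        call=node.name,
        path=path,
        node_support=support,
        ambiguous=ambiguous,
        ambiguous_children=ambiguous_children,
    )


def read_haplogroup_tree_tsv(path) -> HaplogroupNode:
    """Read a ``node<TAB>parent<TAB>comma-separated variants`` tree table.

    The root row has an empty parent field.
    """
    nodes: Dict[str, HaplogroupNode] = {}
    parents: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            name, parent, var_field = parts
            if name in nodes:
                raise TreeError(f"{path}:{lineno}: duplicate node {name!r}")
            variants = [
                parse_variant(tok) for tok in var_field.split(",") if tok.strip()
            ]
            nodes[name] = HaplogroupNode(name, variants)
            parents[name] = parent
    roots = [n for n, p in parents.items() if not p]
    if len(roots) != 1:
        raise TreeError(f"{path}: expected exactly one root row, found {roots}")
    for name, parent in parents.items():
        if parent:
            if parent not in nodes:
                raise TreeError(f"{path}: unknown parent {parent!r} of {name!r}")
            nodes[parent].children.append(nodes[name])
    root = nodes[roots[0]]
    root.validate()
    return root


def write_haplogroup_tree_tsv(tree: HaplogroupNode, path) -> None:
    with open(path, "w") as fh:
        def emit(node: HaplogroupNode, parent: str) -> None:
            labels = ",".join(v.label for v in node.defining_variants)
            fh.write(f"{node.name}\t{parent}\t{labels}\n")
            for child in node.children:
                emit(child, node.name)

        emit(tree, "")


# ---------------------------------------------------------------------------
# distance matrices and neighbor joining


@dataclass
class DistanceMatrix:
    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=0.0):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.values < 0.0):
            raise ValidationError("distances must be nonnegative")


def p_distance_matrix(
    genomes: Sequence[GenomeRecord],
    mask: RegionMask = RegionMask(),
    region: str = "complete",
) -> DistanceMatrix:
    """Pairwise masked p-distances (diff fraction over comparable sites).

    ``region="coding"`` restricts the comparison to the coding-region
    window (positions 577–16023 of the standard frame).
    """
    if len(genomes) < 2:
        raise ConfigError("need at least two genomes")
    if region not in ("complete", "coding"):
        raise ConfigError(f"region must be 'complete' or 'coding', got {region!r}")
    window = CODING_REGION if region == "coding" else None
    n = len(genomes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cmp = pairwise_comparison(genomes[i], genomes[j], mask, window)
            d[i, j] = d[j, i] = cmp.n_diff / cmp.n_compared
    return DistanceMatrix([g.id for g in genomes], d)


class _NJNode:
    __slots__ = ("name", "children", "min_leaf")

    def __init__(self, name: Optional[str], children=None, min_leaf: str = ""):
        self.name = name
        self.children: List[Tuple["_NJNode", float]] = children or []
        self.min_leaf = min_leaf if min_leaf else (name or "")

    def newick(self) -> str:
        if not self.children:
            return self.name or ""
        parts = [
            f"{child.newick()}:{bl:.10g}"
            for child, bl in sorted(self.children, key=lambda cb: cb[0].min_leaf)
        ]
        label = self.name or ""
        return f"({','.join(parts)}){label}"


def nj_tree(dm: DistanceMatrix, outgroup: Optional[str] = None) -> str:
    """Neighbor joining; returns a Newick string with branch lengths.

    Exact on additive matrices.  Without an outgroup the tree is emitted
    from the final trifurcating node (unrooted convention); with an
    outgroup, the tree is rooted at the midpoint of the outgroup's pendant
    edge.  Pair selection ties are broken by the smallest leaf label of
    each subtree, so output is deterministic.
    """
    n = len(dm.labels)
    if n < 3:
        raise ConfigError("neighbor joining needs at least 3 taxa")
    if outgroup is not None and outgroup not in dm.labels:
        raise MissingTaxonError(f"outgroup {outgroup!r} not among taxa {dm.labels}")

    # active nodes sorted by min leaf label for deterministic iteration
    order = sorted(range(n), key=lambda i: dm.labels[i])
    nodes: List[_NJNode] = [_NJNode(dm.labels[i]) for i in order]
    D = dm.values[np.ix_(order, order)].copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        # Q criterion; first strictly-smallest pair in sorted order wins
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-14:
                    best = (q, i, j)
        _, i, j = best
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        new = _NJNode(
            None,
            children=[(nodes[i], li), (nodes[j], lj)],
            min_leaf=min(nodes[i].min_leaf, nodes[j].min_leaf),
        )
        dk = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D_new = np.zeros((m - 1, m - 1))
        D_new[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D_new[m - 2, : m - 2] = D_new[: m - 2, m - 2] = dk[keep]
        remaining = [nodes[x] for x in keep] + [new]
        # keep sorted by min leaf label
        resort = sorted(range(m - 1), key=lambda x: remaining[x].min_leaf)
        nodes = [remaining[x] for x in resort]
        D = D_new[np.ix_(resort, resort)]

    # final trifurcation: three-point formulas
    a, b, c = 0, 1, 2
    la = (D[a, b] + D[a, c] - D[b, c]) / 2.0
    lb = (D[a, b] + D[b, c] - D[a, c]) / 2.0
    lc = (D[a, c] + D[b, c] - D[a, b]) / 2.0
    center = _NJNode(
        None,
        children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)],
        min_leaf=min(x.min_leaf for x in nodes),
    )

    if outgroup is None:
        return center.newick() + ";"

    # root on the outgroup's pendant edge (adjacency walk)
    adjacency: Dict[int, List[Tuple[int, float]]] = {}
    node_of: Dict[int, _NJNode] = {}

    def collect(node: _NJNode) -> int:
        nid = id(node)
        node_of[nid] = node
        adjacency.setdefault(nid, [])
        for child, bl in node.children:
            cid = collect(child)
            adjacency[nid].append((cid, bl))
            adjacency[cid].append((nid, bl))
        return nid

    collect(center)
    leaf_id = next(
        nid for nid, node in node_of.items() if node.name == outgroup
    )
    (nbr_id, bl), = adjacency[leaf_id]

    def build(nid: int, parent: int) -> _NJNode:
        node = node_of[nid]
        if node.name is not None and not [
            c for c, _ in adjacency[nid] if c != parent
        ]:
            return _NJNode(node.name)
        children = []
        for cid, length in adjacency[nid]:
            if cid == parent:
                continue
            sub = build(cid, nid)
            children.append((sub, length))
        built = _NJNode(node.name, children=children)
        built.min_leaf = min(c.min_leaf for c, _ in children) if children else (node.name or "")
        return built

    out_leaf = _NJNode(outgroup)
    subtree = build(nbr_id, leaf_id)
    root = _NJNode(
        None,
        children=[(out_leaf, bl / 2.0), (subtree, bl / 2.0)],
        min_leaf=min(out_leaf.min_leaf, subtree.min_leaf),
    )
    return root.newick() + ";"
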