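"""Tumor purity, cancer cell fraction, clonality, and parsimony phylogenies.

Purity is read off the B-allele frequency of loss-of-heterozygosity (LOH)
regions under a single-copy-loss mixture model: a tumor of purity ``p``
retaining one parental allele shows a major-allele BAF of ``1 / (2 - p)``,
so ``p = 2 - 1/b``.  The cancer cell fraction of a variant with allele
frequency ``vaf`` in local tumor copy number ``nt`` (normal ``nn``) at
multiplicity ``m`` is ``ccf = vaf * (p*nt + (1-p)*nn) / (p*m)``; a mutation
is clonal when its CCF reaches 0.8.

Trees over tumor components/regions are maximum-parsimony trees over binary
presence/absence characters with an all-reference (germline) outgroup,
found by exhaustive search over unrooted topologies (up to 9 leaves
including the outgroup) scored by the Fitch algorithm; branch lengths are
the per-edge character changes of a minimum reconstruction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLONAL_CCF",
    "PurityEstimate",
    "CcfAnnotation",
    "PhyloTree",
    "DriverPlacement",
    "estimate_purity",
    "compute_ccf",
    "partition_trunk_branch",
    "build_parsimony_tree",
    "place_drivers",
    "enumerate_unrooted_topologies",
]

#: a mutation is clonal when its cancer cell fraction reaches this value
CLONAL_CCF = 0.8
#: CCF values may exceed 1 by at most this much during multiplicity search
CCF_TOLERANCE = 0.2
MAX_REGIONS = 8


# ---------------------------------------------------------------------------
# purity and CCF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PurityEstimate:
    purity: float
    n_loh_regions: int
    region_bafs: tuple

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0,1], got {self.purity}")


def estimate_purity(
    segments=None,
    loh_variants=None,
    model: str = "single_copy_loss",
) -> PurityEstimate:
    """Estimate tumor purity from major-allele BAF in LOH regions.

    BAF values are collected from segments carrying a ``baf`` field and/or
    from variants already called as LOH (their VAF read as the major-allele
    BAF).  Only values strictly above 0.5 are informative.  Per-region
    purity is ``2 - 1/b`` under single-copy loss (or ``2b - 1`` for
    copy-neutral LOH); the estimate is the median across regions, clipped
    to (0, 1].

    Raises
    ------
    ValueError
        When no LOH region with BAF > 0.5 is available.
    """
    bafs = []
    for s in segments or ():
        if s.baf is not None:
            bafs.append(float(s.baf))
    for v in loh_variants or ():
        bafs.append(float(v.vaf))
    informative = [b for b in bafs if 0.5 < b <= 1.0]
    if not informative:
        raise ValueError("purity unestimable: no LOH region with BAF > 0.5")
    if model == "single_copy_loss":
        purities = [2.0 - 1.0 / b for b in informative]
    elif model == "copy_neutral":
        purities = [2.0 * b - 1.0 for b in informative]
    else:
        raise ValueError(f"unknown purity model {model!r}")
    p = float(np.clip(np.median(purities), 1e-9, 1.0))
    return PurityEstimate(p, len(informative), tuple(informative))


@dataclass(frozen=True)
class CcfAnnotation:
    ccf: float            # capped at 1 for reporting
    ccf_raw: float
    multiplicity: int
    clonal: bool


def compute_ccf(
    vaf: float,
    purity: float,
    tumor_cn: int = 2,
    normal_cn: int = 2,
    multiplicity: int | None = None,
) -> CcfAnnotation:
    """Cancer cell fraction of a variant from VAF, purity and copy number.

    When ``multiplicity`` is None it is resolved as the value in
    ``1..tumor_cn`` minimising ``|ccf - 1|`` subject to
    ``ccf <= 1 + 0.2`` (falling back to the least-excess multiplicity when
    every candidate overshoots).
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    if tumor_cn < 1:
        raise ValueError("tumor copy number must be >= 1")
    if not 0.0 <= vaf <= 1.0:
        raise ValueError("vaf must be in [0, 1]")
    denom_cn = purity * tumor_cn + (1.0 - purity) * normal_cn

    def ccf_for(m: int) -> float:
        return vaf * denom_cn / (purity * m)

    if multiplicity is None:
        candidates = [(m, ccf_for(m)) for m in range(1, tumor_cn + 1)]
        admissible = [(m, c) for m, c in candidates if c <= 1.0 + CCF_TOLERANCE]
        if admissible:
            multiplicity, raw = min(admissible, key=lambda mc: (abs(mc[1] - 1.0), mc[0]))
        else:
            multiplicity, raw = min(candidates, key=lambda mc: (mc[1], mc[0]))
    else:
        if not 1 <= multiplicity <= tumor_cn:
            raise ValueError("multiplicity must be in 1..tumor_cn")
        raw = ccf_for(multiplicity)
    capped = float(min(raw, 1.0))
    return CcfAnnotation(
        ccf=capped, ccf_raw=float(raw), multiplicity=int(multiplicity),
        clonal=capped >= CLONAL_CCF,
    )


# ---------------------------------------------------------------------------
# trunk / branch partition of two components
# ---------------------------------------------------------------------------

def partition_trunk_branch(component_a, component_b) -> dict:
    """Split two components' variant keys into trunk (shared) and branches.

    Returns a dict with the three key sets, their counts, and the trunk
    fraction (shared / union).
    """
    a, b = set(component_a), set(component_b)
    union = a | b
    if not union:
        raise ValueError("cannot partition an empty variant union")
    trunk = a & b
    return {
        "trunk": trunk,
        "branch_a": a - b,
        "branch_b": b - a,
        "n_trunk": len(trunk),
        "n_branch_a": len(a - b),
        "n_branch_b": len(b - a),
        "trunk_fraction": len(trunk) / len(union),
    }


# ---------------------------------------------------------------------------
# maximum-parsimony trees (exhaustive Fitch)
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(n_leaves: int):
    """Yield every unrooted binary topology over leaves ``0..n_leaves-1``.

    Trees are edge lists ``[(u, v), ...]`` with internal nodes numbered
    from ``n_leaves`` upward, built by stepwise leaf addition (so the count
    is 1, 3, 15, 105, ... double factorials).
    """
    if n_leaves < 3:
        raise ValueError("need >= 3 leaves for an unrooted topology")

    def grow(edges, next_leaf, next_internal):
        if next_leaf == n_leaves:
            yield edges
            return
        for i, (u, v) in enumerate(edges):
            w = next_internal
            new_edges = edges[:i] + edges[i + 1:] + [(u, w), (v, w), (next_leaf, w)]
            yield from grow(new_edges, next_leaf + 1, next_internal + 1)

    first = [(0, n_leaves), (1, n_leaves), (2, n_leaves)]
    yield from grow(first, 3, n_leaves + 1)


def _root_at(edges, root):
    """Children lists of the tree rooted at ``root``; returns (children, order).

    ``order`` is a postorder list of nodes (root last).
    """
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    children: dict = {}
    order = []
    stack = [(root, None, False)]
    while stack:
        node, parent, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        kids = [x for x in adj[node] if x != parent]
        children[node] = kids
        stack.append((node, parent, True))
        for k in kids:
            stack.append((k, node, False))
    return children, order


def _fitch_sets(children, order, leaf_states):
    """Bottom-up Fitch state sets (bitmask 1={0}, 2={1}, 3=both) and score."""
    n_chars = next(iter(leaf_states.values())).shape[0] if leaf_states else 0
    sets: dict = {}
    score = np.zeros(n_chars, dtype=np.int32)
    for node in order:
        # the root is the outgroup leaf: its own state joins the combine
        parts = [leaf_states[node]] if node in leaf_states else []
        parts += [sets[k] for k in children[node]]
        s = parts[0]
        for t in parts[1:]:
            inter = s & t
            score += (inter == 0)
            s = np.where(inter != 0, inter, s | t).astype(np.uint8)
        sets[node] = s
    return sets, score


@dataclass
class DriverPlacement:
    variant: object
    edges: list            # (parent, child) node-id pairs carrying the gain
    homoplasy: bool
    clonal: bool | None = None


@dataclass
class PhyloTree:
    """Rooted view of a maximum-parsimony tree (root = germline outgroup)."""

    leaf_names: dict                 # node id -> name (includes outgroup)
    root: int                        # node id of the outgroup leaf
    children: dict                   # node id -> list of child node ids
    edge_lengths: dict               # (parent, child) -> number of changes
    parsimony_length: int
    node_states: dict = field(default_factory=dict)   # node -> 0/1 array per char
    char_names: list = field(default_factory=list)
    driver_placements: dict = field(default_factory=dict)

    @property
    def edges(self) -> list:
        return list(self.edge_lengths)

    def splits(self) -> frozenset:
        """Non-trivial splits as frozensets of leaf names (outgroup side dropped)."""
        leaf_ids = set(self.leaf_names)
        below: dict = {}

        def collect(node):
            if not self.children[node]:
                below[node] = {node}
                return below[node]
            acc = set()
            for k in self.children[node]:
                acc |= collect(k)
            below[node] = acc
            return acc

        collect(self.root)
        out = set()
        for parent, child in self.edge_lengths:
            side = below[child] & leaf_ids
            if 1 < len(side) < len(leaf_ids) - 1:
                out.add(frozenset(self.leaf_names[i] for i in side))
        return frozenset(out)

    def newick(self) -> str:
        """Newick string rooted at the outgroup, branch lengths = changes."""

        def rec(node, parent):
            name = self.leaf_names.get(node, "")
            kids = self.children[node]
            label = name if not kids else (
                "(" + ",".join(rec(k, node) for k in kids) + ")" + name
            )
            if parent is None:
                return label
            ln = self.edge_lengths[(parent, node)]
            return f"{label}:{ln}"

        inner = ",".join(rec(k, self.root) for k in self.children[self.root])
        return f"({inner}){self.leaf_names[self.root]};"


def _canonical_splits(edges, n_leaves, outgroup):
    """Sorted tuple of leaf partitions (side away from the outgroup) per edge."""
    children, order = _root_at(edges, outgroup)
    below: dict = {}
    for node in order:
        kids = children[node]
        below[node] = {node} if not kids else set().union(*(below[k] for k in kids))
    reps = []
    for parent in children:
        for child in children[parent]:
            reps.append(tuple(sorted(x for x in below[child] if x < n_leaves)))
    return tuple(sorted(reps))


def build_parsimony_tree(
    presence_matrix,
    region_names=None,
    char_names=None,
    outgroup_name: str = "germline",
) -> PhyloTree:
    """Exhaustive maximum-parsimony tree over binary presence characters.

    Parameters
    ----------
    presence_matrix
        Regions x variants array of 0/1 (DataFrame accepted; NaN treated as
        absent).  2 to 8 regions; an all-absent germline outgroup is
        appended automatically.

    Among equally parsimonious topologies the one with the
    lexicographically smallest leaf-partition representation is returned,
    so the output is deterministic.
    """
    if hasattr(presence_matrix, "to_numpy"):
        if region_names is None:
            region_names = list(presence_matrix.index)
        if char_names is None:
            char_names = list(presence_matrix.columns)
        presence_matrix = presence_matrix.to_numpy()
    M = np.nan_to_num(np.asarray(presence_matrix, dtype=float), nan=0.0)
    M = (M > 0.5).astype(np.uint8)
    n_regions, n_chars = M.shape
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if n_regions > MAX_REGIONS:
        raise ValueError(
            f"{n_regions} regions exceeds the exhaustive-search limit of "
            f"{MAX_REGIONS}; reduce regions or pre-cluster them"
        )
    if region_names is None:
        region_names = [f"R{i+1}" for i in range(n_regions)]
    if char_names is None:
        char_names = [f"var{j+1}" for j in range(n_chars)]

    n_leaves = n_regions + 1
    outgroup = n_regions  # appended as the last leaf
    leaf_states = {
        i: (M[i] + 1).astype(np.uint8) for i in range(n_regions)  # 1={0}, 2={1}
    }
    leaf_states[outgroup] = np.ones(n_chars, dtype=np.uint8)

    best_score, best_edges, best_canon = None, None, None
    for edges in enumerate_unrooted_topologies(n_leaves):
        children, order = _root_at(edges, outgroup)
        _, score = _fitch_sets(children, order, leaf_states)
        total = int(score.sum())
        if best_score is None or total < best_score:
            best_score, best_edges, best_canon = total, edges, None
        elif total == best_score:
            # canonicalise lazily, only when ties actually occur
            if best_canon is None:
                best_canon = _canonical_splits(best_edges, n_leaves, outgroup)
            cur = _canonical_splits(edges, n_leaves, outgroup)
            if cur < best_canon:
                best_edges, best_canon = edges, cur

    total, edges = best_score, best_edges
    children, order = _root_at(edges, outgroup)
    sets, _ = _fitch_sets(children, order, leaf_states)

    # top-down minimum reconstruction: root (outgroup) is reference state 0
    states: dict = {outgroup: np.zeros(n_chars, dtype=np.uint8)}
    for node in reversed(order):  # preorder
        for k in children[node]:
            parent_state = states[node]
            parent_bit = (parent_state + 1).astype(np.uint8)  # state -> bitmask
            child_set = sets[k]
            keep = (child_set & parent_bit) != 0
            other = np.where(child_set == 3, parent_state, child_set - 1)
            states[k] = np.where(keep, parent_state, other).astype(np.uint8)

    edge_lengths = {}
    for node in reversed(order):
        for k in children[node]:
            edge_lengths[(node, k)] = int((states[node] != states[k]).sum())
    assert sum(edge_lengths.values()) == total

    leaf_names = {i: str(region_names[i]) for i in range(n_regions)}
    leaf_names[outgroup] = outgroup_name
    return PhyloTree(
        leaf_names=leaf_names,
        root=outgroup,
        children=children,
        edge_lengths=edge_lengths,
        parsimony_length=total,
        node_states=states,
        char_names=list(char_names),
    )


def place_drivers(tree: PhyloTree, driver_names, ccf_by_region: dict | None = None) -> PhyloTree:
    """Attach driver mutations to the tree edges where they were acquired.

    Each driver (a character name of the tree's matrix) is placed on the
    edge(s) where the minimum reconstruction switches from absent to
    present; several gain edges mean homoplasy and are flagged.  When
    ``ccf_by_region`` maps ``(driver, region) -> CcfAnnotation`` (or float
    CCF), the placement is annotated clonal when the median CCF over the
    regions carrying the driver reaches 0.8.
    """
    name_to_col = {n: j for j, n in enumerate(tree.char_names)}
    for driver in driver_names:
        if driver not in name_to_col:
            raise KeyError(f"driver {driver!r} not among tree characters")
        j = name_to_col[driver]
        gain_edges = [
            e for e in tree.edge_lengths
            if tree.node_states[e[0]][j] == 0 and tree.node_states[e[1]][j] == 1
        ]
        clonal = None
        if ccf_by_region is not None:
            ccfs = []
            for node, name in tree.leaf_names.items():
                if node == tree.root or tree.node_states[node][j] != 1:
                    continue
                ann = ccf_by_region.get((driver, name))
                if ann is not None:
                    ccfs.append(ann.ccf if hasattr(ann, "ccf") else float(ann))
            if ccfs:
                clonal = bool(np.median(ccfs) >= CLONAL_CCF)
        tree.driver_placements[driver] = DriverPlacement(
            variant=driver, edges=gain_edges,
            homoplasy=len(gain_edges) > 1, clonal=clonal,
        )
    return tree
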