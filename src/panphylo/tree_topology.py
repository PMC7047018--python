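"""Gene trees, outgroup screening, topology census and bootstrap supports.

Each masked codon alignment yields one unrooted tree (neighbor joining on
Jukes-Cantor distances by default; the tree builder is pluggable).  Trees
in which the rice/brachypodium outgroup pair is not monophyletic and
sister to all other taxa are rejected; the rest are rooted on that edge,
reduced to a canonical branch-length-free string, and tallied.  Census
percentages are truncated (not rounded) to one decimal.  Bootstrap
supports resample masked codon columns, rebuild trees, and average
per-branch support across the groups sharing a topology class.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .align_qc import CodonAlignment
from .species import OUTGROUP

MAX_DISTANCE = 5.0  # clamp for saturated JC distances


@dataclass
class RootedTopology:
    canonical: str
    count: int
    members: list[tuple[str, int]] = field(default_factory=list)  # (group, combo)
    avg_support: dict[frozenset, float] = field(default_factory=dict)


def truncate_percent(count: float, total: float, decimals: int = 1) -> float:
    """100*count/total truncated (floored) at the given decimal place."""
    if total == 0:
        return 0.0
    scale = 10 ** decimals
    return math.floor(100.0 * count / total * scale) / scale


def jc_distance_matrix(rows: Mapping[str, str], max_distance: float = MAX_DISTANCE) -> DistanceMatrix:
    """Pairwise Jukes-Cantor distances over shared non-gap columns."""
    ids = sorted(rows)
    arrs = {sp: np.frombuffer(rows[sp].encode(), dtype="S1") for sp in ids}
    gap = np.bytes_("-")
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            ok = (a != gap) & (b != gap)
            sites = int(ok.sum())
            if sites == 0:
                dist = max_distance
            else:
                p = float((a[ok] != b[ok]).sum()) / sites
                if p >= 0.75:
                    dist = max_distance
                else:
                    dist = min(-0.75 * math.log(1.0 - 4.0 * p / 3.0), max_distance)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """NJ tree (standard Q-matrix agglomeration) as an unrooted dendropy tree."""
    newick = str(_skbio_nj(dm))
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def build_tree(a: CodonAlignment, masked: bool = True) -> dendropy.Tree:
    """Tree from a codon alignment; requires >= 4 rows and >= 1 masked codon."""
    if len(a.rows) < 4:
        raise ValueError("tree building requires at least 4 taxa")
    rows = a.masked_rows() if masked else dict(a.rows)
    if len(next(iter(rows.values()))) < 3:
        raise ValueError("masked alignment shorter than one codon")
    return neighbor_joining(jc_distance_matrix(rows))


def check_outgroup_and_root(
    t: dendropy.Tree, outgroup: frozenset = OUTGROUP
) -> Optional[dendropy.Tree]:
    """Root on the outgroup bipartition, or None when it does not exist.

    The tree is accepted when some edge splits exactly the outgroup taxa
    from everything else; the returned tree is rooted on that edge.
    """
    labels = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    missing = set(outgroup) - labels
    if missing:
        raise ValueError(f"outgroup taxa missing from tree: {sorted(missing)}")
    tree = t.clone(depth=1)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below == set(outgroup) or (labels - below) == set(outgroup):
            edge = node.edge
            length = edge.length or 0.0
            tree.reroot_at_edge(edge, length1=length / 2.0, length2=length / 2.0)
            tree.is_rooted = True
            return tree
    return None


def canonical_topology(rt: dendropy.Tree) -> str:
    """Branch-length-free canonical string, invariant under child rotation."""
    labels = [leaf.taxon.label for leaf in rt.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels")

    def rec(node) -> str:
        if node.is_leaf():
            return node.taxon.label
        return "(" + ",".join(sorted(rec(c) for c in node.child_nodes())) + ")"

    return rec(rt.seed_node)


def canonical_from_newick(newick: str) -> str:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return canonical_topology(tree)


def census(
    rooted: Sequence[tuple[str, int, dendropy.Tree]]
) -> list[RootedTopology]:
    """Tally canonical topologies of accepted rooted trees.

    ``rooted`` holds (group_id, combo_index, tree) records.  The result is
    sorted by count descending, ties broken by canonical string order.
    """
    tally: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for group_id, combo, tree in rooted:
        tally[canonical_topology(tree)].append((group_id, combo))
    out = [
        RootedTopology(canonical=c, count=len(members), members=members)
        for c, members in tally.items()
    ]
    out.sort(key=lambda t: (-t.count, t.canonical))
    return out


def census_table(topologies: Sequence[RootedTopology]) -> pd.DataFrame:
    total = sum(t.count for t in topologies)
    rows = [
        {
            "rank": i + 1,
            "canonical": t.canonical,
            "count": t.count,
            "percent": truncate_percent(t.count, total),
        }
        for i, t in enumerate(topologies)
    ]
    return pd.DataFrame(rows, columns=["rank", "canonical", "count", "percent"])


def _clades(rt: dendropy.Tree) -> list[frozenset]:
    """Non-trivial clades (internal nodes below the root) as leaf-label sets."""
    out = []
    for node in rt.preorder_internal_node_iter():
        if node is rt.seed_node:
            continue
        out.append(frozenset(leaf.taxon.label for leaf in node.leaf_iter()))
    return out


def bootstrap_support(
    alignments: Sequence[CodonAlignment],
    n_trees: int,
    reps: int,
    seed: int,
    outgroup: frozenset = OUTGROUP,
) -> dict[str, dict[frozenset, float]]:
    """Column-resampling bootstrap, averaged per topology class.

    ``n_trees`` alignments are drawn without replacement.  For each, the
    masked codon columns are resampled with replacement ``reps`` times and
    trees rebuilt; the support of each branch of that alignment's best
    tree is the percentage of replicates containing the branch.  Groups
    are binned by the canonical topology of their best tree and supports
    averaged within each bin.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n_trees > len(alignments):
        raise ValueError("n_trees exceeds the number of available alignments")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(alignments), size=n_trees, replace=False)
    per_topology: dict[str, list[dict[frozenset, float]]] = defaultdict(list)
    for idx in sorted(chosen):
        a = alignments[idx]
        best = check_outgroup_and_root(build_tree(a), outgroup)
        if best is None:
            continue
        best_clades = _clades(best)
        rows = a.masked_rows()
        ncod = len(next(iter(rows.values()))) // 3
        hits = {c: 0 for c in best_clades}
        for _ in range(reps):
            cols = rng.integers(0, ncod, size=ncod)
            resampled = {
                sp: "".join(row[3 * c : 3 * c + 3] for c in cols)
                for sp, row in rows.items()
            }
            rep_tree = check_outgroup_and_root(
                neighbor_joining(jc_distance_matrix(resampled)), outgroup
            )
            if rep_tree is None:
                continue
            rep_clades = set(_clades(rep_tree))
            for c in best_clades:
                if c in rep_clades:
                    hits[c] += 1
        supports = {c: 100.0 * h / reps for c, h in hits.items()}
        per_topology[canonical_topology(best)].append(supports)
    averaged: dict[str, dict[frozenset, float]] = {}
    for topo, slist in per_topology.items():
        keys = set().union(*(s.keys() for s in slist))
        averaged[topo] = {
            c: float(np.mean([s.get(c, 0.0) for s in slist])) for c in keys
        }
    return averaged
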