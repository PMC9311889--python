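"""Distance trees: UPGMA (rooted, ultrametric) and neighbor-joining.

Both algorithms are implemented here with fully deterministic
tie-breaking (the lexicographically smallest label pair wins), so a given
matrix always yields the same Newick string. Trees are scikit-bio
``TreeNode`` objects; Newick reading/writing goes through that library.
"""

from __future__ import annotations

import io as _io
from typing import Callable

import numpy as np
from skbio import TreeNode

from .distances import DistanceMatrix, population_distance_matrix
from .errors import MitopopError
from .haplotypes import collapse_haplotypes
from .io import Alignment


def _pairs(labels: list[str]):
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            yield a, b


def upgma(d: DistanceMatrix) -> TreeNode:
    """Average-linkage agglomerative tree.

    Node heights are half the merge distance, so root-to-leaf path lengths
    are all equal (ultrametric). Ties pick the lexicographically smallest
    label pair, comparing each cluster's smallest member label.
    """
    if len(d.labels) < 2:
        raise MitopopError("UPGMA needs at least two labels")
    nodes: dict[str, TreeNode] = {
        lab: TreeNode(name=lab, length=None) for lab in d.labels
    }
    height = {lab: 0.0 for lab in d.labels}
    size = {lab: 1 for lab in d.labels}
    # cluster key = smallest member label (stable, deterministic)
    dist = {
        frozenset((a, b)): float(d.loc(a, b)) for a, b in _pairs(list(d.labels))
    }
    active = sorted(d.labels)
    while len(active) > 1:
        best = min(
            ((dist[frozenset((a, b))], a, b) for a, b in _pairs(active)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        dm, a, b = best
        h = dm / 2.0
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length = h - height[a]
        child_b.length = h - height[b]
        new = TreeNode(children=[child_a, child_b])
        key = min(a, b)
        other = max(a, b)
        for c in active:
            if c in (a, b):
                continue
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            dist[frozenset((key, c))] = (
                (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
            )
        dist.pop(frozenset((a, b)))
        active.remove(other)
        nodes[key] = new
        height[key] = h
        size[key] = size[a] + size[b]
    root = nodes[active[0]]
    root.length = None
    return root


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining (unrooted; root is the final
    trifurcation/bifurcation).

    Negative branch lengths are clamped to zero and the deficit moved to
    the sister branch, preserving the pair's summed length. Q-matrix ties
    break on the lexicographically smallest label pair.
    """
    labels = list(d.labels)
    if len(labels) < 3:
        raise MitopopError("neighbor joining needs at least three labels")
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    dist = {frozenset((a, b)): float(d.loc(a, b)) for a, b in _pairs(labels)}
    active = sorted(labels)
    while len(active) > 2:
        r = len(active)
        totals = {
            a: sum(dist[frozenset((a, c))] for c in active if c != a)
            for a in active
        }
        best = min(
            (
                ((r - 2) * dist[frozenset((a, b))] - totals[a] - totals[b], a, b)
                for a, b in _pairs(active)
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        _, a, b = best
        dab = dist[frozenset((a, b))]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2.0 * (r - 2))
        lb = dab - la
        # clamp negatives, transferring length to the sister edge
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length = max(la, 0.0)
        child_b.length = max(lb, 0.0)
        new = TreeNode(children=[child_a, child_b])
        key = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            dac = dist.pop(frozenset((a, c)))
            dbc = dist.pop(frozenset((b, c)))
            dist[frozenset((key, c))] = 0.5 * (dac + dbc - dab)
        dist.pop(frozenset((a, b)))
        active.remove(max(a, b))
        nodes[key] = new
    a, b = active
    dab = dist[frozenset((a, b))]
    na, nb = nodes[a], nodes[b]
    if na.is_tip():
        na, nb = nb, na
        # attach the tip under the internal node
    nb.length = dab
    na.append(nb)
    na.length = None
    return na


def root_with_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Re-root an (unrooted) tree on the edge leading to the outgroup tip."""
    tips = {t.name for t in tree.tips()}
    if outgroup not in tips:
        raise MitopopError(f"outgroup {outgroup!r} not among tips")
    return tree.root_at(tree.find(outgroup).parent)


def is_ultrametric(tree: TreeNode, tol: float = 1e-9) -> bool:
    depths = [tree.distance(t) for t in tree.tips()]
    return max(depths) - min(depths) <= tol


def bipartitions(tree: TreeNode, min_length: float = 1e-12) -> set[frozenset[str]]:
    """Non-trivial tip bipartitions (as the smaller-side tip set of each
    internal edge), canonicalised against the full tip set.

    Edges of (near-)zero length carry no resolved signal and are skipped,
    so a tree built from an uninformative matrix supports nothing.
    """
    tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        if node.length is not None and node.length <= min_length:
            continue
        side = frozenset(t.name for t in node.tips())
        if min(len(side), len(tips) - len(side)) >= 2:
            canon = min(side, tips - side, key=lambda s: (len(s), sorted(s)))
            out.add(canon)
    return out


def bootstrap_support(
    aln: Alignment,
    tree_method: str = "nj",
    model: str = "k2p",
    B: int = 1000,
    seed: int | None = None,
    kind: str = "dxy",
) -> TreeNode:
    """Population tree with column-bootstrap support percentages.

    The reference tree is built from the population distance matrix of the
    full alignment; each of B replicates resamples alignment columns with
    replacement, rebuilds the tree, and every internal edge of the
    reference tree is scored by the percentage of replicates containing
    its bipartition. Supports are stored as internal node names.
    """
    if B < 1:
        raise MitopopError("B must be at least 1")
    builders: dict[str, Callable[[DistanceMatrix], TreeNode]] = {
        "nj": neighbor_joining, "upgma": upgma,
    }
    if tree_method not in builders:
        raise ValueError(f"unknown tree method {tree_method!r}")
    build = builders[tree_method]

    def _tree_of(a: Alignment) -> TreeNode:
        tab = collapse_haplotypes(a)
        dm = population_distance_matrix(tab, model=model, kind=kind)
        return build(dm)

    ref = _tree_of(aln)
    npops = len(aln.populations)
    if npops < 3:
        raise MitopopError("bootstrap needs at least three populations")
    rng = np.random.default_rng(seed)
    m = aln.matrix()
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(ref)}
    for _ in range(B):
        cols = rng.integers(aln.length, size=aln.length)
        sub = m[:, cols]
        rep_aln = Alignment(
            ids=list(aln.ids),
            seqs=[row.tobytes().decode() for row in sub],
            population_of=dict(aln.population_of),
        )
        rep_bps = bipartitions(_tree_of(rep_aln))
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    tips = frozenset(t.name for t in ref.tips())
    for node in ref.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        canon = min(side, tips - side, key=lambda s: (len(s), sorted(s)))
        if canon in counts:
            node.name = f"{100.0 * counts[canon] / B:g}"
    return ref


def write_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(text), format="newick")
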