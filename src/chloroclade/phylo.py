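"""TN93 distances, neighbor-joining trees, outgroup rooting, clade calls.

The Tamura–Nei (1993) distance distinguishes the two transition classes
(A<->G, C<->T) from transversions and allows unequal base frequencies.  With
pooled per-pair frequencies ``g`` (``gR = gA+gG``, ``gY = gC+gT``) and
observed difference proportions ``P1`` (A<->G), ``P2`` (C<->T) and ``Q``
(transversions), the estimator is::

    k1 = 2 gA gG / gR
    k2 = 2 gC gT / gY
    k3 = 2 (gR gY - gA gG gY/gR - gC gT gR/gY)
    d  = -k1 ln(1 - P1/k1 - Q/(2 gR))
         -k2 ln(1 - P2/k2 - Q/(2 gY))
         -k3 ln(1 - Q/(2 gR gY))

Columns with a gap or N in either member of a pair are deleted pairwise.
Saturated pairs (any log argument <= 0) raise rather than silently cap.

Neighbor joining follows the classic agglomeration: join the pair
minimising ``Q(i,j) = (n-2) d(i,j) - R(i) - R(j)``, with ties broken by the
lexicographically smallest pair of subtree labels, so the output Newick is
bit-reproducible.  Negative branch lengths are kept (an optional flag
clamps them) because they preserve exact additivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentMatrix, encode_sequence

logger = logging.getLogger(__name__)


class SaturationError(ValueError):
    """A pairwise distance is undefined (log argument <= 0)."""


class OutgroupError(ValueError):
    """The requested outgroup is not monophyletic on the unrooted tree."""


class CladeError(ValueError):
    """The domesticated accessions do not form the expected clade."""


# ---------------------------------------------------------------------------
# TN93
# ---------------------------------------------------------------------------

def tn93_distance(
    seq1: str | np.ndarray, seq2: str | np.ndarray,
    ids: tuple[str, str] = ("seq1", "seq2"),
) -> float:
    """TN93 distance between two aligned sequences (substitutions/site).

    Base frequencies are estimated from the two sequences pooled over the
    pairwise-usable sites.  Identical sequences give exactly 0.
    """
    x = encode_sequence(seq1) if isinstance(seq1, str) else np.asarray(seq1)
    y = encode_sequence(seq2) if isinstance(seq2, str) else np.asarray(seq2)
    if x.shape != y.shape:
        raise ValueError("sequences must have equal aligned length")
    usable = (x < 4) & (y < 4)
    n = int(usable.sum())
    if n == 0:
        raise SaturationError(f"no usable sites for pair {ids}")
    xu, yu = x[usable], y[usable]
    p1 = int((((xu == 0) & (yu == 2)) | ((xu == 2) & (yu == 0))).sum())
    p2 = int((((xu == 1) & (yu == 3)) | ((xu == 3) & (yu == 1))).sum())
    diff = int((xu != yu).sum())
    q = diff - p1 - p2
    base_counts = np.bincount(xu, minlength=4) + np.bincount(yu, minlength=4)
    return _tn93_value(
        n, p1 / n, p2 / n, q / n, base_counts / (2 * n), ids
    )


def _tn93_value(
    n: int, P1: float, P2: float, Q: float, freqs: np.ndarray,
    pair: tuple[str, str],
) -> float:
    gA, gC, gG, gT = (float(f) for f in freqs)
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2 * gC * gT / gY if gY > 0 else 0.0
    k3 = 2 * (gR * gY
              - (gA * gG * gY / gR if gR > 0 else 0.0)
              - (gC * gT * gR / gY if gY > 0 else 0.0))
    total = 0.0
    for k, P, g in ((k1, P1, gR), (k2, P2, gY)):
        if k > 0:
            w = 1 - P / k - Q / (2 * g)
            if w <= 0:
                raise SaturationError(f"saturated transition term for pair {pair}")
            total += -k * np.log(w)
        elif P > 0:
            raise SaturationError(
                f"transition differences without matching base classes for {pair}"
            )
    if k3 > 0 or Q > 0:
        denom = 2 * gR * gY
        if denom <= 0:
            raise SaturationError(f"degenerate base composition for pair {pair}")
        w3 = 1 - Q / denom
        if w3 <= 0:
            raise SaturationError(f"saturated transversion term for pair {pair}")
        total += -k3 * np.log(w3)
    return float(total)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with ordered ids."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        self._index = {a: i for i, a in enumerate(self.ids)}

    def d(self, id1: str, id2: str) -> float:
        return float(self.values[self._index[id1], self._index[id2]])

    def write_tsv(self, path: str | Path, phylip: bool = False) -> None:
        with open(path, "w") as handle:
            if phylip:
                handle.write(f"{len(self.ids)}\n")
                for acc, row in zip(self.ids, self.values):
                    cells = " ".join(f"{v:.6f}" for v in row)
                    handle.write(f"{acc}  {cells}\n")
            else:
                handle.write("\t" + "\t".join(self.ids) + "\n")
                for acc, row in zip(self.ids, self.values):
                    cells = "\t".join(f"{v:.6f}" for v in row)
                    handle.write(f"{acc}\t{cells}\n")


def tn93_distance_matrix(
    alignment: AlignmentMatrix, ids: Optional[Sequence[str]] = None
) -> DistanceMatrix:
    """All-pairs TN93 distances (vectorised over the alignment).

    Pairwise deletion of gap/N columns and per-pair pooled base frequencies,
    identical to :func:`tn93_distance` pair by pair.
    """
    sub = alignment.subset(ids) if ids is not None else alignment
    X = sub.data
    usable = (X < 4)
    Uf = usable.astype(np.float32)
    onehot = [((X == b) & usable).astype(np.float32) for b in range(4)]

    n = Uf @ Uf.T
    nag = onehot[0] @ onehot[2].T
    nct = onehot[1] @ onehot[3].T
    p1c = nag + nag.T
    p2c = nct + nct.T
    same = sum(h @ h.T for h in onehot)
    qc = n - same - p1c - p2c

    base = []
    for h in onehot:
        c = h @ Uf.T
        base.append(c + c.T)

    m = len(sub.ids)
    off = ~np.eye(m, dtype=bool)
    if np.any(n[off] < 1):
        i, j = np.argwhere((n < 1) & off)[0]
        raise SaturationError(
            f"no usable sites for pair ({sub.ids[i]}, {sub.ids[j]})"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        nn = n.astype(np.float64)
        nn[~off] = 1.0
        P1, P2, Q = p1c / nn, p2c / nn, qc / nn
        tot = 2 * nn
        gA, gC, gG, gT = (b / tot for b in base)
        gR, gY = gA + gG, gC + gT
        k1 = np.where(gR > 0, 2 * gA * gG / np.where(gR > 0, gR, 1), 0.0)
        k2 = np.where(gY > 0, 2 * gC * gT / np.where(gY > 0, gY, 1), 0.0)
        k3 = 2 * (gR * gY
                  - np.where(gR > 0, gA * gG * gY / np.where(gR > 0, gR, 1), 0.0)
                  - np.where(gY > 0, gC * gT * gR / np.where(gY > 0, gY, 1), 0.0))
        w1 = np.where(k1 > 0, 1 - P1 / np.where(k1 > 0, k1, 1) - Q / (2 * gR), 1.0)
        w2 = np.where(k2 > 0, 1 - P2 / np.where(k2 > 0, k2, 1) - Q / (2 * gY), 1.0)
        denom = 2 * gR * gY
        w3 = np.where(denom > 0, 1 - Q / np.where(denom > 0, denom, 1), 1.0)

        bad = off & (
            (w1 <= 0) | (w2 <= 0) | (w3 <= 0)
            | ((k1 <= 0) & (P1 > 0)) | ((k2 <= 0) & (P2 > 0))
            | ((denom <= 0) & (Q > 0))
        )
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise SaturationError(
                f"saturated or degenerate pair ({sub.ids[i]}, {sub.ids[j]})"
            )
        D = -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)

    D[~off] = 0.0
    D = (D + D.T) / 2  # symmetrise away float noise
    return DistanceMatrix(list(sub.ids), D)


def p_distance(seq1: str | np.ndarray, seq2: str | np.ndarray) -> float:
    """Proportion of differing usable sites (pairwise deletion)."""
    x = encode_sequence(seq1) if isinstance(seq1, str) else np.asarray(seq1)
    y = encode_sequence(seq2) if isinstance(seq2, str) else np.asarray(seq2)
    usable = (x < 4) & (y < 4)
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no usable sites")
    return float((x[usable] != y[usable]).sum() / n)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Minimal phylogenetic tree node with parent links."""

    __slots__ = ("name", "branch_length", "children", "parent")

    def __init__(self, name: Optional[str] = None,
                 branch_length: Optional[float] = None):
        self.name = name
        self.branch_length = branch_length
        self.children: list["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add_child(self, node: "TreeNode", branch_length: float) -> None:
        node.parent = self
        node.branch_length = float(branch_length)
        self.children.append(node)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):
        return f"TreeNode({self.name!r}, n_children={len(self.children)})"


_NEWICK_UNSAFE = set("(),:;'\" \t\n[]")


def _quote_label(label: str) -> str:
    if set(label) & _NEWICK_UNSAFE:
        return "'" + label.replace("'", "''") + "'"
    return label


class PhyloTree:
    """A (possibly unrooted) tree over accession leaves."""

    def __init__(self, root: TreeNode, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    # -- traversal (iterative: trees from large populations can be deep) ----
    def preorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def postorder(self) -> list[TreeNode]:
        return list(reversed(self._reverse_postorder()))

    def _reverse_postorder(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def leafsets(self) -> dict[int, frozenset]:
        """``id(node) -> frozenset of leaf names under it``."""
        sets: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[id(node)] = frozenset([node.name])
            else:
                acc: set = set()
                for child in node.children:
                    acc |= sets[id(child)]
                sets[id(node)] = frozenset(acc)
        return sets

    def mrca(self, names: Iterable[str]) -> TreeNode:
        target = frozenset(names)
        sets = self.leafsets()
        best: Optional[TreeNode] = None
        for node in self.postorder():
            if target <= sets[id(node)]:
                best = node
                break
        if best is None:
            raise ValueError("leaves not found in tree")
        return best

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each named by its smaller side."""
        all_leaves = frozenset(self.leaf_names())
        sets = self.leafsets()
        out: set[frozenset] = set()
        for node in self.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = sets[id(node)]
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    def path_length(self, name1: str, name2: str) -> float:
        """Sum of branch lengths on the leaf-to-leaf path."""
        nodes = {n.name: n for n in self.leaves()}
        a, b = nodes[name1], nodes[name2]
        anc_a: dict[int, float] = {}
        node, dist = a, 0.0
        while node is not None:
            anc_a[id(node)] = dist
            dist += node.branch_length or 0.0
            node = node.parent
        node, dist = b, 0.0
        while node is not None:
            if id(node) in anc_a:
                return dist + anc_a[id(node)]
            dist += node.branch_length or 0.0
            node = node.parent
        raise ValueError("leaves are not in the same tree")

    def newick(self) -> str:
        """Newick string, branch lengths to 6 decimals, labels quoted as needed."""
        done: dict[int, str] = {}
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if node.children and not expanded:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
                continue
            if node.children:
                inner = ",".join(done.pop(id(c)) for c in node.children)
                text = f"({inner})"
                if node.name:
                    text += _quote_label(node.name)
            else:
                text = _quote_label(node.name or "")
            if node.branch_length is not None:
                text += f":{node.branch_length:.6f}"
            done[id(node)] = text
        return done[id(self.root)] + ";"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")

    def copy(self) -> "PhyloTree":
        mapping: dict[int, TreeNode] = {}
        for node in self.preorder():
            clone = TreeNode(node.name, node.branch_length)
            mapping[id(node)] = clone
            if node.parent is not None:
                parent = mapping[id(node.parent)]
                clone.parent = parent
                parent.children.append(clone)
        return PhyloTree(mapping[id(self.root)], rooted=self.rooted)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(matrix: DistanceMatrix, clamp_negative: bool = False) -> PhyloTree:
    """Classic neighbor joining; exact on additive matrices.

    Ties in the Q criterion are broken by the lexicographically smallest
    pair of subtree labels (the smallest leaf id each subtree contains), so
    repeated runs give byte-identical trees.  Negative branch lengths are
    kept and logged unless ``clamp_negative``.
    """
    ids = matrix.ids
    n_leaves = len(ids)
    if n_leaves < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.any(np.diag(matrix.values) != 0) or not np.allclose(
        matrix.values, matrix.values.T, atol=1e-12
    ):
        raise ValueError("input matrix must be symmetric with zero diagonal")

    size = 2 * n_leaves
    D = np.zeros((size, size))
    D[:n_leaves, :n_leaves] = matrix.values
    nodes: list[TreeNode] = [TreeNode(name) for name in ids]
    keys: list[str] = list(ids)
    active: list[int] = list(range(n_leaves))
    n_negative = 0

    def finish(length: float) -> float:
        nonlocal n_negative
        if length < 0:
            n_negative += 1
            if clamp_negative:
                return 0.0
        return length

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (m - 2) * sub - R[:, None] - R[None, :]
        # evaluate the criterion on the upper triangle only: broadcasting is
        # not bit-symmetric, and the join pair is unordered anyway
        Q[np.tril_indices(m)] = np.inf
        qmin = Q.min()
        best = None
        for li, lj in np.argwhere(Q == qmin):
            ki, kj = keys[active[li]], keys[active[lj]]
            pair_key = (min(ki, kj), max(ki, kj))
            if best is None or pair_key < best[0]:
                best = (pair_key, int(li), int(lj))
        _, i, j = best
        gi, gj = active[i], active[j]
        dij = sub[i, j]
        vi = dij / 2 + (R[i] - R[j]) / (2 * (m - 2))
        vj = dij - vi
        parent = TreeNode()
        parent.add_child(nodes[gi], finish(vi))
        parent.add_child(nodes[gj], finish(vj))
        g = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[gi], keys[gj]))
        rest = [a for a in active if a not in (gi, gj)]
        for a in rest:
            D[g, a] = D[a, g] = (D[gi, a] + D[gj, a] - dij) / 2
        active = rest + [g]

    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    va = (dab + dac - dbc) / 2
    vb = dab - va
    vc = dac - va
    center = TreeNode()
    for g, v in ((a, va), (b, vb), (c, vc)):
        center.add_child(nodes[g], finish(v))

    if n_negative:
        logger.warning(
            "neighbor joining produced %d negative branch length(s)%s",
            n_negative, " (clamped to 0)" if clamp_negative else "",
        )
    return PhyloTree(center, rooted=False)


# ---------------------------------------------------------------------------
# rooting and clade assignment
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: PhyloTree, outgroup_ids: Iterable[str]) -> PhyloTree:
    """Root on the branch separating the outgroup set from everything else.

    The branch length is split equally between the two root children.  The
    input tree is left untouched.
    """
    outgroup = frozenset(outgroup_ids)
    work = tree.copy()
    all_leaves = frozenset(work.leaf_names())
    if not outgroup:
        raise OutgroupError("empty outgroup set")
    if not outgroup <= all_leaves:
        raise OutgroupError(
            f"outgroup ids missing from tree: {sorted(outgroup - all_leaves)}"
        )
    if outgroup == all_leaves:
        raise OutgroupError("outgroup cannot be the entire leaf set")

    sets = work.leafsets()
    target: Optional[TreeNode] = None
    target_is_outgroup_side = False
    for node in work.preorder():
        if node is work.root:
            continue
        side = sets[id(node)]
        if side == outgroup:
            target, target_is_outgroup_side = node, True
            break
        if side == all_leaves - outgroup:
            target, target_is_outgroup_side = node, False
            break
    if target is None:
        raise OutgroupError(
            f"outgroup {sorted(outgroup)} is not monophyletic on the tree"
        )

    old_parent = target.parent
    branch = target.branch_length or 0.0
    old_parent.children.remove(target)
    target.parent = None
    target.branch_length = None

    flipped, extra = _reorient_upward(old_parent)
    new_root = TreeNode()
    if target_is_outgroup_side:
        new_root.add_child(flipped, branch / 2 + extra)
        new_root.add_child(target, branch / 2)
    else:
        new_root.add_child(target, branch / 2)
        new_root.add_child(flipped, branch / 2 + extra)
    return PhyloTree(new_root, rooted=True)


def _reorient_upward(node: TreeNode) -> tuple[TreeNode, float]:
    """Turn ``node`` into the root of its remaining tree.

    The former parent chain is flipped into a child chain.  A node left with
    a single child (a former degree-2 root) is suppressed; the second
    element of the return value carries the suppressed branch length, to be
    added onto the caller's connecting edge.
    """
    parent = node.parent
    up_branch = node.branch_length or 0.0
    node.parent = None
    node.branch_length = None
    if parent is not None:
        parent.children.remove(node)
        sub, extra = _reorient_upward(parent)
        node.add_child(sub, up_branch + extra)
    if len(node.children) == 1:
        only = node.children[0]
        suppressed = only.branch_length or 0.0
        only.parent = None
        only.branch_length = None
        return only, suppressed
    return node, 0.0


@dataclass
class CladeAssignment:
    """Accession -> {A, B, other} labels plus the anchoring rule used."""

    labels: dict[str, str]
    anchor_rule: str = "indica-majority child is clade A"

    @property
    def clade_a_ids(self) -> list[str]:
        return [a for a, l in self.labels.items() if l == "A"]

    @property
    def clade_b_ids(self) -> list[str]:
        return [a for a, l in self.labels.items() if l == "B"]

    @property
    def size_A(self) -> int:
        return len(self.clade_a_ids)

    @property
    def size_B(self) -> int:
        return len(self.clade_b_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"accession_id": list(self.labels), "clade": list(self.labels.values())}
        )


def assign_clades(
    tree: PhyloTree,
    metadata: pd.DataFrame,
    anchor_a: Optional[str] = None,
) -> CladeAssignment:
    """Split the domesticated clade of a rooted tree into clades A and B.

    The smallest clade containing every domesticated accession is split at
    its root into its two children.  The child with the larger indica
    proportion becomes clade A (override with ``anchor_a``, an accession id
    that must land in A).  African accessions are allowed inside the
    domesticated clade (they nest within clade A) but keep label ``other``.
    """
    if not tree.rooted:
        raise ValueError("assign_clades needs a rooted tree")
    groups = dict(zip(metadata["accession_id"], metadata["group"]))
    subspecies = dict(zip(metadata["accession_id"], metadata["subspecies"]))
    domesticated = {a for a, g in groups.items() if g == "domesticated"}
    african = {a for a, g in groups.items() if g == "african"}
    if not domesticated:
        raise CladeError("no domesticated accessions in metadata")

    present = set(tree.leaf_names())
    missing = sorted(domesticated - present)
    if missing:
        raise CladeError(f"domesticated accessions missing from tree: {missing[:10]}")

    mrca = tree.mrca(domesticated)
    sets = tree.leafsets()
    under = sets[id(mrca)]
    intruders = sorted(under - domesticated - african)
    if intruders:
        raise CladeError(
            f"domesticated accessions are not monophyletic; intruding leaves: "
            f"{intruders[:10]}"
        )
    if len(mrca.children) != 2:
        raise CladeError(
            f"domesticated clade root has {len(mrca.children)} children; "
            f"cannot split into two clades"
        )

    sides = [sets[id(child)] for child in mrca.children]
    dom_sides = [side & domesticated for side in sides]
    if not all(dom_sides):
        raise CladeError("one side of the domesticated split has no accessions")

    if anchor_a is not None:
        a_index = 0 if anchor_a in sides[0] else 1
        rule = f"anchor accession {anchor_a} defines clade A"
    else:
        fracs = [
            sum(1 for a in dom if subspecies.get(a) == "indica") / len(dom)
            for dom in dom_sides
        ]
        if fracs[0] == fracs[1]:
            a_index = 0 if min(sides[0]) < min(sides[1]) else 1
        else:
            a_index = int(fracs[1] > fracs[0])
        rule = "indica-majority child is clade A"

    labels = {acc: "other" for acc in groups}
    for acc in dom_sides[a_index]:
        labels[acc] = "A"
    for acc in dom_sides[1 - a_index]:
        labels[acc] = "B"
    return CladeAssignment(labels=labels, anchor_rule=rule)
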