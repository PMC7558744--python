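"""TN93 distances, neighbor joining, rooting and clade assignment."""

import math
from collections import Counter

import numpy as np
import pytest

from chloroclade import (
    AlignmentMatrix,
    CladeError,
    DistanceMatrix,
    OutgroupError,
    SaturationError,
    assign_clades,
    default_table3_config,
    nj_tree,
    p_distance,
    planted_clade_labels,
    root_with_outgroup,
    simulate_population,
    tn93_distance,
    tn93_distance_matrix,
)

BASES = "ACGT"


def tn93_bruteforce(seq1: str, seq2: str) -> float:
    """Independent site-by-site evaluation of the three-term estimator."""
    pairs = [
        (a, b) for a, b in zip(seq1, seq2)
        if a in BASES and b in BASES
    ]
    n = len(pairs)
    P1 = sum(1 for a, b in pairs if {a, b} == {"A", "G"}) / n
    P2 = sum(1 for a, b in pairs if {a, b} == {"C", "T"}) / n
    Q = sum(
        1 for a, b in pairs
        if a != b and {a, b} not in ({"A", "G"}, {"C", "T"})
    ) / n
    tally = Counter(base for pair in pairs for base in pair)
    total = 2 * n
    gA, gC, gG, gT = (tally[b] / total for b in BASES)
    gR, gY = gA + gG, gC + gT
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    return (
        -k1 * math.log(1 - P1 / k1 - Q / (2 * gR))
        - k2 * math.log(1 - P2 / k2 - Q / (2 * gY))
        - k3 * math.log(1 - Q / (2 * gR * gY))
    )


def random_pair(rng, length=1000, max_diffs=60):
    x = "".join(rng.choice(list(BASES), length))
    y = list(x)
    k = int(rng.integers(1, max_diffs))
    for i in rng.choice(length, k, replace=False):
        y[i] = str(rng.choice(list(BASES)))
    return x, "".join(y)


class TestTN93:
    def test_identical_sequences_give_zero(self):
        seq = "ACGT" * 100
        assert tn93_distance(seq, seq) == 0.0

    def test_balanced_composition_worked_example(self):
        """1000 sites, 10 A<->G differences, all base frequencies 0.25:
        d = -k1 ln(1 - P1/k1) with k1 = 1/4 -> -(1/4) ln(0.96)."""
        s1 = list("ACGT" * 250)
        s2 = list(s1)
        for i in [k for k, c in enumerate(s1) if c == "A"][:5]:
            s2[i] = "G"
        for i in [k for k, c in enumerate(s1) if c == "G"][:5]:
            s2[i] = "A"
        d = tn93_distance("".join(s1), "".join(s2))
        assert d == pytest.approx(0.010205498630063791, abs=1e-15)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(30):
            x, y = random_pair(rng)
            d = tn93_distance(x, y)
            assert d == pytest.approx(tn93_bruteforce(x, y), abs=1e-12)
            assert d == tn93_distance(y, x)
            assert d >= p_distance(x, y)

    def test_small_distance_limit(self, rng):
        """d/p -> 1 as p -> 0."""
        length = 10000
        x = "".join(rng.choice(list(BASES), length))
        y = list(x)
        i = int(rng.integers(length))
        y[i] = "G" if x[i] != "G" else "A"
        y = "".join(y)
        p = p_distance(x, y)
        assert p == pytest.approx(1e-4)
        assert tn93_distance(x, y) / p == pytest.approx(1.0, abs=1e-3)

    def test_saturation_raises_with_pair_ids(self):
        x = "ACGT" * 25
        y = x.translate(str.maketrans("ACGT", "CATG"))  # all transversions
        with pytest.raises(SaturationError, match="left"):
            tn93_distance(x, y, ids=("left", "right"))

    def test_pairwise_deletion_of_gaps_and_n(self):
        x = "ACGTACGTAC" * 20
        y = "-CGTACGTNC" * 20
        usable = [(a, b) for a, b in zip(x, y) if a in BASES and b in BASES]
        assert tn93_distance(x, y) == 0.0
        assert len(usable) == 160

    def test_no_usable_sites_is_an_error(self):
        with pytest.raises(SaturationError):
            tn93_distance("NNNN", "ACGT")

    def test_matrix_agrees_with_pair_function(self, rng):
        base = "".join(rng.choice(list(BASES), 500))
        seqs = []
        for i in range(8):
            x = list(base)
            for j in rng.choice(500, 25, replace=False):
                x[j] = str(rng.choice(list(BASES)))
            for j in rng.choice(500, 10, replace=False):   # sprinkle gaps/N
                x[j] = str(rng.choice(list("-N")))
            seqs.append((f"s{i}", "".join(x)))
        aln = AlignmentMatrix.from_sequences(seqs)
        dm = tn93_distance_matrix(aln)
        for i, (id1, s1) in enumerate(seqs):
            for j, (id2, s2) in enumerate(seqs):
                if i < j:
                    assert dm.d(id1, id2) == pytest.approx(
                        tn93_distance(s1, s2), abs=1e-6
                    )


def random_additive_tree(rng, n_taxa):
    """Random topology with positive branch lengths; returns (ids, matrix,
    set of planted splits)."""
    ids = [f"t{i:02d}" for i in range(n_taxa)]
    nodes = {name: [name] for name in ids}
    dist = {(a, b): 0.0 for a in ids for b in ids}

    def add_length(members, length):
        for m in members:
            for other in ids:
                if other not in members:
                    key = (min(m, other), max(m, other))
                    dist[key] = dist.get(key, 0.0) + length

    groups = [[name] for name in ids]
    for group in groups:
        add_length(group, float(rng.uniform(0.05, 1.0)))
    splits = set()
    while len(groups) > 2:
        i, j = sorted(rng.choice(len(groups), 2, replace=False))
        merged = groups[i] + groups[j]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.append(merged)
        if 2 <= len(merged) <= n_taxa - 2:
            splits.add(frozenset(merged))
        if len(groups) > 2:
            add_length(merged, float(rng.uniform(0.05, 1.0)))
    values = np.zeros((n_taxa, n_taxa))
    for a_idx, a in enumerate(ids):
        for b_idx, b in enumerate(ids):
            if a_idx < b_idx:
                d = dist[(min(a, b), max(a, b))]
                values[a_idx, b_idx] = values[b_idx, a_idx] = d
    canonical = {
        min(s, frozenset(ids) - s, key=lambda x: (len(x), sorted(x)))
        for s in splits
    }
    return ids, DistanceMatrix(ids, values), canonical


class TestNeighborJoining:
    def test_four_taxon_worked_example(self):
        ids = ["A", "B", "C", "D"]
        values = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, values))
        lengths = {n.name: n.branch_length for n in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        assert tree.splits() == {frozenset({"A", "B"})}
        internal = [
            n for n in tree.preorder()
            if not n.is_leaf and n is not tree.root
        ]
        assert len(internal) == 1 and internal[0].branch_length == 1.0
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                assert tree.path_length(a, b) == pytest.approx(
                    values[ids.index(a), ids.index(b)]
                )

    def test_three_taxon_closed_form(self):
        ids = ["x", "y", "z"]
        values = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(ids, values))
        lengths = {n.name: n.branch_length for n in tree.leaves()}
        assert lengths["x"] == pytest.approx((4 + 6 - 8) / 2)
        assert lengths["y"] == pytest.approx((4 + 8 - 6) / 2)
        assert lengths["z"] == pytest.approx((6 + 8 - 4) / 2)

    def test_recovers_additive_matrices_exactly(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 13))
            ids, dm, splits = random_additive_tree(rng, n)
            tree = nj_tree(dm)
            assert tree.splits() == splits
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    assert tree.path_length(a, b) == pytest.approx(
                        dm.d(a, b), abs=1e-9
                    )

    def test_agrees_with_skbio_on_additive_input(self, rng):
        skbio = pytest.importorskip("skbio")
        ids, dm, _ = random_additive_tree(rng, 8)
        mine = nj_tree(dm).splits()
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dm.values, ids))
        all_ids = frozenset(ids)
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= len(ids) - 2:
                theirs.add(
                    min(side, all_ids - side, key=lambda s: (len(s), sorted(s)))
                )
        assert mine == theirs

    def test_newick_is_reproducible(self, rng):
        ids, dm, _ = random_additive_tree(rng, 9)
        assert nj_tree(dm).newick() == nj_tree(dm).newick()

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))
        values = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        bad = DistanceMatrix(["a", "b", "c"], values)
        bad.values[0, 1] = 5.0  # break symmetry after validation
        with pytest.raises(ValueError):
            nj_tree(bad)


class TestRooting:
    def _four_taxon_tree(self):
        ids = ["A", "B", "C", "D"]
        values = np.array([
            [0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0],
        ], dtype=float)
        return nj_tree(DistanceMatrix(ids, values))

    def test_root_splits_outgroup_pendant_branch(self):
        rooted = root_with_outgroup(self._four_taxon_tree(), ["D"])
        assert rooted.rooted
        children = rooted.root.children
        assert len(children) == 2
        outgroup_child = next(
            c for c in children if c.is_leaf and c.name == "D"
        )
        assert outgroup_child.branch_length == pytest.approx(2.0)
        # path lengths are preserved by rerooting
        for a, b, expected in [("A", "B", 3), ("A", "D", 6), ("C", "D", 7)]:
            assert rooted.path_length(a, b) == pytest.approx(expected)

    def test_non_monophyletic_outgroup_raises(self):
        with pytest.raises(OutgroupError):
            root_with_outgroup(self._four_taxon_tree(), ["A", "C"])

    def test_unknown_outgroup_raises(self):
        with pytest.raises(OutgroupError):
            root_with_outgroup(self._four_taxon_tree(), ["Z"])


@pytest.fixture(scope="module")
def rooted_population(noisy_population):
    config, alignment, metadata, _, _ = noisy_population
    dm = tn93_distance_matrix(alignment, list(metadata["accession_id"]))
    tree = nj_tree(dm)
    outgroup = list(
        metadata.loc[metadata["group"] == "outgroup", "accession_id"]
    )
    return config, metadata, root_with_outgroup(tree, outgroup)


class TestCladeAssignment:
    def test_labels_match_planted_truth(self, rooted_population):
        config, metadata, rooted = rooted_population
        assignment = assign_clades(rooted, metadata)
        truth = planted_clade_labels(metadata)
        for accession, label in truth.items():
            if label in ("A", "B"):
                assert assignment.labels[accession] == label
        assert assignment.size_A == config.n_clade_A
        assert assignment.size_B == config.n_clade_B

    def test_african_accessions_stay_other(self, rooted_population):
        config, metadata, rooted = rooted_population
        assignment = assign_clades(rooted, metadata)
        for accession in metadata.loc[
            metadata["group"] == "african", "accession_id"
        ]:
            assert assignment.labels[accession] == "other"

    def test_wild_relatives_topology(self, rooted_population):
        """Wild Asian sister to the domesticated clade, Australian outside."""
        config, metadata, rooted = rooted_population
        sets = rooted.leafsets()
        groups = dict(zip(metadata["accession_id"], metadata["group"]))
        dom = [a for a, g in groups.items() if g == "domesticated"]
        was = [a for a, g in groups.items() if g == "wild_asian"]
        aus = [a for a, g in groups.items() if g == "australian"]
        afr = {a for a, g in groups.items() if g == "african"}
        inner = sets[id(rooted.mrca(dom + was))]
        assert inner - set(dom) - set(was) - afr == frozenset()
        outer = sets[id(rooted.mrca(dom + was + aus))]
        assert outer - set(dom) - set(was) - set(aus) - afr == frozenset()

    def test_assignment_invariant_to_leaf_input_order(self, noisy_population, rng):
        config, alignment, metadata, _, _ = noisy_population
        ids = list(metadata["accession_id"])
        shuffled = list(ids)
        rng.shuffle(shuffled)
        outgroup = list(
            metadata.loc[metadata["group"] == "outgroup", "accession_id"]
        )
        a1 = assign_clades(
            root_with_outgroup(nj_tree(tn93_distance_matrix(alignment, ids)),
                               outgroup), metadata
        )
        a2 = assign_clades(
            root_with_outgroup(
                nj_tree(tn93_distance_matrix(alignment, shuffled)), outgroup
            ), metadata
        )
        assert a1.labels == a2.labels

    def test_two_leaf_domesticated_clade(self):
        import pandas as pd
        ids = ["d1", "d2", "w1", "o1"]
        values = np.array([
            [0.0, 0.02, 0.10, 0.30],
            [0.02, 0.0, 0.10, 0.30],
            [0.10, 0.10, 0.0, 0.32],
            [0.30, 0.30, 0.32, 0.0],
        ])
        metadata = pd.DataFrame({
            "accession_id": ids,
            "group": ["domesticated", "domesticated", "wild_asian", "outgroup"],
            "subspecies": ["indica", "japonica", "none", "none"],
        })
        rooted = root_with_outgroup(nj_tree(DistanceMatrix(ids, values)), ["o1"])
        assignment = assign_clades(rooted, metadata)
        assert assignment.labels["d1"] == "A"      # indica side is clade A
        assert assignment.labels["d2"] == "B"
        assert assignment.labels["w1"] == "other"

    def test_non_monophyletic_domesticated_raises(self):
        import pandas as pd
        ids = ["d1", "d2", "w1", "o1"]
        values = np.array([
            [0.0, 0.20, 0.02, 0.30],
            [0.20, 0.0, 0.20, 0.30],
            [0.02, 0.20, 0.0, 0.30],
            [0.30, 0.30, 0.30, 0.0],
        ])
        metadata = pd.DataFrame({
            "accession_id": ids,
            "group": ["domesticated", "domesticated", "wild_asian", "outgroup"],
            "subspecies": ["indica", "japonica", "none", "none"],
        })
        rooted = root_with_outgroup(nj_tree(DistanceMatrix(ids, values)), ["o1"])
        with pytest.raises(CladeError, match="w1"):
            assign_clades(rooted, metadata)
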