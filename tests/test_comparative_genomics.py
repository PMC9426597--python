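import numpy as np
import pytest
from skbio import DistanceMatrix

from baiminer import comparative_genomics as cg
from baiminer.io_formats import SequenceRecord


def random_tree_distances(n_taxa: int, seed: int):
    """An additive distance matrix from a random binary tree with
    uniform branch lengths, built by path summation (independent of the
    NJ implementation)."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_taxa)]
    # random topology: start from a 3-star, attach remaining leaves to
    # random edges; represent as parent pointers with branch lengths
    nodes = {0: None}  # node -> (parent, length)
    next_id = 1
    leaves = {}
    edges = []

    def new_node(parent):
        nonlocal next_id
        nid = next_id
        next_id += 1
        length = float(rng.uniform(0.5, 2.0))
        nodes[nid] = (parent, length)
        edges.append(nid)
        return nid

    for i in range(3):
        leaves[labels[i]] = new_node(0)
    for i in range(3, n_taxa):
        split = int(rng.choice(edges))
        parent, length = nodes[split]
        mid = new_node(parent)
        u = float(rng.uniform(0.2, 0.8))
        nodes[mid] = (parent, length * u)
        nodes[split] = (mid, length * (1 - u))
        leaves[labels[i]] = new_node(mid)

    def path_to_root(nid):
        path = {}
        total = 0.0
        while nodes[nid] is not None:
            parent, length = nodes[nid]
            path[nid] = total
            total += length
            nid = parent
        path[nid] = total
        return path

    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        pi = path_to_root(leaves[labels[i]])
        for j in range(i + 1, n_taxa):
            pj = path_to_root(leaves[labels[j]])
            shared = [k for k in pi if k in pj]
            dist = min(pi[k] + pj[k] for k in shared)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(d, ids=labels)


class TestPDistance:
    def test_identical_sequences(self):
        dm = cg.p_distance({"a": "MKVL", "b": "MKVL"})
        assert dm["a", "b"] == 0.0

    def test_half_different(self):
        dm = cg.p_distance({"a": "AAAA", "b": "AATT"})
        assert dm["a", "b"] == 0.5

    def test_pairwise_deletion(self):
        dm = cg.p_distance({"a": "AK-L", "b": "AC-L"})
        assert dm["a", "b"] == pytest.approx(1 / 3)

    def test_matches_per_column_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            length = int(rng.integers(20, 60))
            seqs = {}
            for k in range(4):
                chars = rng.choice(list("ACDEFG-"), size=length)
                seqs[f"s{k}"] = "".join(chars)
            dm = cg.p_distance(seqs)
            for a in seqs:
                for b in seqs:
                    if a >= b:
                        continue
                    diff = tot = 0
                    for x, y in zip(seqs[a], seqs[b]):
                        if x == "-" or y == "-":
                            continue
                        tot += 1
                        diff += x != y
                    assert dm[a, b] == pytest.approx(diff / tot)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cg.p_distance({"a": "AAA", "b": "AAAA"})


class TestNJTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], float),
                            ids=["x", "y", "z"])
        tree = cg.nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"x": pytest.approx(2.0), "y": pytest.approx(1.0),
                           "z": pytest.approx(3.0)}

    @pytest.mark.parametrize("n_taxa,seed", [(4, 1), (5, 2), (6, 3), (7, 4), (8, 5)])
    def test_additive_matrix_recovered_exactly(self, n_taxa, seed):
        dm = random_tree_distances(n_taxa, seed)
        tree = cg.nj_tree(dm)
        got = tree.tip_tip_distances(list(dm.ids))
        assert np.allclose(got.filter(dm.ids).data, dm.data, atol=1e-9)

    def test_agrees_with_skbio_on_additive_matrix(self):
        from skbio.tree import nj

        dm = random_tree_distances(6, seed=9)
        ours = cg.nj_tree(dm).tip_tip_distances(list(dm.ids))
        theirs = nj(dm).tip_tip_distances(list(dm.ids))
        assert np.allclose(ours.filter(dm.ids).data, theirs.filter(dm.ids).data, atol=1e-9)

    def test_ultrametric_matches_upgma_topology(self):
        """On an ultrametric matrix NJ groups the same sisters as
        average-linkage clustering."""
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        # ultrametric: ((a,b):1,(c,d):2) with molecular-clock depths
        d = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float
        )
        dm = DistanceMatrix(d, ids=list("abcd"))
        tree = cg.nj_tree(dm)
        sisters = {
            frozenset(t.name for t in ch.tips())
            for ch in tree.children if not ch.is_tip()
        }
        linkage = average(squareform(d))
        first_pair = frozenset("abcd"[int(i)] for i in linkage[0][:2])
        assert first_pair in sisters or frozenset("abcd") - first_pair in sisters

    def test_non_symmetric_rejected(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises(Exception):
            cg.nj_tree(DistanceMatrix(d, ids=list("abc")))

    def test_negative_limbs_clamped(self):
        # a matrix known to produce a negative NJ limb
        d = np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 1], [9, 10, 1, 0]], float
        )
        tree = cg.nj_tree(DistanceMatrix(d, ids=list("abcd")))
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0


@pytest.fixture(scope="module")
def genome_pair():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=12_000))
    original = [SequenceRecord("gA", seq, "dna")]
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for pos in np.flatnonzero(rng.random(len(seq)) < 0.02):
        alternatives = bases[bases != arr[pos]]
        arr[pos] = alternatives[rng.integers(3)]
    mutated = [SequenceRecord("gB", arr.tobytes().decode(), "dna")]
    return original, mutated


class TestOrthoANI:
    def test_self_ani_is_100(self, genome_pair):
        original, _ = genome_pair
        res = cg.orthoani(original, original, "a", "a2")
        assert res.ani == 100.0
        assert res.same_species

    def test_two_percent_divergence(self, genome_pair):
        original, mutated = genome_pair
        res = cg.orthoani(original, mutated, "a", "b")
        assert res.ani == pytest.approx(98.0, abs=0.5)
        assert res.same_species

    def test_symmetry(self, genome_pair):
        original, mutated = genome_pair
        ab = cg.orthoani(original, mutated, "a", "b")
        ba = cg.orthoani(mutated, original, "b", "a")
        assert ab.ani == pytest.approx(ba.ani, abs=1e-9)

    def test_unrelated_genomes_have_no_orthologs(self, genome_pair):
        original, _ = genome_pair
        rng = np.random.default_rng(99)
        other = [SequenceRecord("gC", "".join(rng.choice(list("ACGT"), size=12_000)), "dna")]
        with pytest.raises(ValueError, match="undefined"):
            cg.orthoani(original, other, "a", "c")

    def test_too_short_genome_rejected(self, genome_pair):
        original, _ = genome_pair
        stub = [SequenceRecord("gS", "ACGT" * 100, "dna")]
        with pytest.raises(ValueError, match="fragments"):
            cg.orthoani(original, stub, "a", "s")
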