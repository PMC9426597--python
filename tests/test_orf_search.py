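import numpy as np
import pytest
from Bio.Align import substitution_matrices

from baiminer import orf_search as osr
from baiminer import synthetic_data as sd
from baiminer.io_formats import SequenceRecord


def sw_affine_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Brute-force affine-gap Smith-Waterman DP (gap of length g costs
    gap_open + g*gap_extend), independent of the library path."""
    matrix = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - gap_open - gap_extend, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open - gap_extend, Iy[i][j - 1] - gap_extend)
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]))
            best = max(best, M[i][j])
    return int(best)



@pytest.fixture(scope="module")
def family40():
    """Query ancestor plus members at ~40% identity to it."""
    anc = sd.random_protein(177, np.random.default_rng(5), "query")
    members = sd.mutate_family(sd.FamilySpec(anc, 6, 0.40, seed=9))
    return anc, members


@pytest.fixture(scope="module")
def chain():
    """Transitive family S -> A -> B -> C at ~65% per link, so the
    seed reaches only A directly at the 50% cutoff."""
    seed_prot = sd.random_protein(177, np.random.default_rng(6), "S")
    a = sd.mutate_family(sd.FamilySpec(seed_prot, 1, 0.65, seed=1))[0]
    a = SequenceRecord("A", a.seq, "protein")
    b = sd.mutate_family(sd.FamilySpec(a, 1, 0.65, seed=2))[0]
    b = SequenceRecord("B", b.seq, "protein")
    c = sd.mutate_family(sd.FamilySpec(b, 1, 0.65, seed=3))[0]
    c = SequenceRecord("C", c.seq, "protein")
    return seed_prot, [a, b, c]

class TestExtractOrfs:
    def test_minimal_orf(self):
        contig = SequenceRecord("c", "ATGAAATAA", "dna")
        (orf,) = osr.extract_orfs(contig, min_protein_len=1)
        assert orf.protein.seq == "MK"
        assert (orf.start, orf.end, orf.strand) == (0, 9, "+")

    def test_strand_symmetry(self):
        contig = SequenceRecord("c", "ATGAAATAA", "dna")
        rc = SequenceRecord("c_rc", sd.revcomp(contig.seq), "dna")
        (orf,) = osr.extract_orfs(rc, min_protein_len=1)
        assert orf.protein.seq == "MK"
        assert orf.strand == "-"
        assert (orf.start, orf.end) == (0, 9)

    def test_non_dna_characters_rejected(self):
        with pytest.raises(ValueError):
            osr.extract_orfs(SequenceRecord("c", "ATGAAATAA", "protein"))

    def test_planted_intervals_recovered(self, table1_contig, bai_refs):
        contig, intervals = table1_contig
        orfs = osr.extract_orfs(contig, min_protein_len=100)
        recovered = {(o.start, o.end, o.strand): o for o in orfs}
        for gene, start, end, strand in intervals:
            key = (start, end, strand)
            assert key in recovered, f"planted {gene} interval missing"
            assert recovered[key].protein.seq == bai_refs[gene].seq

    def test_min_length_filter(self):
        # MK protein (2 aa) dropped at the default threshold
        contig = SequenceRecord("c", "ATGAAATAA", "dna")
        assert osr.extract_orfs(contig) == []


class TestLocalAlign:
    def test_identical_proteins(self):
        p = sd.random_protein(177, np.random.default_rng(1), "p")
        q = SequenceRecord("q", p.seq, "protein")
        aln = osr.local_align(p, q)
        assert aln.pct_identity == 100.0
        assert aln.query_coverage == 100.0

    def test_self_score_dominates_mutants(self):
        anc = sd.random_protein(150, np.random.default_rng(2), "anc")
        self_score = osr.local_align(anc, SequenceRecord("c", anc.seq, "protein")).raw_score
        for seed in range(5):
            (mut,) = sd.mutate_family(sd.FamilySpec(anc, 1, 0.8, seed=seed))
            assert osr.local_align(anc, mut).raw_score <= self_score

    def test_score_symmetry_and_evalue_monotone(self):
        rng = np.random.default_rng(3)
        pairs = []
        for i in range(6):
            a = sd.random_protein(80, rng, f"a{i}")
            b = sd.mutate_family(sd.FamilySpec(a, 1, 0.7, seed=i))[0]
            aln_ab = osr.local_align(a, b)
            aln_ba = osr.local_align(b, a)
            assert aln_ab.raw_score == aln_ba.raw_score
            pairs.append(aln_ab)
        by_score = sorted(pairs, key=lambda x: x.raw_score)
        evals = [p.e_value for p in by_score]
        assert evals == sorted(evals, reverse=True)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for i in range(10):
            la, lb = rng.integers(10, 31, size=2)
            a = "".join(rng.choice(list(sd.AMINO_ACIDS), size=la))
            b = "".join(rng.choice(list(sd.AMINO_ACIDS), size=lb))
            got = osr.local_align(
                SequenceRecord("a", a, "protein"), SequenceRecord("b", b, "protein")
            ).raw_score
            assert got == sw_affine_oracle(a, b), (a, b)

    def test_empty_sequence_rejected(self):
        p = sd.random_protein(60, np.random.default_rng(0), "p")
        with pytest.raises(ValueError):
            SequenceRecord("q", "", "protein")
        with pytest.raises(ValueError):
            osr.local_align(p, SequenceRecord("d", "ACGT", "dna"))


class TestSearch:

    def test_identical_entry_is_perfect_hit(self, family40):
        anc, members = family40
        db = members + [SequenceRecord("twin", anc.seq, "protein")]
        hits = osr.search([anc], db, osr.SearchParams(min_identity=50))
        twin = [h for h in hits if h.subject_id == "twin"]
        assert len(twin) == 1 and twin[0].pct_identity == 100.0

    def test_threshold_bracketing(self, family40):
        anc, members = family40
        at50 = osr.search([anc], members, osr.SearchParams(min_identity=50))
        at30 = osr.search([anc], members, osr.SearchParams(min_identity=30))
        assert at50 == []
        assert {h.subject_id for h in at30} == {m.id for m in members}

    def test_database_order_invariance(self, family40):
        anc, members = family40
        params = osr.SearchParams(min_identity=30)
        fwd = osr.search([anc], members, params)
        rev = osr.search([anc], members[::-1], params)
        assert fwd == rev

    def test_empty_database(self, family40):
        anc, _ = family40
        assert osr.search([anc], [], osr.SearchParams()) == []


class TestIterativeExpand:

    def test_chain_recovered_in_three_rounds(self, chain):
        seed_prot, db = chain
        accepted, rounds = osr.iterative_expand(
            [seed_prot], db, osr.SearchParams(min_identity=50)
        )
        assert {r.id for r in accepted} == {"A", "B", "C"}
        assert rounds == 3

    def test_full_coverage_converges_in_one_round(self, chain):
        seed_prot, db = chain
        accepted, rounds = osr.iterative_expand(
            [seed_prot] + db, db, osr.SearchParams(min_identity=50)
        )
        assert rounds == 1

    def test_decoy_family_never_accepted(self, chain):
        seed_prot, db = chain
        rng = np.random.default_rng(8)
        decoys = [sd.random_protein(177, rng, f"decoy{i}") for i in range(3)]
        accepted, _ = osr.iterative_expand(
            [seed_prot], db + decoys, osr.SearchParams(min_identity=30)
        )
        assert not {r.id for r in accepted} & {d.id for d in decoys}

    def test_seed_order_independence(self, chain):
        seed_prot, db = chain
        other = sd.random_protein(177, np.random.default_rng(10), "S2")
        params = osr.SearchParams(min_identity=50)
        acc1, _ = osr.iterative_expand([seed_prot, other], db, params)
        acc2, _ = osr.iterative_expand([other, seed_prot], db, params)
        assert [r.id for r in acc1] == [r.id for r in acc2]

    def test_empty_seeds_rejected(self, chain):
        _, db = chain
        with pytest.raises(ValueError):
            osr.iterative_expand([], db, osr.SearchParams())
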