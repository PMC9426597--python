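"""ORF extraction and iterative protein homology search.

The discovery stage of the pipeline: contigs are scanned in six frames
for methionine-initiated, stop-terminated ORFs; candidate marker
proteins are then found by Smith-Waterman local alignment against the
ORF database with identity/coverage cutoffs (50%/90% against reference
databases, 30%/90% against metagenome ORFs), iterated with
similarity-network clustering until no new members appear.

Alignment statistics follow the Karlin-Altschul gapped model with the
conventional BLOSUM62 11/1 parameters (lambda=0.267, K=0.041); E-values
use the product of sequence lengths as the search space unless an
explicit database size is set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import DNA_ALPHABET, SequenceRecord
from .synthetic_data import _CODON_TABLE, STOP_CODONS, revcomp

logger = logging.getLogger("baiminer")

LN2 = math.log(2.0)

_CODON_TO_AA = dict(_CODON_TABLE.forward_table)


def translate(dna: str) -> str:
    """Translate an in-frame coding sequence (bacterial code, table 11).

    Codons containing N become X; stop codons are not translated and may
    only appear at the end.
    """
    aa = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i : i + 3]
        if codon in STOP_CODONS:
            if i + 3 != len(dna):
                raise ValueError(f"internal stop codon at nucleotide {i}")
            break
        aa.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aa)


@dataclass(frozen=True)
class Orf:
    """An open reading frame on a contig.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand and include the stop codon, so the encoded protein has
    ``(end - start) / 3 - 1`` residues.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: SequenceRecord

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")
        if len(self.protein) != (self.end - self.start) // 3 - 1:
            raise ValueError("protein length inconsistent with ORF interval")


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    pct_identity: float
    query_coverage: float
    aln_len: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity out of range")
        if not 0.0 <= self.query_coverage <= 100.0:
            raise ValueError("query_coverage out of range")
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


@dataclass(frozen=True)
class SearchParams:
    """Thresholds and scoring model of one search stage."""

    min_identity: float = 50.0
    min_coverage: float = 90.0
    substitution_matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    db_size: int = 0  # 0 => use the pairwise product of lengths

    def __post_init__(self) -> None:
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin parameters must be positive")


REFERENCE_STAGE = SearchParams(min_identity=50.0, min_coverage=90.0)
METAGENOME_STAGE = SearchParams(min_identity=30.0, min_coverage=90.0)


def extract_orfs(contig: SequenceRecord, min_protein_len: int = 100) -> list[Orf]:
    """Six-frame ORF scan.

    An ORF is the first ATG after a stop (or sequence start) in a frame,
    through the next in-frame stop; unterminated stretches are not
    reported.  ORFs whose protein is shorter than ``min_protein_len`` are
    dropped.  Output is sorted by (start, strand).
    """
    if contig.alphabet != "dna":
        raise ValueError("extract_orfs requires a dna contig")
    bad = set(contig.seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"contig {contig.id}: non-ACGTN characters {sorted(bad)}")
    L = len(contig.seq)
    orfs: list[Orf] = []
    for strand in "+-":
        s = contig.seq if strand == "+" else revcomp(contig.seq)
        for frame in range(3):
            atg: int | None = None
            for i in range(frame, L - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    if atg is not None:
                        n_aa = (i - atg) // 3
                        if n_aa >= min_protein_len:
                            lo, hi = atg, i + 3
                            if strand == "-":
                                lo, hi = L - (i + 3), L - atg
                            protein = translate(s[atg : i + 3])
                            orfs.append(
                                Orf(
                                    contig.id,
                                    lo,
                                    hi,
                                    strand,
                                    frame,
                                    SequenceRecord(
                                        f"{contig.id}|{lo}-{hi}{strand}",
                                        protein,
                                        "protein",
                                        source=contig.id,
                                    ),
                                )
                            )
                    atg = None
                elif codon == "ATG" and atg is None:
                    atg = i
    orfs.sort(key=lambda o: (o.start, o.strand))
    logger.info("extract_orfs: %d ORFs >= %d aa on %s", len(orfs), min_protein_len, contig.id)
    return orfs


@lru_cache(maxsize=8)
def _protein_aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: a gap of length g costs open + g * extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int]:
    """(identities, columns, aligned-query-residues) of a local alignment."""
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    qblocks = alignment.aligned[0]
    q_res = int(sum(int(e) - int(s) for s, e in qblocks))
    return int(counts.identities), int(columns), q_res


def local_align(
    query: SequenceRecord, subject: SequenceRecord, params: SearchParams = SearchParams()
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two proteins.

    Bit score ``(lambda*S - ln K) / ln 2``; E-value ``m*n * 2**-bits``
    with ``n`` replaced by ``params.db_size`` when set.  Percent identity
    is computed over all aligned columns, counting gap columns in the
    denominator; query coverage is the fraction of query residues inside
    the alignment.
    """
    if query.alphabet != "protein" or subject.alphabet != "protein":
        raise ValueError("local_align requires protein records")
    if not query.seq or not subject.seq:
        raise ValueError("empty sequence")
    aligner = _protein_aligner(
        params.substitution_matrix, params.gap_open, params.gap_extend
    )
    alignments = aligner.align(query.seq, subject.seq)
    raw = int(alignments.score)
    if raw <= 0:
        space = len(query.seq) * (params.db_size or len(subject.seq))
        return AlignmentResult(query.id, subject.id, 0, 0.0, float(max(space, 1)), 0.0, 0.0, 0)
    best = alignments[0]
    identities, columns, q_res = _alignment_stats(best)
    bits = (params.karlin_lambda * raw - math.log(params.karlin_k)) / LN2
    space = len(query.seq) * (params.db_size if params.db_size > 0 else len(subject.seq))
    log10_e = math.log10(space) - bits * math.log10(2.0)
    e_value = 10.0 ** max(log10_e, -300.0)
    return AlignmentResult(
        query_id=query.id,
        subject_id=subject.id,
        raw_score=raw,
        bit_score=bits,
        e_value=e_value,
        pct_identity=100.0 * identities / columns if columns else 0.0,
        query_coverage=100.0 * q_res / len(query.seq),
        aln_len=columns,
    )


def search(
    queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    params: SearchParams,
) -> list[AlignmentResult]:
    """All queries against all database entries; keep passing hits.

    A hit passes when identity >= ``min_identity`` AND query coverage >=
    ``min_coverage``.  Output ordering is (query_id, descending
    bit score, subject_id), independent of database order.
    """
    if not database:
        logger.warning("search: empty database, returning no hits")
        return []
    hits = []
    for q in queries:
        for s in database:
            if q.id == s.id:
                continue
            aln = local_align(q, s, params)
            if aln.pct_identity >= params.min_identity and aln.query_coverage >= params.min_coverage:
                hits.append(aln)
    hits.sort(key=lambda h: (h.query_id, -h.bit_score, h.subject_id))
    logger.info(
        "search: %d queries x %d subjects -> %d passing hits",
        len(queries), len(database), len(hits),
    )
    return hits


def iterative_expand(
    seed_queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    params: SearchParams,
    ssn_threshold: float = 70.0,
    max_rounds: int = 20,
    verdict_fn: Callable[[frozenset[str]], str] | None = None,
) -> tuple[list[SequenceRecord], int]:
    """Repeat search -> SSN clustering -> acceptance until a fixed point.

    Each round searches with the current query set, clusters queries plus
    passing hits in a similarity network at ``ssn_threshold``, and
    accepts members of clusters containing at least one current query
    (optionally also requiring ``verdict_fn`` not to return
    ``"non-candidate"`` for the cluster's member-id set, emulating the
    neighborhood-completeness filter).  Accepted members join the query
    set; the loop stops when a round adds nothing.  The accepted set is
    monotone non-decreasing and bounded by the database, so termination
    is guaranteed; the returned round count is the number of productive
    rounds (minimum 1).

    Returns ``(accepted database records sorted by id, rounds)``.
    """
    from . import ssn as ssn_mod

    if not seed_queries:
        raise ValueError("seed_queries must be non-empty")
    db_by_id = {r.id: r for r in database}
    seeds = sorted(seed_queries, key=lambda r: r.id)
    accepted: dict[str, SequenceRecord] = {}
    productive = 0
    seed_ids = {r.id for r in seeds}
    for round_no in range(1, max_rounds + 1):
        queries = seeds + sorted(
            (r for r in accepted.values() if r.id not in seed_ids),
            key=lambda r: r.id,
        )
        query_ids = {q.id for q in queries}
        hits = search(queries, database, params)
        candidates = {
            h.subject_id: db_by_id[h.subject_id]
            for h in hits
            if h.subject_id not in query_ids
        }
        pool = queries + sorted(candidates.values(), key=lambda r: r.id)
        newly: set[str] = set()
        if len(pool) >= 2:
            graph = ssn_mod.build_ssn(pool, params, threshold=ssn_threshold)
            clusters = ssn_mod.components(graph, query_ids=frozenset(query_ids))
            for cluster in clusters:
                if not cluster.contains_query:
                    continue
                if verdict_fn is not None and verdict_fn(frozenset(cluster.members)) == "non-candidate":
                    continue
                for mid in cluster.members:
                    if mid in db_by_id and mid not in accepted:
                        newly.add(mid)
        logger.info("iterative_expand round %d: %d new members", round_no, len(newly))
        if not newly:
            return sorted(accepted.values(), key=lambda r: r.id), max(productive, 1)
        for mid in newly:
            accepted[mid] = db_by_id[mid]
        productive += 1
    raise RuntimeError(
        f"iterative_expand did not reach a fixed point in {max_rounds} rounds "
        f"({len(accepted)} accepted so far)"
    )


def hits_to_table(hits: Sequence[AlignmentResult]):
    """BLAST outfmt-6-like columns as a pandas DataFrame."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "pct_identity": round(h.pct_identity, 2),
                "aln_len": h.aln_len,
                "query_coverage": round(h.query_coverage, 2),
                "raw_score": h.raw_score,
                "bit_score": round(h.bit_score, 1),
                "e_value": h.e_value,
            }
            for h in hits
        ]
    )
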