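"""Average nucleotide identity and distance-based phylogeny.

ANI follows the orthologous-fragment approach: genomes are cut into
non-overlapping 1020 bp fragments, reciprocal best-hit fragment pairs
are found by nucleotide local alignment (admission at >= 35% identity
and >= 35% fragment coverage, the published tool defaults), and ANI is
the mean identity over reciprocal pairs.  The species boundary defaults
to 95%, the midpoint of the conventional 94-96% band.

Trees come from classical Saitou-Nei neighbor joining on a symmetric
distance matrix, with deterministic tie-breaking (lowest index pair) and
negative branch lengths clamped to zero with the remainder moved to the
sibling branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from skbio import DistanceMatrix, TreeNode

from .io_formats import SequenceRecord
from .synthetic_data import revcomp

logger = logging.getLogger("baiminer")

FRAGMENT_LEN = 1020
ADMIT_IDENTITY = 35.0
ADMIT_COVERAGE = 35.0
SPECIES_CUTOFF = 95.0
_PRESCREEN_K = 12  # skip fragment pairs sharing no 12-mer (non-homologous)


@dataclass(frozen=True)
class AniResult:
    genome_a: str
    genome_b: str
    ani: float
    n_fragments_used: int
    same_species: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.ani <= 100.0:
            raise ValueError("ani out of range")


def _fragments(genome: Sequence[SequenceRecord], fragment_len: int) -> list[str]:
    frags = []
    for rec in genome:
        for i in range(0, len(rec.seq) - fragment_len + 1, fragment_len):
            frags.append(rec.seq[i : i + fragment_len])
    return frags


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def _kmer_set(seq: str) -> frozenset[str]:
    return frozenset(
        seq[i : i + _PRESCREEN_K] for i in range(0, len(seq) - _PRESCREEN_K + 1, 4)
    )


def _align_fragment(aligner, a: str, b: str) -> tuple[float, float, float]:
    """(score, percent identity, percent fragment coverage), best strand."""
    best = (0.0, 0.0, 0.0)
    for target in (b, revcomp(b)):
        alns = aligner.align(a, target)
        if alns.score <= best[0]:
            continue
        counts = alns[0].counts()
        columns = counts.gaps + counts.identities + counts.mismatches
        if columns == 0:
            continue
        identity = 100.0 * counts.identities / columns
        coverage = 100.0 * (counts.identities + counts.mismatches) / len(a)
        best = (float(alns.score), identity, coverage)
    return best


def orthoani(
    genome_a: Sequence[SequenceRecord],
    genome_b: Sequence[SequenceRecord],
    name_a: str = "a",
    name_b: str = "b",
    fragment_len: int = FRAGMENT_LEN,
    species_cutoff: float = SPECIES_CUTOFF,
) -> AniResult:
    """Orthologous-fragment average nucleotide identity of two genomes.

    Symmetric by construction: reciprocal best-hit pairs are found once
    and each contributes its single pairwise identity.  Raises
    ``ValueError`` when either genome yields fewer than two fragments or
    no reciprocal pairs pass admission (undefined ANI).
    """
    frags_a = _fragments(genome_a, fragment_len)
    frags_b = _fragments(genome_b, fragment_len)
    if len(frags_a) < 2 or len(frags_b) < 2:
        raise ValueError("each genome must yield at least 2 fragments")
    kmers_a = [_kmer_set(f) for f in frags_a]
    kmers_b = [
        _kmer_set(f) | _kmer_set(revcomp(f)) for f in frags_b
    ]
    aligner = _nt_aligner()
    scores: dict[tuple[int, int], tuple[float, float]] = {}
    for i, fa in enumerate(frags_a):
        for j, fb in enumerate(frags_b):
            if not (kmers_a[i] & kmers_b[j]):
                continue
            score, ident, cov = _align_fragment(aligner, fa, fb)
            if ident >= ADMIT_IDENTITY and cov >= ADMIT_COVERAGE:
                scores[(i, j)] = (score, ident)
    if not scores:
        raise ValueError(
            f"no admitted fragment pairs between {name_a} and {name_b}: ANI undefined"
        )
    best_a: dict[int, int] = {}
    best_b: dict[int, int] = {}
    for (i, j), (score, _) in scores.items():
        if i not in best_a or score > scores[(i, best_a[i])][0]:
            best_a[i] = j
        if j not in best_b or score > scores[(best_b[j], j)][0]:
            best_b[j] = i
    reciprocal = [
        (i, j) for i, j in best_a.items() if best_b.get(j) == i
    ]
    if not reciprocal:
        raise ValueError(f"no reciprocal best-hit pairs: ANI undefined")
    identities = [scores[(i, j)][1] for i, j in sorted(reciprocal)]
    ani = float(np.mean(identities))
    logger.info(
        "orthoani(%s, %s): %d reciprocal pairs, ANI %.2f%%",
        name_a, name_b, len(reciprocal), ani,
    )
    return AniResult(
        genome_a=name_a,
        genome_b=name_b,
        ani=ani,
        n_fragments_used=len(reciprocal),
        same_species=ani >= species_cutoff,
    )


def p_distance(aligned: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise p-distances of an aligned sequence set.

    The proportion of differing columns among columns where neither
    sequence has a gap (pairwise deletion).  All sequences must have the
    same aligned length.
    """
    labels = sorted(aligned)
    if len(labels) < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(aligned[l]) for l in labels}
    if len(lengths) != 1:
        raise ValueError("aligned sequences differ in length")
    arrs = {l: np.frombuffer(aligned[l].upper().encode(), dtype="S1") for l in labels}
    gap = np.bytes_(b"-")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[labels[i]], arrs[labels[j]]
            keep = (a != gap) & (b != gap)
            if not keep.any():
                raise ValueError(
                    f"no shared ungapped columns between {labels[i]} and {labels[j]}"
                )
            d[i, j] = d[j, i] = np.mean(a[keep] != b[keep])
    return DistanceMatrix(d, ids=labels)


def _as_matrix(d) -> tuple[list[str], np.ndarray]:
    if isinstance(d, DistanceMatrix):
        return list(d.ids), d.data.astype(float).copy()
    raise TypeError("nj_tree expects an skbio DistanceMatrix")


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Agglomerates the pair minimizing the Q-criterion
    ``(n-2) d_ij - r_i - r_j`` (ties to the lowest index pair), computes
    limb lengths by the standard formulas, and finishes with the
    three-point formulas on the last three nodes, producing an unrooted
    tree with a trifurcating root.  Negative limb lengths are clamped to
    zero and the deficit moved to the sibling limb, preserving their sum.
    Exact on additive matrices.
    """
    labels, dist = _as_matrix(d)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    viol = _triangle_violations(dist)
    if viol:
        logger.warning("nj_tree: %d triangle-inequality violations (tolerated)", viol)

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    d_work = dist
    while len(nodes) > 3:
        m = len(nodes)
        r = d_work.sum(axis=1)
        q = (m - 2) * d_work - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) pair among minima, i < j
        i, j = min(
            (int(a), int(b))
            for a, b in zip(*np.where(q == q.min()))
            if a < b
        )
        dij = d_work[i, j]
        limb_i = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        limb_j = dij - limb_i
        limb_i, limb_j = _clamp_pair(limb_i, limb_j)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(limb_i)
        child_j.length = float(limb_j)
        parent = TreeNode(children=[child_i, child_j])
        new_row = 0.5 * (d_work[i, :] + d_work[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d_work[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = np.maximum(new_row[keep], 0.0)
        nodes = [nodes[k] for k in keep] + [parent]
        d_work = d_new

    # three-point formulas for the final trifurcation
    d01, d02, d12 = d_work[0, 1], d_work[0, 2], d_work[1, 2]
    limbs = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    limbs = _clamp_trio(limbs)
    for node, limb in zip(nodes, limbs):
        node.length = float(limb)
    return TreeNode(children=nodes)


def _clamp_pair(x: float, y: float) -> tuple[float, float]:
    if x < 0:
        return 0.0, x + y
    if y < 0:
        return x + y, 0.0
    return x, y


def _clamp_trio(limbs: list[float]) -> list[float]:
    limbs = list(limbs)
    for k in range(3):
        if limbs[k] < 0:
            sib = max(range(3), key=lambda t: limbs[t])
            limbs[sib] += limbs[k]
            limbs[k] = 0.0
    return [max(l, 0.0) for l in limbs]


def _triangle_violations(d: np.ndarray, tol: float = 1e-9) -> int:
    n = len(d)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(d[i, j] > d[i, :] + d[:, j] + tol):
                count += 1
    return count


def tip_distances(tree: TreeNode) -> DistanceMatrix:
    """Path-length distances between all tips of a tree."""
    return tree.tip_tip_distances()
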