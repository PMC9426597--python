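"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators cover the pipeline's input space:

* protein families with controlled identity to a common ancestor
  (the similarity-network cluster structure),
* contigs carrying complete or incomplete *bai* operons as real ORFs
  (the genome-neighborhood structure), and
* short-read sets drawn at planted cluster abundances with sequencing
  error, plus sample metadata with planted group effects and planted
  bile-acid-ratio correlations.

Every generator is a pure function of (spec, seed) and emits its planted
truth alongside the data so downstream recovery is testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from scipy import stats

from .io_formats import SampleMetadata, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

BAI_GENES = ("baiE", "baiCD", "baiH", "barA", "barB", "baiA", "baiB", "baiG", "baiF")

# Protein lengths (aa) of the ten-gene bai operon of the cluster-1
# reference genome; the two baiF paralogs share one synthetic profile.
BAI_GENE_LENGTHS = {
    "baiE": 177,
    "baiCD": 644,
    "baiH": 663,
    "barA": 514,
    "barB": 195,
    "baiA": 255,
    "baiB": 506,
    "baiG": 473,
    "baiF": 452,
}

# Gene order and coding strands of the complete cluster-1 bai operon.
TABLE1_LAYOUT: tuple[tuple[str, str], ...] = (
    ("baiE", "-"),
    ("baiCD", "-"),
    ("baiH", "+"),
    ("barA", "+"),
    ("barB", "+"),
    ("baiA", "+"),
    ("baiB", "+"),
    ("baiG", "+"),
    ("baiF", "+"),
    ("baiF", "+"),
)

# Period-4 palindromic spacer unit: carries a stop codon in all six
# reading frames within any 12 bp and contains no ATG, so planted ORFs
# can neither start inside nor read through intergenic spacers.
_SPACER_UNIT = "CTAG"

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]  # bacterial/archaeal
_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
for aa in _BACK_TABLE:
    _BACK_TABLE[aa].sort()
STOP_CODONS = tuple(sorted(_CODON_TABLE.stop_codons))

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# BLOSUM62-conditional replacement weights: p(b | a) ~ 2^(s(a,b)/2), b != a.
_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_SUB_WEIGHTS: dict[str, np.ndarray] = {}
for _a in AMINO_ACIDS:
    w = np.array(
        [0.0 if _b == _a else 2.0 ** (_BLOSUM62[_a, _b] / 2.0) for _b in AMINO_ACIDS]
    )
    _SUB_WEIGHTS[_a] = w / w.sum()


@dataclass(frozen=True)
class FamilySpec:
    """A protein family derived from one ancestor by point substitution."""

    ancestor: SequenceRecord
    n_members: int
    target_identity: float
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.target_identity <= 1.0:
            raise ValueError("target_identity must be in (0, 1]")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")


@dataclass(frozen=True)
class OperonSpec:
    """Gene content and orientation of one synthetic operon contig."""

    gene_set: tuple[tuple[str, str], ...]
    intergenic_len: int = 100
    complete: bool = True

    def __post_init__(self) -> None:
        names = [g for g, _ in self.gene_set]
        for g, s in self.gene_set:
            if g not in BAI_GENES:
                raise ValueError(f"unknown gene {g!r}")
            if s not in "+-":
                raise ValueError(f"bad strand {s!r} for {g}")
        for g in set(names):
            if names.count(g) > 1 and g != "baiF":
                raise ValueError(f"gene {g} may not be duplicated (only baiF may)")
        if self.intergenic_len < 0:
            raise ValueError("intergenic_len must be >= 0")


@dataclass(frozen=True)
class CommunitySpec:
    """A planted community: contigs, abundances and a read-error model."""

    contigs: tuple[tuple[SequenceRecord, str], ...]  # (contig, cluster label)
    relative_abundances: Mapping[str, float]
    depth: int
    read_len: int = 100
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.relative_abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"relative abundances sum to {total}, not 1")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not self.contigs:
            raise ValueError("contigs must be non-empty")


def random_protein(length: int, rng: np.random.Generator, name: str = "anc") -> SequenceRecord:
    """Uniform-random methionine-initiated protein (an ORF product)."""
    seq = "M" + "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
    return SequenceRecord(name, seq, "protein", source="synthetic")


def mutate_family(spec: FamilySpec) -> list[SequenceRecord]:
    """Derive ``n_members`` proteins from the ancestor by i.i.d. substitution.

    Each site mutates with probability ``1 - target_identity``; the
    replacement residue is drawn with BLOSUM62-conditional weights, which
    keeps alignment scores of mutated pairs realistic.  Deterministic
    given the spec seed.
    """
    if spec.ancestor.alphabet != "protein":
        raise ValueError("ancestor must be a protein")
    if len(spec.ancestor) < 50:
        raise ValueError("ancestor must be >= 50 residues")
    rng = np.random.default_rng(spec.seed)
    rate = 1.0 - spec.target_identity
    residues = list(spec.ancestor.seq)
    members = []
    # position 0 is exempt when it is the initiator methionine, so family
    # members remain translatable ORF products
    first_mutable = 1 if residues[0] == "M" else 0
    for i in range(spec.n_members):
        mutated = residues[:]
        hits = np.flatnonzero(rng.random(len(residues)) < rate)
        for pos in hits:
            if pos < first_mutable:
                continue
            a = mutated[pos]
            weights = _SUB_WEIGHTS.get(a)
            if weights is None:  # X or other non-standard residue: leave as is
                continue
            mutated[pos] = AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=weights)]
        members.append(
            SequenceRecord(
                f"{spec.ancestor.id}_m{i + 1}",
                "".join(mutated),
                "protein",
                source="synthetic",
            )
        )
    return members


def pairwise_identity(a: str, b: str) -> float:
    """Fraction identical positions of two equal-length ungapped sequences."""
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Protein -> ORF nucleotides (ATG...stop), uniform synonymous codons.

    The first residue is encoded as ATG regardless of identity so the ORF
    is methionine-initiated; a uniform-random stop codon terminates it.
    """
    codons = ["ATG"]
    for aa in protein[1:]:
        choices = _BACK_TABLE.get(aa)
        if choices is None:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        codons.append(choices[rng.integers(len(choices))])
    codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


def bai_reference_proteins(seed: int = 2022) -> dict[str, SequenceRecord]:
    """Synthetic stand-ins for the nine bai/bar reference proteins.

    Random proteins at the documented lengths; used both to build
    synthetic operon contigs and as the neighborhood-annotation profiles,
    so annotation recovers the planted gene names.
    """
    rng = np.random.default_rng(seed)
    return {
        gene: random_protein(length, rng, name=gene)
        for gene, length in sorted(BAI_GENE_LENGTHS.items())
    }


def _spacer(length: int) -> str:
    length = max(length, len(_SPACER_UNIT) * 3)
    reps = -(-length // len(_SPACER_UNIT))
    return (_SPACER_UNIT * reps)[: reps * len(_SPACER_UNIT)]


def build_contig(
    spec: OperonSpec,
    codon_seed: int,
    proteins: Mapping[str, SequenceRecord] | None = None,
    contig_id: str = "contig",
) -> tuple[SequenceRecord, list[tuple[str, int, int, str]]]:
    """Assemble a contig carrying the spec's genes as real ORFs.

    Returns the contig and the planted gene intervals as
    ``(gene, start, end, strand)`` with 0-based half-open coordinates on
    the forward strand; intervals include the stop codon, and translating
    the interval on its strand recovers the source protein exactly.
    """
    if proteins is None:
        proteins = bai_reference_proteins()
    rng = np.random.default_rng(codon_seed)
    parts: list[str] = [_spacer(spec.intergenic_len)]
    intervals: list[tuple[str, int, int, str]] = []
    pos = len(parts[0])
    for gene, strand in spec.gene_set:
        if gene not in proteins:
            raise ValueError(f"no protein provided for gene {gene!r}")
        orf = reverse_translate(proteins[gene].seq, rng)
        if strand == "-":
            orf = revcomp(orf)
        parts.append(orf)
        intervals.append((gene, pos, pos + len(orf), strand))
        pos += len(orf)
        spc = _spacer(spec.intergenic_len)
        parts.append(spc)
        pos += len(spc)
    contig = SequenceRecord(contig_id, "".join(parts), "dna", source="synthetic")
    return contig, intervals


def simulate_reads(spec: CommunitySpec) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Draw reads from the community with substitution errors.

    Reads are sampled from contigs with probability proportional to
    cluster abundance times contig length, positions uniform, strand
    random, per-base substitution at ``error_rate``, constant Q40
    qualities.  Returns ``(reads, truth)`` where ``truth[i]`` is the
    cluster label the i-th read was drawn from.
    """
    rng = np.random.default_rng(spec.seed)
    min_len = min(len(c) for c, _ in spec.contigs)
    if spec.read_len > min_len:
        raise ValueError(
            f"read_len {spec.read_len} exceeds shortest contig ({min_len} bp)"
        )
    weights = np.array(
        [spec.relative_abundances.get(lbl, 0.0) * len(c) for c, lbl in spec.contigs],
        dtype=float,
    )
    if weights.sum() <= 0:
        raise ValueError("all contigs have zero sampling weight")
    weights /= weights.sum()
    choices = rng.choice(len(spec.contigs), size=spec.depth, p=weights)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    qual = "I" * spec.read_len  # Q40
    reads: list[tuple[str, str, str]] = []
    truth: list[str] = []
    for i, ci in enumerate(choices):
        contig, label = spec.contigs[ci]
        start = int(rng.integers(0, len(contig) - spec.read_len + 1))
        frag = contig.seq[start : start + spec.read_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        if spec.error_rate > 0:
            arr = np.frombuffer(frag.encode(), dtype="S1").copy()
            errs = np.flatnonzero(rng.random(spec.read_len) < spec.error_rate)
            for p in errs:
                alternatives = bases[bases != arr[p]]
                arr[p] = alternatives[rng.integers(len(alternatives))]
            frag = arr.tobytes().decode()
        reads.append((f"read_{i:07d}", frag, qual))
        truth.append(label)
    return reads, truth


def simulate_metadata(
    abundances: Mapping[str, float],
    rho_target: float,
    group_effect: float,
    seed: int,
    disease_label: str = "CD",
) -> list[SampleMetadata]:
    """Metadata with a planted abundance/BA-ratio Spearman correlation.

    The secondary:primary bile-acid ratio is generated through a Gaussian
    copula on the normal scores of the abundance ranks, with Pearson
    latent correlation ``2*sin(pi*rho_target/6)`` so the realized
    Spearman rho approximates ``rho_target`` (exact +-1 in the noiseless
    limits).  Disease labels are assigned by a logistic link on the
    standardized log-abundance with slope ``-group_effect``; at
    ``group_effect=0`` labels are exchangeable.
    """
    if not -1.0 <= rho_target <= 1.0:
        raise ValueError("rho_target must be in [-1, 1]")
    samples = sorted(abundances)
    n = len(samples)
    if n < 10:
        raise ValueError("need >= 10 samples")
    rng = np.random.default_rng(seed)
    values = np.array([abundances[s] for s in samples], dtype=float)
    ranks = stats.rankdata(values, method="average")
    z = stats.norm.ppf(ranks / (n + 1))
    if abs(rho_target) == 1.0:
        latent = math.copysign(1.0, rho_target) * z
    else:
        r = 2.0 * math.sin(math.pi * rho_target / 6.0)
        latent = r * z + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    ratio = np.exp(0.6 * latent)

    log_ab = np.log1p(values)
    sd = log_ab.std()
    z_ab = (log_ab - log_ab.mean()) / sd if sd > 0 else np.zeros(n)
    p_disease = 1.0 / (1.0 + np.exp(group_effect * z_ab))
    is_disease = rng.random(n) < p_disease

    out = []
    for i, sid in enumerate(samples):
        ca = float(rng.lognormal(mean=0.0, sigma=0.3))
        cdca = float(rng.lognormal(mean=0.0, sigma=0.3))
        total_secondary = ratio[i] * (ca + cdca)
        u = float(rng.uniform(0.3, 0.7))
        out.append(
            SampleMetadata(
                sid,
                disease_label if is_disease[i] else "healthy",
                {
                    "CA": ca,
                    "CDCA": cdca,
                    "DCA": u * total_secondary,
                    "LCA": (1.0 - u) * total_secondary,
                },
            )
        )
    return out
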