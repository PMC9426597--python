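"""Genome-neighborhood annotation and operon-completeness classification.

Around each marker (baiE) hit, ORFs within a window are assigned to
reference bai/bar proteins by best local-alignment bit score; a contig
is a 7alpha-dehydroxylation *candidate* when the full operon-local gene
set {baiA, baiB, baiCD, baiE, baiF, baiG, baiH} is present.  The barA and
barB regulators, and the distally encoded baiN/baiK, are reported but
never affect the verdict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import SequenceRecord
from .orf_search import Orf, SearchParams, local_align
from . import synthetic_data

logger = logging.getLogger("baiminer")

REQUIRED_GENES = frozenset({"baiA", "baiB", "baiCD", "baiE", "baiF", "baiG", "baiH"})
OPTIONAL_GENES = frozenset({"barA", "barB"})
DISTAL_GENES = frozenset({"baiN", "baiK"})

DEFAULT_WINDOW = 15_000  # bp each side of the anchor; bai operons span ~12 kb
ASSIGN_MIN_IDENTITY = 30.0
ASSIGN_MIN_COVERAGE = 50.0  # of the reference profile


@dataclass(frozen=True)
class BaiReferenceSet:
    """Reference protein profiles per gene plus the required-gene rule."""

    profiles: Mapping[str, tuple[SequenceRecord, ...]]
    required: frozenset[str] = REQUIRED_GENES
    optional: frozenset[str] = OPTIONAL_GENES
    distal: frozenset[str] = DISTAL_GENES

    def __post_init__(self) -> None:
        if self.required & self.optional:
            raise ValueError("required and optional gene sets overlap")
        for gene, profile in self.profiles.items():
            if not profile:
                raise ValueError(f"empty profile for gene {gene}")

    @classmethod
    def synthetic(cls, seed: int = 2022) -> "BaiReferenceSet":
        """Profiles from the synthetic bai reference proteins.

        Synthetic stand-ins (random proteins at the documented gene
        lengths), matched to contigs built from the same generator.
        """
        prots = synthetic_data.bai_reference_proteins(seed)
        return cls(profiles={g: (p,) for g, p in prots.items()})


@dataclass(frozen=True)
class OperonCall:
    """Annotation and completeness verdict for one contig neighborhood."""

    contig_id: str
    annotated: tuple[tuple[Orf, str, float], ...]  # (orf, gene or "unassigned", identity %)
    present: frozenset[str]
    missing_required: frozenset[str]
    verdict: str

    def __post_init__(self) -> None:
        expected = "candidate" if not self.missing_required else "non-candidate"
        if self.verdict != expected:
            raise ValueError("verdict inconsistent with missing_required")

    @property
    def resolved(self) -> bool:
        """True when the neighborhood holds more than the anchor ORF."""
        return len(self.annotated) > 1


def annotate_neighborhood(
    contig: SequenceRecord,
    orfs: Sequence[Orf],
    ref: BaiReferenceSet,
    anchor: Orf,
    window: int = DEFAULT_WINDOW,
    params: SearchParams = SearchParams(),
) -> list[tuple[Orf, str, float]]:
    """Assign each ORF near the anchor to its best-matching reference gene.

    An ORF within ``window`` bp of the anchor is assigned the gene of the
    reference profile with the highest bit score, provided the alignment
    reaches 30% identity and covers 50% of the reference; otherwise it is
    reported as "unassigned".  Output is ordered by (start, strand),
    independent of the input ORF order.
    """
    if anchor not in orfs:
        raise ValueError("anchor ORF is not in the supplied ORF list")
    lo, hi = anchor.start - window, anchor.end + window
    out: list[tuple[Orf, str, float]] = []
    for orf in sorted(orfs, key=lambda o: (o.start, o.strand)):
        if orf.end <= lo or orf.start >= hi:
            continue
        best_gene, best_bits, best_ident = "unassigned", float("-inf"), 0.0
        for gene in sorted(ref.profiles):
            for profile in ref.profiles[gene]:
                # The profile is the alignment query so coverage is
                # measured on the reference protein.
                aln = local_align(profile, orf.protein, params)
                if (
                    aln.pct_identity >= ASSIGN_MIN_IDENTITY
                    and aln.query_coverage >= ASSIGN_MIN_COVERAGE
                    and aln.bit_score > best_bits
                ):
                    best_gene, best_bits, best_ident = gene, aln.bit_score, aln.pct_identity
        out.append((orf, best_gene, round(best_ident, 2)))
    logger.info(
        "annotate_neighborhood: %s: %d ORFs in window, %d assigned",
        contig.id, len(out), sum(1 for _, g, _ in out if g != "unassigned"),
    )
    return out


def classify(
    contig_id: str,
    annotations: Sequence[tuple[Orf, str, float]],
    ref: BaiReferenceSet,
) -> OperonCall:
    """Completeness verdict from a neighborhood annotation.

    Candidate iff every required gene is present; duplicated genes (the
    two baiF paralogs) count once; optional and distal genes never
    affect the verdict.
    """
    present = frozenset(g for _, g, _ in annotations if g != "unassigned")
    missing = ref.required - present
    return OperonCall(
        contig_id=contig_id,
        annotated=tuple(annotations),
        present=present,
        missing_required=missing,
        verdict="candidate" if not missing else "non-candidate",
    )


def cluster_verdict(calls: Sequence[OperonCall]) -> str:
    """Existential rule over a cluster's member contigs.

    Candidate when any member neighborhood is complete; indeterminate
    when no member has a resolvable neighborhood (e.g. every contig is
    too short to carry more than the anchor); non-candidate otherwise.
    """
    if not calls:
        raise ValueError("need at least one member call")
    resolved = [c for c in calls if c.resolved]
    if any(c.verdict == "candidate" for c in resolved):
        return "candidate"
    if not resolved:
        return "indeterminate"
    return "non-candidate"


def calls_to_tables(
    calls: Sequence[OperonCall],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(gene-arrow table, verdict table) for TSV export."""
    gene_rows, verdict_rows = [], []
    for call in calls:
        for orf, gene, ident in call.annotated:
            gene_rows.append(
                {
                    "contig_id": call.contig_id,
                    "gene": gene,
                    "start": orf.start,
                    "end": orf.end,
                    "strand": orf.strand,
                    "identity": ident,
                }
            )
        verdict_rows.append(
            {
                "contig_id": call.contig_id,
                "present": ",".join(sorted(call.present)),
                "missing_required": ",".join(sorted(call.missing_required)),
                "verdict": call.verdict,
            }
        )
    cols_g = ["contig_id", "gene", "start", "end", "strand", "identity"]
    cols_v = ["contig_id", "present", "missing_required", "verdict"]
    return (
        pd.DataFrame(gene_rows, columns=cols_g),
        pd.DataFrame(verdict_rows, columns=cols_v),
    )
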