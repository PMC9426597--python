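"""Plain-text formats shared by every pipeline stage.

All sequence data flows through :class:`SequenceRecord` and all sample
annotation through :class:`SampleMetadata`; downstream modules never touch
raw files.  Coordinates everywhere in the package are 0-based, half-open,
strand in ``{"+", "-"}``.  FASTQ qualities are Phred+33 only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("baiminer")

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

BA_COLUMNS = ("CA", "CDCA", "DCA", "LCA")


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein or nucleotide sequence.

    Parameters
    ----------
    id : str
        Non-empty identifier, unique within any collection.
    seq : str
        Residues; uppercased on construction.
    alphabet : {"protein", "dna"}
    source : str
        Free-text provenance tag (query set, database, synthetic, ...).
    """

    id: str
    seq: str
    alphabet: str
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.seq) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"not in the {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        if self.alphabet != "dna":
            raise ValueError("reverse_complement requires a dna record")
        return SequenceRecord(
            self.id, str(Seq(self.seq).reverse_complement()), "dna", self.source
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotation: disease group and optional bile-acid levels.

    ``ba_concentrations`` maps the four bile acids CA, CDCA (primary) and
    DCA, LCA (secondary) to non-negative concentrations; ``None`` means the
    metabolome was not measured for this sample (never encoded as zeros).
    """

    sample_id: str
    group: str
    ba_concentrations: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.ba_concentrations is not None:
            missing = set(BA_COLUMNS) - set(self.ba_concentrations)
            if missing:
                raise ValueError(
                    f"sample {self.sample_id}: missing bile acids {sorted(missing)}"
                )
            for ba, conc in self.ba_concentrations.items():
                if conc < 0:
                    raise ValueError(
                        f"sample {self.sample_id}: negative {ba} concentration {conc}"
                    )
            object.__setattr__(
                self, "ba_concentrations", dict(self.ba_concentrations)
            )


def _check_unique_ids(records: Sequence[SequenceRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


def read_fasta(path: str | Path, alphabet: str) -> list[SequenceRecord]:
    """Parse a FASTA file into validated records.

    A strict parser: empty sequences, data before the first header and
    duplicate ids are rejected, with the offending line number in the
    error message.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise FastaParseError(
                f"{path}:{header_line}: record {header!r} has an empty sequence"
            )
        records.append(
            SequenceRecord(header, "".join(chunks), alphabet, source=str(path))
        )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunks.append(line)
    flush()
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    _check_unique_ids(records)
    logger.info("read_fasta: %d %s records from %s", len(records), alphabet, path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    records = list(records)
    _check_unique_ids(records)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
    logger.info("write_fasta: %d records to %s", len(records), path)


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read Phred+33 FASTQ as (id, sequence, quality-string) tuples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append((rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals)))
    logger.info("read_fastq: %d reads from %s", len(out), path)
    return out


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    n = 0
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            if len(seq) != len(qual):
                raise ValueError(f"read {rid}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    logger.info("write_fastq: %d reads to %s", n, path)


def read_metadata_table(path: str | Path) -> list[SampleMetadata]:
    """Read a sample-metadata TSV.

    Required columns: ``sample_id`` and ``group``.  The four bile-acid
    columns (CA, CDCA, DCA, LCA) are optional; rows where any of them is
    missing get ``ba_concentrations=None``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: metadata table lacks a sample_id column")
    if "group" not in df.columns:
        raise ValueError(f"{path}: metadata table lacks a group column")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    has_ba = all(c in df.columns for c in BA_COLUMNS)
    out = []
    for _, row in df.iterrows():
        ba = None
        if has_ba and not any(pd.isna(row[c]) for c in BA_COLUMNS):
            ba = {c: float(row[c]) for c in BA_COLUMNS}
        out.append(SampleMetadata(str(row["sample_id"]), str(row["group"]), ba))
    logger.info("read_metadata_table: %d samples from %s", len(out), path)
    return out


def write_metadata_table(samples: Sequence[SampleMetadata], path: str | Path) -> None:
    rows = []
    for s in samples:
        row: dict[str, object] = {"sample_id": s.sample_id, "group": s.group}
        if s.ba_concentrations is not None:
            row.update({c: s.ba_concentrations[c] for c in BA_COLUMNS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- Newick -----------------------------------------------------------------

def _format_branch_length(bl: float) -> str:
    s = f"{bl:.6f}".rstrip("0")
    if s.endswith("."):
        s += "0"
    return s


def write_newick(tree) -> str:
    """Serialize a tree (skbio ``TreeNode``-like) to a Newick string.

    Branch lengths are written to six decimals with trailing zeros
    stripped (always keeping one), so ``(a:1,b:2)`` renders as
    ``(a:1.0,b:2.0);``.  The output is parseable by :func:`read_newick`.
    """
    if tree is None or (not tree.children and tree.name is None):
        raise ValueError("cannot serialize an empty tree")
    seen: set[int] = set()

    def render(node) -> str:
        if id(node) in seen:
            raise ValueError("cycle detected in tree topology")
        seen.add(id(node))
        label = node.name or ""
        if node.children:
            inner = ",".join(render(c) for c in node.children)
            label = f"({inner}){label}"
        if node.length is not None:
            label += f":{_format_branch_length(node.length)}"
        return label

    return render(tree) + ";"


def read_newick(text: str):
    """Parse a Newick string into an skbio ``TreeNode``."""
    from io import StringIO

    from skbio import TreeNode

    return TreeNode.read(StringIO(text))
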