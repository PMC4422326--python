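"""Amplicon reference sequences and their cytosine-context maps.

Bisulfite conversion deaminates unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine is protected.  Methylation is therefore
read out at CpG dinucleotides, while cytosines *outside* CpG context — which
are essentially unmethylated in mammalian somatic DNA — serve as built-in
conversion controls.  This module precomputes, for each amplicon reference:

* ``cpg_sites`` — forward-strand positions of the C of every CpG;
* ``noncpg_c_top`` — forward-strand cytosines not in CpG context;
* ``noncpg_c_bottom`` — reverse-strand cytosines not in CpG context,
  stored as the forward-strand position of the complementary G.

All coordinates are 0-based half-open internally; exported reports use
1-based positions and say so in their headers.  A CpG site is always keyed
by its forward-strand C position, whichever strand a read derives from,
so the two strands of one biological site aggregate under one key.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "AmpliconReference",
    "ConvertedReference",
    "find_cpg_sites",
    "classify_cytosines",
    "convert_reference",
    "load_references",
    "write_cpg_bed",
    "reverse_complement",
]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TOP = "top"
BOTTOM = "bottom"


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


def _validate(sequence: str) -> None:
    for i, base in enumerate(sequence):
        if base not in _ALPHABET:
            raise ValueError(
                f"invalid base {base!r} at position {i}: sequence must be "
                "uppercase DNA over A/C/G/T/N"
            )


def find_cpg_sites(sequence: str) -> list[int]:
    """Return 0-based positions p with ``sequence[p:p+2] == 'CG'``.

    Positions are strictly increasing.  Raises ``ValueError`` on characters
    outside A/C/G/T/N, naming the offending position.
    """
    _validate(sequence)
    return [i for i in range(len(sequence) - 1) if sequence[i] == "C" and sequence[i + 1] == "G"]


def classify_cytosines(sequence: str) -> tuple[list[int], list[int], list[int]]:
    """Partition cytosine positions by strand and CpG context.

    Returns ``(cpg_sites, noncpg_c_top, noncpg_c_bottom)``:

    * ``cpg_sites`` — forward-strand C of each CpG dinucleotide;
    * ``noncpg_c_top`` — forward-strand Cs not followed by G;
    * ``noncpg_c_bottom`` — forward-strand Gs not preceded by C (these are
      cytosines on the reverse strand, outside CpG context).

    Positions whose context involves an N are excluded from all three maps
    (the context, hence the expected conversion behaviour, is unknown).
    """
    _validate(sequence)
    cpg: list[int] = []
    noncpg_top: list[int] = []
    noncpg_bottom: list[int] = []
    n = len(sequence)
    for i, base in enumerate(sequence):
        if base == "C":
            nxt = sequence[i + 1] if i + 1 < n else ""
            if nxt == "G":
                cpg.append(i)
            elif nxt != "N":
                noncpg_top.append(i)
        elif base == "G":
            prev = sequence[i - 1] if i > 0 else ""
            if prev not in ("C", "N"):
                noncpg_bottom.append(i)
    return cpg, noncpg_top, noncpg_bottom


@dataclasses.dataclass(frozen=True)
class AmpliconReference:
    """An amplicon reference sequence with precomputed cytosine maps."""

    id: str
    sequence: str
    cpg_sites: tuple[int, ...]
    noncpg_c_top: tuple[int, ...]
    noncpg_c_bottom: tuple[int, ...]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_sequence(cls, id: str, sequence: str) -> "AmpliconReference":
        sequence = sequence.upper()
        if not sequence:
            raise ValueError(f"amplicon {id!r}: empty sequence")
        cpg, top, bottom = classify_cytosines(sequence)
        return cls(
            id=id,
            sequence=sequence,
            cpg_sites=tuple(cpg),
            noncpg_c_top=tuple(top),
            noncpg_c_bottom=tuple(bottom),
        )


@dataclasses.dataclass(frozen=True)
class ConvertedReference:
    """An in-silico fully bisulfite-converted reference strand.

    ``top``: every C substituted with T (the converted forward strand);
    ``bottom``: every G substituted with A (the converted reverse strand,
    written in forward-strand coordinates).  Reads are aligned against these
    in the collapsed three-letter space.
    """

    amplicon_id: str
    strand: str
    converted_sequence: str


def convert_reference(ref: AmpliconReference, strand: str) -> ConvertedReference:
    """Fully convert a reference strand: top C→T, bottom G→A."""
    if strand == TOP:
        converted = ref.sequence.replace("C", "T")
    elif strand == BOTTOM:
        converted = ref.sequence.replace("G", "A")
    else:
        raise ValueError(f"strand must be {TOP!r} or {BOTTOM!r}, got {strand!r}")
    return ConvertedReference(amplicon_id=ref.id, strand=strand, converted_sequence=converted)


def load_references(fasta_path) -> dict[str, AmpliconReference]:
    """Load amplicon references from a multi-record FASTA.

    The record id (first whitespace-delimited token) is the amplicon id.
    """
    refs: dict[str, AmpliconReference] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in refs:
            raise ValueError(f"duplicate amplicon id {record.id!r} in {fasta_path}")
        refs[record.id] = AmpliconReference.from_sequence(record.id, str(record.seq))
    if not refs:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return refs


def write_cpg_bed(refs: Iterable[AmpliconReference] | dict[str, AmpliconReference], path) -> None:
    """Export per-amplicon CpG sites as BED6 (0-based half-open).

    Each interval covers the CpG dinucleotide ``[p, p+2)`` on the forward
    strand, named ``<amplicon>_CpG<k>`` with k counting from 1.
    """
    if isinstance(refs, dict):
        refs = refs.values()
    with open(path, "w") as fh:
        for ref in refs:
            for k, p in enumerate(ref.cpg_sites, start=1):
                fh.write(f"{ref.id}\t{p}\t{p + 2}\t{ref.id}_CpG{k}\t0\t+\n")
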