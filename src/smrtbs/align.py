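"""Bisulfite-aware semi-global alignment of amplicon reads.

Alignment follows the three-letter strategy: both the reference strand and
the read are collapsed into a reduced alphabet (top strand: C→T, bottom
strand: G→A) so that conversion status does not penalise the placement, and
the methylation state is afterwards read back from the *original* read
bases.  For every read, four candidates are evaluated per amplicon —
(read, reverse complement) × (top-converted, bottom-converted reference) —
with a semi-global affine-gap alignment (reference end gaps free, the read
fully aligned).  The highest-scoring candidate wins; ties between distinct
amplicons discard the read as ambiguous, since multiplexed amplicons must
not cross-contaminate.

Scoring defaults (match +2, mismatch −3, gap open −5, gap extend −2, with a
gap of length k costing open + (k−1)·extend; minimum identity 0.7) are this
package's own and are exposed as parameters.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

from Bio import Align

from .amplicon import BOTTOM, TOP, AmpliconReference, convert_reference, reverse_complement
from .demux import FORWARD, REVCOMP, DemuxedRead

__all__ = [
    "METH", "UNMETH", "AMBIG", "UNCOVERED", "CONVERTED", "RETAINED",
    "AlignedRead", "BisulfiteAligner", "call_methylation", "write_calls_tsv",
    "write_sam",
]

# CpG call states
METH = "METH"
UNMETH = "UNMETH"
AMBIG = "AMBIG"
UNCOVERED = "UNCOVERED"
# non-CpG cytosine states
CONVERTED = "CONVERTED"
RETAINED = "RETAINED"

_COLLAPSE_CT = str.maketrans("C", "T")
_COLLAPSE_GA = str.maketrans("G", "A")


@dataclasses.dataclass
class AlignedRead:
    """A read's placement on an amplicon with its per-site evidence.

    ``cpg_calls`` maps every CpG site of the reference (keyed by the
    forward-strand C position) to METH/UNMETH/AMBIG/UNCOVERED;
    ``noncpg_vector`` maps every strand-appropriate non-CpG cytosine to
    CONVERTED/RETAINED/AMBIG/UNCOVERED.
    """

    read_id: str
    sample_id: str | None
    amplicon_id: str
    strand: str
    orientation: str
    start: int
    end: int
    score: float
    identity: float
    cpg_calls: dict[int, str]
    noncpg_vector: dict[int, str]


def _build_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on the reference (the read aligns within the amplicon)
    aligner.end_deletion_score = 0
    return aligner


def _alignment_stats(alignment, ref_len: int) -> tuple[int, int, float, dict[int, int]]:
    """Derive (start, end, identity, ref→read position map) from an alignment.

    Identity counts matches over all aligned columns within the read's span
    on the reference (internal gaps included, reference overhangs excluded).
    """
    target_blocks, query_blocks = alignment.aligned
    if len(target_blocks) == 0:
        return 0, 0, 0.0, {}
    tseq = alignment.target
    qseq = alignment.query
    pos_map: dict[int, int] = {}
    matches = 0
    columns = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        if prev_t is not None:
            columns += (ts - prev_t) + (qs - prev_q)  # internal gaps
        for k in range(te - ts):
            t_i, q_i = ts + k, qs + k
            pos_map[t_i] = q_i
            if tseq[t_i] == qseq[q_i]:
                matches += 1
            columns += 1
        prev_t, prev_q = te, qe
    start = target_blocks[0][0]
    end = target_blocks[-1][1]
    identity = matches / columns if columns else 0.0
    return int(start), int(end), identity, pos_map


def call_methylation(
    pos_map: Mapping[int, int],
    span: tuple[int, int],
    oriented_read: str,
    ref: AmpliconReference,
    strand: str,
) -> tuple[dict[int, str], dict[int, str]]:
    """Read methylation evidence off the original (uncollapsed) read bases.

    ``pos_map`` maps reference positions to positions in ``oriented_read``
    (the read in forward-amplicon orientation).  On the top strand the CpG
    evidence base sits at the C position (C retained = METH, T = UNMETH);
    on the bottom strand it sits at the G position p+1 in forward
    coordinates (G = METH, A = UNMETH), but the call is keyed by the
    forward-strand C position p.  Deletions over a cytosine yield AMBIG;
    positions outside the aligned span are UNCOVERED.
    """
    start, end = span

    def _call(pos: int, retained_base: str, converted_base: str) -> str:
        if not (start <= pos < end):
            return UNCOVERED
        q = pos_map.get(pos)
        if q is None:
            return AMBIG  # deletion in the read over this cytosine
        base = oriented_read[q]
        if base == retained_base:
            return RETAINED
        if base == converted_base:
            return CONVERTED
        return AMBIG

    cpg_calls: dict[int, str] = {}
    noncpg_vector: dict[int, str] = {}
    if strand == TOP:
        for p in ref.cpg_sites:
            state = _call(p, "C", "T")
            cpg_calls[p] = {RETAINED: METH, CONVERTED: UNMETH}.get(state, state)
        for p in ref.noncpg_c_top:
            noncpg_vector[p] = _call(p, "C", "T")
    else:
        for p in ref.cpg_sites:
            state = _call(p + 1, "G", "A")
            cpg_calls[p] = {RETAINED: METH, CONVERTED: UNMETH}.get(state, state)
        for p in ref.noncpg_c_bottom:
            noncpg_vector[p] = _call(p, "G", "A")
    return cpg_calls, noncpg_vector


class BisulfiteAligner:
    """Aligns reads against a panel of bisulfite-converted amplicon references."""

    def __init__(
        self,
        refs: Mapping[str, AmpliconReference] | Iterable[AmpliconReference],
        match: float = 2.0,
        mismatch: float = -3.0,
        gap_open: float = -5.0,
        gap_extend: float = -2.0,
        min_identity: float = 0.7,
    ):
        if isinstance(refs, Mapping):
            refs = list(refs.values())
        else:
            refs = list(refs)
        if not refs:
            raise ValueError("no amplicon references loaded")
        self.refs: dict[str, AmpliconReference] = {r.id: r for r in refs}
        self.min_identity = min_identity
        self._aligner = _build_aligner(match, mismatch, gap_open, gap_extend)
        self._converted: dict[tuple[str, str], str] = {}
        for r in refs:
            self._converted[(r.id, TOP)] = convert_reference(r, TOP).converted_sequence
            self._converted[(r.id, BOTTOM)] = convert_reference(r, BOTTOM).converted_sequence

    def _candidates(self, seq: str):
        """Yield (amplicon_id, strand, orientation, collapsed_read, conv_ref)."""
        oriented = {FORWARD: seq, REVCOMP: reverse_complement(seq)}
        for amp_id in self.refs:
            for strand, table in ((TOP, _COLLAPSE_CT), (BOTTOM, _COLLAPSE_GA)):
                conv_ref = self._converted[(amp_id, strand)]
                for orientation, oseq in oriented.items():
                    yield amp_id, strand, orientation, oseq.translate(table), conv_ref

    def align_read(self, read: DemuxedRead | str) -> AlignedRead | None:
        """Best placement of a read across all amplicons, strands and
        orientations, or None if ambiguous or below the identity floor."""
        if isinstance(read, str):
            read = DemuxedRead(read_id="read", sample_id=None, sequence=read)
        seq = read.sequence.upper()
        if not seq:
            return None
        scored: list[tuple[float, str, str, str, str, str]] = []
        for amp_id, strand, orientation, collapsed, conv_ref in self._candidates(seq):
            score = self._aligner.score(conv_ref, collapsed)
            scored.append((score, amp_id, strand, orientation, collapsed, conv_ref))
        best_score = max(s[0] for s in scored)
        best = [s for s in scored if s[0] == best_score]
        if len({s[1] for s in best}) > 1:
            return None  # tie across distinct amplicons: ambiguous
        score, amp_id, strand, orientation, collapsed, conv_ref = best[0]
        alignment = self._aligner.align(conv_ref, collapsed)[0]
        ref = self.refs[amp_id]
        start, end, identity, pos_map = _alignment_stats(alignment, ref.length)
        if identity < self.min_identity:
            return None
        oriented_read = seq if orientation == FORWARD else reverse_complement(seq)
        cpg_calls, noncpg_vector = call_methylation(
            pos_map, (start, end), oriented_read, ref, strand
        )
        return AlignedRead(
            read_id=read.read_id,
            sample_id=read.sample_id,
            amplicon_id=amp_id,
            strand=strand,
            orientation=orientation,
            start=start,
            end=end,
            score=float(score),
            identity=identity,
            cpg_calls=cpg_calls,
            noncpg_vector=noncpg_vector,
        )

    def align_all(self, reads: Iterable[DemuxedRead]) -> tuple[list[AlignedRead], int]:
        """Align many reads; returns (aligned reads, number unaligned)."""
        aligned: list[AlignedRead] = []
        n_unaligned = 0
        for read in reads:
            result = self.align_read(read)
            if result is None:
                n_unaligned += 1
            else:
                aligned.append(result)
        return aligned, n_unaligned


def write_calls_tsv(aligned_reads: Iterable[AlignedRead], path) -> None:
    """Per-read per-site calls as TSV (site positions are 1-based)."""
    with open(path, "w") as fh:
        fh.write("# site_1based: 1-based forward-strand C position of the CpG\n")
        fh.write("read_id\tsample\tamplicon\tstrand\tsite_1based\tcall\n")
        for ar in aligned_reads:
            for pos in sorted(ar.cpg_calls):
                fh.write(
                    f"{ar.read_id}\t{ar.sample_id}\t{ar.amplicon_id}\t{ar.strand}"
                    f"\t{pos + 1}\t{ar.cpg_calls[pos]}\n"
                )


def write_sam(
    aligned_reads: Iterable[AlignedRead],
    reads_by_id: Mapping[str, str],
    refs: Mapping[str, AmpliconReference],
    path,
) -> None:
    """Minimal SAM export of the placements (converted-space coordinates).

    CIGAR is reduced to a soft-clip-free span match (the per-column path is
    not retained on the AlignedRead); ZS carries the bisulfite strand.
    """
    import pysam

    ref_ids = list(refs)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": rid, "LN": refs[rid].length} for rid in ref_ids],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for ar in aligned_reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = ar.read_id
            seq = reads_by_id.get(ar.read_id, "")
            oriented = seq if ar.orientation == FORWARD else reverse_complement(seq)
            a.query_sequence = oriented or None
            a.flag = 16 if ar.strand == BOTTOM else 0
            a.reference_id = ref_ids.index(ar.amplicon_id)
            a.reference_start = ar.start
            a.mapping_quality = 60
            if oriented:
                span = ar.end - ar.start
                clip = max(len(oriented) - span, 0)
                a.cigartuples = [(0, min(span, len(oriented)))] + ([(4, clip)] if clip else [])
            a.set_tag("ZS", ar.strand)
            a.set_tag("ZI", round(ar.identity, 4))
            out.write(a)
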