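"""Barcode demultiplexing, barcode/primer trimming, and the length filter.

Reads carry an 18 bp sample barcode plus a universal primer on each end:

    bc_fwd + primer_fwd + insert + revcomp(primer_rev) + revcomp(bc_rev)

Assignment tolerates a bounded Levenshtein edit distance (default 2,
insertions/deletions included) against the 5' barcode of either read
orientation.  Ties between two distinct samples at the minimal distance
leave the read unassigned — arbitrary assignment would cross-contaminate
samples.  After assignment, barcodes and universal primers are trimmed at
their best sub-alignment and reads not longer than ``min_len`` (default
50 bp, strict) are discarded.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import edlib
import pandas as pd

from .amplicon import reverse_complement

__all__ = [
    "ManifestEntry",
    "BarcodeManifest",
    "DemuxedRead",
    "assign_barcode",
    "trim_read",
    "length_filter",
    "demux_reads",
    "demux_fastq",
    "read_fastq",
    "write_fastq",
]

logger = logging.getLogger(__name__)

UNASSIGNED = None
FORWARD = "forward"
REVCOMP = "reverse-complement"


@dataclasses.dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    bc_fwd: str
    bc_rev: str
    primer_fwd: str
    primer_rev: str


@dataclasses.dataclass
class BarcodeManifest:
    """Sample manifest: barcodes and universal primers per sample."""

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("barcode manifest is empty")
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids in manifest must be unique")
        lengths = {len(e.bc_fwd) for e in self.entries} | {len(e.bc_rev) for e in self.entries}
        if len(lengths) != 1:
            raise ValueError(f"all barcodes must share one length, got {sorted(lengths)}")
        self.barcode_length = lengths.pop()
        self.min_pairwise_distance = self._min_pairwise_distance()
        logger.info(
            "manifest: %d samples, %d bp barcodes, min pairwise edit distance %d",
            len(self.entries), self.barcode_length, self.min_pairwise_distance,
        )

    def _min_pairwise_distance(self) -> int:
        barcodes = sorted({e.bc_fwd for e in self.entries} | {e.bc_rev for e in self.entries})
        best = self.barcode_length
        for i in range(len(barcodes)):
            for j in range(i + 1, len(barcodes)):
                d = edlib.align(barcodes[i], barcodes[j], task="distance")["editDistance"]
                best = min(best, d)
        return best

    @classmethod
    def from_tsv(cls, path) -> "BarcodeManifest":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = ["sample_id", "bc_fwd", "bc_rev", "primer_fwd", "primer_rev"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"manifest {path} lacks required columns: {missing}")
        entries = [
            ManifestEntry(r.sample_id, r.bc_fwd.upper(), r.bc_rev.upper(),
                          r.primer_fwd.upper(), r.primer_rev.upper())
            for r in df.itertuples()
        ]
        return cls(entries)

    def to_tsv(self, path) -> None:
        pd.DataFrame([dataclasses.asdict(e) for e in self.entries]).to_csv(
            path, sep="\t", index=False
        )

    def entry(self, sample_id: str) -> ManifestEntry:
        for e in self.entries:
            if e.sample_id == sample_id:
                return e
        raise KeyError(sample_id)


@dataclasses.dataclass
class DemuxedRead:
    """A read after demultiplexing, oriented to the forward product strand."""

    read_id: str
    sample_id: str | None
    sequence: str
    quals: str | None = None
    barcode_edits: int = -1
    orientation: str = FORWARD
    flags: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.sequence)


def _prefix_distance(barcode: str, read_seq: str, max_edits: int) -> int:
    """Min edits to align ``barcode`` to a prefix of the read (indels allowed)."""
    window = read_seq[: len(barcode) + max_edits]
    if len(window) < len(barcode) - max_edits:
        return len(barcode)
    return edlib.align(barcode, window, mode="SHW", task="distance")["editDistance"]


def assign_barcode(
    read_seq: str,
    manifest: BarcodeManifest,
    max_edits: int = 2,
) -> tuple[str | None, int, str]:
    """Assign a read to a sample by its 5' barcode, testing both orientations.

    Returns ``(sample_id or None, edits, orientation)``.  The unique sample
    with minimum edit distance ≤ ``max_edits`` wins; a tie between two
    distinct samples, or no qualifying barcode, leaves the read unassigned
    (edits then reports the best distance seen).
    """
    if len(read_seq) < manifest.barcode_length:
        return UNASSIGNED, manifest.barcode_length, FORWARD
    oriented = {FORWARD: read_seq, REVCOMP: reverse_complement(read_seq)}
    best_d = manifest.barcode_length + 1
    best: list[tuple[str, str]] = []  # (sample_id, orientation)
    for orientation in (FORWARD, REVCOMP):
        seq = oriented[orientation]
        for entry in manifest.entries:
            d = _prefix_distance(entry.bc_fwd, seq, max_edits)
            if d < best_d:
                best_d = d
                best = [(entry.sample_id, orientation)]
            elif d == best_d:
                best.append((entry.sample_id, orientation))
    if best_d > max_edits:
        return UNASSIGNED, best_d, FORWARD
    samples = {s for s, _ in best}
    if len(samples) > 1:
        return UNASSIGNED, best_d, FORWARD  # ambiguous between samples
    sample_id, orientation = best[0]  # same sample; prefer forward orientation
    for s, o in best:
        if o == FORWARD:
            orientation = o
            break
    return sample_id, best_d, orientation


def _locate_prefix(query: str, read_seq: str, budget: int) -> int | None:
    """End position (exclusive) of the best prefix alignment of ``query``,
    or None if it exceeds the edit ``budget``."""
    window = read_seq[: len(query) + budget]
    res = edlib.align(query, window, mode="SHW", task="locations")
    if res["editDistance"] > budget or not res["locations"]:
        return None
    return res["locations"][0][1] + 1


def trim_read(
    read: DemuxedRead,
    manifest: BarcodeManifest,
    max_edits: int = 2,
    primer_max_edits: int | None = None,
) -> DemuxedRead:
    """Trim barcode + universal primer from both ends of an assigned read.

    The 5' end is trimmed at the best sub-alignment of bc_fwd+primer_fwd;
    the 3' end likewise for the reverse barcode/primer (searched on the
    reverse complement).  If the combined barcode+primer cannot be located
    within the edit budget, the barcode alone is trimmed and the read is
    flagged ``primer_fwd_missing`` / ``primer_rev_missing``; if not even the
    barcode is locatable the read is flagged and left untouched at that end.
    """
    if read.sample_id is UNASSIGNED:
        raise ValueError("trim_read requires an assigned read")
    entry = manifest.entry(read.sample_id)
    if primer_max_edits is None:
        primer_max_edits = max(2, len(entry.primer_fwd) // 5)
    flags = list(read.flags)
    seq, quals = read.sequence, read.quals

    def _trim_5p(seq: str, quals: str | None, barcode: str, primer: str, tag: str):
        cut = _locate_prefix(barcode + primer, seq, max_edits + primer_max_edits)
        if cut is None:
            cut = _locate_prefix(barcode, seq, max_edits)
            if cut is None:
                flags.append(f"barcode_{tag}_missing")
                return seq, quals
            flags.append(f"primer_{tag}_missing")
        return seq[cut:], quals[cut:] if quals is not None else None

    # 5' end
    seq, quals = _trim_5p(seq, quals, entry.bc_fwd, entry.primer_fwd, "fwd")
    # 3' end: work on the reverse complement so it is again a prefix problem
    rc_seq = reverse_complement(seq)
    rc_quals = quals[::-1] if quals is not None else None
    rc_seq, rc_quals = _trim_5p(rc_seq, rc_quals, entry.bc_rev, entry.primer_rev, "rev")
    seq = reverse_complement(rc_seq)
    quals = rc_quals[::-1] if rc_quals is not None else None

    return dataclasses.replace(read, sequence=seq, quals=quals, flags=tuple(flags))


def length_filter(
    reads: Iterable[DemuxedRead],
    min_len: int = 50,
    inclusive: bool = False,
) -> list[DemuxedRead]:
    """Keep reads strictly longer than ``min_len`` (or ≥ with ``inclusive``)."""
    reads = list(reads)
    if inclusive:
        kept = [r for r in reads if len(r) >= min_len]
    else:
        kept = [r for r in reads if len(r) > min_len]
    logger.info("length filter (>%s%d bp): %d in, %d retained",
                "=" if inclusive else "", min_len, len(reads), len(kept))
    return kept


def _check_3p_barcode(
    oriented_seq: str, manifest: BarcodeManifest, sample_id: str, max_edits: int
) -> str | None:
    """Return the conflicting sample_id if the 3' barcode strictly favours a
    different sample within the edit budget, else None."""
    if len(manifest.entries) < 2:
        return None
    tail = reverse_complement(oriented_seq[-(manifest.barcode_length + max_edits):])
    dists = {
        e.sample_id: edlib.align(e.bc_rev, tail, mode="SHW", task="distance")["editDistance"]
        for e in manifest.entries
    }
    best_other = min((d, s) for s, d in dists.items() if s != sample_id)
    if best_other[0] <= max_edits and best_other[0] < dists[sample_id]:
        return best_other[1]
    return None


def demux_reads(
    records: Iterable[tuple[str, str, str | None]],
    manifest: BarcodeManifest,
    max_edits: int = 2,
    min_len: int = 50,
    require_end_agreement: bool = True,
) -> tuple[dict[str, list[DemuxedRead]], list[DemuxedRead], pd.DataFrame]:
    """Demultiplex, trim and length-filter an iterable of (id, seq, qual).

    Returns ``(per-sample reads, unassigned reads, stats table)``.  Every
    input read lands in exactly one bin before the length filter; the stats
    table additionally reports how many assigned reads each sample lost to
    the length filter and to 5'/3' barcode conflicts.
    """
    by_sample: dict[str, list[DemuxedRead]] = {e.sample_id: [] for e in manifest.entries}
    unassigned: list[DemuxedRead] = []
    n_short: dict[str, int] = {e.sample_id: 0 for e in manifest.entries}
    n_conflict = 0
    edit_sums: dict[str, int] = {e.sample_id: 0 for e in manifest.entries}
    n_assigned: dict[str, int] = {e.sample_id: 0 for e in manifest.entries}

    for read_id, seq, qual in records:
        seq = seq.upper()
        sample_id, edits, orientation = assign_barcode(seq, manifest, max_edits)
        if sample_id is UNASSIGNED:
            unassigned.append(DemuxedRead(read_id, None, seq, qual, edits, FORWARD))
            continue
        if orientation == REVCOMP:
            seq = reverse_complement(seq)
            qual = qual[::-1] if qual is not None else None
        if require_end_agreement:
            conflict = _check_3p_barcode(seq, manifest, sample_id, max_edits)
            if conflict is not None:
                n_conflict += 1
                unassigned.append(
                    DemuxedRead(read_id, None, seq, qual, edits, orientation,
                                flags=("barcode_conflict",))
                )
                continue
        read = DemuxedRead(read_id, sample_id, seq, qual, edits, orientation)
        read = trim_read(read, manifest, max_edits)
        n_assigned[sample_id] += 1
        edit_sums[sample_id] += edits
        if (len(read) > min_len) if min_len is not None else True:
            by_sample[sample_id].append(read)
        else:
            n_short[sample_id] += 1

    rows = []
    for e in manifest.entries:
        kept = by_sample[e.sample_id]
        rows.append({
            "sample": e.sample_id,
            "n_reads": len(kept),
            "n_assigned": n_assigned[e.sample_id],
            "n_too_short": n_short[e.sample_id],
            "median_len": float(pd.Series([len(r) for r in kept]).median()) if kept else 0.0,
            "mean_edits": edit_sums[e.sample_id] / n_assigned[e.sample_id]
            if n_assigned[e.sample_id] else 0.0,
        })
    rows.append({
        "sample": "unassigned", "n_reads": len(unassigned), "n_assigned": 0,
        "n_too_short": 0,
        "median_len": float(pd.Series([len(r) for r in unassigned]).median())
        if unassigned else 0.0,
        "mean_edits": 0.0,
    })
    stats = pd.DataFrame(rows)
    stats.attrs["n_barcode_conflicts"] = n_conflict
    return by_sample, unassigned, stats


def _open_maybe_gzip(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality-string) records; gzip-transparent."""
    with _open_maybe_gzip(path, "r") as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:].split()[0], seq, qual


def write_fastq(reads: Sequence[DemuxedRead], path) -> None:
    with _open_maybe_gzip(path, "w") as fh:
        for r in reads:
            qual = r.quals if r.quals is not None else "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def demux_fastq(
    fastq_path,
    manifest: BarcodeManifest,
    max_edits: int = 2,
    min_len: int = 50,
    outdir=None,
) -> tuple[dict[str, list[DemuxedRead]], list[DemuxedRead], pd.DataFrame]:
    """File-level wrapper: demultiplex a FASTQ, optionally writing per-sample
    FASTQs, ``unassigned.fastq`` and ``demux_stats.tsv`` to ``outdir``."""
    by_sample, unassigned, stats = demux_reads(
        read_fastq(fastq_path), manifest, max_edits=max_edits, min_len=min_len
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample_id, reads in by_sample.items():
            write_fastq(reads, outdir / f"{sample_id}.fastq")
        write_fastq(unassigned, outdir / "unassigned.fastq")
        stats.to_csv(outdir / "demux_stats.tsv", sep="\t", index=False)
    return by_sample, unassigned, stats
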