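"""End-to-end analysis: demultiplex → align → filter → quantify."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .align import AlignedRead, BisulfiteAligner
from .amplicon import AmpliconReference, load_references
from .demux import BarcodeManifest, demux_reads, read_fastq
from .qc import FilterReport, apply_filters, write_filter_report
from .quant import MethylationProfile, quantify, write_methylation_tsv

__all__ = ["PipelineResult", "run_pipeline", "run_pipeline_files"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineResult:
    profiles: dict[tuple[str, str], MethylationProfile]   # (sample, amplicon)
    filter_reports: list[FilterReport]
    aligned: dict[tuple[str, str], list[AlignedRead]]     # post-filter reads
    demux_stats: pd.DataFrame
    n_unaligned: int

    def profile(self, sample_id: str, amplicon_id: str) -> MethylationProfile:
        return self.profiles[(sample_id, amplicon_id)]


def run_pipeline(
    records: Iterable[tuple[str, str, str | None]],
    manifest: BarcodeManifest,
    refs: Mapping[str, AmpliconReference],
    max_edits: int = 2,
    min_len: int = 50,
    min_identity: float = 0.7,
    min_conversion: float = 0.95,
    min_depth: int = 10,
    drop_clones: bool = True,
    drop_all_clones: bool = False,
) -> PipelineResult:
    """Run the full analysis on (id, sequence, quality) records."""
    by_sample, _unassigned, demux_stats = demux_reads(
        records, manifest, max_edits=max_edits, min_len=min_len
    )
    aligner = BisulfiteAligner(refs, min_identity=min_identity)
    grouped: dict[tuple[str, str], list[AlignedRead]] = {}
    n_unaligned = 0
    for sample_id, reads in by_sample.items():
        aligned, n_un = aligner.align_all(reads)
        n_unaligned += n_un
        for ar in aligned:
            grouped.setdefault((sample_id, ar.amplicon_id), []).append(ar)

    profiles: dict[tuple[str, str], MethylationProfile] = {}
    reports: list[FilterReport] = []
    kept_reads: dict[tuple[str, str], list[AlignedRead]] = {}
    for (sample_id, amp_id), reads in sorted(grouped.items()):
        kept, report = apply_filters(
            reads, sample_id=sample_id, amplicon_id=amp_id,
            threshold=min_conversion, drop_clones=drop_clones,
            drop_all_clones=drop_all_clones,
        )
        reports.append(report)
        kept_reads[(sample_id, amp_id)] = kept
        profiles[(sample_id, amp_id)] = quantify(
            kept, refs[amp_id], min_depth=min_depth, sample_id=sample_id
        )
    return PipelineResult(
        profiles=profiles,
        filter_reports=reports,
        aligned=kept_reads,
        demux_stats=demux_stats,
        n_unaligned=n_unaligned,
    )


def run_pipeline_files(
    fastq_path,
    manifest_path,
    refs_path,
    outdir,
    **kwargs,
) -> PipelineResult:
    """File-level wrapper: reads FASTQ/TSV/FASTA, writes result tables."""
    manifest = BarcodeManifest.from_tsv(manifest_path)
    refs = load_references(refs_path)
    result = run_pipeline(read_fastq(fastq_path), manifest, refs, **kwargs)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.demux_stats.to_csv(outdir / "demux_stats.tsv", sep="\t", index=False)
    write_filter_report(result.filter_reports, outdir / "filter_report.tsv")
    write_methylation_tsv(result.profiles.values(), outdir / "methylation.tsv")
    return result
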