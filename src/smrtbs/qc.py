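"""Per-read QC filters: bisulfite conversion rate and clonal PCR artifacts.

Two read-level filters precede methylation quantitation:

1. **Conversion-rate filter.** Non-CpG cytosines are essentially
   unmethylated in mammalian somatic DNA, so the fraction converted to T
   measures per-molecule bisulfite chemistry.  Reads with a conversion rate
   below 0.95 are removed (pass requires rate ≥ threshold); reads with no
   informative non-CpG cytosine cannot be verified and fail by default.

2. **Clonal-artifact filter.** PCR copies of one original molecule show
   identical patterns of both CpG and non-CpG cytosines throughout the
   amplicon and would otherwise inflate apparent depth.  Reads whose full
   call vectors (including UNCOVERED positions, i.e. identical aligned
   spans) coincide form a clone group; one representative per group is
   retained by default.

The conversion filter runs first, then clonal detection on its survivors.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import pandas as pd

from .align import AMBIG, CONVERTED, RETAINED, UNCOVERED, AlignedRead

__all__ = [
    "FilterReport",
    "conversion_rate",
    "filter_by_conversion",
    "detect_clonal",
    "remove_clones",
    "apply_filters",
    "write_filter_report",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class FilterReport:
    """Read accounting for one sample×amplicon through both filters.

    Counts partition the input exactly:
    ``n_input = n_low_conversion + n_clonal_removed + n_pass``.
    """

    sample_id: str
    amplicon_id: str
    n_input: int
    n_low_conversion: int
    n_clonal_removed: int
    n_pass: int
    mean_conversion_before: float
    mean_conversion_after: float

    def __post_init__(self) -> None:
        assert self.n_input == self.n_low_conversion + self.n_clonal_removed + self.n_pass


def conversion_rate(read: AlignedRead) -> float | None:
    """CONVERTED / (CONVERTED + RETAINED) over covered, unambiguous non-CpG
    cytosines; None when no informative position exists."""
    n_conv = sum(1 for v in read.noncpg_vector.values() if v == CONVERTED)
    n_ret = sum(1 for v in read.noncpg_vector.values() if v == RETAINED)
    denom = n_conv + n_ret
    if denom == 0:
        return None
    return n_conv / denom


def filter_by_conversion(
    reads: Iterable[AlignedRead],
    threshold: float = 0.95,
    fail_uninformative: bool = True,
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Split reads into (pass, fail) at the conversion-rate threshold.

    Pass requires rate ≥ threshold.  Reads whose rate is undefined (zero
    informative non-CpG cytosines) fail unless ``fail_uninformative`` is
    False.
    """
    passed: list[AlignedRead] = []
    failed: list[AlignedRead] = []
    for read in reads:
        rate = conversion_rate(read)
        if rate is None:
            (failed if fail_uninformative else passed).append(read)
        elif rate >= threshold:
            passed.append(read)
        else:
            failed.append(read)
    logger.info("conversion filter (>=%.2f): %d pass, %d fail",
                threshold, len(passed), len(failed))
    return passed, failed


def _clone_key(read: AlignedRead) -> tuple:
    return (
        read.amplicon_id,
        read.strand,
        tuple(sorted(read.cpg_calls.items())),
        tuple(sorted(read.noncpg_vector.items())),
    )


def detect_clonal(reads: Sequence[AlignedRead]) -> list[list[AlignedRead]]:
    """Group reads with identical CpG and non-CpG call vectors.

    Reads are first sorted by read_id so grouping (and the representative
    chosen downstream) is independent of input order.  Matching includes
    UNCOVERED positions, so only reads with identical aligned spans can be
    clones of each other.  A group of size k contributes k−1 removable
    clones.
    """
    groups: dict[tuple, list[AlignedRead]] = {}
    for read in sorted(reads, key=lambda r: r.read_id):
        groups.setdefault(_clone_key(read), []).append(read)
    return list(groups.values())


def remove_clones(
    reads: Sequence[AlignedRead],
    drop_all: bool = False,
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Collapse clone groups; returns (kept, removed).

    By default one representative (first by read_id) per group is retained;
    with ``drop_all`` every member of a multi-read group is removed.
    """
    kept: list[AlignedRead] = []
    removed: list[AlignedRead] = []
    for group in detect_clonal(reads):
        if len(group) == 1:
            kept.append(group[0])
        elif drop_all:
            removed.extend(group)
        else:
            kept.append(group[0])
            removed.extend(group[1:])
    order = {id(r): i for i, r in enumerate(reads)}
    kept.sort(key=lambda r: order[id(r)])
    return kept, removed


def _mean_rate(reads: Sequence[AlignedRead]) -> float:
    rates = [r for r in (conversion_rate(x) for x in reads) if r is not None]
    return sum(rates) / len(rates) if rates else float("nan")


def apply_filters(
    reads: Sequence[AlignedRead],
    sample_id: str = "",
    amplicon_id: str = "",
    threshold: float = 0.95,
    drop_clones: bool = True,
    drop_all_clones: bool = False,
    fail_uninformative: bool = True,
) -> tuple[list[AlignedRead], FilterReport]:
    """Run both filters in order for one sample×amplicon group."""
    reads = list(reads)
    mean_before = _mean_rate(reads)
    passed, failed = filter_by_conversion(
        reads, threshold=threshold, fail_uninformative=fail_uninformative
    )
    if drop_clones:
        kept, clones = remove_clones(passed, drop_all=drop_all_clones)
    else:
        kept, clones = passed, []
    report = FilterReport(
        sample_id=sample_id,
        amplicon_id=amplicon_id,
        n_input=len(reads),
        n_low_conversion=len(failed),
        n_clonal_removed=len(clones),
        n_pass=len(kept),
        mean_conversion_before=mean_before,
        mean_conversion_after=_mean_rate(kept),
    )
    return kept, report


def write_filter_report(reports: Iterable[FilterReport], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in reports]).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )
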