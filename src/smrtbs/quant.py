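"""Per-CpG methylation quantitation and downstream statistics.

The methylation level of a CpG site is the fraction of molecules carrying
a retained (methylated) C among all unambiguous observations,
``level = n_meth / (n_meth + n_unmeth)``; AMBIG calls count toward neither.
Sites observed at depth below ``min_depth`` (default 10X) are excluded
from exported profiles — low-depth estimates are too noisy to report.

Also here: replicate reproducibility statistics (pairwise Pearson r over
common sites, per-site standard deviation across replicates), comparison
of two site→level maps from different platforms, the CpG-island
amplicon-coverage fraction, and the equimolar pooling-volume calculation

    V_i = M * L_i / (n * C_i * sum_j L_j)

which pools amplicons so each contributes equal molecule counts.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import AMBIG, METH, UNMETH, AlignedRead
from .amplicon import AmpliconReference

__all__ = [
    "SiteStats",
    "MethylationProfile",
    "ReplicateSet",
    "PlatformComparison",
    "IslandCoverage",
    "PoolingResult",
    "quantify",
    "replicate_stats",
    "compare_platforms",
    "island_coverage",
    "pooling_volumes",
    "write_methylation_tsv",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class SiteStats:
    level: float
    depth: int
    n_meth: int
    n_unmeth: int
    n_ambig: int


@dataclasses.dataclass
class MethylationProfile:
    """Per-CpG-site methylation levels for one sample×amplicon."""

    sample_id: str
    amplicon_id: str
    sites: dict[int, SiteStats]
    n_sites_below_depth: int = 0

    def levels(self) -> dict[int, float]:
        return {p: s.level for p, s in self.sites.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": self.sample_id,
                "amplicon": self.amplicon_id,
                "site_1based": p + 1,
                "level": s.level,
                "depth": s.depth,
                "n_meth": s.n_meth,
                "n_unmeth": s.n_unmeth,
                "n_ambig": s.n_ambig,
            }
            for p, s in sorted(self.sites.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["sample", "amplicon", "site_1based", "level", "depth",
                     "n_meth", "n_unmeth", "n_ambig"],
        )


def quantify(
    reads: Iterable[AlignedRead],
    ref: AmpliconReference,
    min_depth: int = 10,
    sample_id: str | None = None,
) -> MethylationProfile:
    """Aggregate filtered reads of one sample×amplicon into a profile.

    Sites with depth (n_meth + n_unmeth) below ``min_depth`` are dropped
    and counted in ``n_sites_below_depth``.
    """
    reads = list(reads)
    if sample_id is None:
        sample_id = reads[0].sample_id if reads else ""
    if not reads:
        logger.warning("quantify: no reads for %s/%s — empty profile", sample_id, ref.id)
        return MethylationProfile(sample_id or "", ref.id, {})
    counts = {p: [0, 0, 0] for p in ref.cpg_sites}  # meth, unmeth, ambig
    for read in reads:
        if read.amplicon_id != ref.id:
            raise ValueError(
                f"read {read.read_id} aligned to {read.amplicon_id}, not {ref.id}"
            )
        for p, call in read.cpg_calls.items():
            if call == METH:
                counts[p][0] += 1
            elif call == UNMETH:
                counts[p][1] += 1
            elif call == AMBIG:
                counts[p][2] += 1
    sites: dict[int, SiteStats] = {}
    n_below = 0
    for p in ref.cpg_sites:
        n_meth, n_unmeth, n_ambig = counts[p]
        depth = n_meth + n_unmeth
        if depth < min_depth:
            n_below += 1
            continue
        sites[p] = SiteStats(n_meth / depth, depth, n_meth, n_unmeth, n_ambig)
    if n_below:
        logger.info("quantify %s/%s: %d sites below %dX dropped",
                    sample_id, ref.id, n_below, min_depth)
    return MethylationProfile(sample_id or "", ref.id, sites, n_below)


@dataclasses.dataclass
class ReplicateSet:
    """Reproducibility statistics across replicate profiles of one amplicon."""

    amplicon_id: str
    sample_ids: list[str]
    common_sites: list[int]
    correlations: pd.DataFrame          # symmetric, unit diagonal; NaN if undefined
    undefined_pairs: list[tuple[str, str]]
    per_site_sd: dict[int, float]       # ddof=1 across replicates
    median_sd: float
    mean_r: float
    sd_r: float


def replicate_stats(profiles: Sequence[MethylationProfile]) -> ReplicateSet:
    """Pairwise Pearson r and per-site SD across ≥2 replicate profiles.

    Statistics are restricted to sites present (depth-gated) in *all*
    replicates.  A pair where either profile has zero variance across sites
    has undefined correlation; it is reported as NaN and listed in
    ``undefined_pairs`` rather than silently coerced.
    """
    if len(profiles) < 2:
        raise ValueError("replicate_stats requires at least 2 profiles")
    amplicon_ids = {p.amplicon_id for p in profiles}
    if len(amplicon_ids) != 1:
        raise ValueError(f"profiles span several amplicons: {sorted(amplicon_ids)}")
    amplicon_id = amplicon_ids.pop()
    sample_ids = [p.sample_id for p in profiles]
    common = sorted(set.intersection(*(set(p.sites) for p in profiles)))
    mat = np.array([[p.sites[s].level for s in common] for p in profiles])
    n_rep = len(profiles)
    corr = np.full((n_rep, n_rep), np.nan)
    np.fill_diagonal(corr, 1.0)
    undefined: list[tuple[str, str]] = []
    r_values: list[float] = []
    for i, j in itertools.combinations(range(n_rep), 2):
        if len(common) < 2 or mat[i].std() == 0 or mat[j].std() == 0:
            undefined.append((sample_ids[i], sample_ids[j]))
            continue
        r = sps.pearsonr(mat[i], mat[j]).statistic
        corr[i, j] = corr[j, i] = r
        r_values.append(float(r))
    per_site_sd = {
        s: float(np.std(mat[:, k], ddof=1)) for k, s in enumerate(common)
    }
    sds = list(per_site_sd.values())
    return ReplicateSet(
        amplicon_id=amplicon_id,
        sample_ids=sample_ids,
        common_sites=common,
        correlations=pd.DataFrame(corr, index=sample_ids, columns=sample_ids),
        undefined_pairs=undefined,
        per_site_sd=per_site_sd,
        median_sd=float(np.median(sds)) if sds else float("nan"),
        mean_r=float(np.mean(r_values)) if r_values else float("nan"),
        sd_r=float(np.std(r_values, ddof=1)) if len(r_values) > 1 else float("nan"),
    )


@dataclasses.dataclass
class PlatformComparison:
    n_common: int
    pearson_r: float | None
    differences: dict[int, float]       # site → (a − b), for bias inspection
    status: str


def compare_platforms(
    profile_a: Mapping[int, float],
    profile_b: Mapping[int, float],
) -> PlatformComparison:
    """Compare two site→level maps (shared coordinate system) by Pearson r.

    Returns the per-site signed differences (a − b) alongside r; with no
    common sites or zero variance the correlation is None with an explicit
    status.
    """
    common = sorted(set(profile_a) & set(profile_b))
    diffs = {s: profile_a[s] - profile_b[s] for s in common}
    if not common:
        return PlatformComparison(0, None, {}, "no_common_sites")
    a = np.array([profile_a[s] for s in common])
    b = np.array([profile_b[s] for s in common])
    if len(common) < 2 or a.std() == 0 or b.std() == 0:
        return PlatformComparison(len(common), None, diffs, "correlation_undefined")
    r = float(sps.pearsonr(a, b).statistic)
    return PlatformComparison(len(common), r, diffs, "ok")


@dataclasses.dataclass
class IslandCoverage:
    n_islands: int
    n_coverable: int
    fraction: float | None
    status: str


def _read_bed_intervals(bed) -> pd.DataFrame:
    if isinstance(bed, pd.DataFrame):
        df = bed.iloc[:, :3].copy()
        df.columns = ["chrom", "start", "end"]
        df["line"] = np.arange(1, len(df) + 1)
        return df
    rows = []
    with open(bed) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed}:{lineno}: BED line has <3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{bed}:{lineno}: non-integer coordinates") from exc
            rows.append({"chrom": fields[0], "start": start, "end": end, "line": lineno})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "line"])


def island_coverage(bed, max_amplicon: int = 1500) -> IslandCoverage:
    """Fraction of CpG islands short enough to be covered by one amplicon.

    An island of length (end − start) ≤ ``max_amplicon`` counts as
    coverable (the boundary is inclusive: a 1.5 kb amplicon is achievable).
    Malformed intervals (end ≤ start) are rejected with their line number.
    """
    df = _read_bed_intervals(bed)
    if df.empty:
        return IslandCoverage(0, 0, None, "empty_bed")
    bad = df[df.end <= df.start]
    if not bad.empty:
        raise ValueError(
            f"BED line {int(bad.iloc[0].line)}: interval end must exceed start "
            f"({bad.iloc[0].chrom}:{int(bad.iloc[0].start)}-{int(bad.iloc[0].end)})"
        )
    lengths = df.end - df.start
    n_cover = int((lengths <= max_amplicon).sum())
    return IslandCoverage(len(df), n_cover, n_cover / len(df), "ok")


@dataclasses.dataclass
class PoolingResult:
    volumes: list[float]                # V_i, same units as M/C_i
    total_volume: float
    molar_shares: list[float]           # V_i*C_i/L_i normalised — equal when equimolar
    total_mass: float                   # sum over samples×amplicons of V_i*C_i


def pooling_volumes(
    total_mass: float,
    entries: Sequence[tuple[float, float]],
    n_samples: int = 1,
) -> PoolingResult:
    """Equimolar pooling volumes V_i = M*L_i / (n*C_i*sum_j L_j).

    ``entries`` is a list of (length_bp, concentration) per amplicon; M and
    the concentrations share a mass unit, volumes come out in the
    corresponding volume unit.  Each of the n samples contributes every
    amplicon, so the pooled mass over all samples×amplicons sums to M.
    """
    if total_mass <= 0:
        raise ValueError(f"total_mass must be positive, got {total_mass}")
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    if not entries:
        raise ValueError("entries must be non-empty")
    for i, (length, conc) in enumerate(entries):
        if length <= 0:
            raise ValueError(f"length of amplicon {i} must be positive, got {length}")
        if conc <= 0:
            raise ValueError(f"concentration of amplicon {i} must be positive, got {conc}")
    sum_len = sum(length for length, _ in entries)
    volumes = [
        total_mass * length / (n_samples * conc * sum_len) for length, conc in entries
    ]
    molar = [v * conc / length for v, (length, conc) in zip(volumes, entries)]
    total = sum(molar)
    shares = [m / total for m in molar]
    mass = n_samples * sum(v * conc for v, (_, conc) in zip(volumes, entries))
    return PoolingResult(
        volumes=volumes,
        total_volume=math.fsum(volumes) * n_samples,
        molar_shares=shares,
        total_mass=mass,
    )


def write_methylation_tsv(profiles: Iterable[MethylationProfile], path) -> None:
    """Export profiles as TSV; site positions 1-based, levels to 3 decimals."""
    frames = [p.to_frame() for p in profiles]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    with open(path, "w") as fh:
        fh.write("# site_1based: 1-based forward-strand C position of the CpG\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.3f")
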