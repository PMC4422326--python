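"""Synthetic barcoded bisulfite amplicon reads with known ground truth.

The generator emulates the molecule pool that targeted amplicon bisulfite
sequencing actually observes, at CCS (consensus read) level:

* per-molecule CpG methylation drawn as independent coin flips at each
  site's true level (methylation states independent across sites);
* incomplete bisulfite conversion — every unmethylated cytosine (CpG or
  not) converts to T with probability ``conversion_efficiency`` (default
  0.97) and is retained otherwise; methylated CpG cytosines never convert;
* strand of the bisulfite template chosen uniformly (top C→T chemistry or
  bottom G→A in forward coordinates);
* PCR bias toward unmethylated templates: a template carrying u
  unmethylated CpGs is sampled with weight ``pcr_bias_weight ** u``
  (w = 1 disables the bias);
* clonal PCR artifacts: with probability ``clonal_fraction`` a read is an
  exact copy of a previously emitted molecule's converted sequence (errors
  are injected independently afterwards);
* sequencing error: per-base substitutions and indels at configured rates;
* sample barcodes (18 bp) and universal primers attached to both ends,
  read orientation uniform.

Every emitted read has exactly one truth record (template provenance,
strand, clone-of, methylation pattern, injected error counts), and per-site
true levels are emitted alongside.  A fixed seed makes the full output
byte-for-byte reproducible.

``exact_sampling`` replaces the per-molecule coin flips with stratified
assignment — each site is methylated in exactly ``round(level * n)`` of the
n molecules — so that with conversion 1.0 and errors off the full pipeline
recovers every true level exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .amplicon import BOTTOM, TOP, AmpliconReference, reverse_complement
from .demux import BarcodeManifest, ManifestEntry

__all__ = [
    "AmpliconSpec",
    "SimConfig",
    "SimResult",
    "Molecule",
    "random_amplicon",
    "random_barcodes",
    "make_manifest",
    "simulate_templates",
    "simulate_reads",
    "write_outputs",
    "paper_like_site_levels",
    "paper_like_config",
    "UNIVERSAL_PRIMER_FWD",
    "UNIVERSAL_PRIMER_REV",
]

_BASES = np.array(list("ACGT"))

# Fixed universal tag sequences attached between barcode and insert.
UNIVERSAL_PRIMER_FWD = "TATCGGTACGAACTGAGGTC"
UNIVERSAL_PRIMER_REV = "CAGTTCGGAGATCGTTCAGA"


@dataclasses.dataclass
class AmpliconSpec:
    """An amplicon to simulate: explicit sequence, or a random one of the
    given length carrying ``n_cpg`` evenly spaced CpG sites."""

    id: str
    sequence: str | None = None
    length: int = 700
    n_cpg: int = 25


@dataclasses.dataclass
class SimConfig:
    amplicons: list[AmpliconSpec]
    samples: list[str]
    # per amplicon id: scalar level, per-site list (cycled over sites), or
    # explicit {0-based site position: level}
    site_levels: dict[str, float | Sequence[float] | dict[int, float]]
    conversion_efficiency: float | Sequence[tuple[float, float]] = 0.97
    substitution_rate: float = 0.005
    indel_rate: float = 0.001
    reads_per_amplicon: int = 100
    clonal_fraction: float = 0.003
    pcr_bias_weight: float = 1.0
    barcode_length: int = 18
    seed: int = 0
    exact_sampling: bool = False
    quality_char: str = "I"

    def __post_init__(self) -> None:
        for frac in (self.substitution_rate, self.indel_rate, self.clonal_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"rates/fractions must lie in [0,1], got {frac}")
        if self.pcr_bias_weight < 1.0:
            raise ValueError("pcr_bias_weight must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["amplicons"] = [AmpliconSpec(**a) for a in raw["amplicons"]]
        eff = raw.get("conversion_efficiency")
        if isinstance(eff, list):
            raw["conversion_efficiency"] = [tuple(pair) for pair in eff]
        return cls(**raw)


@dataclasses.dataclass
class Molecule:
    """One bisulfite-converted template molecule (forward coordinates)."""

    meth: tuple[bool, ...]          # per CpG site, in ref.cpg_sites order
    strand: str
    converted_fwd: str
    efficiency: float

    @property
    def n_unmeth(self) -> int:
        return len(self.meth) - sum(self.meth)


def random_amplicon(
    rng: np.random.Generator, length: int, n_cpg: int, id: str = "amplicon"
) -> AmpliconReference:
    """A random amplicon with exactly ``n_cpg`` evenly spaced CpG sites.

    Accidental CpGs in the random background are broken (G→A) before the
    intended sites are planted, so the CpG map is fully controlled while
    non-CpG cytosines remain at natural density.
    """
    if n_cpg * 3 > length:
        raise ValueError("amplicon too short for the requested CpG count")
    seq = list(rng.choice(_BASES, size=length))
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = "A"
    positions = np.linspace(2, length - 4, n_cpg).astype(int) if n_cpg else []
    for p in positions:
        seq[p], seq[p + 1] = "C", "G"
    # planting cannot create extra CpGs (a new CG would need a C immediately
    # before a planted G, which the planted C position excludes)
    ref = AmpliconReference.from_sequence(id, "".join(seq))
    assert len(ref.cpg_sites) == n_cpg
    return ref


def random_barcodes(
    rng: np.random.Generator, n: int, length: int = 18, min_distance: int = 6
) -> list[str]:
    """Random barcodes with pairwise edit distance ≥ ``min_distance``."""
    import edlib

    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("could not generate well-separated barcodes")
        cand = "".join(rng.choice(_BASES, size=length))
        if all(
            edlib.align(cand, b, task="distance")["editDistance"] >= min_distance
            for b in barcodes
        ):
            barcodes.append(cand)
    return barcodes


def make_manifest(
    samples: Sequence[str], rng: np.random.Generator, barcode_length: int = 18
) -> BarcodeManifest:
    barcodes = random_barcodes(rng, 2 * len(samples), length=barcode_length)
    entries = [
        ManifestEntry(
            sample_id=s,
            bc_fwd=barcodes[2 * i],
            bc_rev=barcodes[2 * i + 1],
            primer_fwd=UNIVERSAL_PRIMER_FWD,
            primer_rev=UNIVERSAL_PRIMER_REV,
        )
        for i, s in enumerate(samples)
    ]
    return BarcodeManifest(entries)


def _resolve_levels(
    ref: AmpliconReference, spec: float | Sequence[float] | dict[int, float]
) -> dict[int, float]:
    sites = ref.cpg_sites
    if isinstance(spec, dict):
        missing = [p for p in sites if p not in spec]
        if missing:
            raise ValueError(f"{ref.id}: site levels missing for positions {missing}")
        levels = {p: float(spec[p]) for p in sites}
    elif np.isscalar(spec):
        levels = {p: float(spec) for p in sites}
    else:
        seq = list(spec)
        levels = {p: float(seq[i % len(seq)]) for i, p in enumerate(sites)}
    for p, lv in levels.items():
        if not 0.0 <= lv <= 1.0:
            raise ValueError(f"{ref.id}: level {lv} at site {p} outside [0,1]")
    return levels


def _draw_efficiency(
    spec: float | Sequence[tuple[float, float]], rng: np.random.Generator
) -> float:
    if np.isscalar(spec):
        return float(spec)
    values = [v for v, _ in spec]
    probs = np.array([p for _, p in spec], dtype=float)
    return float(rng.choice(values, p=probs / probs.sum()))


def _convert_molecule(
    ref: AmpliconReference,
    meth: Sequence[bool],
    strand: str,
    efficiency: float,
    rng: np.random.Generator,
) -> str:
    """Apply bisulfite chemistry to one strand; forward coordinates."""
    seq = list(ref.sequence)
    meth_by_site = dict(zip(ref.cpg_sites, meth))
    if strand == TOP:
        for p in ref.cpg_sites:
            if not meth_by_site[p] and rng.random() < efficiency:
                seq[p] = "T"
        for p in ref.noncpg_c_top:
            if rng.random() < efficiency:
                seq[p] = "T"
    else:
        for p in ref.cpg_sites:  # bottom-strand C of the CpG is the G at p+1
            if not meth_by_site[p] and rng.random() < efficiency:
                seq[p + 1] = "A"
        for p in ref.noncpg_c_bottom:
            if rng.random() < efficiency:
                seq[p] = "A"
    return "".join(seq)


def simulate_templates(
    ref: AmpliconReference,
    levels: dict[int, float],
    n: int,
    efficiency: float | Sequence[tuple[float, float]],
    rng: np.random.Generator,
    exact: bool = False,
) -> list[Molecule]:
    """Draw ``n`` bisulfite-converted template molecules.

    With ``exact`` each site is methylated in exactly round(level*n)
    molecules (stratified assignment, independent permutation per site) and
    strands alternate deterministically; conversion must then be complete
    for downstream recovery to be exact.
    """
    sites = ref.cpg_sites
    if exact:
        meth_matrix = np.zeros((n, len(sites)), dtype=bool)
        for j, p in enumerate(sites):
            k = int(round(levels[p] * n))
            meth_matrix[rng.permutation(n)[:k], j] = True
        strands = [TOP if i % 2 == 0 else BOTTOM for i in range(n)]
    else:
        probs = np.array([levels[p] for p in sites])
        meth_matrix = rng.random((n, len(sites))) < probs
        strands = [TOP if s else BOTTOM for s in rng.random(n) < 0.5]
    molecules: list[Molecule] = []
    for i in range(n):
        eff = _draw_efficiency(efficiency, rng)
        meth = tuple(bool(b) for b in meth_matrix[i])
        molecules.append(
            Molecule(
                meth=meth,
                strand=strands[i],
                converted_fwd=_convert_molecule(ref, meth, strands[i], eff, rng),
                efficiency=eff,
            )
        )
    return molecules


def _inject_errors(
    seq: str, sub_rate: float, indel_rate: float, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Per-base substitutions and indels; returns (sequence, n_sub, n_indel)."""
    if sub_rate == 0 and indel_rate == 0:
        return seq, 0, 0
    out: list[str] = []
    n_sub = n_indel = 0
    for base in seq:
        if indel_rate and rng.random() < indel_rate:
            n_indel += 1
            if rng.random() < 0.5:
                out.append(str(rng.choice(_BASES)))  # insertion before base
                out.append(base)
            else:
                continue  # deletion
        elif sub_rate and rng.random() < sub_rate:
            n_sub += 1
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[int(rng.integers(3))])
        else:
            out.append(base)
    return "".join(out), n_sub, n_indel


@dataclasses.dataclass
class SimResult:
    records: list[tuple[str, str, str]]        # (read_id, sequence, quality)
    truth_reads: pd.DataFrame
    truth_sites: pd.DataFrame
    refs: dict[str, AmpliconReference]
    manifest: BarcodeManifest
    config: SimConfig


def _sample_templates(
    molecules: list[Molecule], n: int, w: float, rng: np.random.Generator
) -> list[Molecule]:
    """PCR-bias sampling: weight w**n_unmeth, without replacement.

    Sampling with replacement would itself create duplicate molecules —
    clonal artifacts — confounding the explicit ``clonal_fraction``
    mechanism, so the pool (10x oversized when w > 1) is drawn without
    replacement."""
    if w == 1.0:
        return molecules[:n]
    weights = np.array([w ** m.n_unmeth for m in molecules], dtype=float)
    idx = rng.choice(len(molecules), size=n, replace=False, p=weights / weights.sum())
    return [molecules[i] for i in idx]


def simulate_reads(config: SimConfig) -> SimResult:
    """Generate FASTQ-level records plus truth tables for a full experiment."""
    rng = np.random.default_rng(config.seed)
    manifest = make_manifest(config.samples, rng, config.barcode_length)
    refs: dict[str, AmpliconReference] = {}
    for spec in config.amplicons:
        if spec.sequence is not None:
            refs[spec.id] = AmpliconReference.from_sequence(spec.id, spec.sequence)
        else:
            refs[spec.id] = random_amplicon(rng, spec.length, spec.n_cpg, spec.id)

    site_rows = []
    levels_by_amp: dict[str, dict[int, float]] = {}
    for amp_id, ref in refs.items():
        levels = _resolve_levels(ref, config.site_levels[amp_id])
        levels_by_amp[amp_id] = levels
        for p in ref.cpg_sites:
            site_rows.append({"amplicon": amp_id, "site": p,
                              "site_1based": p + 1, "true_level": levels[p]})

    records: list[tuple[str, str, str]] = []
    read_rows = []
    n = config.reads_per_amplicon
    w = config.pcr_bias_weight
    for sample in config.samples:
        entry = manifest.entry(sample)
        for amp_id, ref in refs.items():
            pool_n = n if w == 1.0 else 10 * n
            pool = simulate_templates(
                ref, levels_by_amp[amp_id], pool_n,
                config.conversion_efficiency, rng, exact=config.exact_sampling,
            )
            queue = iter(_sample_templates(pool, n, w, rng))
            emitted: list[tuple[str, Molecule]] = []
            for k in range(n):
                read_id = f"{sample}_{amp_id}_{k:05d}"
                clone_of = ""
                if emitted and rng.random() < config.clonal_fraction:
                    clone_of, mol = emitted[int(rng.integers(len(emitted)))]
                else:
                    mol = next(queue)
                emitted.append((read_id, mol))
                product = (
                    entry.bc_fwd + entry.primer_fwd + mol.converted_fwd
                    + reverse_complement(entry.primer_rev)
                    + reverse_complement(entry.bc_rev)
                )
                orientation = "forward" if rng.random() < 0.5 else "reverse-complement"
                if orientation == "reverse-complement":
                    product = reverse_complement(product)
                seq, n_sub, n_indel = _inject_errors(
                    product, config.substitution_rate, config.indel_rate, rng
                )
                records.append((read_id, seq, config.quality_char * len(seq)))
                read_rows.append({
                    "read_id": read_id,
                    "sample": sample,
                    "amplicon": amp_id,
                    "strand": mol.strand,
                    "orientation": orientation,
                    "clone_of": clone_of,
                    "efficiency": mol.efficiency,
                    "n_sub": n_sub,
                    "n_indel": n_indel,
                    "n_unmeth_cpg": mol.n_unmeth,
                    "meth_pattern": "".join("1" if m else "0" for m in mol.meth),
                })
    return SimResult(
        records=records,
        truth_reads=pd.DataFrame(read_rows),
        truth_sites=pd.DataFrame(site_rows),
        refs=refs,
        manifest=manifest,
        config=config,
    )


def write_outputs(result: SimResult, outdir) -> None:
    """Write reads.fastq.gz, truth tables, manifest and references."""
    from .demux import DemuxedRead, write_fastq

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reads = [DemuxedRead(rid, None, seq, qual) for rid, seq, qual in result.records]
    write_fastq(reads, outdir / "reads.fastq.gz")
    result.truth_reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    result.truth_sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    result.manifest.to_tsv(outdir / "manifest.tsv")
    with open(outdir / "refs.fasta", "w") as fh:
        for ref in result.refs.values():
            fh.write(f">{ref.id}\n{ref.sequence}\n")


def paper_like_site_levels(n_cpg: int = 25) -> dict[str, list[float]]:
    """Site-level truth profiles for the three study conditions.

    ``CGI_low`` and ``CGI_high`` carry a shore-like gradient toward the
    island edge; ``CGI_mid`` is intermediately methylated with
    heterogeneous sites spanning the full range (mean 0.5), mirroring the
    within-island variation real intermediate islands show.
    """
    low = list(np.linspace(0.0, 0.25, n_cpg))
    high = list(np.linspace(0.75, 1.0, n_cpg))
    mid = [[0.0, 0.25, 0.5, 0.75, 1.0][i % 5] for i in range(n_cpg)]
    return {"CGI_low": low, "CGI_mid": mid, "CGI_high": high}


def paper_like_config(
    seed: int,
    reads_per_amplicon: int = 100,
    n_cpg: int = 25,
    length: int = 700,
    **overrides,
) -> SimConfig:
    """Default study conditions: three ~700 bp CpG-island amplicons (low,
    intermediate, high methylation) sequenced in triplicate at ~100X with
    conversion efficiency 0.97, 0.5% substitution / 0.1% indel error and
    0.3% clonal reads."""
    levels = paper_like_site_levels(n_cpg)
    kwargs = dict(
        amplicons=[AmpliconSpec(a, length=length, n_cpg=n_cpg) for a in levels],
        samples=["rep1", "rep2", "rep3"],
        site_levels=dict(levels),
        reads_per_amplicon=reads_per_amplicon,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
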