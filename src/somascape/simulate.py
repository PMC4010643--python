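"""Synthetic tumour/normal cohort generator.

Generates somatic call sets and copy-number profiles with the statistical
structure the downstream analyses assume, so every stage is testable without
controlled-access data:

* per-stage somatic SNV burden (Poisson around a group mean, monotone in
  stage) with correlated indel counts,
* a six-class substitution spectrum drawn multinomially from configured
  probabilities,
* subclonal structure: each variant belongs to a subclone with a cellular
  prevalence; read counts are Binomial(depth, expected VAF) with depth
  Poisson around the design coverage, the expected VAF combining prevalence,
  purity and local total copy number,
* segmented copy-number profiles tiling each chromosome exactly once, with
  configurable gain/loss/LOH/homozygous-deletion event rates, an amplicon
  around an anchor gene with a ladder of copy-number levels and allelic
  asymmetry, and injected chromothripsis arms with an exact joint-state
  transition count,
* germline heterozygous SNP seeding for B-allele-fraction profiling.

Every variant carries its true subclone label and multiplicity in the truth
table, so estimator-recovery tests can score against ground truth.  All
randomness flows through one seed; a fixed seed gives identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .cna import CopyNumberSegment
from .genome import GenomeModel
from .spectrum import SIX_CLASSES
from .variants import SomaticVariant

__all__ = [
    "AmpliconSpec",
    "ChromothripsisSpec",
    "CohortConfig",
    "SampleData",
    "generate_cohort",
    "iter_samples",
    "inject_chromothripsis",
    "load_cohort_config",
    "write_cohort",
]

# pyrimidine-reference (ref, alt) per class; purine strand is the complement
_CLASS_ALLELES = {
    "C:G>T:A": (("C", "T"), ("G", "A")),
    "C:G>A:T": (("C", "A"), ("G", "T")),
    "C:G>G:C": (("C", "G"), ("G", "C")),
    "T:A>C:G": (("T", "C"), ("A", "G")),
    "T:A>A:T": (("T", "A"), ("A", "T")),
    "T:A>G:C": (("T", "G"), ("A", "C")),
}

# genome-wide class proportions echoing the observed bladder-cancer spectrum
DEFAULT_SPECTRUM = {
    "C:G>T:A": 0.33, "C:G>A:T": 0.12, "C:G>G:C": 0.17,
    "T:A>C:G": 0.20, "T:A>A:T": 0.10, "T:A>G:C": 0.08,
}


@dataclass
class AmpliconSpec:
    """An amplified region anchored on a gene, with a copy-number ladder.

    ``cn_levels`` are the successive total copy numbers of equal-width blocks
    spanning the region (e.g. ``[3, 8, 3]`` gives an internally heterogeneous
    amplicon with a high-level core); ``minor_cn`` sets the allelic ratio
    (0 keeps one parental allele only: maximal asymmetry).
    """

    anchor_gene: str = "MDM2"
    cn_levels: tuple[int, ...] = (3, 8, 3)
    minor_cn: int = 1
    block_width: int = 150_000  # bp per ladder block (mini-genome scale)


@dataclass
class ChromothripsisSpec:
    """Chromothripsis injection target: which sample/arm, how many transitions."""

    sample_index: int
    chrom: str
    arm: str
    n_transitions: int = 12


@dataclass
class CohortConfig:
    """Cohort-level generator settings.

    Stage-group sizes and burden means default to the discovery-cohort
    design (4 non-invasive + 10 invasive genomes) with per-group mean SNV
    counts scaled to the mini-genome (1/20 of the full-genome burden scale,
    preserving the per-bp rate).  Burden is monotone in stage by default.
    """

    seed: int = 0
    n_samples: dict[str, int] = field(
        default_factory=lambda: {"pTa": 4, "pT1": 5, "pT2": 5})
    mean_snv: dict[str, float] = field(
        default_factory=lambda: {"pTa": 1_750.0, "pT1": 5_700.0, "pT2": 5_900.0})
    indel_ratio: float = 0.22
    spectrum: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    # subclone cellular prevalences (and variant weights) per stage group
    subclone_prevalences: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"pTa": (1.0,), "pT1": (1.0, 0.45),
                                 "pT2": (1.0, 0.5, 0.2)})
    purity: dict[str, float] = field(
        default_factory=lambda: {"pTa": 0.8, "pT1": 0.8, "pT2": 0.8})
    mean_depth: float = 80.0
    normal_mean_depth: float = 30.0
    # expected copy-number events per genome, by type
    event_rates: dict[str, float] = field(
        default_factory=lambda: {"gain": 4.0, "loss": 4.0, "loh": 2.0,
                                 "homozygous_deletion": 0.7})
    invasive_cna_multiplier: float = 3.0
    amplicon: AmpliconSpec | None = field(default_factory=AmpliconSpec)
    amplicon_sample_indices: tuple[int, ...] = (10, 11)  # invasive samples
    chromothripsis: tuple[ChromothripsisSpec, ...] = field(
        default_factory=lambda: (ChromothripsisSpec(6, "3", "p", 12),
                                 ChromothripsisSpec(6, "5", "q", 12)))
    germline_het_rate: float = 3e-5  # het SNPs per bp
    annotate_fraction: float = 1.0   # fraction of in-gene SNVs annotated

    def validate(self, genome: GenomeModel) -> None:
        probs = np.array([self.spectrum.get(c, 0.0) for c in SIX_CLASSES])
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"spectrum probabilities sum to {probs.sum()}, not 1")
        for stage, prevs in self.subclone_prevalences.items():
            for p in prevs:
                if not 0 < p <= 1:
                    raise ValueError(f"{stage}: prevalence {p} outside (0, 1]")
        for stage, pur in self.purity.items():
            if not 0 < pur <= 1:
                raise ValueError(f"{stage}: purity {pur} outside (0, 1]")
        if self.amplicon is not None:
            try:
                genome.gene(self.amplicon.anchor_gene)
            except KeyError:
                raise ValueError(
                    f"amplicon anchor gene {self.amplicon.anchor_gene!r} "
                    "not in genome catalog") from None


@dataclass
class SampleData:
    """One simulated tumour: calls, segments, germline hets, truth, metadata."""

    sample: str
    stage: str
    purity: float
    variants: list[SomaticVariant]
    segments: list[CopyNumberSegment]
    germline_hets: list[dict]
    truth: pd.DataFrame
    dna_index: float
    grade: str
    n_snv: int = 0
    n_indel: int = 0


# ---------------------------------------------------------------------------
# Segment machinery
# ---------------------------------------------------------------------------

def _diploid_tiling(sample: str, genome: GenomeModel) -> dict[str, list[CopyNumberSegment]]:
    return {
        chrom: [CopyNumberSegment(sample, chrom, 1, length, 2, 1)]
        for chrom, length in genome.chromosomes
    }


def _apply_event(
    segs: list[CopyNumberSegment], start: int, end: int, total_cn: int, minor_cn: int
) -> list[CopyNumberSegment]:
    """Overwrite [start, end] with a new state, preserving the tiling."""
    out: list[CopyNumberSegment] = []
    sample = segs[0].sample
    chrom = segs[0].chrom
    for s in segs:
        if s.end < start or s.start > end:
            out.append(s)
            continue
        if s.start < start:
            out.append(CopyNumberSegment(sample, chrom, s.start, start - 1,
                                         s.total_cn, s.minor_cn))
        if s.end > end:
            out.append(CopyNumberSegment(sample, chrom, end + 1, s.end,
                                         s.total_cn, s.minor_cn))
    out.append(CopyNumberSegment(sample, chrom, start, end, total_cn, minor_cn))
    out.sort(key=lambda s: s.start)
    # merge-adjacent same-state pieces is unnecessary; tiling holds
    return out


_EVENT_STATES = {
    "gain": (3, 1),
    "loss": (1, 0),
    "loh": (2, 0),                # copy-neutral LOH
    "homozygous_deletion": (0, 0),
}


def _random_segments(
    sample: str, genome: GenomeModel, rates: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, list[CopyNumberSegment]]:
    tiling = _diploid_tiling(sample, genome)
    chrom_names = genome.chrom_names
    lengths = np.array([genome.chrom_length(c) for c in chrom_names], dtype=float)
    weights = lengths / lengths.sum()
    for event, rate in rates.items():
        cn, minor = _EVENT_STATES[event]
        n_events = rng.poisson(rate)
        for _ in range(n_events):
            ci = int(rng.choice(len(chrom_names), p=weights))
            chrom = chrom_names[ci]
            length = int(lengths[ci])
            # homozygous deletions are focal; other events arm-scale-ish
            frac = rng.uniform(0.001, 0.01) if event == "homozygous_deletion" \
                else rng.uniform(0.05, 0.5)
            ev_len = max(1, int(length * frac))
            start = int(rng.integers(1, max(2, length - ev_len + 1)))
            end = min(length, start + ev_len - 1)
            tiling[chrom] = _apply_event(tiling[chrom], start, end, cn, minor)
    return tiling


def _apply_amplicon(
    tiling: dict[str, list[CopyNumberSegment]],
    spec: AmpliconSpec,
    genome: GenomeModel,
) -> None:
    gene = genome.gene(spec.anchor_gene)
    chrom_len = genome.chrom_length(gene.chrom)
    total_width = spec.block_width * len(spec.cn_levels)
    mid = (gene.start + gene.end) // 2
    start = max(1, mid - total_width // 2)
    for i, cn in enumerate(spec.cn_levels):
        b_start = start + i * spec.block_width
        b_end = min(chrom_len, b_start + spec.block_width - 1)
        minor = min(spec.minor_cn, cn // 2)
        tiling[gene.chrom] = _apply_event(tiling[gene.chrom], b_start, b_end, cn, minor)


def inject_chromothripsis(
    segments: Sequence[CopyNumberSegment],
    arm: tuple[str, str],
    n_transitions: int,
    genome: GenomeModel,
    rng: np.random.Generator | None = None,
) -> list[CopyNumberSegment]:
    """Rewrite one arm so it has exactly ``n_transitions`` joint-state changes.

    The arm is cut into ``n_transitions + 1`` blocks (random widths when an
    ``rng`` is given, equal widths otherwise) whose (total_cn, LOH) states
    cycle so every adjacent pair differs.  The rest of the genome is
    untouched; with ``n_transitions == 0`` the segments are returned as-is.
    """
    if n_transitions < 0:
        raise ValueError("n_transitions must be >= 0")
    if n_transitions == 0:
        return list(segments)
    chrom, arm_letter = arm
    lo, hi = genome.arm_bounds(chrom, arm_letter)
    arm_len = hi - lo + 1
    n_blocks = n_transitions + 1
    if arm_len < n_blocks:
        raise ValueError(
            f"arm {chrom}{arm_letter} ({arm_len} bp) too short for "
            f"{n_blocks} segments")
    sample = segments[0].sample if segments else ""
    if rng is None:
        cuts = np.linspace(lo - 1, hi, n_blocks + 1).astype(int)
    else:
        interior: set[int] = set()
        while len(interior) < n_blocks - 1:
            need = n_blocks - 1 - len(interior)
            interior.update(rng.integers(lo, hi, size=need).tolist())
        cuts = np.concatenate(
            [[lo - 1], np.sort(np.fromiter(interior, dtype=int)), [hi]])
    # states cycling so adjacent joint states always differ
    cycle = [(2, 1), (1, 0), (3, 1), (2, 0)]
    out = [s for s in segments if not (s.chrom == chrom and s.start >= lo and s.end <= hi)]
    # clip any segment partially overlapping the arm
    clipped = []
    for s in list(out):
        if s.chrom == chrom and s.start <= hi and s.end >= lo:
            out.remove(s)
            if s.start < lo:
                clipped.append(CopyNumberSegment(s.sample, chrom, s.start, lo - 1,
                                                 s.total_cn, s.minor_cn))
            if s.end > hi:
                clipped.append(CopyNumberSegment(s.sample, chrom, hi + 1, s.end,
                                                 s.total_cn, s.minor_cn))
    out.extend(clipped)
    for i in range(n_blocks):
        cn, minor = cycle[i % len(cycle)]
        out.append(CopyNumberSegment(sample, chrom, int(cuts[i]) + 1,
                                     int(cuts[i + 1]), cn, minor))
    out.sort(key=lambda s: (s.chrom, s.start))
    return out


# ---------------------------------------------------------------------------
# Variant generation
# ---------------------------------------------------------------------------

_GRADE = {"pTa": "G2", "pT1": "G3", "pT2": "G3"}

_CONSEQUENCE_CHOICES = ("missense", "synonymous", "stop-gain", "splice-site")
_CONSEQUENCE_PROBS = (0.62, 0.28, 0.06, 0.04)


def _cn_at(segs: list[CopyNumberSegment], positions: np.ndarray) -> np.ndarray:
    starts = np.array([s.start for s in segs])
    cns = np.array([s.total_cn for s in segs])
    idx = np.searchsorted(starts, positions, side="right") - 1
    return cns[np.clip(idx, 0, len(segs) - 1)]


def _simulate_sample(
    sample: str, stage: str, config: CohortConfig, genome: GenomeModel,
    rng: np.random.Generator, has_amplicon: bool,
    chromo_specs: Sequence[ChromothripsisSpec],
    counts_only: bool = False,
) -> SampleData:
    purity = config.purity[stage]
    prevalences = np.array(config.subclone_prevalences[stage], dtype=float)
    weights = np.ones(len(prevalences)) / len(prevalences)

    # segments
    rates = dict(config.event_rates)
    if stage in ("pT1", "pT2"):
        rates = {k: v * config.invasive_cna_multiplier for k, v in rates.items()}
    tiling = _random_segments(sample, genome, rates, rng)
    if has_amplicon and config.amplicon is not None:
        _apply_amplicon(tiling, config.amplicon, genome)
    segments = [s for c in genome.chrom_names for s in tiling[c]]
    for spec in chromo_specs:
        segments = inject_chromothripsis(
            segments, (spec.chrom, spec.arm), spec.n_transitions, genome, rng)
    seg_by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for s in segments:
        seg_by_chrom.setdefault(s.chrom, []).append(s)
    for segs in seg_by_chrom.values():
        segs.sort(key=lambda s: s.start)

    # variant counts
    n_snv = int(rng.poisson(config.mean_snv[stage]))
    n_indel = int(round(config.indel_ratio * n_snv))

    chrom_names = genome.chrom_names
    lengths = np.array([genome.chrom_length(c) for c in chrom_names], dtype=float)
    cweights = lengths / lengths.sum()
    spec_probs = np.array([config.spectrum[c] for c in SIX_CLASSES])

    def _positions(n: int) -> tuple[np.ndarray, np.ndarray]:
        ci = rng.choice(len(chrom_names), size=n, p=cweights)
        pos = (rng.random(n) * lengths[ci]).astype(np.int64) + 1
        return ci, pos

    variants: list[SomaticVariant] = []
    truth_rows: list[dict] = []

    def _emit(n: int, is_snv: bool) -> None:
        ci, pos = _positions(n)
        classes = rng.choice(len(SIX_CLASSES), size=n, p=spec_probs) if is_snv else None
        strand = rng.integers(0, 2, size=n)
        clone = rng.choice(len(prevalences), size=n, p=weights)
        depth = rng.poisson(config.mean_depth, size=n)
        for j in range(n):
            chrom = chrom_names[ci[j]]
            segs = seg_by_chrom[chrom]
            cn = int(_cn_at(segs, np.array([pos[j]]))[0])
            if cn == 0:
                continue  # unobservable: locus deleted in tumour
            prev = float(prevalences[clone[j]])
            vaf = prev * purity * 1 / (purity * cn + (1 - purity) * 2)
            d = int(depth[j])
            alt = int(rng.binomial(d, min(vaf, 1.0))) if d > 0 else 0
            if is_snv:
                ref, altb = _CLASS_ALLELES[SIX_CLASSES[classes[j]]][strand[j]]
            else:
                base = "ACGT"[int(rng.integers(0, 4))]
                ins = "ACGT"[int(rng.integers(0, 4))]
                if rng.random() < 0.5:
                    ref, altb = base + ins, base       # deletion
                else:
                    ref, altb = base, base + ins       # insertion
            gene_hits = genome.genes_at(chrom, int(pos[j]))
            gene = gene_hits[0].name if gene_hits else None
            consequence = None
            sift = pp2 = None
            if gene is not None and rng.random() < config.annotate_fraction:
                if is_snv:
                    consequence = str(rng.choice(_CONSEQUENCE_CHOICES,
                                                 p=_CONSEQUENCE_PROBS))
                else:
                    consequence = "frameshift"
                if consequence == "missense":
                    sift = float(np.round(rng.random(), 3))
                    pp2 = float(np.round(rng.random(), 3))
            variants.append(SomaticVariant(
                sample=sample, chrom=chrom, pos=int(pos[j]), ref=ref, alt=altb,
                depth=d, alt_reads=alt, gene=gene, consequence=consequence,
                sift_score=sift, polyphen2_score=pp2,
            ))
            truth_rows.append({
                "sample": sample, "chrom": chrom, "pos": int(pos[j]),
                "ref": ref, "alt": altb,
                "subclone": int(clone[j]), "prevalence": prev,
                "multiplicity": 1, "total_cn": cn, "expected_vaf": vaf,
            })

    if not counts_only:
        _emit(n_snv, is_snv=True)
        _emit(n_indel, is_snv=False)

    # germline heterozygous SNPs for BAF profiling
    n_het = 0 if counts_only else rng.poisson(
        config.germline_het_rate * genome.total_length)
    ci, pos = _positions(int(n_het))
    hets: list[dict] = []
    for j in range(int(n_het)):
        chrom = chrom_names[ci[j]]
        segs = seg_by_chrom[chrom]
        starts = np.array([s.start for s in segs])
        k = int(np.clip(np.searchsorted(starts, pos[j], side="right") - 1,
                        0, len(segs) - 1))
        seg = segs[k]
        if seg.total_cn == 0:
            continue
        allele_cn = seg.major_cn if rng.random() < 0.5 else seg.minor_cn
        exp_baf = ((purity * allele_cn + (1 - purity) * 1)
                   / (purity * seg.total_cn + (1 - purity) * 2))
        d_t = max(1, int(rng.poisson(config.mean_depth)))
        d_n = max(1, int(rng.poisson(config.normal_mean_depth)))
        hets.append({
            "chrom": chrom, "pos": int(pos[j]),
            "tumour_baf": rng.binomial(d_t, min(exp_baf, 1.0)) / d_t,
            "constitutional_baf": rng.binomial(d_n, 0.5) / d_n,
        })

    ploidy = sum(s.length * s.total_cn for s in segments) / genome.total_length
    return SampleData(
        sample=sample, stage=stage, purity=purity, variants=variants,
        segments=segments, germline_hets=hets,
        truth=pd.DataFrame(truth_rows), dna_index=ploidy / 2.0,
        grade=_GRADE[stage], n_snv=n_snv, n_indel=n_indel,
    )


def iter_samples(
    config: CohortConfig, genome: GenomeModel, counts_only: bool = False
) -> Iterator[SampleData]:
    """Generate samples one at a time (constant memory for large cohorts).

    With ``counts_only=True`` the per-variant emission is skipped and only
    burden counts, segments and metadata are produced (burden-level studies
    at full-genome mutation counts).
    """
    config.validate(genome)
    rng = np.random.default_rng(config.seed)
    idx = 0
    for stage in ("pTa", "pT1", "pT2"):
        for _ in range(config.n_samples.get(stage, 0)):
            sample = f"S{idx:02d}_{stage}"
            has_amp = idx in config.amplicon_sample_indices
            chromo = [c for c in config.chromothripsis if c.sample_index == idx]
            yield _simulate_sample(sample, stage, config, genome, rng,
                                   has_amp, chromo, counts_only=counts_only)
            idx += 1


def generate_cohort(
    config: CohortConfig, genome: GenomeModel, counts_only: bool = False
) -> list[SampleData]:
    """Generate the full synthetic cohort (see module docstring)."""
    return list(iter_samples(config, genome, counts_only=counts_only))


# ---------------------------------------------------------------------------
# Config file and output bundle
# ---------------------------------------------------------------------------

def load_cohort_config(path: str) -> CohortConfig:
    """Read a YAML cohort config; the seed key is mandatory."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("cohort config must set a seed")
    if "amplicon" in raw and raw["amplicon"] is not None:
        raw["amplicon"] = AmpliconSpec(**raw["amplicon"])
    if "chromothripsis" in raw:
        raw["chromothripsis"] = tuple(
            ChromothripsisSpec(**c) for c in raw["chromothripsis"])
    known = {f for f in CohortConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return CohortConfig(**raw)


def write_cohort(cohort: Sequence[SampleData], outdir: str,
                 genome: GenomeModel) -> None:
    """Write the bundle: per-sample VCFs, segment/metadata/truth/het TSVs."""
    import os

    from .variants import write_segments, write_somatic_vcf

    os.makedirs(outdir, exist_ok=True)
    all_segments = []
    meta_rows = []
    truths = []
    het_rows = []
    for s in cohort:
        write_somatic_vcf(s.variants, os.path.join(outdir, f"{s.sample}.vcf"),
                          genome)
        all_segments.extend(s.segments)
        meta_rows.append({
            "sample": s.sample, "stage": s.stage, "grade": s.grade,
            "purity": s.purity, "dna_index": round(s.dna_index, 4),
        })
        truths.append(s.truth)
        for h in s.germline_hets:
            het_rows.append({"sample": s.sample, **h})
    write_segments(all_segments, os.path.join(outdir, "segments.tsv"))
    pd.DataFrame(meta_rows).to_csv(
        os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
    pd.concat(truths, ignore_index=True).to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    pd.DataFrame(het_rows).to_csv(
        os.path.join(outdir, "germline_hets.tsv"), sep="\t", index=False)
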