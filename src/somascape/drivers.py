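"""Driver-gene prioritization: functional filter cascade and gene-by-sample matrix.

The cascade restricts to protein-coding consequences, keeps every
protein-truncating (stop-gain, stop-loss, frameshift) and splice-site
mutation, and excludes missense changes predicted benign by *both* scores
(SIFT > 0.2 AND PolyPhen2 < 0.8 — SIFT is benign when high, PolyPhen2 when
low).  A missense variant missing either score cannot satisfy the
conjunction and is retained.  Genes mutated in only one sample are then
dropped (recurrence filter), except for genes on an explicit known-driver
whitelist.  A per-variant ``quality_flag`` stands in for manual read review:
variants with the flag unset are excluded before the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .variants import SomaticVariant, TRUNCATING

__all__ = [
    "functional_filter",
    "GeneSampleMatrix",
    "build_gene_sample_matrix",
    "recurrence_filter",
    "cooccurrence",
    "load_driver_table",
    "matrix_from_driver_table",
]

_CODING_FOR_CASCADE = TRUNCATING | {"splice-site", "missense"}


def functional_filter(variant: SomaticVariant) -> bool:
    """Whether a variant survives the predicted-functional-effect filter.

    Truncating and splice-site mutations are always retained; missense
    mutations are excluded only when both benign-prediction conditions hold
    (SIFT > 0.2 and PolyPhen2 < 0.8); synonymous/UTR/intergenic consequences
    never enter the cascade.  Variants failing manual review (quality_flag
    False) are excluded.
    """
    if not variant.quality_flag:
        return False
    cons = variant.consequence
    if cons is None or cons not in _CODING_FOR_CASCADE:
        return False
    if cons in TRUNCATING or cons == "splice-site":
        return True
    # missense: exclusion requires both conditions demonstrably true
    sift_benign = variant.sift_score is not None and variant.sift_score > 0.2
    pp2_benign = variant.polyphen2_score is not None and variant.polyphen2_score < 0.8
    return not (sift_benign and pp2_benign)


@dataclass
class GeneSampleMatrix:
    """Filtered mutation counts per gene x sample, with event flags.

    ``counts`` has one row per gene with at least one non-zero cell or flag;
    the flag frames mark truncating mutations, LOH at the locus, and
    amplification calls merged from copy-number input.
    """

    counts: pd.DataFrame
    truncating: pd.DataFrame
    loh: pd.DataFrame
    amplified: pd.DataFrame
    n_skipped_no_gene: int = 0

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def mutated_samples(self, gene: str) -> list[str]:
        """Samples with >= 1 filtered mutation or an amplification flag."""
        self._require(gene)
        mask = (self.counts.loc[gene] > 0) | self.amplified.loc[gene]
        return list(self.counts.columns[mask])

    def loh_proportion(self, gene: str) -> float:
        """Fraction of mutated samples that also show LOH at the gene."""
        mutated = self.mutated_samples(gene)
        if not mutated:
            raise ValueError(f"gene {gene!r} has no mutated samples")
        return sum(bool(self.loh.loc[gene, s]) for s in mutated) / len(mutated)

    def _require(self, gene: str) -> None:
        if gene not in self.counts.index:
            raise KeyError(f"gene {gene!r} not in matrix")

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: gene, sample, count, truncating, loh, amplified."""
        rows = []
        for g in self.genes:
            for s in self.samples:
                c = int(self.counts.loc[g, s])
                if c or self.amplified.loc[g, s] or self.loh.loc[g, s]:
                    rows.append({
                        "gene": g, "sample": s, "count": c,
                        "truncating": bool(self.truncating.loc[g, s]),
                        "loh": bool(self.loh.loc[g, s]),
                        "amplified": bool(self.amplified.loc[g, s]),
                    })
        return pd.DataFrame(rows, columns=["gene", "sample", "count",
                                           "truncating", "loh", "amplified"])


def build_gene_sample_matrix(
    variants: Iterable[SomaticVariant],
    amplification_calls: Sequence[tuple[str, str]] = (),
    loh_calls: Sequence[tuple[str, str]] = (),
    samples: Sequence[str] | None = None,
    apply_functional_filter: bool = True,
) -> GeneSampleMatrix:
    """Build the gene-by-sample matrix from (optionally pre-filtered) variants.

    ``amplification_calls`` and ``loh_calls`` are (sample, gene) pairs merged
    in as flags; an amplification with no SNV still creates a flagged,
    zero-count cell.  Variants without a gene annotation are skipped and
    counted in ``n_skipped_no_gene``.
    """
    variants = list(variants)
    if apply_functional_filter:
        kept = [v for v in variants if v.gene is not None and functional_filter(v)]
    else:
        kept = [v for v in variants if v.gene is not None]
    n_skipped = sum(1 for v in variants if v.gene is None)

    sample_set = {v.sample for v in kept}
    sample_set.update(s for s, _ in amplification_calls)
    sample_set.update(s for s, _ in loh_calls)
    if samples is not None:
        sample_set.update(samples)
    cols = sorted(sample_set)

    gene_set = {v.gene for v in kept} | {g for _, g in amplification_calls}
    rows = sorted(gene_set)

    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    trunc = pd.DataFrame(False, index=rows, columns=cols)
    amp = pd.DataFrame(False, index=rows, columns=cols)
    loh = pd.DataFrame(False, index=rows, columns=cols)
    for v in kept:
        counts.loc[v.gene, v.sample] += 1
        if v.consequence in TRUNCATING:
            trunc.loc[v.gene, v.sample] = True
        if v.loh_flag:
            loh.loc[v.gene, v.sample] = True
    for s, g in amplification_calls:
        amp.loc[g, s] = True
    for s, g in loh_calls:
        if g in loh.index:
            loh.loc[g, s] = True

    return GeneSampleMatrix(counts=counts, truncating=trunc, loh=loh,
                            amplified=amp, n_skipped_no_gene=n_skipped)


def recurrence_filter(
    matrix: GeneSampleMatrix,
    min_samples: int = 2,
    whitelist: Sequence[str] = (),
) -> GeneSampleMatrix:
    """Drop genes mutated in fewer than ``min_samples`` distinct samples.

    Whitelisted known drivers bypass the threshold.
    """
    keep = [
        g for g in matrix.genes
        if g in whitelist or len(matrix.mutated_samples(g)) >= min_samples
    ]
    return GeneSampleMatrix(
        counts=matrix.counts.loc[keep],
        truncating=matrix.truncating.loc[keep],
        loh=matrix.loh.loc[keep],
        amplified=matrix.amplified.loc[keep],
        n_skipped_no_gene=matrix.n_skipped_no_gene,
    )


def cooccurrence(
    matrix: GeneSampleMatrix, gene_a: str, gene_b: str
) -> tuple[int, int, int, int]:
    """2x2 sample table for two genes: (both, A-only, B-only, neither).

    Mutual exclusivity corresponds to ``both == 0``.
    """
    a = set(matrix.mutated_samples(gene_a))
    b = set(matrix.mutated_samples(gene_b))
    universe = set(matrix.samples)
    return (
        len(a & b),
        len(a - b),
        len(b - a),
        len(universe - a - b),
    )


# ---------------------------------------------------------------------------
# Published driver-mutation table fixture
# ---------------------------------------------------------------------------

def load_driver_table(path: str | None = None) -> pd.DataFrame:
    """Load a driver-mutation table (tumour, chrom, pos, gene, detail, loh).

    With no path, the packaged discovery-set table of filtered driver
    mutations (48 mutations in 14 genes across 15 tumours) is loaded.
    ``loh`` is 1/0/NA as published.
    """
    if path is None:
        src = resources.files("somascape.data").joinpath("driver_mutations.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", dtype={"tumour": str, "chrom": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"tumour": str, "chrom": str})
    required = {"tumour", "chrom", "pos", "gene", "detail", "loh"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"driver table missing columns: {sorted(missing)}")
    return df


def load_cdkn1a_replication(path: str | None = None) -> pd.DataFrame:
    """Load the CDKN1A replication-set mutant list (tumour, gene, loh).

    The packaged default is a synthetic stand-in: the published counts (four
    additional mutant tumours, one with LOH) with placeholder sample ids.
    """
    if path is None:
        src = resources.files("somascape.data").joinpath(
            "cdkn1a_replication_synthetic.tsv")
        with resources.as_file(src) as p:
            return pd.read_csv(p, sep="\t", comment="#", dtype={"tumour": str})
    return pd.read_csv(path, sep="\t", comment="#", dtype={"tumour": str})


def gene_loh_proportion(
    gene: str, *tables: pd.DataFrame
) -> float:
    """LOH proportion for a gene across one or more mutant-sample tables.

    Each table needs columns tumour, gene, loh; rows for other genes are
    ignored.  The tables are merged into a gene-by-sample matrix and the
    proportion of mutated samples with LOH at the gene is returned.
    """
    frames = []
    for t in tables:
        sub = t.loc[t["gene"] == gene, ["tumour", "gene", "loh"]].copy()
        if "chrom" not in t.columns:
            sub["chrom"] = "0"
            sub["pos"] = 0
            sub["detail"] = "unspecified"
        else:
            sub["chrom"] = t.loc[sub.index, "chrom"]
            sub["pos"] = t.loc[sub.index, "pos"]
            sub["detail"] = t.loc[sub.index, "detail"]
        frames.append(sub)
    combined = pd.concat(frames, ignore_index=True)
    matrix = matrix_from_driver_table(combined)
    return matrix.loh_proportion(gene)


def matrix_from_driver_table(
    table: pd.DataFrame,
    amplification_calls: Sequence[tuple[str, str]] = (),
    samples: Sequence[str] | None = None,
) -> GeneSampleMatrix:
    """Gene-by-sample matrix from an already-filtered driver-mutation table."""
    trunc_markers = ("fs", "X", "del", "ins")
    variants = []
    loh_calls = []
    for r in table.itertuples(index=False):
        detail = str(r.detail)
        consequence = (
            "frameshift" if any(m in detail.split(":")[-1] for m in trunc_markers)
            else "missense"
        )
        variants.append(SomaticVariant(
            sample=str(r.tumour), chrom=str(r.chrom), pos=int(r.pos),
            ref="N", alt="A",  # alleles not carried by the published table
            gene=str(r.gene), consequence=consequence,
            loh_flag=bool(int(r.loh)) if not pd.isna(r.loh) else None,
        ))
        if not pd.isna(r.loh) and int(r.loh) == 1:
            loh_calls.append((str(r.tumour), str(r.gene)))
    return build_gene_sample_matrix(
        variants, amplification_calls=amplification_calls, loh_calls=loh_calls,
        samples=samples, apply_functional_filter=False,
    )
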