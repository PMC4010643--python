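"""Six-class, strand-collapsed somatic substitution spectra.

Every base substitution is reported relative to the pyrimidine of the mutated
base pair, giving six classes: C:G>T:A, C:G>A:T, C:G>G:C, T:A>C:G, T:A>A:T
and T:A>G:C.  A G>A change is the same event as C>T read from the other
strand, so both collapse to C:G>T:A.

Spectra are compared descriptively by cosine similarity of the proportion
vectors and inferentially by a chi-square goodness-of-fit of the observed
class counts against expected counts under a reference proportion vector,
merging any expected cell below 5 into its nearest neighbouring class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .variants import SomaticVariant

__all__ = [
    "SIX_CLASSES",
    "SpectrumProfile",
    "classify_substitution",
    "compute_spectrum",
    "compare_spectra",
    "subset_spectrum",
]

SIX_CLASSES: tuple[str, ...] = (
    "C:G>T:A", "C:G>A:T", "C:G>G:C", "T:A>C:G", "T:A>A:T", "T:A>G:C",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# pyrimidine-reference (ref, alt) -> class
_CLASS_OF = {
    ("C", "T"): "C:G>T:A",
    ("C", "A"): "C:G>A:T",
    ("C", "G"): "C:G>G:C",
    ("T", "C"): "T:A>C:G",
    ("T", "A"): "T:A>A:T",
    ("T", "G"): "T:A>G:C",
}


def classify_substitution(ref: str, alt: str) -> str:
    """Strand-collapsed class of a single-base substitution.

    Purine-reference substitutions are mapped to their pyrimidine-reference
    equivalent (reverse complement), so exactly six classes are possible.
    """
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT:
        raise ValueError(f"non-ACGT alleles: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r})")
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return _CLASS_OF[(ref, alt)]


@dataclass
class SpectrumProfile:
    """Counts and proportions of SNVs over the six substitution classes."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in SIX_CLASSES}
    )
    n_skipped_non_snv: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def is_empty(self) -> bool:
        """True when proportions are undefined (no SNVs)."""
        return self.total == 0

    @property
    def count_vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in SIX_CLASSES], dtype=float)

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total
        if t == 0:
            return {c: float("nan") for c in SIX_CLASSES}
        return {c: self.counts[c] / t for c in SIX_CLASSES}

    @property
    def proportion_vector(self) -> np.ndarray:
        return np.array([self.proportions[c] for c in SIX_CLASSES])

    def __add__(self, other: "SpectrumProfile") -> "SpectrumProfile":
        return SpectrumProfile(
            counts={c: self.counts[c] + other.counts[c] for c in SIX_CLASSES},
            n_skipped_non_snv=self.n_skipped_non_snv + other.n_skipped_non_snv,
        )


def compute_spectrum(variants: Iterable[SomaticVariant]) -> SpectrumProfile:
    """Six-class spectrum of the SNVs in ``variants``.

    Indels are skipped; the skip count is carried on the profile.
    """
    prof = SpectrumProfile()
    for v in variants:
        if not v.is_snv:
            prof.n_skipped_non_snv += 1
            continue
        prof.counts[classify_substitution(v.ref, v.alt)] += 1
    return prof


def subset_spectrum(
    variants: Iterable[SomaticVariant],
    region_set: Sequence[tuple[str, int, int]],
) -> SpectrumProfile:
    """Spectrum of the variants overlapping a region set (1-based inclusive).

    Enables e.g. exome-vs-genome spectrum comparison with a BED-derived
    interval list.  An empty region set yields an empty profile.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in region_set:
        by_chrom.setdefault(chrom, []).append((start, end))
    selected = [
        v for v in variants
        if any(s <= v.pos <= e for s, e in by_chrom.get(v.chrom, ()))
    ]
    return compute_spectrum(selected)


def _merge_small_expected(
    observed: np.ndarray, expected: np.ndarray, min_expected: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Merge any expected cell < min_expected into its nearest neighbour."""
    obs = list(observed.astype(float))
    exp = list(expected.astype(float))
    while len(exp) > 1 and min(exp) < min_expected:
        i = int(np.argmin(exp))
        # nearest neighbour by index; prefer the smaller-expected side on ties
        if i == 0:
            j = 1
        elif i == len(exp) - 1:
            j = i - 1
        else:
            j = i - 1 if exp[i - 1] <= exp[i + 1] else i + 1
        obs[j] += obs[i]
        exp[j] += exp[i]
        del obs[i], exp[i]
    return np.array(obs), np.array(exp)


def compare_spectra(
    p: SpectrumProfile, q: Sequence[float]
) -> tuple[float, int, float, float]:
    """Compare an observed spectrum against reference proportions ``q``.

    Returns ``(chi_square, df, p_value, cosine_similarity)``.  The chi-square
    is a goodness-of-fit of the observed class counts against ``total * q``,
    with expected cells below 5 merged into their nearest neighbour (df =
    cells_after_merging - 1).  Cosine similarity is computed on the proportion
    vectors and lies in [0, 1].
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (len(SIX_CLASSES),):
        raise ValueError(f"reference must have {len(SIX_CLASSES)} classes")
    if abs(q.sum() - 1.0) > 1e-9:
        raise ValueError(f"reference proportions sum to {q.sum()}, not 1")
    if p.is_empty:
        raise ValueError("observed profile has no SNVs")

    observed = p.count_vector
    expected = p.total * q
    obs_m, exp_m = _merge_small_expected(observed, expected)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs_m - exp_m) ** 2 / exp_m
    terms = terms[exp_m > 0]
    chi2 = float(terms.sum())
    df = len(exp_m) - 1
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else float("nan")

    pv = p.proportion_vector
    denom = np.linalg.norm(pv) * np.linalg.norm(q)
    cosine = float(pv @ q / denom) if denom > 0 else float("nan")
    return chi2, df, p_value, cosine
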