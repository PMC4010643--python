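import numpy as np
import pytest

from somascape.drivers import (
    build_gene_sample_matrix,
    cooccurrence,
    functional_filter,
    gene_loh_proportion,
    load_cdkn1a_replication,
    load_driver_table,
    matrix_from_driver_table,
    recurrence_filter,
)
from somascape.variants import SomaticVariant


def mk(sample="T1", gene="G1", consequence="missense", sift=None, pp2=None,
       pos=1, quality=True, loh=None):
    return SomaticVariant(sample=sample, chrom="1", pos=pos, ref="C", alt="T",
                          depth=50, alt_reads=25, gene=gene,
                          consequence=consequence, sift_score=sift,
                          polyphen2_score=pp2, quality_flag=quality,
                          loh_flag=loh)


class TestFunctionalFilter:
    @pytest.mark.parametrize("sift,pp2,kept", [
        (0.05, 0.87, True),    # severe on both predictors
        (0.11, 0.553, True),   # only one benign condition met
        (0.5, 0.5, False),     # benign on both: excluded
        (0.00, 0.997, True),   # strongly deleterious
    ])
    def test_published_missense_score_cases(self, sift, pp2, kept):
        assert functional_filter(mk(sift=sift, pp2=pp2)) is kept

    @pytest.mark.parametrize("consequence", ["stop-gain", "stop-loss",
                                             "frameshift", "splice-site"])
    def test_truncating_and_splice_always_retained(self, consequence):
        assert functional_filter(mk(consequence=consequence))
        # even with benign-looking scores
        assert functional_filter(mk(consequence=consequence, sift=0.9, pp2=0.1))

    def test_missing_scores_cannot_satisfy_exclusion(self):
        assert functional_filter(mk(sift=None, pp2=None))
        assert functional_filter(mk(sift=0.5, pp2=None))
        assert functional_filter(mk(sift=None, pp2=0.5))
        assert not functional_filter(mk(sift=0.21, pp2=0.79))

    @pytest.mark.parametrize("consequence", ["synonymous", "UTR", "intergenic"])
    def test_noncoding_never_enters_cascade(self, consequence):
        assert not functional_filter(mk(consequence=consequence))

    def test_quality_flag_honoured(self):
        assert not functional_filter(mk(consequence="stop-gain", quality=False))

    def test_brute_force_oracle_equivalence(self, rng):
        """Direct predicate scan reproduces the cascade's retained set."""
        consequences = ["missense", "stop-gain", "stop-loss", "frameshift",
                        "splice-site", "synonymous", "UTR", "intergenic"]
        variants = []
        for i in range(200):
            sift = None if rng.random() < 0.3 else float(np.round(rng.random(), 3))
            pp2 = None if rng.random() < 0.3 else float(np.round(rng.random(), 3))
            variants.append(mk(pos=i + 1,
                               consequence=consequences[rng.integers(8)],
                               sift=sift, pp2=pp2))
        cascade = [v for v in variants if functional_filter(v)]
        truncating = {"stop-gain", "stop-loss", "frameshift"}
        oracle = []
        for v in variants:
            if v.consequence in truncating or v.consequence == "splice-site":
                oracle.append(v)
            elif v.consequence == "missense":
                benign_both = (v.sift_score is not None and v.sift_score > 0.2
                               and v.polyphen2_score is not None
                               and v.polyphen2_score < 0.8)
                if not benign_both:
                    oracle.append(v)
        assert cascade == oracle


class TestGeneSampleMatrix:
    def test_two_variants_one_cell(self):
        m = build_gene_sample_matrix([mk(pos=1, sift=0.01, pp2=0.99),
                                      mk(pos=2, sift=0.01, pp2=0.99)])
        assert m.counts.loc["G1", "T1"] == 2

    def test_amplification_only_cell(self):
        m = build_gene_sample_matrix([], amplification_calls=[("T1", "MDM2")])
        assert m.counts.loc["MDM2", "T1"] == 0
        assert bool(m.amplified.loc["MDM2", "T1"])
        assert m.mutated_samples("MDM2") == ["T1"]

    def test_no_gene_variants_skipped_with_log(self):
        m = build_gene_sample_matrix([mk(gene=None)])
        assert m.n_skipped_no_gene == 1

    def test_published_table_shape(self):
        t = load_driver_table()
        assert len(t) == 48
        m = matrix_from_driver_table(t)
        assert len(m.genes) == 14

    def test_input_order_invariance(self, rng):
        vs = [mk(sample=f"T{rng.integers(5)}", gene=f"G{rng.integers(6)}",
                 pos=i + 1, sift=0.01, pp2=0.99) for i in range(60)]
        m1 = build_gene_sample_matrix(vs)
        shuffled = list(vs)
        rng.shuffle(shuffled)
        m2 = build_gene_sample_matrix(shuffled)
        assert m1.counts.equals(m2.counts)


class TestRecurrenceFilter:
    def test_fgfr3_pattern_retained(self):
        m = matrix_from_driver_table(load_driver_table())
        filtered = recurrence_filter(m, min_samples=2)
        assert "FGFR3" in filtered.genes
        assert set(m.mutated_samples("FGFR3")) == \
            {"4070", "4121", "615", "4078", "3010", "4101"}

    def test_single_sample_gene_removed_unless_whitelisted(self):
        m = matrix_from_driver_table(load_driver_table())
        assert m.mutated_samples("CDKN2A") == ["2010"]
        assert "CDKN2A" not in recurrence_filter(m, 2).genes
        assert "CDKN2A" in recurrence_filter(m, 2, whitelist=["CDKN2A"]).genes

    def test_empty_matrix_passthrough(self):
        m = build_gene_sample_matrix([])
        assert recurrence_filter(m).genes == []

    def test_threshold_monotonicity(self):
        m = matrix_from_driver_table(load_driver_table())
        previous = set(m.genes)
        for k in range(1, 8):
            current = set(recurrence_filter(m, k).genes)
            assert current <= previous
            previous = current


class TestCooccurrence:
    def test_disjoint_and_identical_sets(self):
        vs = ([mk(sample=s, gene="A", pos=1, sift=0.01, pp2=0.99) for s in "12"]
              + [mk(sample=s, gene="B", pos=2, sift=0.01, pp2=0.99) for s in "34"])
        m = build_gene_sample_matrix(vs)
        assert cooccurrence(m, "A", "B") == (0, 2, 2, 0)
        vs2 = [mk(sample=s, gene=g, pos=i, sift=0.01, pp2=0.99)
               for i, (s, g) in enumerate([("1", "A"), ("1", "B"),
                                           ("2", "A"), ("2", "B")], 1)]
        m2 = build_gene_sample_matrix(vs2)
        assert cooccurrence(m2, "A", "B") == (2, 0, 0, 0)

    def test_unknown_gene_raises(self):
        m = build_gene_sample_matrix([mk()])
        with pytest.raises(KeyError):
            cooccurrence(m, "G1", "NOPE")

    def test_cdkn1a_tp53_mutually_exclusive_in_discovery_set(self):
        m = matrix_from_driver_table(load_driver_table())
        n_both, a_only, b_only, neither = cooccurrence(m, "CDKN1A", "TP53")
        assert n_both == 0
        assert a_only == 2 and b_only == 3  # 3034,745 vs 3010,2010,799


class TestCdkn1aLohWorkedExample:
    def test_six_mutants_two_with_loh(self):
        discovery = load_driver_table()
        replication = load_cdkn1a_replication()
        prop = gene_loh_proportion("CDKN1A", discovery, replication)
        assert prop == pytest.approx(2 / 6)
        assert round(100 * prop) == 33
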