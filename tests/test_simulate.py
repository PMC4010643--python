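import numpy as np
import pytest

from somascape.cna import chromothripsis_scan, count_arm_transitions
from somascape.simulate import (
    AmpliconSpec,
    ChromothripsisSpec,
    CohortConfig,
    generate_cohort,
    inject_chromothripsis,
    iter_samples,
    load_cohort_config,
)


def small_config(**kw):
    defaults = dict(seed=7, n_samples={"pTa": 1, "pT1": 1, "pT2": 1},
                    mean_snv={"pTa": 200.0, "pT1": 500.0, "pT2": 600.0},
                    germline_het_rate=1e-6)
    defaults.update(kw)
    return CohortConfig(**defaults)


class TestConfigValidation:
    def test_spectrum_must_sum_to_one(self, genome):
        cfg = small_config(spectrum={c: 0.1 for c in
                                     ["C:G>T:A", "C:G>A:T", "C:G>G:C",
                                      "T:A>C:G", "T:A>A:T", "T:A>G:C"]})
        with pytest.raises(ValueError, match="sum"):
            generate_cohort(cfg, genome)

    def test_prevalence_and_purity_bounds(self, genome):
        with pytest.raises(ValueError, match="prevalence"):
            generate_cohort(small_config(
                subclone_prevalences={"pTa": (1.2,), "pT1": (1.0,),
                                      "pT2": (1.0,)}), genome)
        with pytest.raises(ValueError, match="purity"):
            generate_cohort(small_config(
                purity={"pTa": 0.0, "pT1": 0.8, "pT2": 0.8}), genome)

    def test_unknown_amplicon_anchor(self, genome):
        cfg = small_config(amplicon=AmpliconSpec(anchor_gene="NOPE"))
        with pytest.raises(ValueError, match="anchor"):
            generate_cohort(cfg, genome)


class TestDeterminism:
    def test_same_seed_identical_output(self, genome):
        a = generate_cohort(small_config(), genome)
        b = generate_cohort(small_config(), genome)
        for sa, sb in zip(a, b):
            assert sa.variants == sb.variants
            assert sa.segments == sb.segments
            assert sa.truth.equals(sb.truth)

    def test_different_seed_differs(self, genome):
        a = generate_cohort(small_config(seed=7), genome)
        b = generate_cohort(small_config(seed=8), genome)
        assert a[0].variants != b[0].variants


class TestExpectedAlleleFractions:
    def test_pure_monoclonal_diploid_gives_half(self, genome):
        cfg = small_config(
            n_samples={"pTa": 1},
            purity={"pTa": 1.0},
            subclone_prevalences={"pTa": (1.0,)},
            event_rates={"gain": 0, "loss": 0, "loh": 0, "homozygous_deletion": 0},
            amplicon=None, chromothripsis=(),
        )
        sample = generate_cohort(cfg, genome)[0]
        assert (sample.truth["expected_vaf"] == 0.5).all()

    def test_truth_carries_subclone_labels(self, genome):
        cfg = small_config(subclone_prevalences={"pTa": (1.0, 0.3),
                                                 "pT1": (1.0,), "pT2": (1.0,)})
        sample = generate_cohort(cfg, genome)[0]
        assert set(sample.truth["subclone"]) <= {0, 1}
        assert set(sample.truth.loc[sample.truth.subclone == 1,
                                    "prevalence"]) == {0.3}


class TestSegmentTiling:
    def test_every_chromosome_tiled_exactly_once(self, default_cohort, genome):
        for sample in default_cohort[:4]:
            by_chrom = {}
            for s in sample.segments:
                by_chrom.setdefault(s.chrom, []).append(s)
            for chrom, length in genome.chromosomes:
                segs = sorted(by_chrom[chrom], key=lambda s: s.start)
                assert segs[0].start == 1
                assert segs[-1].end == length
                assert all(a.end + 1 == b.start for a, b in zip(segs, segs[1:]))


class TestBurden:
    def test_group_means_within_three_poisson_sd(self, genome):
        cfg = CohortConfig(seed=42, n_samples={"pTa": 4, "pT1": 5, "pT2": 5},
                           mean_snv={"pTa": 35_000.0, "pT1": 115_000.0,
                                     "pT2": 115_000.0})
        counts = {"pTa": [], "inv": []}
        for s in iter_samples(cfg, genome, counts_only=True):
            counts["pTa" if s.stage == "pTa" else "inv"].append(s.n_snv)
        for group, mean in (("pTa", 35_000), ("inv", 115_000)):
            n = len(counts[group])
            sd_of_mean = np.sqrt(mean / n)
            assert abs(np.mean(counts[group]) - mean) < 3 * sd_of_mean

    def test_indel_count_proportional_to_snv_count(self, genome):
        cfg = small_config(indel_ratio=0.22)
        for s in iter_samples(cfg, genome, counts_only=True):
            assert s.n_indel == round(0.22 * s.n_snv)

    def test_stage_monotone_group_medians(self, genome):
        successes = 0
        for seed in range(20):
            cfg = CohortConfig(seed=seed, germline_het_rate=0.0)
            med = {}
            for stage in ("pTa", "pT1", "pT2"):
                med[stage] = []
            for s in iter_samples(cfg, genome, counts_only=True):
                med[s.stage].append(s.n_snv)
            m = [np.median(med[st]) for st in ("pTa", "pT1", "pT2")]
            if m[0] < m[1] < m[2]:
                successes += 1
        assert successes >= 19


class TestInjectChromothripsis:
    def _diploid(self, tiny_genome):
        from somascape.cna import CopyNumberSegment

        return [CopyNumberSegment("T1", c, 1, L, 2, 1)
                for c, L in tiny_genome.chromosomes]

    def test_zero_transitions_unchanged(self, tiny_genome):
        segs = self._diploid(tiny_genome)
        assert inject_chromothripsis(segs, ("1", "p"), 0, tiny_genome) == segs

    @pytest.mark.parametrize("n", [1, 5, 9, 10, 17])
    def test_exact_transition_count(self, tiny_genome, n):
        segs = inject_chromothripsis(self._diploid(tiny_genome), ("1", "p"),
                                     n, tiny_genome)
        arm = [s for s in segs if s.chrom == "1" and s.end <= 400]
        assert count_arm_transitions(arm) == n
        # rest of genome untouched
        rest = [s for s in segs if s.chrom == "2"]
        assert len(rest) == 1 and rest[0].state == (2, False)

    def test_downstream_caller_threshold(self, tiny_genome):
        for n, flagged in ((9, False), (10, True)):
            segs = inject_chromothripsis(self._diploid(tiny_genome), ("1", "p"),
                                         n, tiny_genome)
            scan = chromothripsis_scan(segs, tiny_genome)
            rec = next(r for r in scan if r["chrom"] == "1" and r["arm"] == "p")
            assert rec["flagged"] is flagged

    def test_arm_too_short(self, tiny_genome):
        with pytest.raises(ValueError, match="too short"):
            inject_chromothripsis(self._diploid(tiny_genome), ("1", "p"),
                                  500, tiny_genome)

    def test_random_breakpoints_deterministic_given_rng(self, tiny_genome):
        a = inject_chromothripsis(self._diploid(tiny_genome), ("1", "q"), 12,
                                  tiny_genome, np.random.default_rng(3))
        b = inject_chromothripsis(self._diploid(tiny_genome), ("1", "q"), 12,
                                  tiny_genome, np.random.default_rng(3))
        assert a == b
        arm = [s for s in a if s.chrom == "1" and s.start >= 401]
        assert count_arm_transitions(arm) == 12


class TestConfigFile:
    def test_yaml_round_trip_and_seed_mandatory(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("seed: 9\nindel_ratio: 0.3\n")
        cfg = load_cohort_config(str(p))
        assert cfg.seed == 9 and cfg.indel_ratio == 0.3
        p2 = tmp_path / "noseed.yaml"
        p2.write_text("indel_ratio: 0.3\n")
        with pytest.raises(ValueError, match="seed"):
            load_cohort_config(str(p2))
        p3 = tmp_path / "unknown.yaml"
        p3.write_text("seed: 1\nbogus_key: 2\n")
        with pytest.raises(ValueError, match="unknown"):
            load_cohort_config(str(p3))
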