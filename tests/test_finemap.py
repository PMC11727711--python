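"""Ancestry painting, breakpoints, blocks, concordance and the screen."""

import numpy as np
import pandas as pd
import pytest

from plumagemap import cross_sim, finemap, popgen, variant_io
from plumagemap.finemap import (
    STATE_HET,
    STATE_HOM_P1,
    STATE_HOM_P2,
    STATE_UNKNOWN,
    CandidateRegion,
)

from conftest import make_region_cohort

REGION = CandidateRegion("chr33", 400_000, 800_000)


def region_inputs(cohort):
    pops = dict(zip(cohort.metadata["sample_id"], cohort.metadata["breed"]))
    div = popgen.divergence_table(cohort.dataset, pops, "LC", "PK")
    info = finemap.informative_snps(div, REGION, 0.8)
    return pops, div, info


class TestInformativeSnps:
    def test_planted_fixed_snp_included_and_weak_excluded(self):
        div = pd.DataFrame(
            {
                "chrom": ["chr33"] * 3,
                "pos": [450_000, 500_000, 900_000],
                "p1": [1.0, 0.7, 1.0],
                "delta_af": [1.0, 0.5, 1.0],
            }
        )
        info = finemap.informative_snps(div, REGION, 0.8)
        assert info["pos"].tolist() == [450_000]

    def test_engineered_count_returned_exactly(self):
        pos = np.linspace(410_000, 790_000, 36).astype(int)
        div = pd.DataFrame(
            {"chrom": "chr33", "pos": pos, "p1": 1.0, "delta_af": 0.95}
        )
        assert len(finemap.informative_snps(div, REGION, 0.8)) == 36

    def test_empty_result_warns(self):
        div = pd.DataFrame({"chrom": ["chr33"], "pos": [450_000], "p1": [0.5], "delta_af": [0.1]})
        with pytest.warns(UserWarning):
            finemap.informative_snps(div, REGION, 0.8)


class TestInferAncestry:
    def test_f1_all_het_and_founders_homozygous(self, region_cohort):
        pops, div, info = region_inputs(region_cohort)
        pos, states = finemap.infer_ancestry(region_cohort.dataset, info)
        meta = region_cohort.metadata
        f1 = (meta["generation"] == "F1").to_numpy()
        lc = (meta["breed"] == "LC").to_numpy()
        pk = (meta["breed"] == "PK").to_numpy()
        assert (states[f1] == STATE_HET).all()
        assert (states[lc] == STATE_HOM_P1).all()
        assert (states[pk] == STATE_HOM_P2).all()

    def test_single_crossover_paths_switch_once(self, region_cohort):
        pops, div, info = region_inputs(region_cohort)
        pos, states = finemap.infer_ancestry(region_cohort.dataset, info)
        meta = region_cohort.metadata
        f2 = (meta["generation"] == "F2").to_numpy()
        ids = meta.loc[f2, "sample_id"].to_numpy()
        checked = 0
        for i, sid in zip(np.flatnonzero(f2), ids):
            xo = np.concatenate(
                [region_cohort.truth["crossovers"][sid][p]["chr33"] for p in ("maternal", "paternal")]
            )
            in_span = xo[(xo > pos[0]) & (xo < pos[-1])]
            if len(in_span) == 1:
                assert len(finemap.find_breakpoints(pos, states[i])) == 1
                checked += 1
        assert checked > 0

    def test_missing_genotypes_become_unknown(self):
        ds = variant_io.VariantDataset(
            pd.DataFrame(
                {"chrom": ["chr33"], "pos": [450_000], "id": ["x"], "ref": ["A"], "alt": ["G"], "vtype": ["SNP"]}
            ),
            np.array([[variant_io.MISSING]], dtype=np.int8),
            ["s0"],
        )
        info = pd.DataFrame({"chrom": ["chr33"], "pos": [450_000], "p1": [1.0], "delta_af": [1.0]})
        _, states = finemap.infer_ancestry(ds, info)
        assert states[0, 0] == STATE_UNKNOWN

    def test_no_informative_snps_rejected(self, region_cohort):
        with pytest.raises(ValueError):
            finemap.infer_ancestry(region_cohort.dataset, pd.DataFrame(columns=["chrom", "pos", "p1"]))


class TestFindBreakpoints:
    def test_uniform_path_has_none(self):
        pos = np.array([10, 20, 30])
        assert finemap.find_breakpoints(pos, np.array([1, 1, 1])) == []

    def test_single_change_reports_flanking_interval(self):
        pos = np.array([10, 20, 30, 40])
        states = np.array([STATE_HOM_P1, STATE_HOM_P1, STATE_HET, STATE_HET])
        assert finemap.find_breakpoints(pos, states) == [(20, 30)]

    def test_unknown_states_skipped_with_carryover(self):
        pos = np.array([10, 20, 30, 40])
        states = np.array([STATE_HOM_P1, STATE_UNKNOWN, STATE_UNKNOWN, STATE_HET])
        assert finemap.find_breakpoints(pos, states) == [(10, 40)]

    def test_detected_intervals_contain_true_crossovers(self, region_cohort):
        # Noise-free painting: every detected interval brackets a real event.
        pops, div, info = region_inputs(region_cohort)
        pos, states = finemap.infer_ancestry(region_cohort.dataset, info)
        meta = region_cohort.metadata
        f2 = (meta["generation"] == "F2").to_numpy()
        ids = meta.loc[f2, "sample_id"].to_numpy()
        total = contained = 0
        for i, sid in zip(np.flatnonzero(f2), ids):
            xo = np.concatenate(
                [region_cohort.truth["crossovers"][sid][p]["chr33"] for p in ("maternal", "paternal")]
            )
            for lo, hi in finemap.find_breakpoints(pos, states[i]):
                total += 1
                contained += bool(np.any((xo > lo) & (xo < hi)))
        assert total > 0
        assert contained == total


class TestPartitionBlocks:
    def test_four_cuts_make_five_blocks(self):
        pos = np.arange(10, 110, 10)  # 10 SNPs
        cuts = [[(20, 30)], [(40, 50)], [(60, 70)], [(80, 90)]]
        blocks = finemap.partition_blocks(cuts, pos, CandidateRegion("c", 1, 200))
        assert len(blocks) == 5

    def test_no_breakpoints_single_block(self):
        pos = np.arange(10, 60, 10)
        blocks = finemap.partition_blocks([[]], pos, CandidateRegion("c", 1, 100))
        assert len(blocks) == 1
        assert blocks[0].start == 10 and blocks[0].end == 50

    def test_duplicate_cuts_counted_once(self):
        pos = np.arange(10, 60, 10)
        cuts = [[(20, 30)], [(20, 30)], [(20, 30)]]
        blocks = finemap.partition_blocks(cuts, pos, CandidateRegion("c", 1, 100))
        assert len(blocks) == 2


class TestBlockConcordance:
    def test_causal_block_scores_one(self, region_cohort):
        pops, div, info = region_inputs(region_cohort)
        meta = region_cohort.metadata
        f2 = (meta["generation"] == "F2").to_numpy()
        idx = np.flatnonzero(f2)
        sub = variant_io.VariantDataset(
            region_cohort.dataset.variants,
            region_cohort.dataset.genotypes[idx],
            [region_cohort.samples[i] for i in idx],
        )
        pos, states = finemap.infer_ancestry(sub, info)
        bps = [finemap.find_breakpoints(pos, states[i]) for i in range(states.shape[0])]
        blocks = finemap.partition_blocks(bps, pos, REGION)
        bstates = finemap.block_states(blocks, states)
        scores = finemap.block_concordance(bstates, meta.loc[f2, "phenotype"].to_numpy())
        causal = [i for i, b in enumerate(blocks) if b.start <= 600_001 <= b.end]
        assert len(causal) == 1
        assert scores[causal[0]] == 1.0
        # a block separated from the causal one by recombinants scores < 1
        assert scores.min() < 1.0

    def test_f1_only_cohort_degenerate_all_perfect(self):
        bstates = np.full((10, 3), STATE_HET, dtype=np.int8)
        scores = finemap.block_concordance(bstates, ["GF"] * 10)
        assert (scores == 1.0).all()

    def test_no_black_beaked_individuals_rejected(self):
        with pytest.raises(ValueError):
            finemap.block_concordance(np.zeros((2, 1), dtype=np.int8), ["WY", "WY"])


class TestLdR2:
    def test_identical_vectors(self):
        g = np.array([0, 1, 2, 1, 0])
        assert finemap.ld_r2(g, g) == pytest.approx(1.0)

    def test_complement_vectors(self):
        g = np.array([0, 1, 2, 1, 0])
        assert finemap.ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 1000)
        b = rng.integers(0, 3, 1000)
        assert finemap.ld_r2(a, b) < 0.02

    def test_monomorphic_undefined(self):
        assert np.isnan(finemap.ld_r2(np.ones(5), np.array([0, 1, 2, 1, 0])))


class TestCausativeScreen:
    REGION = CandidateRegion("chr33", 5_240_000, 5_320_000)

    def run(self, **kw):
        ds, meta, truth = cross_sim.simulate_screen_panel(seed=3, **kw)
        pops = dict(zip(meta["sample_id"], meta["breed"]))
        return finemap.causative_screen(ds, pops, self.REGION), truth

    def test_recovers_exactly_the_planted_pair(self):
        report, truth = self.run()
        assert sorted(report.final_ids) == sorted(truth["causal_ids"])

    def test_complete_ld_pair_reported_as_one_group(self):
        report, truth = self.run()
        assert len(report.ld_groups) == 1
        assert sorted(report.ld_groups[0]) == sorted(truth["causal_ids"])

    def test_planted_indels_excluded_not_candidates(self):
        report, truth = self.run()
        v = report.variants
        assert sorted(v.loc[v["indel_excluded"], "id"]) == sorted(truth["indel_ids"])
        assert not set(truth["indel_ids"]) & set(report.final_ids)

    def test_step_nesting_invariant(self):
        report, _ = self.run()
        v = report.variants
        assert (v["step3"] <= v["step2"]).all()
        assert (v["step2"] <= v["step1"]).all()
        assert not (v["step1"] & v["indel_excluded"]).any()

    def test_single_causal_no_twin(self):
        report, truth = self.run(include_ld_twin=False)
        assert report.final_ids == truth["causal_ids"]
        assert len(truth["causal_ids"]) == 1

    def test_screen_deterministic(self):
        r1, _ = self.run()
        r2, _ = self.run()
        assert r1.variants.equals(r2.variants)
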