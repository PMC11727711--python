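"""Simulator correctness: founder sampling, meiosis, cross structure, truth."""

import numpy as np
import pytest

from plumagemap import cross_sim, finemap, mendel, popgen, variant_io
from plumagemap.cross_sim import CrossConfig, GenomeLayout

from conftest import make_region_cohort


def tiny_layout(recomb_rate=1.0, n_snps=5):
    return GenomeLayout(
        chromosomes=(("chr13", 10_000_000), ("chr33", 10_000_000)),
        snp_positions={
            "chr13": np.linspace(1_000_000, 9_000_000, n_snps).astype(int),
            "chr33": np.linspace(1_000_000, 9_000_000, n_snps).astype(int),
        },
        recomb_rate=recomb_rate,
    )


def tiny_config(seed=0, recomb_rate=1.0, **kw):
    layout = tiny_layout(recomb_rate)
    panel = cross_sim.default_panel(
        layout, seed=seed + 1,
        causal_B=("chr13", 5_000_000), causal_R=("chr33", 5_000_000),
    )
    defaults = dict(n_per_founder=(10, 10), n_f1=20, n_f2=50)
    defaults.update(kw)
    return CrossConfig(layout=layout, founders=panel, seed=seed, **defaults)


class TestLayoutValidation:
    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            GenomeLayout((("c", 100),), {"c": np.array([5, 3])})

    def test_out_of_bounds_positions_rejected(self):
        with pytest.raises(ValueError):
            GenomeLayout((("c", 100),), {"c": np.array([50, 200])})

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            GenomeLayout((("c", 100),), {"c": np.array([5])}, recomb_rate=-1)


class TestFounders:
    def test_causal_loci_fixed_per_breed(self):
        cfg = tiny_config(seed=3)
        coh = cross_sim.simulate_founders(cfg)
        g = coh.dataset.genotypes
        b_idx = coh.truth["causal_B"]["index"]
        r_idx = coh.truth["causal_R"]["index"]
        lc = coh.metadata["breed"] == "LC"
        pk = coh.metadata["breed"] == "PK"
        assert (g[lc.to_numpy(), b_idx] == 2).all()  # BB
        assert (g[lc.to_numpy(), r_idx] == 0).all()  # rr
        assert (g[pk.to_numpy(), b_idx] == 0).all()  # bb
        assert (g[pk.to_numpy(), r_idx] == 2).all()  # RR

    def test_zero_frequency_means_no_alt_alleles(self):
        layout = tiny_layout()
        freqs = {
            b: {c: np.zeros(len(p)) for c, p in layout.snp_positions.items()}
            for b in ("LC", "PK")
        }
        freqs["LC"]["chr13"][2] = 1.0
        freqs["PK"]["chr33"][2] = 1.0
        panel = cross_sim.FounderPanel(("LC", "PK"), freqs, ("chr13", 5_000_000), ("chr33", 5_000_000))
        cfg = CrossConfig(layout=layout, founders=panel, n_per_founder=(8, 8), n_f1=0, n_f2=0, seed=1)
        coh = cross_sim.simulate_founders(cfg)
        neutral = [j for j in range(coh.dataset.n_variants)
                   if j not in (coh.truth["causal_B"]["index"], coh.truth["causal_R"]["index"])]
        assert (coh.dataset.genotypes[:, neutral] == 0).all()

    def test_binomial_sampling_mean(self):
        # freq 0.5, 50 founders per breed: mean genotype within 3 binomial SDs of 1.
        layout = tiny_layout()
        freqs = {
            b: {c: np.full(len(p), 0.5) for c, p in layout.snp_positions.items()}
            for b in ("LC", "PK")
        }
        freqs["LC"]["chr13"][2] = 1.0
        freqs["PK"]["chr13"][2] = 0.0
        freqs["LC"]["chr33"][2] = 0.0
        freqs["PK"]["chr33"][2] = 1.0
        panel = cross_sim.FounderPanel(("LC", "PK"), freqs, ("chr13", 5_000_000), ("chr33", 5_000_000))
        cfg = CrossConfig(layout=layout, founders=panel, n_per_founder=(50, 50), n_f1=0, n_f2=0, seed=5)
        coh = cross_sim.simulate_founders(cfg)
        j = 0  # a neutral SNP
        mean = coh.dataset.genotypes[:, j].mean()
        sd = np.sqrt(2 * 0.5 * 0.5 / 100)
        assert abs(mean - 1.0) <= 3 * sd

    def test_invalid_frequency_rejected(self):
        layout = tiny_layout()
        freqs = {
            b: {c: np.full(len(p), 1.5) for c, p in layout.snp_positions.items()}
            for b in ("LC", "PK")
        }
        with pytest.raises(ValueError):
            cross_sim.FounderPanel(("LC", "PK"), freqs, ("chr13", 5_000_000), ("chr33", 5_000_000))

    def test_causal_loci_on_same_chromosome_rejected(self):
        layout = tiny_layout()
        freqs = {
            b: {c: np.full(len(p), 0.5) for c, p in layout.snp_positions.items()}
            for b in ("LC", "PK")
        }
        with pytest.raises(ValueError):
            cross_sim.FounderPanel(("LC", "PK"), freqs, ("chr13", 1_000_000), ("chr13", 5_000_000))


class TestMakeGamete:
    def test_zero_rate_returns_a_parental_haplotype(self):
        rng = np.random.default_rng(0)
        layout = tiny_layout(recomb_rate=0.0)
        haps = (rng.random((2, layout.n_snps)) < 0.5).astype(np.int8)
        for _ in range(5):
            gamete, xo = cross_sim.make_gamete(haps, layout, rng)
            for chrom, sl in layout.chrom_slices().items():
                seg = gamete[sl]
                assert (seg == haps[0, sl]).all() or (seg == haps[1, sl]).all()
                assert len(xo[chrom]) == 0

    def test_single_snp_chromosome(self):
        layout = GenomeLayout((("c", 1000),), {"c": np.array([500])}, recomb_rate=5.0)
        rng = np.random.default_rng(1)
        haps = np.array([[0], [1]], dtype=np.int8)
        alleles = {int(cross_sim.make_gamete(haps, layout, rng)[0][0]) for _ in range(20)}
        assert alleles <= {0, 1}

    def test_poisson_crossover_mean(self):
        # 1 cM/Mb over 100 Mb = 1 Morgan: mean crossover count ~ 1.
        layout = GenomeLayout(
            (("c", 100_000_000),), {"c": np.array([50_000_000])}, recomb_rate=1.0
        )
        rng = np.random.default_rng(2)
        haps = np.zeros((2, 1), dtype=np.int8)
        counts = [len(cross_sim.make_gamete(haps, layout, rng)[1]["c"]) for _ in range(10_000)]
        se = 1.0 / np.sqrt(10_000)
        assert abs(np.mean(counts) - 1.0) <= 3 * se


class TestBreedCross:
    def test_f1_all_gray_and_double_het(self):
        coh = cross_sim.breed_cross(tiny_config(seed=4))
        f1 = coh.metadata["generation"] == "F1"
        assert (coh.metadata.loc[f1, "phenotype"] == "GF").all()
        for sid in coh.metadata.loc[f1, "sample_id"]:
            assert coh.truth["causal_diplotypes"][sid] == (1, 1)

    def test_no_f2_requested(self):
        coh = cross_sim.breed_cross(tiny_config(seed=4, n_f2=0))
        assert set(coh.metadata["generation"]) == {"F0", "F1"}

    def test_f2_without_f1_rejected(self):
        with pytest.raises(ValueError):
            cross_sim.breed_cross(tiny_config(seed=4, n_f1=0, n_f2=10))

    def test_determinism(self):
        a = cross_sim.breed_cross(tiny_config(seed=9))
        b = cross_sim.breed_cross(tiny_config(seed=9))
        assert np.array_equal(a.dataset.genotypes, b.dataset.genotypes)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert a.metadata.equals(b.metadata)

    def test_phenotype_matches_truth_diplotype(self):
        model = mendel.SegregationModel()
        coh = cross_sim.breed_cross(tiny_config(seed=10))
        for _, row in coh.metadata[coh.metadata["generation"] == "F2"].iterrows():
            nb, nr = coh.truth["causal_diplotypes"][row["sample_id"]]
            assert row["phenotype"] == model.phenotype(nb, nr)

    def test_mendelian_conservation_at_fixed_differences(self):
        # Noise-free informative SNPs: every F2 haplotype allele must equal
        # one of the two founder-breed fixed alleles (0 or 1 by breed).
        coh = make_region_cohort(seed=21, n_f2=40)
        assert set(np.unique(coh.haplotypes)) <= {0, 1}

    def test_zero_recombination_yields_intact_founder_chromosomes(self):
        layout = cross_sim.GenomeLayout(
            chromosomes=(("chr13", 2_000_000), ("chr33", 1_000_000)),
            snp_positions={
                "chr13": np.array([1_000_000]),
                "chr33": np.linspace(400_000, 800_000, 30).astype(int),
            },
            recomb_rate=0.0,
        )
        panel = cross_sim.default_panel(
            layout, seed=1, aim_fraction=1.0, aim_freqs=(0.0, 1.0),
            causal_B=("chr13", 1_000_000), causal_R=("chr33", 400_000),
        )
        cfg = CrossConfig(layout=layout, founders=panel, n_per_founder=(10, 10),
                          n_f1=10, n_f2=60, seed=2)
        coh = cross_sim.breed_cross(cfg)
        pops = dict(zip(coh.metadata["sample_id"], coh.metadata["breed"]))
        div = popgen.divergence_table(coh.dataset, pops, "LC", "PK")
        region = finemap.CandidateRegion("chr33", 400_000, 800_000)
        info = finemap.informative_snps(div, region, 0.8)
        pos, states = finemap.infer_ancestry(coh.dataset, info)
        for i in range(states.shape[0]):
            assert finemap.find_breakpoints(pos, states[i]) == []


class TestDepthSimulation:
    def test_window_validation(self):
        coh = make_region_cohort(seed=30, n_f2=10)
        with pytest.raises(ValueError):
            cross_sim.simulate_depth(coh, [], window_bp=0)
        with pytest.raises(ValueError):
            cross_sim.simulate_depth(coh, [("chrX", 1, 10, {"LC": 0})])

    def test_depth_scales_with_planted_copy_number(self):
        coh = make_region_cohort(seed=31, n_f2=0)
        cnvs = [
            ("chr33", 500_000, 520_000, {"LC": 3.0}),   # het duplication
            ("chr33", 700_000, 720_000, {"LC": 0.0}),   # homozygous loss
        ]
        depth, truth = cross_sim.simulate_depth(
            coh, cnvs, chroms=["chr33"], mean_depth=40, seed=5
        )
        lc = [s for s in coh.samples if s.startswith("LC")]
        dup = depth[(depth.start > 500_000 - 1000) & (depth.end <= 520_000)]
        loss = depth[(depth.start > 700_000 - 1000) & (depth.end <= 720_000)]
        rest = depth[depth.end <= 500_000]
        assert dup[lc].to_numpy().mean() == pytest.approx(60, rel=0.05)
        assert loss[lc].to_numpy().sum() == 0
        assert rest[lc].to_numpy().mean() == pytest.approx(40, rel=0.05)


class TestWriters:
    def test_vcf_metadata_truth_round_trip(self, tmp_path):
        coh = cross_sim.breed_cross(tiny_config(seed=12, n_f2=5, missing_rate=0.1))
        paths = cross_sim.write_cohort(coh, tmp_path)
        back = variant_io.read_vcf(paths["vcf"])
        assert back.samples == coh.samples
        assert np.array_equal(back.genotypes, coh.dataset.genotypes)
        assert (back.variants["pos"].to_numpy() == coh.dataset.variants["pos"].to_numpy()).all()
        assert paths["metadata"].exists() and paths["truth"].exists()
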