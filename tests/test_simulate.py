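import numpy as np
import pandas as pd
import pytest

from autozyg import io, pedigree, simulate
from autozyg.simulate import SimConfig, TraitLocus


def _tiny_genome(**kw):
    defaults = dict(
        n_chromosomes=2, chrom_length_mb=100.0, snps_per_chromosome=150,
        dpr_additive=[], dpr_recessive=[], scs_additive=[], scs_recessive=[],
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestPedigreeSimulation:
    def test_single_sire_makes_half_sibs(self):
        cfg = _tiny_genome(
            seed=1, n_founders=20, n_generations=3, sires_per_generation=1,
            offspring_per_generation=15,
        )
        ped = simulate.simulate_pedigree(cfg, np.random.default_rng(1))
        gen3 = ped[ped.generation == 3]
        assert gen3["sire"].nunique() == 1

    def test_parents_strictly_older(self):
        cfg = _tiny_genome(seed=2, n_founders=30, n_generations=5)
        ped = simulate.simulate_pedigree(cfg, np.random.default_rng(2))
        years = ped.set_index("animal")["birth_year"]
        for row in ped.itertuples(index=False):
            for p in (row.sire, row.dam):
                if p is not None:
                    assert years[p] < row.birth_year

    def test_acyclic_and_fped_computable(self):
        cfg = _tiny_genome(seed=3, n_founders=30, n_generations=4)
        peddf = simulate.simulate_pedigree(cfg, np.random.default_rng(3))
        ped = pedigree.Pedigree.from_frame(peddf[["animal", "sire", "dam", "birth_year"]])
        f = pedigree.compute_fped(ped)
        assert ((f >= 0) & (f < 1)).all()

    def test_random_mating_large_pool_low_inbreeding(self):
        cfg = _tiny_genome(
            seed=4, n_founders=200, n_generations=3, sires_per_generation=40,
            offspring_per_generation=50, relative_mating_propensity=0.0,
        )
        peddf = simulate.simulate_pedigree(cfg, np.random.default_rng(4))
        ped = pedigree.Pedigree.from_frame(peddf[["animal", "sire", "dam", "birth_year"]])
        f = pedigree.compute_fped(ped, peddf[peddf.generation > 0]["animal"])
        assert f.mean() < 0.02

    def test_default_config_reaches_study_f_range(self):
        """Mean FPED in [0.03, 0.10]; distribution spans up past 0.25."""
        cfg = SimConfig(seed=11)
        peddf = simulate.simulate_pedigree(cfg, np.random.default_rng(cfg.seed))
        ped = pedigree.Pedigree.from_frame(peddf[["animal", "sire", "dam", "birth_year"]])
        f = pedigree.compute_fped(ped, peddf[peddf.generation > 0]["animal"]).to_numpy()
        assert 0.03 <= f.mean() <= 0.10
        assert f.min() <= 0.02
        assert f.max() >= 0.25

    def test_infeasible_config_raises(self):
        cfg = _tiny_genome(seed=5, n_founders=1, n_generations=2)
        with pytest.raises(ValueError, match="infeasible|eligible"):
            simulate.simulate_pedigree(cfg, np.random.default_rng(5))


class TestGeneDrop:
    def test_collapse_identity_and_founder_truth(self, small_cohort):
        sim, _ = small_cohort
        hapsum = sim.haplotypes.values[0::2].astype(int) + sim.haplotypes.values[1::2]
        assert np.array_equal(hapsum, sim.genotypes.values)
        founders = ~sim.non_founder_mask()
        assert sim.true_autozygosity[founders].sum() == 0

    def test_autozygous_implies_homozygous(self, small_cohort):
        sim, _ = small_cohort
        auto = sim.true_autozygosity.astype(bool)
        hom = (sim.genotypes.values == 0) | (sim.genotypes.values == 2)
        assert hom[auto].all()

    def test_zero_recombination_parent_offspring_tracts(self):
        """Without crossovers, a parent-offspring mating yields whole-chromosome
        autozygous tracts with probability 1/4 per chromosome."""
        cfg = _tiny_genome(seed=6, cm_per_mb=0.0)
        rows = [("S", None, None, 1990), ("D", None, None, 1990)]
        rows.append(("C", "S", "D", 1991))
        for k in range(400):
            rows.append((f"X{k}", "S", "C", 1992))
        ped = pd.DataFrame(rows, columns=["animal", "sire", "dam", "birth_year"])
        ped["generation"] = [0, 0, 1] + [2] * 400
        sim = simulate.gene_drop(ped, cfg, np.random.default_rng(6))
        mm = sim.genotypes.marker_map
        offspring = [i for i, a in enumerate(sim.ids) if a.startswith("X")]
        fracs = []
        for c in ("1", "2"):
            cols = np.flatnonzero((mm["chrom"] == c).to_numpy())
            A = sim.true_autozygosity[np.ix_(offspring, cols)]
            whole = A.all(axis=1)
            none = ~A.any(axis=1)
            assert (whole | none).all()  # tracts are whole chromosomes
            fracs.append(whole.mean())
        assert np.mean(fracs) == pytest.approx(0.25, abs=0.06)

    def test_haldane_crossover_rate(self):
        """~1 crossover per transmitted 100-Mb chromosome at 1 cM/Mb."""
        rng = np.random.default_rng(8)
        m = 400
        pos_mb = np.linspace(0.25, 99.75, m)
        hapA = np.zeros(m, dtype=np.uint8)
        hapB = np.ones(m, dtype=np.uint8)
        switches = []
        for _ in range(3000):
            gam, _org = simulate._meiosis(
                hapA, hapB, np.zeros(m, np.int32), np.ones(m, np.int32),
                [slice(0, m)], pos_mb, 100.0, 1.0, rng,
            )
            switches.append(int((np.diff(gam.astype(int)) != 0).sum()))
        # observed switches undercount crossovers only via double-crossovers
        # inside one marker interval (negligible at this density)
        assert np.mean(switches) == pytest.approx(1.0, abs=0.07)

    def test_full_sib_offspring_mean_autozygosity(self):
        """Mean true autozygosity of full-sib offspring is 1/4 (within 3 SE)."""
        cfg = _tiny_genome(seed=9)
        rows = []
        n_fam, n_off = 250, 8
        for fam in range(n_fam):
            a, b, c, d = (f"A{fam}", f"B{fam}", f"C{fam}", f"D{fam}")
            rows += [(a, None, None, 0, 1990), (b, None, None, 0, 1990),
                     (c, a, b, 1, 1991), (d, a, b, 1, 1991)]
            rows += [(f"X{fam}_{k}", c, d, 2, 1992) for k in range(n_off)]
        ped = pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation", "birth_year"])
        sim = simulate.gene_drop(ped, cfg, np.random.default_rng(9))
        idx = {a: i for i, a in enumerate(sim.ids)}
        fam_means = np.array([
            np.mean([
                sim.true_autozygosity[idx[f"X{fam}_{k}"]].mean() for k in range(n_off)
            ])
            for fam in range(n_fam)
        ])
        se = fam_means.std(ddof=1) / np.sqrt(n_fam)
        assert abs(fam_means.mean() - 0.25) <= 3 * se

    def test_mean_autozygosity_matches_fped_across_replicates(self):
        """E[true autozygous fraction] over replicate drops equals pedigree F."""
        parents = {
            "A": (None, None), "B": (None, None), "C": ("A", "B"),
            "D": ("A", "B"), "X": ("C", "D"), "Y": ("X", "C"),
        }
        ped = pd.DataFrame(
            [(a, s, d, 0 if s is None else 1, 1990) for a, (s, d) in parents.items()],
            columns=["animal", "sire", "dam", "generation", "birth_year"],
        )
        pobj = pedigree.Pedigree(parents)
        cfg = _tiny_genome(seed=10, n_chromosomes=1, snps_per_chromosome=60)
        rng = np.random.default_rng(10)
        mm = simulate.default_marker_map(cfg, rng)
        reps = 400
        vals = {"X": [], "Y": []}
        for _ in range(reps):
            sim = simulate.gene_drop(ped, cfg, rng, marker_map=mm)
            idx = {a: i for i, a in enumerate(sim.ids)}
            for a in vals:
                vals[a].append(sim.true_autozygosity[idx[a]].mean())
        for a, lst in vals.items():
            arr = np.array(lst)
            se = arr.std(ddof=1) / np.sqrt(reps)
            assert abs(arr.mean() - pedigree.inbreeding(pobj, a)) <= 3 * se + 1e-9

    def test_missingness_injection_feeds_qc(self):
        cfg = _tiny_genome(seed=12, n_founders=30, n_generations=2,
                           offspring_per_generation=20, missing_rate=0.05)
        sim, _traits = simulate.simulate_cohort(cfg)
        assert (sim.genotypes.values == io.MISSING).mean() == pytest.approx(0.05, abs=0.01)
        out, report = io.apply_qc(sim.genotypes)
        assert out.n_snps > 0

    def test_deterministic_under_seed(self):
        cfg = _tiny_genome(seed=13, n_founders=20, n_generations=2,
                           offspring_per_generation=10)
        s1, t1 = simulate.simulate_cohort(cfg)
        s2, t2 = simulate.simulate_cohort(cfg)
        assert np.array_equal(s1.haplotypes.values, s2.haplotypes.values)
        assert t1.equals(t2)


class TestTraits:
    def test_zero_effects_noise_variance(self):
        cfg = _tiny_genome(seed=14, n_founders=60, n_generations=3,
                           offspring_per_generation=200, dpr_residual_sd=1.0)
        sim, traits = simulate.simulate_cohort(cfg)
        assert traits["dpr_pta"].var() == pytest.approx(1.0, rel=0.15)

    def test_single_recessive_locus_no_noise_two_values(self):
        cfg = _tiny_genome(
            seed=15, n_founders=20, n_generations=4, offspring_per_generation=40,
            relative_mating_propensity=0.6,
            dpr_recessive=[TraitLocus("1", 50_000_000, -0.4)],
            dpr_residual_sd=0.0, scs_residual_sd=0.0,
        )
        sim, traits = simulate.simulate_cohort(cfg)
        vals = set(np.round(traits["dpr_pta"], 9))
        assert vals <= {0.0, -0.4}
        assert len(vals) == 2  # both autozygous and non-autozygous animals exist

    def test_birth_years_follow_generations(self, small_cohort):
        sim, traits = small_cohort
        gen = sim.pedigree.set_index("animal")["generation"]
        for row in traits.itertuples(index=False):
            assert row.birth_year == sim.config.base_year + gen[row.animal]

    def test_off_map_trait_locus_rejected(self):
        cfg = _tiny_genome(seed=16, dpr_recessive=[TraitLocus("9", 1_000, -0.1)])
        with pytest.raises(ValueError, match="not on the map"):
            simulate.simulate_cohort(cfg)
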