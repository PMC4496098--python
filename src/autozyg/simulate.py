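"""Pedigree, gene-drop and trait simulation with tracked true autozygosity.

The generator emulates an intensively selected dairy-cattle cohort: a
multi-generation pedigree in which a handful of AI sires father most
offspring per generation, with a configurable propensity to mate relatives,
which drives pedigree inbreeding into the study-like range (a handful of
animals above 0.25, cohort mean near 0.06).  Founder haplotypes are drawn
per SNP from a shared allele-frequency spectrum (MAF uniform on
[0.05, 0.5]), so chance homozygosity exists even without inbreeding.
Transmission follows Mendelian segregation with Haldane (no-interference)
crossovers at 1 cM = 1 Mb.  Every founder haplotype carries a unique
origin label that propagates through meioses; a locus is truly autozygous
when both inherited labels coincide, giving an exact identity-by-descent
truth for validating ROH calls and inbreeding estimators.

Traits are PTA-like: a sum of additive locus effects (x allele dosage),
recessive locus effects (x true autozygosity at the locus) and Gaussian
noise.  The fertility-like trait (DPR) uses negative recessive effects,
the udder-health-like trait (SCS) positive ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix
from .hapwin import HaplotypeMatrix
from .pedigree import Pedigree


@dataclass
class TraitLocus:
    """One planted effect locus: chromosome label, bp position, effect size."""

    chrom: str
    pos_bp: int
    effect: float


@dataclass
class SimConfig:
    """Simulation parameters; defaults give the desk-scale study-like cohort."""

    # pedigree
    n_founders: int = 80
    n_generations: int = 10
    sires_per_generation: int = 6
    offspring_per_generation: int = 60
    relative_mating_propensity: float = 0.3
    selection_proportion: float = 1.0  # 1.0 = no truncation selection on the trait
    base_year: int = 1990
    # genome: 10 x 100 Mb at 15 SNPs/Mb ~ the real chip's ~68 kb spacing
    n_chromosomes: int = 10
    chrom_length_mb: float = 100.0
    snps_per_chromosome: int = 1500
    maf_min: float = 0.05
    maf_max: float = 0.5
    cm_per_mb: float = 1.0  # Haldane map, 1 cM = 1 Mb
    # traits; None = defaults placed on the configured genome in __post_init__
    dpr_additive: Optional[list] = None
    dpr_recessive: Optional[list] = None
    scs_additive: Optional[list] = None
    scs_recessive: Optional[list] = None
    dpr_residual_sd: float = 0.3
    scs_residual_sd: float = 0.05
    # data quality
    missing_rate: float = 0.0  # optional missingness injection into genotypes
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_founders", "n_generations", "sires_per_generation",
                     "offspring_per_generation", "n_chromosomes", "snps_per_chromosome"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.selection_proportion <= 1):
            raise ValueError("selection_proportion must be in (0, 1]")
        if not (0 <= self.relative_mating_propensity <= 1):
            raise ValueError("relative_mating_propensity must be in [0, 1]")
        # default planted loci, wrapped onto the configured chromosomes;
        # DPR-like effects negative (inbreeding depression), SCS-like positive
        L = self.chrom_length_mb * 1e6

        def chrom(c):
            return str((c - 1) % self.n_chromosomes + 1)

        if self.dpr_additive is None:
            self.dpr_additive = [TraitLocus(chrom(7), int(0.44 * L), -0.15)]
        if self.dpr_recessive is None:
            self.dpr_recessive = [TraitLocus(chrom(3), int(0.40 * L), -0.4)]
        if self.scs_additive is None:
            self.scs_additive = [TraitLocus(chrom(1), int(0.52 * L), 0.03)]
        if self.scs_recessive is None:
            self.scs_recessive = [TraitLocus(chrom(4), int(0.08 * L), 0.07)]


@dataclass
class SimOutput:
    """Everything a downstream stage needs, plus the IBD ground truth."""

    config: SimConfig
    pedigree: pd.DataFrame  # animal, sire, dam, birth_year, generation, sex
    haplotypes: HaplotypeMatrix
    origins: np.ndarray  # 2N x M founder-allele labels
    genotypes: GenotypeMatrix
    true_autozygosity: np.ndarray  # N x M, 1 iff both labels identical

    @property
    def ids(self) -> list[str]:
        return self.haplotypes.ids

    def non_founder_mask(self) -> np.ndarray:
        gen = self.pedigree.set_index("animal")["generation"]
        return np.array([gen[a] > 0 for a in self.ids])


def default_marker_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Evenly spaced SNPs with sub-spacing jitter; strictly increasing positions."""
    rows = []
    length_bp = cfg.chrom_length_mb * 1e6
    spacing = length_bp / (cfg.snps_per_chromosome + 1)
    for c in range(1, cfg.n_chromosomes + 1):
        base = spacing * (np.arange(1, cfg.snps_per_chromosome + 1))
        jitter = rng.uniform(-0.4, 0.4, cfg.snps_per_chromosome) * spacing
        pos = np.round(base + jitter).astype(np.int64)
        pos = np.maximum(pos, 1)
        for j, p in enumerate(pos):
            rows.append((str(c), int(p), f"snp_{c}_{j + 1}"))
    mm = pd.DataFrame(rows, columns=["chrom", "pos", "snp_id"])
    return mm


def simulate_pedigree(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Sire-limited, overlapping-loop pedigree as a DataFrame.

    Each generation, a few sires drawn from the previous generation's males
    father all offspring; dams come from recent females.  With probability
    ``relative_mating_propensity`` a dam is chosen as the candidate most kin
    to the sire (close-line breeding), otherwise uniformly at random.
    Parents are strictly older than offspring, so the graph is acyclic by
    construction.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_f = cfg.n_founders
    animals = [f"F{i + 1}" for i in range(n_f)]
    sex = {a: ("M" if i < n_f // 2 else "F") for i, a in enumerate(animals)}
    records = {a: (None, None) for a in animals}
    generation = {a: 0 for a in animals}
    years = {a: cfg.base_year for a in animals}

    ped = Pedigree(records)  # incremental kinship queries against a live pedigree
    counter = 0
    for g in range(1, cfg.n_generations + 1):
        prev_males = [a for a in animals if sex[a] == "M" and generation[a] == g - 1]
        if len(prev_males) < cfg.sires_per_generation:
            prev_males = [a for a in animals if sex[a] == "M" and generation[a] < g]
        if not prev_males:
            raise ValueError("infeasible config: no eligible sires")
        sires = list(
            rng.choice(prev_males, size=min(cfg.sires_per_generation, len(prev_males)),
                       replace=False)
        )
        dams_pool = [
            a for a in animals if sex[a] == "F" and g - 3 <= generation[a] <= g - 1
        ]
        if not dams_pool:
            raise ValueError("infeasible config: no eligible dams")
        for _ in range(cfg.offspring_per_generation):
            sire = sires[rng.integers(len(sires))]
            if rng.random() < cfg.relative_mating_propensity:
                # close-line breeding: dam sampled proportional to kinship with the sire
                kin = np.array([ped._kinship(sire, d) for d in dams_pool])
                if kin.sum() > 0:
                    dam = dams_pool[rng.choice(len(dams_pool), p=kin / kin.sum())]
                else:
                    dam = dams_pool[rng.integers(len(dams_pool))]
            else:
                dam = dams_pool[rng.integers(len(dams_pool))]
            counter += 1
            child = f"G{g}_{counter}"
            animals.append(child)
            records[child] = (sire, dam)
            ped.parents[child] = (sire, dam)
            ped._depth[child] = max(ped._depth[sire], ped._depth[dam]) + 1
            sex[child] = "M" if rng.random() < 0.5 else "F"
            generation[child] = g
            years[child] = cfg.base_year + g

    return pd.DataFrame(
        {
            "animal": animals,
            "sire": [records[a][0] for a in animals],
            "dam": [records[a][1] for a in animals],
            "birth_year": [years[a] for a in animals],
            "generation": [generation[a] for a in animals],
            "sex": [sex[a] for a in animals],
        }
    )


def _meiosis(
    hapA: np.ndarray,
    hapB: np.ndarray,
    origA: np.ndarray,
    origB: np.ndarray,
    chrom_slices: list[slice],
    pos_mb: np.ndarray,
    chrom_length_mb: float,
    cm_per_mb: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: Haldane crossovers per chromosome, random start phase."""
    gam = np.empty_like(hapA)
    gor = np.empty_like(origA)
    morgans = chrom_length_mb * cm_per_mb / 100.0
    for sl in chrom_slices:
        n_cross = rng.poisson(morgans)
        start = rng.integers(2)
        p = pos_mb[sl]
        if n_cross == 0:
            src = np.full(p.shape, start, dtype=np.int8)
        else:
            xpos = np.sort(rng.uniform(0.0, chrom_length_mb, n_cross))
            src = (start + np.searchsorted(xpos, p)) % 2
        take_a = src == 0
        gam[sl] = np.where(take_a, hapA[sl], hapB[sl])
        gor[sl] = np.where(take_a, origA[sl], origB[sl])
    return gam, gor


def gene_drop(
    ped: pd.DataFrame,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    marker_map: Optional[pd.DataFrame] = None,
) -> SimOutput:
    """Drop labeled founder haplotypes down a pedigree with recombination.

    Founders receive two uniquely labeled haplotypes drawn per SNP from the
    configured frequency spectrum; every transmission recombines the
    parental pair under the Haldane model.  True autozygosity is 1 where
    the two inherited origin labels match (always 0 in founders).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if marker_map is None:
        marker_map = default_marker_map(cfg, rng)
    m = len(marker_map)
    chroms = marker_map["chrom"].to_numpy()
    pos_mb = marker_map["pos"].to_numpy() / 1e6
    block_starts = [0] + (np.flatnonzero(chroms[1:] != chroms[:-1]) + 1).tolist()
    chrom_slices = [
        slice(s, e) for s, e in zip(block_starts, block_starts[1:] + [m])
    ]

    # allele-1 frequency with MAF ~ U[maf_min, maf_max]
    q = rng.uniform(cfg.maf_min, cfg.maf_max, m)
    flip = rng.random(m) < 0.5
    q = np.where(flip, 1.0 - q, q)

    order = ped.sort_values("generation", kind="stable")
    ids = order["animal"].tolist()
    row_of = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    hap = np.empty((2 * n, m), dtype=np.uint8)
    orig = np.empty((2 * n, m), dtype=np.int32)

    label = 0
    for rec in order.itertuples(index=False):
        i = row_of[rec.animal]
        for k, parent in enumerate((rec.sire, rec.dam)):
            if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                hap[2 * i + k] = rng.random(m) < q
                orig[2 * i + k] = label
                label += 1
            else:
                pi = row_of[parent]
                hap[2 * i + k], orig[2 * i + k] = _meiosis(
                    hap[2 * pi], hap[2 * pi + 1], orig[2 * pi], orig[2 * pi + 1],
                    chrom_slices, pos_mb, cfg.chrom_length_mb, cfg.cm_per_mb, rng,
                )

    auto = (orig[0::2] == orig[1::2]).astype(np.uint8)
    codes = (hap[0::2].astype(np.int8) + hap[1::2]).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(codes.shape) < cfg.missing_rate
        codes[mask] = MISSING

    hap_mat = HaplotypeMatrix(hap, ids, marker_map)
    geno = GenotypeMatrix(codes, ids, marker_map.copy())
    ped_out = order.reset_index(drop=True)
    return SimOutput(
        config=cfg,
        pedigree=ped_out,
        haplotypes=hap_mat,
        origins=orig,
        genotypes=geno,
        true_autozygosity=auto,
    )


def _locus_index(marker_map: pd.DataFrame, locus: TraitLocus) -> int:
    """Index of the SNP nearest the planted locus on its chromosome."""
    on = marker_map.index[marker_map["chrom"] == locus.chrom]
    if len(on) == 0:
        raise ValueError(f"trait locus chromosome {locus.chrom} not on the map")
    pos = marker_map.loc[on, "pos"].to_numpy()
    return int(on[np.argmin(np.abs(pos - locus.pos_bp))])


def simulate_traits(
    sim: SimOutput, cfg: Optional[SimConfig] = None, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """PTA-like DPR and SCS values with planted additive/recessive effects.

    trait = sum(additive effect x allele dosage)
          + sum(recessive effect x true autozygosity at the locus)
          + Gaussian noise.
    Birth years follow the pedigree's generations.
    """
    if cfg is None:
        cfg = sim.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    mm = sim.genotypes.marker_map
    dosage = sim.haplotypes.values[0::2].astype(float) + sim.haplotypes.values[1::2]
    n = len(sim.ids)

    def build(additive, recessive, sd):
        y = np.zeros(n)
        for locus in additive:
            y += locus.effect * dosage[:, _locus_index(mm, locus)]
        for locus in recessive:
            y += locus.effect * sim.true_autozygosity[:, _locus_index(mm, locus)]
        return y + rng.normal(0.0, sd, n)

    dpr = build(cfg.dpr_additive, cfg.dpr_recessive, cfg.dpr_residual_sd)
    scs = build(cfg.scs_additive, cfg.scs_recessive, cfg.scs_residual_sd)
    years = sim.pedigree.set_index("animal")["birth_year"]
    return pd.DataFrame(
        {
            "animal": sim.ids,
            "dpr_pta": dpr,
            "scs_pta": scs,
            "birth_year": [int(years[a]) for a in sim.ids],
        }
    )


def simulate_cohort(cfg: Optional[SimConfig] = None) -> tuple[SimOutput, pd.DataFrame]:
    """Pedigree + gene drop + traits under one seed; the standard entry point."""
    if cfg is None:
        cfg = SimConfig()
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    sim = gene_drop(ped, cfg, rng)
    traits = simulate_traits(sim, cfg, rng)
    return sim, traits
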