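"""Genotype, map, pedigree and trait I/O plus marker/individual quality control.

Genotypes are held as an individuals x SNPs matrix of small integers:
0 and 2 are the two homozygotes (0 counts zero copies of the non-reference
allele), 1 is the heterozygote, and :data:`MISSING` (-1) marks a missing
call.  The reference allele of each SNP is the first allele observed while
reading the PED file.  Marker coordinates are 1-based inclusive base pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

MISSING: int = -1
"""Sentinel genotype code for a missing call (never 0)."""

_VALID_ALLELES = frozenset("ACGT")


def _chrom_sort_key(chrom: str):
    """Numeric-aware chromosome ordering ('2' before '10')."""
    try:
        return (0, int(chrom))
    except ValueError:
        return (1, chrom)


def validate_marker_map(marker_map: pd.DataFrame) -> None:
    """Check map invariants: columns, strictly increasing positions, unique ids.

    Parameters
    ----------
    marker_map : DataFrame with columns ``chrom`` (str), ``pos`` (int, 1-based)
        and ``snp_id`` (str), ordered by (chromosome, position).
    """
    required = {"chrom", "pos", "snp_id"}
    missing_cols = required - set(marker_map.columns)
    if missing_cols:
        raise ValueError(f"marker map lacks columns: {sorted(missing_cols)}")
    if marker_map["snp_id"].duplicated().any():
        dup = marker_map["snp_id"][marker_map["snp_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate snp_id in map: {dup!r}")
    if (marker_map["pos"] < 1).any():
        raise ValueError("map positions must be >= 1 (1-based base pairs)")
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        d = np.diff(grp["pos"].to_numpy())
        if (d <= 0).any():
            raise ValueError(f"positions not strictly increasing on chromosome {chrom}")


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs genotype codes tied to a marker map.

    Attributes
    ----------
    values : int8 ndarray, shape (n_individuals, n_snps)
        Codes in {0, 1, 2, MISSING}.
    ids : list of individual identifiers (row order).
    marker_map : DataFrame aligned to columns (chrom, pos, snp_id).
    """

    values: np.ndarray
    ids: list[str]
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D")
        if self.values.shape[0] != len(self.ids):
            raise ValueError("row count does not match number of individual ids")
        if self.values.shape[1] != len(self.marker_map):
            raise ValueError("column count does not match map length")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")
        validate_marker_map(self.marker_map)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def subset(self, ind_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given row/column indices."""
        v = self.values
        ids = self.ids
        mm = self.marker_map
        if ind_idx is not None:
            ind_idx = np.asarray(ind_idx)
            v = v[ind_idx]
            ids = [self.ids[i] for i in ind_idx]
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            v = v[:, snp_idx]
            mm = mm.iloc[snp_idx].reset_index(drop=True)
        return GenotypeMatrix(v.copy(), list(ids), mm.copy())


def read_map(path) -> pd.DataFrame:
    """Read a PLINK text MAP file (chrom, snp_id, cM, pos) sorted by (chrom, pos)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}: line {ln}: expected 4 MAP columns, got {len(parts)}")
            chrom, snp_id, _cm, pos = parts
            rows.append((chrom, snp_id, int(pos)))
    mm = pd.DataFrame(rows, columns=["chrom", "snp_id", "pos"])
    mm = mm.sort_values(
        by=["chrom", "pos"], key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s
    ).reset_index(drop=True)
    mm = mm[["chrom", "pos", "snp_id"]]
    validate_marker_map(mm)
    return mm


def read_ped_map(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into a :class:`GenotypeMatrix`.

    The first allele observed at a SNP (scanning individuals in file order)
    becomes the reference allele (code 0 = homozygous reference); "0 0"
    becomes :data:`MISSING`.  Columns follow the MAP sorted by
    (chromosome, position).

    Raises
    ------
    ValueError
        On a triallelic SNP (named) or a PED row of the wrong length
        (line number reported).
    """
    raw_map = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(
                    f"{map_path}: line {ln}: expected 4 MAP columns, got {len(parts)}"
                )
            raw_map.append((parts[0], parts[1], int(parts[3])))
    m = len(raw_map)

    ids: list[str] = []
    a1_rows: list[np.ndarray] = []
    a2_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} fields "
                    f"for {m} SNPs, got {len(parts)}"
                )
            ids.append(parts[1])
            alleles = np.array(parts[6:], dtype="U1")
            a1_rows.append(alleles[0::2])
            a2_rows.append(alleles[1::2])
    a1 = np.array(a1_rows) if a1_rows else np.empty((0, m), dtype="U1")
    a2 = np.array(a2_rows) if a2_rows else np.empty((0, m), dtype="U1")

    codes = np.full((len(ids), m), MISSING, dtype=np.int8)
    for j in range(m):
        c1, c2 = a1[:, j], a2[:, j]
        called = (c1 != "0") & (c2 != "0")
        observed: list[str] = []
        for allele in np.concatenate([c1[called], c2[called]]):
            if allele not in observed:
                observed.append(allele)
        if any(al not in _VALID_ALLELES for al in observed):
            bad = next(al for al in observed if al not in _VALID_ALLELES)
            raise ValueError(f"SNP {raw_map[j][1]}: invalid allele {bad!r}")
        if len(observed) > 2:
            raise ValueError(
                f"SNP {raw_map[j][1]} is not biallelic: alleles {sorted(observed)}"
            )
        if observed:
            ref = observed[0]
            codes[called, j] = (c1[called] != ref).astype(np.int8) + (
                c2[called] != ref
            ).astype(np.int8)

    mm = pd.DataFrame(raw_map, columns=["chrom", "snp_id", "pos"])
    order = sorted(range(m), key=lambda j: (_chrom_sort_key(mm["chrom"][j]), mm["pos"][j]))
    mm = mm.iloc[order].reset_index(drop=True)[["chrom", "pos", "snp_id"]]
    codes = codes[:, order]
    return GenotypeMatrix(codes, ids, mm)


def write_ped_map(g: GenotypeMatrix, ped_path, map_path, alleles: tuple[str, str] = ("A", "G")) -> None:
    """Write PLINK text PED/MAP; codes 0/2 map to ``alleles[0]``/``alleles[1]``."""
    ref, alt = alleles
    lut = {0: f"{ref} {ref}", 1: f"{ref} {alt}", 2: f"{alt} {alt}", MISSING: "0 0"}
    with open(map_path, "w") as fh:
        for _, row in g.marker_map.iterrows():
            fh.write(f"{row.chrom} {row.snp_id} 0 {row.pos}\n")
    with open(ped_path, "w") as fh:
        for i, ind in enumerate(g.ids):
            geno = " ".join(lut[int(c)] for c in g.values[i])
            fh.write(f"FAM {ind} 0 0 0 -9 {geno}\n")


def read_pedigree(path) -> pd.DataFrame:
    """Read a 4-column pedigree text file (animal, sire, dam, birth_year).

    "0" or blank parent fields mean unknown and become ``None``.
    """
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["animal", "sire", "dam", "birth_year"],
        dtype=str, comment="#",
    )
    for col in ("sire", "dam"):
        df[col] = df[col].where(~df[col].isin(["0", "", "NA"]), None)
    df["birth_year"] = pd.to_numeric(df["birth_year"], errors="coerce").astype("Int64")
    return df


def write_pedigree(ped: pd.DataFrame, path) -> None:
    out = ped.copy()
    for col in ("sire", "dam"):
        out[col] = out[col].fillna("0").replace({None: "0"})
    out.to_csv(path, sep="\t", header=False, index=False)


def read_traits(path) -> pd.DataFrame:
    """Read a headered TSV trait table (animal, dpr_pta, scs_pta, birth_year...)."""
    df = pd.read_csv(path, sep="\t", dtype={"animal": str})
    if "animal" not in df.columns:
        raise ValueError("trait table must have an 'animal' column")
    return df


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hardy-Weinberg tests
# ---------------------------------------------------------------------------

def hwe_exact_test(hom0: int, het: int, hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test on the heterozygote count.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (the Wigginton/Cutler/Abecasis convention, PLINK's default).

    Returns a p-value in (0, 1]; NaN when all genotypes are missing.
    Monomorphic SNPs return 1.0 (no polymorphism, no deviation).
    """
    if hom0 < 0 or het < 0 or hom2 < 0:
        raise ValueError("genotype counts must be non-negative")
    n = hom0 + het + hom2
    if n == 0:
        return float("nan")
    n_a = 2 * hom0 + het            # copies of one allele
    n_b = 2 * hom2 + het
    n_rare = min(n_a, n_b)
    if n_rare == 0:
        return 1.0
    # Heterozygote count has the parity of the rare-allele count.
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    valid = hom_common >= 0
    hets, hom_rare, hom_common = hets[valid], hom_rare[valid], hom_common[valid]
    # log P(het = h | n, n_rare) up to a constant shared across h
    logp = (
        hets * math.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == het][0]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_chi2_test(hom0: int, het: int, hom2: int) -> float:
    """One-df chi-square Hardy-Weinberg test (alternative to the exact test)."""
    n = hom0 + het + hom2
    if n == 0:
        return float("nan")
    p = (2 * hom0 + het) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([hom0, het, hom2], dtype=float)
    chi2 = ((obs - exp) ** 2 / exp).sum()
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Accounting of individuals and SNPs removed by each QC filter."""

    n_ind_in: int
    n_ind_out: int
    n_snps_in: int
    n_snps_out: int
    removed: dict = field(default_factory=dict)  # keys: ind_missingness, snp_callrate, maf, hwe
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ind_removed = self.removed.get("ind_missingness", 0)
        snp_removed = sum(
            self.removed.get(k, 0) for k in ("snp_callrate", "maf", "hwe")
        )
        if self.n_ind_in - ind_removed != self.n_ind_out:
            raise ValueError("individual counts do not reconcile")
        if self.n_snps_in - snp_removed != self.n_snps_out:
            raise ValueError("SNP counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = [("individuals_in", self.n_ind_in), ("individuals_out", self.n_ind_out),
                ("snps_in", self.n_snps_in), ("snps_out", self.n_snps_out)]
        rows += [(f"removed_{k}", v) for k, v in self.removed.items()]
        rows += [(f"threshold_{k}", v) for k, v in self.thresholds.items()]
        return pd.DataFrame(rows, columns=["item", "value"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:
        lines = [
            f"QC: individuals {self.n_ind_in} -> {self.n_ind_out}, "
            f"SNPs {self.n_snps_in} -> {self.n_snps_out}",
        ]
        for k, v in self.removed.items():
            lines.append(f"  removed by {k}: {v}")
        return "\n".join(lines)


def apply_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_neglogp_max: float = 3.0,
    snp_callrate_min: float = 0.8,
    ind_missing_max: float = 0.2,
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply marker/individual QC in a fixed, logged order.

    Order: individuals with missing fraction >= ``ind_missing_max`` first,
    then SNPs failing call rate (<= ``snp_callrate_min``), then minor allele
    frequency (<= ``maf_min``, computed on non-missing calls), then
    Hardy-Weinberg (-log10 p >= ``hwe_neglogp_max``).

    Returns the filtered matrix and a :class:`QCReport`.  Raises if no SNP
    survives.
    """
    if g.n_individuals == 0 or g.n_snps == 0:
        raise ValueError("empty genotype matrix")
    hwe = hwe_exact_test if hwe_method == "exact" else hwe_chi2_test

    miss = g.missing_mask()
    ind_frac = miss.mean(axis=1)
    keep_ind = ind_frac < ind_missing_max
    n_ind_removed = int((~keep_ind).sum())
    v = g.values[keep_ind]
    n = v.shape[0]
    if n == 0:
        raise ValueError("no individuals left after missingness filter")

    miss = v == MISSING
    callrate = 1.0 - miss.mean(axis=0)
    keep_call = callrate > snp_callrate_min
    n_call_removed = int((~keep_call).sum())

    n_called = (~miss).sum(axis=0)
    alt_count = np.where(miss, 0, v).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt_count / (2.0 * n_called), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    keep_maf = keep_call & (maf > maf_min)
    n_maf_removed = int((keep_call & ~(maf > maf_min)).sum())

    keep_hwe = keep_maf.copy()
    n_hwe_removed = 0
    for j in np.flatnonzero(keep_maf):
        col = v[:, j]
        called = col[col != MISSING]
        hom0 = int((called == 0).sum())
        het = int((called == 1).sum())
        hom2 = int((called == 2).sum())
        p = hwe(hom0, het, hom2)
        if np.isnan(p) or -math.log10(max(p, 1e-300)) >= hwe_neglogp_max:
            keep_hwe[j] = False
            n_hwe_removed += 1

    if not keep_hwe.any():
        raise ValueError("empty dataset after QC")

    out = g.subset(np.flatnonzero(keep_ind), np.flatnonzero(keep_hwe))
    report = QCReport(
        n_ind_in=g.n_individuals,
        n_ind_out=out.n_individuals,
        n_snps_in=g.n_snps,
        n_snps_out=out.n_snps,
        removed={
            "ind_missingness": n_ind_removed,
            "snp_callrate": n_call_removed,
            "maf": n_maf_removed,
            "hwe": n_hwe_removed,
        },
        thresholds={
            "maf_min": maf_min,
            "hwe_neglogp_max": hwe_neglogp_max,
            "snp_callrate_min": snp_callrate_min,
            "ind_missing_max": ind_missing_max,
            "hwe_method": hwe_method,
        },
    )
    return out, report
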