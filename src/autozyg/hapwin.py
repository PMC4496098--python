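"""Sliding-window haplotype homozygosity (HH) and haplotype-trait models.

Phased haplotypes come in as a 2N x M binary matrix: rows 2i and 2i+1 are
the two haplotypes of individual i.  Per 50-SNP window, the distinct
haplotype strings are the window's alleles, ranked by descending frequency
(allele 1 = most frequent, ties broken by first genomic occurrence).
Expected homozygosity of an allele is its frequency squared; observed
homozygosity is the fraction of individuals whose two window haplotypes
both equal that allele.  The most-frequent allele's per-individual copy
number (0/1/2) feeds SNP-like additive and recessive trait models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc
from .io import GenotypeMatrix, validate_marker_map


@dataclass
class HaplotypeMatrix:
    """Phased alleles: 2N x M binary, row pairs (2i, 2i+1) = individual i."""

    values: np.ndarray
    ids: list[str]
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2 or self.values.shape[0] != 2 * len(self.ids):
            raise ValueError("haplotype matrix must have two rows per individual")
        if self.values.shape[1] != len(self.marker_map):
            raise ValueError("column count does not match map length")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("phased alleles must be 0/1")
        validate_marker_map(self.marker_map)

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def collapse(self) -> GenotypeMatrix:
        """Unphased genotype codes: sum of the two haplotype rows per individual."""
        codes = (self.values[0::2].astype(np.int8) + self.values[1::2]).astype(np.int8)
        return GenotypeMatrix(codes, list(self.ids), self.marker_map.copy())


def read_haplotypes(path, marker_map: pd.DataFrame) -> HaplotypeMatrix:
    """Read the two-rows-per-individual phased text format.

    Each line: ``individual_id hap_index(1|2) allele allele ...``; the two
    lines of an individual must be adjacent (hap 1 then hap 2).
    """
    ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2 + len(marker_map):
                raise ValueError(
                    f"{path}: line {ln}: expected {2 + len(marker_map)} fields"
                )
            ind, hap = parts[0], parts[1]
            if hap == "1":
                ids.append(ind)
            elif not ids or ind != ids[-1]:
                raise ValueError(f"{path}: line {ln}: haplotype 2 of {ind} not adjacent")
            rows.append(np.array(parts[2:], dtype=np.uint8))
    return HaplotypeMatrix(np.array(rows), ids, marker_map)


def write_haplotypes(hap: HaplotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for i, ind in enumerate(hap.ids):
            for k in (0, 1):
                alleles = " ".join(map(str, hap.values[2 * i + k]))
                fh.write(f"{ind} {k + 1} {alleles}\n")


def from_transposed(values_t: np.ndarray, ids: Sequence[str], marker_map) -> HaplotypeMatrix:
    """Adapter for SNPs x haplotypes layouts (columns paired per individual)."""
    return HaplotypeMatrix(np.asarray(values_t).T, list(ids), marker_map)


WINDOW_COLUMNS = ["window_index", "chrom", "start_index", "end_index", "start_bp", "end_bp"]


def make_windows(
    marker_map: pd.DataFrame, window_snps: int = 50, step_snps: int = 1
) -> pd.DataFrame:
    """Fixed-size SNP windows per chromosome; trailing remainders dropped.

    Indices are global, inclusive column indices into the aligned matrices.
    A chromosome with fewer SNPs than the window yields no windows (warning).
    """
    if window_snps < 1 or step_snps < 1:
        raise ValueError("window_snps and step_snps must be positive")
    chroms = marker_map["chrom"].to_numpy()
    pos = marker_map["pos"].to_numpy()
    block_starts = [0] + (np.flatnonzero(chroms[1:] != chroms[:-1]) + 1).tolist()
    bounds = list(zip(block_starts, block_starts[1:] + [len(chroms)]))
    rows = []
    w = 0
    for lo, hi in bounds:
        n = hi - lo
        if n < window_snps:
            warnings.warn(
                f"chromosome {chroms[lo]} has {n} SNPs < window {window_snps}; "
                "no windows emitted",
                stacklevel=2,
            )
            continue
        for s in range(lo, hi - window_snps + 1, step_snps):
            e = s + window_snps - 1
            rows.append((w, chroms[lo], s, e, int(pos[s]), int(pos[e])))
            w += 1
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


@dataclass
class WindowSummary:
    """Ranked haplotype-allele catalog of one window.

    frequencies : descending allele frequencies (sum to 1).
    expected_hh : frequency**2 per allele.
    observed_hh : fraction of individuals homozygous for the allele.
    dosage : per-individual copy number (0/1/2) of the most frequent allele.
    alleles : (n_alleles, window_snps) allele strings in rank order.
    """

    window_index: int
    chrom: str
    start_index: int
    end_index: int
    start_bp: int
    end_bp: int
    frequencies: np.ndarray
    expected_hh: np.ndarray
    observed_hh: np.ndarray
    dosage: np.ndarray
    alleles: np.ndarray

    @property
    def total_observed_hh(self) -> float:
        """Fraction of individuals whose two window haplotypes are identical."""
        return float(self.observed_hh.sum())

    @property
    def total_expected_hh(self) -> float:
        return float(self.expected_hh.sum())


def expected_homozygosity(frequency) -> np.ndarray | float:
    """Expected haplotype homozygosity of an allele: its frequency squared."""
    return np.square(frequency)


def window_summary(hap: HaplotypeMatrix, window) -> WindowSummary:
    """Allele catalog, frequencies, expected/observed HH and top-allele dosages.

    ``window`` is one row of :func:`make_windows` (attribute access).
    Frequency ties are broken by first genomic occurrence (scanning
    haplotype rows in order).
    """
    s, e = int(window.start_index), int(window.end_index)
    W = hap.values[:, s:e + 1]
    uniq, first_idx, inverse, counts = np.unique(
        W, axis=0, return_index=True, return_inverse=True, return_counts=True
    )
    order = np.lexsort((first_idx, -counts))  # by count desc, then first occurrence
    rank_of = np.empty(len(order), dtype=int)
    rank_of[order] = np.arange(len(order))
    ranked_inverse = rank_of[inverse]

    n_hap = W.shape[0]
    freqs = counts[order] / n_hap
    pair = ranked_inverse.reshape(-1, 2)
    hom = pair[:, 0] == pair[:, 1]
    n_ind = pair.shape[0]
    observed = np.bincount(pair[hom][:, 0], minlength=len(order)) / n_ind
    dosage = (pair == 0).sum(axis=1)

    return WindowSummary(
        window_index=int(window.window_index),
        chrom=str(window.chrom),
        start_index=s,
        end_index=e,
        start_bp=int(window.start_bp),
        end_bp=int(window.end_bp),
        frequencies=freqs,
        expected_hh=np.square(freqs),
        observed_hh=observed.astype(float),
        dosage=dosage.astype(np.int8),
        alleles=uniq[order],
    )


def summarize_windows(hap: HaplotypeMatrix, windows: pd.DataFrame) -> list[WindowSummary]:
    return [window_summary(hap, w) for w in windows.itertuples(index=False)]


def windows_to_frame(summaries: Sequence[WindowSummary], top_k: int = 5) -> pd.DataFrame:
    """Tabular genome summary: top-k frequencies and expected/observed HH."""
    rows = []
    for ws in summaries:
        row = {
            "window_index": ws.window_index,
            "chrom": ws.chrom,
            "start_bp": ws.start_bp,
            "end_bp": ws.end_bp,
            "n_alleles": len(ws.frequencies),
            "total_expected_hh": ws.total_expected_hh,
            "total_observed_hh": ws.total_observed_hh,
        }
        for k in range(top_k):
            row[f"freq{k + 1}"] = ws.frequencies[k] if k < len(ws.frequencies) else 0.0
            row[f"obs_hh{k + 1}"] = ws.observed_hh[k] if k < len(ws.observed_hh) else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def hh_vs_roh_correlation(H: np.ndarray, summaries: Sequence[WindowSummary]) -> float:
    """Pearson r between window mean ROH state and total observed HH, over windows."""
    if len(summaries) < 2:
        return float("nan")
    H = np.asarray(H)
    mean_roh = np.array(
        [H[:, ws.start_index:ws.end_index + 1].mean() for ws in summaries]
    )
    obs_hh = np.array([ws.total_observed_hh for ws in summaries])
    if np.std(mean_roh) == 0 or np.std(obs_hh) == 0:
        return float("nan")
    return float(stats.pearsonr(mean_roh, obs_hh).statistic)


def haplotype_trait_association(
    summaries: Sequence[WindowSummary],
    trait: np.ndarray,
    model: str = "additive",
    covariates: Optional[np.ndarray] = None,
    response_name: str = "trait",
) -> assoc.AssociationProfile:
    """Window-level trait association of the most frequent haplotype allele.

    ``additive`` regresses the trait on the 0/1/2 allele count; ``recessive``
    on the homozygote indicator (count == 2).  Same OLS/t machinery as the
    locus scans; monomorphic windows are flagged NaN.
    """
    if model not in ("additive", "recessive"):
        raise ValueError("model must be 'additive' or 'recessive'")
    trait = np.asarray(trait, dtype=float)
    rows = []
    for ws in summaries:
        g = ws.dosage.astype(float)
        if model == "recessive":
            g = (g == 2).astype(float)
        slope, nlp, n = assoc.locus_regression(trait, g, covariates)
        rows.append(
            {
                "snp_id": f"win{ws.window_index}",
                "chrom": ws.chrom,
                "pos": (ws.start_bp + ws.end_bp) // 2,
                "slope": slope,
                "neglog10_p": nlp,
                "n": n,
            }
        )
    table = pd.DataFrame(rows, columns=assoc.PROFILE_COLUMNS)
    mdl = model if covariates is None else f"{model}+pc"
    return assoc.AssociationProfile(response_name=response_name, model=mdl, table=table)
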