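"""Runs of homozygosity (ROH), the per-locus ROH state matrix H, FROH and F_L.

A run is a maximal stretch of consecutive homozygous SNP calls within one
chromosome of one individual.  Heterozygotes always break a run; missing
calls break it too unless an explicit allowance is configured.  A run
qualifies as a ROH either by SNP count (default: 50 or more consecutive
homozygous SNPs) or by physical span (e.g. 3 or 5 Mb).

From the segment set, H[i, j] = 1 when SNP j of individual i lies inside
any ROH.  Row means of H are the genomic inbreeding coefficient FROH;
column means are the locus-level autozygosity frequency F_L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

SEGMENT_COLUMNS = [
    "individual_id", "chrom", "start_index", "end_index",
    "start_bp", "end_bp", "n_snps", "length_bp",
]


@dataclass
class ROHDefinition:
    """What counts as a ROH.

    mode : "count" (>= min_snps consecutive homozygous SNPs) or
        "length" (homozygous run spanning >= min_bp base pairs).
    max_missing_in_run : missing calls tolerated inside a run (default 0:
        missing breaks the run).  Runs always start and end on homozygous calls.
    Heterozygote allowance is fixed at zero: the rule is literal consecutive
    homozygosity.
    """

    mode: str = "count"
    min_snps: int = 50
    min_bp: Optional[int] = None
    max_missing_in_run: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("count", "length"):
            raise ValueError("mode must be 'count' or 'length'")
        if self.mode == "count" and self.min_snps < 1:
            raise ValueError("min_snps must be positive")
        if self.mode == "length" and (self.min_bp is None or self.min_bp < 1):
            raise ValueError("length mode requires positive min_bp")
        if self.max_missing_in_run < 0:
            raise ValueError("max_missing_in_run must be >= 0")

    def qualifies(self, n_snps: int, length_bp: int) -> bool:
        if self.mode == "count":
            return n_snps >= self.min_snps
        return length_bp >= self.min_bp


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end] (inclusive) runs of True in a 1-D boolean array."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs_with_missing(
    hom: np.ndarray, missing: np.ndarray, max_missing: int
) -> list[tuple[int, int]]:
    """Greedily merge homozygous runs across all-missing gaps of bounded size."""
    runs = _runs_of(hom)
    merged: list[tuple[int, int]] = []
    i = 0
    while i < len(runs):
        s, e = runs[i]
        used = 0
        j = i + 1
        while j < len(runs):
            gs, ge = runs[j - 1][1] + 1, runs[j][0] - 1
            gap = ge - gs + 1
            if gap > 0 and missing[gs:ge + 1].all() and used + gap <= max_missing:
                used += gap
                e = runs[j][1]
                j += 1
            else:
                break
        merged.append((s, e))
        i = j
    return merged


def detect_roh(g: GenotypeMatrix, defn: Optional[ROHDefinition] = None) -> pd.DataFrame:
    """Detect ROH segments for every individual.

    Returns a DataFrame with columns ``individual_id, chrom, start_index,
    end_index, start_bp, end_bp, n_snps, length_bp``; indices are global
    column indices into the genotype matrix, inclusive; coordinates are
    1-based inclusive base pairs.  Runs never cross chromosomes and physical
    gap size never breaks a run (SNP-count logic only).
    """
    if defn is None:
        defn = ROHDefinition()
    v = g.values
    pos = g.marker_map["pos"].to_numpy()
    chroms = g.marker_map["chrom"].to_numpy()
    hom_all = (v == 0) | (v == 2)
    miss_all = v == MISSING

    # contiguous chromosome blocks (map is sorted)
    block_starts = [0] + (np.flatnonzero(chroms[1:] != chroms[:-1]) + 1).tolist()
    block_bounds = list(zip(block_starts, block_starts[1:] + [len(chroms)]))

    rows = []
    for i, ind in enumerate(g.ids):
        for lo, hi in block_bounds:
            hom = hom_all[i, lo:hi]
            if defn.max_missing_in_run == 0:
                runs = _runs_of(hom)
            else:
                runs = _merge_runs_with_missing(
                    hom, miss_all[i, lo:hi], defn.max_missing_in_run
                )
            for s, e in runs:
                gs, ge = lo + s, lo + e
                n_snps = ge - gs + 1
                length_bp = int(pos[ge] - pos[gs])
                if defn.qualifies(n_snps, length_bp):
                    rows.append(
                        (ind, chroms[gs], gs, ge, int(pos[gs]), int(pos[ge]),
                         n_snps, length_bp)
                    )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def roh_state_matrix(segments: pd.DataFrame, g: GenotypeMatrix) -> np.ndarray:
    """Binary H (individuals x SNPs): 1 where a SNP lies inside any ROH."""
    H = np.zeros((g.n_individuals, g.n_snps), dtype=np.uint8)
    row_of = {ind: i for i, ind in enumerate(g.ids)}
    for seg in segments.itertuples(index=False):
        i = row_of.get(seg.individual_id)
        if i is None:
            raise KeyError(f"segment references unknown individual {seg.individual_id!r}")
        H[i, seg.start_index:seg.end_index + 1] = 1
    return H


def froh(H: np.ndarray) -> np.ndarray:
    """Genomic inbreeding per individual: fraction of SNPs inside ROH (row mean)."""
    H = np.asarray(H)
    if H.ndim != 2 or H.shape[1] == 0:
        raise ValueError("H must be 2-D with at least one SNP")
    return H.mean(axis=1)


def froh_bp(segments: pd.DataFrame, g: GenotypeMatrix) -> np.ndarray:
    """Length-based genomic inbreeding: summed ROH bp over the mapped genome span.

    The denominator is the sum over chromosomes of (last − first) marker
    position.  Provided for comparisons across Mb-based ROH definitions;
    the SNP-count-based :func:`froh` is the default statistic.
    """
    pos = g.marker_map["pos"].to_numpy()
    chroms = g.marker_map["chrom"].to_numpy()
    starts = [0] + (np.flatnonzero(chroms[1:] != chroms[:-1]) + 1).tolist()
    bounds = list(zip(starts, starts[1:] + [len(chroms)]))
    genome_bp = float(sum(pos[hi - 1] - pos[lo] for lo, hi in bounds))
    if genome_bp <= 0:
        raise ValueError("degenerate map: zero genome span")
    total = pd.Series(0.0, index=g.ids)
    if len(segments):
        per_ind = segments.groupby("individual_id")["length_bp"].sum()
        total.loc[per_ind.index] = per_ind.astype(float)
    return (total / genome_bp).to_numpy()


def locus_autozygosity(H: np.ndarray) -> np.ndarray:
    """F_L per SNP: fraction of individuals whose ROH covers the locus (column mean)."""
    return np.asarray(H).mean(axis=0)


def expected_segment_length_mb(generations: int) -> float:
    """Expected autozygous-segment length (Mb) from a common ancestor g generations back.

    The expected length is 100 / (2 g) cM; with the 1 cM = 1 Mb map used
    throughout, that is 100 / (2 g) Mb (5 Mb at g = 10).
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    return 100.0 / (2.0 * generations)


def write_segments(segments: pd.DataFrame, path) -> None:
    """Write segments as BED-like TSV; coordinates are 1-based inclusive bp."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based inclusive base pairs\n")
        segments[["chrom", "start_bp", "end_bp", "individual_id", "n_snps"]].to_csv(
            fh, sep="\t", index=False
        )
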