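"""Locus-level association of ROH state with inbreeding, birth year or traits.

The model at each SNP is ordinary least squares,

    y = b0 + b1 * H + (PC covariates) + e,

where H is the 0/1 ROH state (or a dosage) of the individuals at that SNP.
Significance is the two-sided t-test on b1.  Genome-wide thresholds come
from permutations of the response: the response vector alone is shuffled
across individuals (covariates stay attached to their individuals), the
scan's maximum -log10 p is recorded per permutation, and the 95th/99th
percentiles of that maximum distribution give the suggestive (5%) and
significant (1%) genome-wide levels.

Scans are computed with the Frisch-Waugh-Lovell closed form (response and
predictors residualized against the covariate block once, then simple
regression per SNP), which is algebraically identical to the full OLS fit
and fast enough to permute thousands of times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

NEGLOG10P_CAP = 300.0

PROFILE_COLUMNS = ["snp_id", "chrom", "pos", "slope", "neglog10_p", "n"]


@dataclass
class AssociationProfile:
    """Per-SNP slopes and -log10 p for one response and one model."""

    response_name: str
    model: str  # "raw" or "pc_adjusted(k)"
    table: pd.DataFrame  # PROFILE_COLUMNS

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class PermThresholds:
    """Genome-wide permutation thresholds on the -log10 p scale."""

    suggestive_neglog10p: float  # genome-wide 5%
    significant_neglog10p: float  # genome-wide 1%
    n_permutations: int
    seed: int
    max_distribution: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.significant_neglog10p < self.suggestive_neglog10p:
            raise AssertionError("significant threshold below suggestive")


def _design(covariates: Optional[np.ndarray], n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    return np.column_stack([np.ones(n), covariates])


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ beta


def _t_to_neglog10p(t2: np.ndarray, df: int) -> np.ndarray:
    """-log10 p of a two-sided t-test given t^2 (equals F(1, df) upper tail)."""
    with np.errstate(invalid="ignore"):
        p = stats.f.sf(t2, 1, df)
    out = np.full_like(np.asarray(t2, dtype=float), np.nan)
    ok = np.isfinite(p)
    with np.errstate(divide="ignore"):
        out[ok] = -np.log10(p[ok])
    return np.minimum(out, NEGLOG10P_CAP)


def locus_regression(
    y: np.ndarray,
    h: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> tuple[float, float, int]:
    """OLS of y on one SNP's ROH state/dosage, optional PC covariates.

    Returns ``(slope, neglog10_p, n_used)``.  Complete-case analysis; a
    constant predictor or response, or fewer than 3 complete cases, yields
    ``(nan, nan, n)`` rather than an exception.
    """
    y = np.asarray(y, dtype=float)
    h = np.asarray(h, dtype=float)
    Z = _design(covariates, len(y))
    complete = np.isfinite(y) & np.isfinite(h) & np.isfinite(Z).all(axis=1)
    n = int(complete.sum())
    if n < 3:
        return (np.nan, np.nan, n)
    yc, hc, Zc = y[complete], h[complete], Z[complete]
    df = n - Zc.shape[1] - 1
    if df < 1 or np.ptp(hc) == 0:
        return (np.nan, np.nan, n)
    ry = _residualize(yc, Zc)
    rh = _residualize(hc, Zc)
    shh = float(rh @ rh)
    if shh <= 1e-12 * n:
        return (np.nan, np.nan, n)
    sxy = float(rh @ ry)
    syy = float(ry @ ry)
    slope = sxy / shh
    denom = shh * syy - sxy * sxy
    if denom <= 0:
        return (slope, NEGLOG10P_CAP, n)  # perfect fit
    t2 = df * sxy * sxy / denom
    return (slope, float(_t_to_neglog10p(np.array([t2]), df)[0]), n)


def genome_scan(
    y: np.ndarray,
    H: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    marker_map: Optional[pd.DataFrame] = None,
    response_name: str = "response",
) -> AssociationProfile:
    """Column-wise :func:`locus_regression` over a state/dosage matrix.

    Vectorized when predictors have no missing values (the ROH state matrix
    never does); falls back to a per-SNP loop otherwise.  Degenerate SNPs
    are flagged with NaN slope and p.
    """
    y = np.asarray(y, dtype=float)
    H = np.asarray(H, dtype=float)
    n_ind, m = H.shape
    if len(y) != n_ind:
        raise ValueError("response not aligned with state matrix rows")
    Z = _design(covariates, n_ind)
    complete = np.isfinite(y) & np.isfinite(Z).all(axis=1)

    if np.isfinite(H[complete]).all():
        yc = y[complete]
        Hc = H[complete]
        Zc = Z[complete]
        n = int(complete.sum())
        df = n - Zc.shape[1] - 1
        slopes = np.full(m, np.nan)
        neglogp = np.full(m, np.nan)
        ns = np.full(m, n)
        if n >= 3 and df >= 1:
            ry = _residualize(yc, Zc)
            RH = _residualize(Hc, Zc)
            shh = (RH * RH).sum(axis=0)
            sxy = RH.T @ ry
            syy = float(ry @ ry)
            defined = (np.ptp(Hc, axis=0) > 0) & (shh > 1e-12 * n)
            with np.errstate(divide="ignore", invalid="ignore"):
                slopes = np.where(defined, sxy / shh, np.nan)
            denom = shh * syy - sxy * sxy
            perfect = defined & (denom <= 0)
            ok = defined & (denom > 0)
            t2 = np.zeros(m)
            t2[ok] = df * sxy[ok] ** 2 / denom[ok]
            neglogp[ok] = _t_to_neglog10p(t2[ok], df)
            neglogp[perfect] = NEGLOG10P_CAP
    else:
        slopes = np.empty(m)
        neglogp = np.empty(m)
        ns = np.empty(m, dtype=int)
        covs = None if covariates is None else np.asarray(covariates, dtype=float)
        for j in range(m):
            slopes[j], neglogp[j], ns[j] = locus_regression(y, H[:, j], covs)

    if marker_map is not None:
        snp_id = marker_map["snp_id"].to_numpy()
        chrom = marker_map["chrom"].to_numpy()
        pos = marker_map["pos"].to_numpy()
    else:
        snp_id = np.array([f"snp{j}" for j in range(m)])
        chrom = np.array(["NA"] * m)
        pos = np.arange(m)
    table = pd.DataFrame(
        {
            "snp_id": snp_id,
            "chrom": chrom,
            "pos": pos,
            "slope": slopes,
            "neglog10_p": neglogp,
            "n": ns,
        }
    )
    model = "raw" if covariates is None else f"pc_adjusted({_design(covariates, n_ind).shape[1] - 1})"
    return AssociationProfile(response_name=response_name, model=model, table=table)


def _batched_max_neglog10p(
    Y: np.ndarray,
    H: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    block: int = 200,
) -> np.ndarray:
    """Max defined -log10 p of the scan for each response column of Y.

    Shared engine for permutation thresholds and calibration experiments.
    Requires complete data (no NaN), which holds for simulated cohorts and
    permuted responses.
    """
    Y = np.asarray(Y, dtype=float)
    H = np.asarray(H, dtype=float)
    n, m = H.shape
    Z = _design(covariates, n)
    df = n - Z.shape[1] - 1
    if df < 1:
        raise ValueError("not enough individuals for the covariate-adjusted scan")
    RH = _residualize(H, Z)
    RY = _residualize(Y, Z)
    shh = (RH * RH).sum(axis=0)
    defined = (np.ptp(H, axis=0) > 0) & (shh > 1e-12 * n)
    syy = (RY * RY).sum(axis=0)
    maxima = np.empty(Y.shape[1])
    for lo in range(0, Y.shape[1], block):
        hi = min(lo + block, Y.shape[1])
        M = RH.T @ RY[:, lo:hi]  # m x b cross-products
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = shh[:, None] * syy[None, lo:hi] - M * M
            t2 = np.where(denom > 0, df * M * M / denom, np.inf)
        t2[~defined, :] = np.nan
        nlp = np.where(
            np.isinf(t2), NEGLOG10P_CAP, _t_to_neglog10p(t2, df)
        )
        maxima[lo:hi] = np.nanmax(nlp, axis=0)
    return maxima


def permutation_thresholds(
    y: np.ndarray,
    H: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermThresholds:
    """Genome-wide 5%/1% thresholds from response permutations.

    Only the response is shuffled across individuals; covariates stay with
    their individuals, preserving the covariate-predictor structure under
    the null of no response association.  Each permutation contributes the
    maximum defined -log10 p of its scan; the suggestive and significant
    thresholds are the 95th and 99th percentiles of those maxima.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm}: genome-wide percentiles are unstable below 100 "
            "permutations",
            stacklevel=2,
        )
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    complete = np.isfinite(y)
    if covariates is not None:
        covs = np.asarray(covariates, dtype=float)
        if covs.ndim == 1:
            covs = covs[:, None]
        complete &= np.isfinite(covs).all(axis=1)
        covs = covs[complete]
    else:
        covs = None
    yc = y[complete]
    Hc = np.asarray(H, dtype=float)[complete]
    perms = np.column_stack([rng.permutation(yc) for _ in range(n_perm)])
    maxima = _batched_max_neglog10p(perms, Hc, covs)
    suggestive = float(np.quantile(maxima, 0.95))
    significant = float(np.quantile(maxima, 0.99))
    return PermThresholds(
        suggestive_neglog10p=suggestive,
        significant_neglog10p=significant,
        n_permutations=n_perm,
        seed=seed,
        max_distribution=maxima,
    )


REGION_COLUMNS = [
    "chrom", "start_bp", "end_bp", "span_bp", "n_snps",
    "peak_pos", "peak_neglog10p", "peak_slope",
]


def call_regions(
    profile: AssociationProfile,
    thresholds: PermThresholds,
    merge_gap_bp: int = 1_000_000,
    min_span_bp: int = 1_000_000,
    level: str = "suggestive",
    f_l: Optional[np.ndarray] = None,
    companion: Optional[AssociationProfile] = None,
) -> pd.DataFrame:
    """Group threshold-exceeding SNPs into reported regions.

    SNPs above the chosen threshold are clustered per chromosome; adjacent
    clusters separated by at most ``merge_gap_bp`` merge; regions spanning
    less than ``min_span_bp`` are dropped.  The peak is the member SNP with
    maximum -log10 p (ties: smallest position).  Optional ``f_l`` (aligned
    to the profile's SNPs) adds the peak's locus autozygosity; an optional
    companion profile (e.g. the ROH-FPED scan) adds its statistic at the peak.
    """
    thr = (
        thresholds.suggestive_neglog10p
        if level == "suggestive"
        else thresholds.significant_neglog10p
    )
    t = profile.table
    above = t["neglog10_p"].to_numpy() > thr
    regions = []
    for chrom in t["chrom"].unique():
        on_chrom = (t["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(on_chrom & above)
        if idx.size == 0:
            continue
        pos = t["pos"].to_numpy()[idx]
        breaks = np.flatnonzero(np.diff(pos) > merge_gap_bp)
        groups = np.split(idx, breaks + 1)
        for grp in groups:
            gpos = t["pos"].to_numpy()[grp]
            span = int(gpos[-1] - gpos[0])
            if span < min_span_bp:
                continue
            nlp = t["neglog10_p"].to_numpy()[grp]
            peak_local = np.flatnonzero(nlp == nlp.max())[0]  # smallest pos wins ties
            peak_idx = grp[peak_local]
            row = {
                "chrom": chrom,
                "start_bp": int(gpos[0]),
                "end_bp": int(gpos[-1]),
                "span_bp": span,
                "n_snps": len(grp),
                "peak_pos": int(t["pos"].iloc[peak_idx]),
                "peak_neglog10p": float(t["neglog10_p"].iloc[peak_idx]),
                "peak_slope": float(t["slope"].iloc[peak_idx]),
            }
            if f_l is not None:
                row["peak_F_L"] = float(np.asarray(f_l)[peak_idx])
            if companion is not None:
                row["companion_neglog10p"] = float(
                    companion.table["neglog10_p"].iloc[peak_idx]
                )
                row["companion_slope"] = float(companion.table["slope"].iloc[peak_idx])
            regions.append(row)
    cols = REGION_COLUMNS.copy()
    if f_l is not None:
        cols.append("peak_F_L")
    if companion is not None:
        cols += ["companion_neglog10p", "companion_slope"]
    return pd.DataFrame(regions, columns=cols)


def effect_profile_correlation(a: AssociationProfile, b: AssociationProfile) -> float:
    """Genome-wide Pearson correlation of two scans' slopes over shared SNPs."""
    merged = a.table[["snp_id", "slope"]].merge(
        b.table[["snp_id", "slope"]], on="snp_id", suffixes=("_a", "_b")
    ).dropna()
    if len(merged) < 2:
        return float("nan")
    return float(
        stats.pearsonr(merged["slope_a"], merged["slope_b"]).statistic
    )
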