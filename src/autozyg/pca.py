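"""Principal components on ROH states or genotypes for stratification covariates.

Columns are mean-centered but, by default, not variance-scaled: ROH states
are binary and unit-scaling would inflate the influence of rare columns.
Missing genotype entries are mean-imputed per column before decomposition
(the ROH state matrix has none by construction).  Component signs are fixed
by making each component's largest-magnitude loading positive, so score
files are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

from .io import MISSING


@dataclass
class PCResult:
    """Scores, loadings and explained-variance fractions of a PCA.

    scores : (n_individuals, k); column j is PC(j+1), mean ~ 0.
    explained_variance_fraction : length-k, non-increasing, each in [0, 1].
    loadings : (k, n_features) principal directions.
    source : "roh-states" | "genotypes" | other label.
    zero_variance : boolean flags for components beyond the matrix rank.
    """

    scores: np.ndarray
    explained_variance_fraction: np.ndarray
    loadings: np.ndarray
    source: str = "roh-states"
    zero_variance: np.ndarray = field(default=None)

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def to_frame(self, ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"PC{i + 1}" for i in range(self.k)]
        )
        if ids is not None:
            df.insert(0, "individual_id", list(ids))
        return df


def pca(matrix: np.ndarray, k: int = 5, scale: bool = False, source: str = "roh-states") -> PCResult:
    """Top-k principal components of an individuals x features matrix.

    Missing entries (NaN or the genotype sentinel) are mean-imputed per
    column.  ``scale=True`` additionally divides columns by their standard
    deviation (documented variant; off by default).  Deterministic up to the
    fixed sign convention.
    """
    X = np.asarray(matrix, dtype=float).copy()
    X[X == MISSING] = np.nan
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds matrix dimensions {X.shape}")
    if scale:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = X / sd

    model = _SkPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_
    # sign convention: largest-magnitude loading of each component positive
    flip = np.sign(loadings[np.arange(k), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = scores * flip
    loadings = loadings * flip[:, None]

    evf = model.explained_variance_ratio_
    zero_var = model.explained_variance_ < 1e-12
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} trailing component(s) have zero variance "
            "(k exceeds matrix rank)",
            stacklevel=2,
        )
    return PCResult(
        scores=scores,
        explained_variance_fraction=evf,
        loadings=loadings,
        source=source,
        zero_variance=zero_var,
    )


def pc_f_correlation(pc: PCResult, f: np.ndarray) -> np.ndarray:
    """Pearson correlation of each PC score with an inbreeding coefficient.

    Individuals must be aligned.  The vector is sign-normalized so that the
    PC1 correlation is reported non-negative (PC signs are arbitrary).
    Zero-variance inputs give NaN.
    """
    f = np.asarray(f, dtype=float)
    if len(f) != pc.scores.shape[0]:
        raise ValueError("inbreeding vector not aligned with PC scores")
    r = np.full(pc.k, np.nan)
    if f.size == 0 or (f == f[0]).all():
        return r
    for j in range(pc.k):
        s = pc.scores[:, j]
        if (s == s[0]).all():
            continue
        r[j] = stats.pearsonr(s, f).statistic
    if not np.isnan(r[0]) and r[0] < 0:
        r[0] = -r[0]
    return r


def fped_strata(f: np.ndarray, edges=(0.03, 0.10)) -> np.ndarray:
    """Bin inbreeding coefficients into plotting strata (low/mid/high)."""
    return np.digitize(np.asarray(f, dtype=float), bins=np.asarray(edges))
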