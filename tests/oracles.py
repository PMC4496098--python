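"""Independent brute-force oracles the implementation is checked against.

Everything here is deliberately naive: direct enumeration, path counting,
string counting.  Nothing imports the code paths it verifies.
"""

from __future__ import annotations

import itertools
from collections import Counter
from fractions import Fraction

import numpy as np


def brute_force_hom_runs(vec, min_snps: int) -> list[tuple[int, int]]:
    """Maximal runs of homozygous calls (0/2) of length >= min_snps, by linear scan."""
    runs = []
    start = None
    for i, v in enumerate(list(vec) + [None]):
        hom = v in (0, 2)
        if hom and start is None:
            start = i
        elif not hom and start is not None:
            if i - start >= min_snps:
                runs.append((start, i - 1))
            start = None
    return runs


def _paths_up(parents: dict, node) -> list[list]:
    """All ancestor paths node -> ... -> ancestor (node inclusive)."""
    out = [[node]]
    s, d = parents.get(node, (None, None))
    for p in (s, d):
        if p is not None:
            out.extend([[node] + rest for rest in _paths_up(parents, p)])
    return out


def _fped_fraction(parents: dict, animal) -> Fraction:
    """Wright's F by explicit path enumeration over all common ancestors.

    F(x) = sum over common ancestors A and pairs of ancestor paths
    (sire->A, dam->A) sharing only A of (1/2)^(n1+n2+1) * (1 + F(A)).
    Exponential in pedigree size; fine for <= ~15 animals.
    """
    sire, dam = parents.get(animal, (None, None))
    if sire is None or dam is None:
        return Fraction(0)
    total = Fraction(0)
    for sp in _paths_up(parents, sire):
        for dp in _paths_up(parents, dam):
            if sp[-1] != dp[-1]:
                continue
            a = sp[-1]
            if set(sp) & set(dp) != {a}:
                continue
            n1, n2 = len(sp) - 1, len(dp) - 1
            total += Fraction(1, 2 ** (n1 + n2 + 1)) * (1 + _fped_fraction(parents, a))
    return total


def path_counting_inbreeding(parents: dict, animal) -> float:
    return float(_fped_fraction(parents, animal))


def random_acyclic_pedigree(rng: np.random.Generator, n_animals: int) -> dict:
    """Random pedigree as {animal: (sire|None, dam|None)}; parents precede children."""
    parents = {}
    names = [f"a{i}" for i in range(n_animals)]
    for i, name in enumerate(names):
        if i < 2 or rng.random() < 0.3:
            parents[name] = (None, None)
        else:
            s = names[rng.integers(i)]
            d = names[rng.integers(i)]
            if s == d:
                parents[name] = (s, None)
            else:
                parents[name] = (s, d)
    return parents


def single_locus_kinship_mc(
    parents: dict, a: str, b: str, n_drops: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Monte-Carlo kinship: gene-drop one unlinked locus, estimate P(IBD).

    Returns (estimate, standard error).  Per drop the exact probability that
    a random allele of `a` equals a random allele of `b` is averaged
    (quarter of the pairwise label matches), which lowers the MC variance.
    """
    order = []
    seen = set()

    def visit(x):
        if x in seen or x is None:
            return
        s, d = parents.get(x, (None, None))
        visit(s)
        visit(d)
        seen.add(x)
        order.append(x)

    for x in parents:
        visit(x)

    label = {}
    next_label = 0
    alleles = {}
    for x in order:
        s, d = parents.get(x, (None, None))
        cols = []
        for p in (s, d):
            if p is None:
                col = np.full(n_drops, next_label, dtype=np.int64)
                next_label += 1
            else:
                pick = rng.integers(2, size=n_drops)
                col = alleles[p][np.arange(n_drops), pick]
            cols.append(col)
        alleles[x] = np.column_stack(cols)

    A, B = alleles[a], alleles[b]
    match = np.zeros(n_drops)
    for i in range(2):
        for j in range(2):
            match += A[:, i] == B[:, j]
    vals = match / 4.0
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_drops))


def hwe_het_distribution(n_rare: int, n_total_genotypes: int) -> dict[int, float]:
    """Exact conditional distribution of the heterozygote count, by enumeration.

    Probability of h heterozygotes among n genotypes given n_rare copies of
    the rarer allele, from the ratio-of-factorials formula with exact
    Fractions.
    """
    from math import factorial

    n = n_total_genotypes
    n_common = 2 * n - n_rare
    probs = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        if hom_c < 0:
            continue
        num = Fraction(2**h) * Fraction(
            factorial(n), factorial(hom_r) * factorial(h) * factorial(hom_c)
        )
        probs[h] = num
    z = sum(probs.values())
    return {h: float(p / z) for h, p in probs.items()}


def hwe_exact_p_oracle(hom0: int, het: int, hom2: int) -> float:
    """Exact HWE p by full enumeration: mass of counts no more probable than observed."""
    n = hom0 + het + hom2
    n_rare = min(2 * hom0 + het, 2 * hom2 + het)
    if n_rare == 0:
        return 1.0
    dist = hwe_het_distribution(n_rare, n)
    p_obs = dist[het]
    return min(1.0, sum(p for p in dist.values() if p <= p_obs * (1 + 1e-12)))


def count_window_alleles(W: np.ndarray):
    """Frequencies / observed homozygosity / top-allele dosage by string counting."""
    strings = ["".join(map(str, row)) for row in W]
    counts = Counter(strings)
    first = {}
    for i, s in enumerate(strings):
        first.setdefault(s, i)
    ranked = sorted(counts, key=lambda s: (-counts[s], first[s]))
    n_hap = len(strings)
    freqs = [counts[s] / n_hap for s in ranked]
    n_ind = n_hap // 2
    obs = []
    for s in ranked:
        hom = sum(
            1 for i in range(n_ind) if strings[2 * i] == s and strings[2 * i + 1] == s
        )
        obs.append(hom / n_ind)
    top = ranked[0]
    dosage = [
        (strings[2 * i] == top) + (strings[2 * i + 1] == top) for i in range(n_ind)
    ]
    return ranked, freqs, obs, dosage


def ols_slope_p_oracle(y, x, covs=None):
    """Reference OLS slope and p-value via statsmodels."""
    import statsmodels.api as sm

    X = np.column_stack([x] + ([] if covs is None else [covs]))
    X = sm.add_constant(X, prepend=True)
    fit = sm.OLS(y, X).fit()
    return fit.params[1], fit.pvalues[1]
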