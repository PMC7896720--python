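"""Missingness profiles, Weir-Cockerham F-statistics and exact tests.

The differentiation estimator is the Weir & Cockerham (1984) analysis of
variance for two alleles: per locus the allele-frequency variance is
split into an among-population component ``a``, an among-individual-
within-population component ``b`` and a within-individual component
``c``; theta = a / (a + b + c). The multilocus estimator is the ratio of
summed components (ratio-of-averages), the convention for this
estimator; per-locus values are also exposed because the outlier
diagnostics work on the per-locus distribution.

F_IS for a population pair is computed on the two samples *pooled* into
one (the diagnostic used to flag undersplit loci): with pooled size n,
pooled allele frequency p and mean observed heterozygosity h,

    b = n/(n-1) * [ p(1-p) - (2n-1)/(4n) * h ],   c = h/2,
    F_IS = 1 - c / (b + c),

i.e. one minus the ratio of observed to small-sample-corrected expected
heterozygosity. Negative values flag heterozygote excess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix

__all__ = [
    "MissingnessProfile",
    "missingness",
    "wc_components_from_counts",
    "pooled_fis_from_counts",
    "wc_pair_stats",
    "multilocus_fst",
    "exact_differentiation_test",
    "pairwise_fst_matrix",
]


# ---------------------------------------------------------------------------
# missingness
# ---------------------------------------------------------------------------

@dataclass
class MissingnessProfile:
    """Fractions of missing calls by individual, by locus x population, and
    by locus overall."""

    per_individual: pd.Series  # index: individual id
    per_locus_by_pop: pd.DataFrame  # index: pop, columns: locus id
    per_locus: pd.Series  # index: locus id


def missingness(matrix: GenotypeMatrix) -> MissingnessProfile:
    miss = matrix.calls == MISSING
    per_ind = pd.Series(
        miss.mean(axis=1), index=pd.Index(matrix.individual_ids, name="individual")
    )
    pops = matrix.populations
    by_pop = np.vstack([miss[matrix.pop_mask(p), :].mean(axis=0) for p in pops])
    per_locus_by_pop = pd.DataFrame(
        by_pop, index=pd.Index(pops, name="pop"), columns=matrix.locus_ids
    )
    per_locus = pd.Series(miss.mean(axis=0), index=pd.Index(matrix.locus_ids))
    return MissingnessProfile(per_ind, per_locus_by_pop, per_locus)


# ---------------------------------------------------------------------------
# Weir-Cockerham components
# ---------------------------------------------------------------------------

def wc_components_from_counts(n1, p1, h1, n2, p2, h2):
    """Weir-Cockerham (1984) two-allele variance components for r=2 samples.

    Parameters are vectorized: diploid sample sizes ``n1``/``n2``, B-allele
    frequencies ``p1``/``p2`` and observed heterozygote proportions
    ``h1``/``h2``. Returns ``(a, b, c)`` arrays.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)

    r = 2.0
    n_tot = n1 + n2
    nbar = n_tot / r
    nc = n_tot - (n1**2 + n2**2) / n_tot  # (r*nbar - sum n_i^2/(r*nbar)) / (r-1)
    pbar = (n1 * p1 + n2 * p2) / n_tot
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / n_tot

    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1 - pbar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
    )
    c = hbar / 2.0
    return a, b, c


def pooled_fis_from_counts(n, p, h):
    """Single-sample Weir-Cockerham F_IS = 1 - c/(b+c); NaN if b+c == 0."""
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    b = (n / (n - 1.0)) * (p * (1 - p) - ((2.0 * n - 1.0) / (4.0 * n)) * h)
    c = h / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        fis = 1.0 - c / (b + c)
    return np.where(b + c == 0, np.nan, fis)


def _pop_counts(matrix: GenotypeMatrix, pop: str):
    """Per-locus genotyped count, B-allele frequency and observed het."""
    calls = matrix.calls[matrix.pop_mask(pop), :]
    geno = calls != MISSING
    n = geno.sum(axis=0).astype(float)
    dosage = np.where(geno, calls, 0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = dosage.sum(axis=0) / (2.0 * n)
        h = (calls == 1).sum(axis=0) / n
    return n, p, h


def wc_pair_stats(matrix: GenotypeMatrix, pop_a: str, pop_b: str) -> pd.DataFrame:
    """Per-locus pair statistics for two samples.

    Returns a DataFrame indexed by locus id with sample sizes, allele
    frequencies, observed heterozygosities, WC components ``a, b, c``,
    per-locus ``fst`` and pooled-sample ``fis_pooled``. Loci genotyped in
    fewer than two individuals in either sample, or monomorphic across
    both, are flagged ``defined=False`` and excluded from multilocus
    ratios.
    """
    n1, p1, h1 = _pop_counts(matrix, pop_a)
    n2, p2, h2 = _pop_counts(matrix, pop_b)

    estimable = (n1 >= 2) & (n2 >= 2)
    # guard against div-by-zero inside the formulas for non-estimable loci
    n1s, n2s = np.where(estimable, n1, 2), np.where(estimable, n2, 2)
    p1s, p2s = np.nan_to_num(p1), np.nan_to_num(p2)
    h1s, h2s = np.nan_to_num(h1), np.nan_to_num(h2)

    a, b, c = wc_components_from_counts(n1s, p1s, h1s, n2s, p2s, h2s)
    denom = a + b + c
    pbar = (n1s * p1s + n2s * p2s) / (n1s + n2s)
    monomorphic = (denom == 0) | np.isclose(pbar * (1 - pbar) + h1s + h2s, 0)
    defined = estimable & ~monomorphic

    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(defined, a / denom, np.nan)
    hbar = (n1s * h1s + n2s * h2s) / (n1s + n2s)
    fis = pooled_fis_from_counts(n1s + n2s, pbar, hbar)
    fis = np.where(defined, fis, np.nan)

    return pd.DataFrame(
        {
            "n1": n1,
            "n2": n2,
            "p1": p1,
            "p2": p2,
            "h1": h1,
            "h2": h2,
            "a": np.where(defined, a, np.nan),
            "b": np.where(defined, b, np.nan),
            "c": np.where(defined, c, np.nan),
            "fst": fst,
            "fis_pooled": fis,
            "defined": defined,
        },
        index=pd.Index(matrix.locus_ids, name="locus"),
    )


def multilocus_fst(stats_df: pd.DataFrame) -> float:
    """Multilocus theta = sum(a) / sum(a+b+c) over defined loci.

    Returns NaN when no locus is estimable. Negative estimates are
    reported as computed, never truncated at zero.
    """
    ok = stats_df["defined"].to_numpy(dtype=bool)
    if not ok.any():
        return float("nan")
    a = stats_df.loc[ok, "a"].to_numpy()
    denom = (stats_df.loc[ok, ["a", "b", "c"]].sum(axis=1)).to_numpy()
    return float(a.sum() / denom.sum())


# ---------------------------------------------------------------------------
# exact tests of differentiation
# ---------------------------------------------------------------------------

def exact_differentiation_test(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    n_mc: int = 100_000,
    seed: int | None = None,
):
    """Per-locus two-sided Fisher exact tests on 2x2 allele-count tables,
    combined across loci with Fisher's method.

    For biallelic loci the exact null distribution is the hypergeometric,
    enumerated exhaustively; ``n_mc``/``seed`` are accepted for API
    stability but Monte-Carlo sampling is never needed for 2x2 tables.
    Monomorphic loci get p = 1 by convention and are excluded from the
    combination.

    Returns ``(per_locus, combined_p)`` where ``per_locus`` is a DataFrame
    with the allele counts, p-value and a ``combined`` flag.
    """
    del n_mc, seed  # 2x2 tables are always enumerated exactly
    n1, p1, _ = _pop_counts(matrix, pop_a)
    n2, p2, _ = _pop_counts(matrix, pop_b)
    a1 = np.rint(2 * n1 * np.nan_to_num(p1)).astype(int)  # B alleles, pop A
    a2 = np.rint(2 * n2 * np.nan_to_num(p2)).astype(int)
    tot1 = (2 * n1).astype(int)
    tot2 = (2 * n2).astype(int)

    pvals = np.ones(matrix.n_loci)
    combined_mask = np.zeros(matrix.n_loci, dtype=bool)
    for j in range(matrix.n_loci):
        if tot1[j] == 0 or tot2[j] == 0:
            continue
        table = [[a1[j], tot1[j] - a1[j]], [a2[j], tot2[j] - a2[j]]]
        monomorphic = (a1[j] + a2[j] == 0) or (a1[j] + a2[j] == tot1[j] + tot2[j])
        if monomorphic:
            pvals[j] = 1.0
            continue
        pvals[j] = stats.fisher_exact(table, alternative="two-sided")[1]
        combined_mask[j] = True

    per_locus = pd.DataFrame(
        {
            "alt_a": a1,
            "total_a": tot1,
            "alt_b": a2,
            "total_b": tot2,
            "p": pvals,
            "combined": combined_mask,
        },
        index=pd.Index(matrix.locus_ids, name="locus"),
    )
    if combined_mask.any():
        combined_p = float(
            stats.combine_pvalues(pvals[combined_mask], method="fisher")[1]
        )
    else:
        combined_p = float("nan")
    return per_locus, combined_p


def pairwise_fst_matrix(
    matrix: GenotypeMatrix,
    pops: list[str] | None = None,
    alpha: float = 0.01,
    with_tests: bool = True,
) -> pd.DataFrame:
    """Multilocus theta and exact-test significance for every population pair.

    Returns a long-format DataFrame (pop_a, pop_b, theta, p, significant).
    Pairs where either sample has no estimable loci get NaN theta.
    """
    pops = pops or matrix.populations
    records = []
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            stats_df = wc_pair_stats(matrix, pa, pb)
            theta = multilocus_fst(stats_df)
            if with_tests and np.isfinite(theta):
                _, combined_p = exact_differentiation_test(matrix, pa, pb)
            else:
                combined_p = float("nan")
            records.append(
                {
                    "pop_a": pa,
                    "pop_b": pb,
                    "theta": theta,
                    "p": combined_p,
                    "significant": bool(np.isfinite(combined_p) and combined_p < alpha),
                }
            )
    return pd.DataFrame.from_records(records)
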