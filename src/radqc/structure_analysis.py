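"""Individual-based PCA and per-pair F_ST distribution characterization.

The PCA deliberately reproduces the common genotype-PCA workflow:
missing dosages are imputed with the locus mean over genotyped
individuals, columns are centred (not variance-scaled), and scores come
from the SVD of the centred matrix. Mean imputation is exactly the
mechanism by which population-specific missingness fabricates cluster
structure — individuals missing many loci are pulled toward the origin
together — so it is the default on purpose, with variance scaling
available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .containers import MISSING, GenotypeMatrix
from . import popgen_stats

__all__ = [
    "PCAResult",
    "pca",
    "cluster_separation",
    "FstDistribution",
    "fst_distribution",
    "FST_BIN_EDGES",
]


@dataclass
class PCAResult:
    """Scores, eigenvalues and the imputation/centering vector."""

    scores: pd.DataFrame  # index: individual, columns: PC1..PCm
    eigenvalues: np.ndarray
    locus_means: pd.Series  # mean dosage used for imputation, by locus
    dropped_loci: list[str]  # loci with zero genotyped individuals


def pca(
    matrix: GenotypeMatrix, n_components: int = 2, scale: bool = False
) -> PCAResult:
    """Mean-imputed, centred genotype PCA.

    Loci with zero genotyped individuals are dropped (and listed in the
    result). With ``scale=True`` columns are also divided by their
    standard deviation (zero-variance columns are left unscaled).
    """
    if matrix.n_individuals < 2 or matrix.n_loci < 1:
        raise ValueError("PCA needs >=2 individuals and >=1 locus")
    X = matrix.calls.astype(float)
    X[matrix.calls == MISSING] = np.nan
    genotyped = np.isfinite(X).sum(axis=0)
    keep = genotyped > 0
    dropped = [matrix.locus_ids[j] for j in np.flatnonzero(~keep)]
    X = X[:, keep]
    means = np.nanmean(X, axis=0)
    X = np.where(np.isfinite(X), X, means[None, :]) - means[None, :]
    if scale:
        sd = X.std(axis=0, ddof=0)
        X = X / np.where(sd > 0, sd, 1.0)

    n_components = min(n_components, min(X.shape))
    # economy SVD of the centred matrix; eigenvalues of X'X / (n-1)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    eigenvalues = (s**2) / (matrix.n_individuals - 1)
    scores = U[:, :n_components] * s[:n_components]
    return PCAResult(
        scores=pd.DataFrame(
            scores,
            index=pd.Index(matrix.individual_ids, name="individual"),
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        eigenvalues=eigenvalues[:n_components],
        locus_means=pd.Series(
            means, index=[matrix.locus_ids[j] for j in np.flatnonzero(keep)]
        ),
        dropped_loci=dropped,
    )


def cluster_separation(result: PCAResult, labels) -> float:
    """Silhouette score of the given labels in PC space.

    Quantifies the visual "does this group separate?" judgement; values
    near 0 mean no separation, > ~0.25 a clearly distinct cluster.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need at least two distinct labels")
    return float(silhouette_score(result.scores.to_numpy(), labels))


# ---------------------------------------------------------------------------
# F_ST distributions
# ---------------------------------------------------------------------------

FST_BIN_EDGES = (0.05, 0.10, 0.15, 0.20)
_BIN_NAMES = ("0-0.05", "0.05-0.1", "0.1-0.15", "0.15-0.2", ">0.2")


@dataclass
class FstDistribution:
    """Per-locus F_ST values and their binned summary for one pair.

    Negative per-locus estimates are counted in the lowest bin; mean and
    max are over all estimable loci. ``subsample_n``/``seed`` record the
    normalization, if any.
    """

    pop_a: str
    pop_b: str
    n_a: int
    n_b: int
    values: np.ndarray
    mean: float
    max: float
    bins: dict[str, int]
    subsample_n: int | None = None
    seed: int | None = None

    def to_row(self) -> dict:
        return {
            "pop_a": self.pop_a,
            "pop_b": self.pop_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "mean": self.mean,
            "max": self.max,
            **self.bins,
            "subsample_n": self.subsample_n,
        }


def fst_distribution(
    matrix: GenotypeMatrix,
    pop_a: str,
    pop_b: str,
    subsample_n: int | None = None,
    seed: int | None = None,
) -> FstDistribution:
    """Characterize the per-locus F_ST distribution for a population pair.

    With ``subsample_n`` both samples are first randomly subsampled to
    that size (seeded), normalizing sample-size differences between
    pairs before the distributions are compared.
    """
    work = matrix
    if subsample_n is not None:
        rng = np.random.default_rng(seed)
        keep_rows: list[int] = []
        for pop in (pop_a, pop_b):
            rows = np.flatnonzero(matrix.pop_mask(pop))
            if rows.size < subsample_n:
                raise ValueError(
                    f"population {pop} has {rows.size} individuals, "
                    f"cannot subsample {subsample_n}"
                )
            keep_rows.extend(rng.choice(rows, size=subsample_n, replace=False))
        work = matrix.take_individuals(np.sort(np.array(keep_rows)))

    stats_df = popgen_stats.wc_pair_stats(work, pop_a, pop_b)
    values = stats_df.loc[stats_df["defined"], "fst"].to_numpy()
    edges = np.array(FST_BIN_EDGES)
    idx = np.searchsorted(edges, values, side="right")  # negatives land in bin 0
    counts = np.bincount(idx, minlength=5)
    n_a = int(work.pop_mask(pop_a).sum())
    n_b = int(work.pop_mask(pop_b).sum())
    return FstDistribution(
        pop_a=pop_a,
        pop_b=pop_b,
        n_a=n_a,
        n_b=n_b,
        values=values,
        mean=float(values.mean()) if values.size else float("nan"),
        max=float(values.max()) if values.size else float("nan"),
        bins={name: int(c) for name, c in zip(_BIN_NAMES, counts)},
        subsample_n=subsample_n,
        seed=seed,
    )
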