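"""Synthetic genotype panels and length-at-age datasets with ground truth.

The genotype generator emulates the failure modes that RADseq QC has to
catch:

* clean biallelic SNPs diverged under the Balding-Nichols model — each
  population's allele frequency is Beta-distributed around an ancestral
  frequency with a single divergence parameter F, so a target multilocus
  F_ST can be dialled in directly;
* *undersplit* loci (two paralogous loci collapsed into one assembled
  locus): in the affected population(s) one copy is fixed and the other
  segregates, so an individual is scored heterozygous whenever the
  variable copy carries the alternate allele. With the variable copy at
  high frequency this yields near-fixed heterozygosity in the affected
  population, strongly negative pooled F_IS, inflated pairwise F_ST and
  an allele read-ratio near 0.75 among heterozygotes;
* *oversplit* loci (one true locus split across assembled loci): one
  allele drops out, converting heterozygotes to homozygotes and adding
  missingness;
* population- and individual-specific missingness, including whole-locus
  dropout in a chosen population (the pattern that fabricates PCA
  structure under mean imputation).

Read depths are modelled as negative-binomial totals with a binomial
allele split (0.5 for true heterozygotes, the paralog ratio for
undersplit ones); they exist to exercise HDplot.

The growth generator draws length-at-age records from the hierarchical
linear model used downstream: river-level random intercepts and age
slopes (correlated), river-level sex effects around a common mean, fixed
effects of location (south vs north), period (contemporary vs
historical) and their interaction, and Gaussian residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_RIVER_LOCATION,
    MISSING,
    DepthTable,
    GenotypeMatrix,
    GrowthDataset,
)

__all__ = [
    "GenoSimConfig",
    "GrowthSimConfig",
    "simulate_genotypes",
    "simulate_growth",
]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenoSimConfig:
    """Parameters of the genotype panel generator.

    ``target_fst`` is the Balding-Nichols divergence parameter F; 0 means
    panmixia. It may also be a per-population sequence: populations with
    F = 0 sit exactly at the ancestral frequencies and therefore form
    one panmictic cluster, while populations with F > 0 diverge from it
    independently — the configuration needed to reproduce the
    missingness-PCA artifact, where a high-missingness population is
    displaced away from its true (panmictic) cluster against a
    backdrop of genuinely diverged populations.

    Artifact fractions partition the locus panel; the remainder
    is clean. ``pop_dropout`` maps a population index to
    ``(fraction_of_loci, (rate_lo, rate_hi))``: that fraction of loci
    gets a per-locus missing rate drawn uniformly from the range, applied
    to that population only (rate 1.0 = whole-locus dropout).
    """

    n_pops: int = 2
    n_per_pop: int = 50
    n_loci: int = 1000
    target_fst: float | Sequence[float] = 0.02
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    frac_undersplit: float = 0.0
    undersplit_pops: Sequence[int] = (0,)
    # variable-copy alternate-allele frequency in affected populations;
    # high values give the near-fixed heterozygosity signature
    undersplit_latent_freq_range: tuple[float, float] = (0.7, 0.95)
    frac_oversplit: float = 0.0
    oversplit_dropout: float = 0.6
    base_missing_rate: float = 0.0
    pop_dropout: dict[int, tuple[float, tuple[float, float]]] = field(
        default_factory=dict
    )
    mean_depth: float = 40.0
    depth_dispersion: float = 5.0
    paralog_ratio: float = 0.75
    pop_names: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        fsts = self.per_pop_fst
        if len(fsts) != self.n_pops:
            raise ValueError("per-pop target_fst needs one value per population")
        if any(not (0.0 <= f < 1.0) for f in fsts):
            raise ValueError("target_fst values must be in [0, 1)")
        for name in ("frac_undersplit", "frac_oversplit", "base_missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_undersplit + self.frac_oversplit >= 1.0:
            raise ValueError("artifact fractions must sum to < 1")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie within (0, 1)")
        if any(i >= self.n_pops for i in self.undersplit_pops):
            raise ValueError("undersplit_pops indexes a population out of range")
        if any(i >= self.n_pops for i in self.pop_dropout):
            raise ValueError("pop_dropout indexes a population out of range")

    @property
    def per_pop_fst(self) -> list[float]:
        if np.isscalar(self.target_fst):
            return [float(self.target_fst)] * self.n_pops
        return [float(f) for f in self.target_fst]

    @property
    def resolved_pop_names(self) -> list[str]:
        if self.pop_names is not None:
            return list(self.pop_names)
        return [f"POP{k + 1}" for k in range(self.n_pops)]


def _balding_nichols_freqs(rng, p_anc: np.ndarray, fsts: list[float]):
    """Population frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F) around p_anc.

    Populations with F = 0 sit exactly at the ancestral frequency."""
    rows = []
    for f in fsts:
        if f == 0.0:
            rows.append(p_anc.copy())
        else:
            scale = (1.0 - f) / f
            rows.append(rng.beta(p_anc * scale, (1.0 - p_anc) * scale))
    return np.vstack(rows)


def simulate_genotypes(config: GenoSimConfig):
    """Generate ``(GenotypeMatrix, DepthTable, ground_truth)``.

    ``ground_truth`` is a dict with per-locus class labels
    ("clean"/"undersplit"/"oversplit"), the Balding-Nichols population
    frequencies, the undersplit latent frequencies, the per-population
    dropout locus indices and rates, and the config echo — enough to
    compute the expected value of every downstream statistic on clean
    loci. All randomness is driven by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_pops, n_per, n_loci = config.n_pops, config.n_per_pop, config.n_loci
    n_ind = n_pops * n_per
    pop_names = config.resolved_pop_names
    pop_index = np.repeat(np.arange(n_pops), n_per)

    # locus classes
    n_under = int(round(config.frac_undersplit * n_loci))
    n_over = int(round(config.frac_oversplit * n_loci))
    classes = np.array(["clean"] * n_loci, dtype=object)
    artifact_idx = rng.choice(n_loci, size=n_under + n_over, replace=False)
    classes[artifact_idx[:n_under]] = "undersplit"
    classes[artifact_idx[n_under:]] = "oversplit"

    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=n_loci)
    pop_freqs = _balding_nichols_freqs(rng, p_anc, config.per_pop_fst)

    # clean / oversplit genotypes from population frequencies
    calls = rng.binomial(2, pop_freqs[pop_index, :]).astype(np.int8)

    # undersplit loci: affected pops near-fixed heterozygous, others near-invariant
    under_idx = np.flatnonzero(classes == "undersplit")
    latent_freq = np.full(n_loci, np.nan)
    if under_idx.size:
        q = rng.uniform(*config.undersplit_latent_freq_range, size=under_idx.size)
        latent_freq[under_idx] = q
        affected = np.isin(pop_index, list(config.undersplit_pops))
        for col, qj in zip(under_idx, q):
            # unaffected pops: the fixed copy with a trace of variation
            eps = rng.uniform(0.0, 0.02)
            calls[:, col] = rng.binomial(2, eps, size=n_ind).astype(np.int8).clip(0, 1)
            latent = rng.binomial(2, qj, size=affected.sum())
            calls[affected, col] = np.where(latent >= 1, 1, 0).astype(np.int8)

    # oversplit loci: allele-specific dropout of the B allele
    over_idx = np.flatnonzero(classes == "oversplit")
    for col in over_idx:
        drop = rng.random(n_ind) < config.oversplit_dropout
        het = calls[:, col] == 1
        hom_b = calls[:, col] == 2
        calls[het & drop, col] = 0
        calls[hom_b & drop, col] = MISSING

    # read depths before missingness so dropped genotypes carry no reads
    depths = _simulate_depths(rng, config, calls, classes)

    # missingness: per-individual base rate, then per-population dropout loci
    if config.base_missing_rate > 0:
        calls[rng.random(calls.shape) < config.base_missing_rate] = MISSING
    dropout_truth: dict[str, dict] = {}
    for k, (frac, (r_lo, r_hi)) in config.pop_dropout.items():
        n_drop = int(round(frac * n_loci))
        drop_loci = rng.choice(n_loci, size=n_drop, replace=False)
        rates = rng.uniform(r_lo, r_hi, size=n_drop)
        rows = np.flatnonzero(pop_index == k)
        for col, rate in zip(drop_loci, rates):
            hit = rows[rng.random(rows.size) < rate]
            calls[hit, col] = MISSING
        dropout_truth[pop_names[k]] = {
            "loci": np.sort(drop_loci).tolist(),
            "rates": {int(c): float(r) for c, r in zip(drop_loci, rates)},
        }

    # canonicalize allele polarity to the genepop reader's convention
    # (allele A = first code encountered in file order), so parsing the
    # emitted file recovers this matrix exactly: flip loci whose first
    # non-missing call is a B homozygote
    reads_a, reads_b = depths
    observed = calls != MISSING
    first_row = np.where(observed.any(axis=0), observed.argmax(axis=0), 0)
    flip = observed.any(axis=0) & (calls[first_row, np.arange(n_loci)] == 2)
    if flip.any():
        cols = np.flatnonzero(flip)
        sub = calls[:, cols]
        calls[:, cols] = np.where(sub != MISSING, 2 - sub, MISSING).astype(np.int8)
        reads_a[:, cols], reads_b[:, cols] = (
            reads_b[:, cols].copy(),
            reads_a[:, cols].copy(),
        )
        pop_freqs[:, cols] = 1.0 - pop_freqs[:, cols]
    depths = (reads_a, reads_b)

    individual_ids = [
        f"{pop_names[k]}_{i + 1:03d}" for k in range(n_pops) for i in range(n_per)
    ]
    matrix = GenotypeMatrix(
        individual_ids=individual_ids,
        pop_labels=[pop_names[k] for k in pop_index],
        locus_ids=[f"L{j + 1:05d}" for j in range(n_loci)],
        calls=calls,
    )
    depth_table = _depths_to_table(matrix, depths)

    ground_truth = {
        "classes": classes.tolist(),
        "pop_freqs": pop_freqs.tolist(),
        "latent_freq": [
            None if not np.isfinite(v) else float(v) for v in latent_freq
        ],
        "polarity_flipped": flip.tolist(),
        "pop_dropout": dropout_truth,
        "pop_names": pop_names,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
            if k != "pop_dropout"
        },
    }
    return matrix, depth_table, ground_truth


def _simulate_depths(rng, config: GenoSimConfig, calls, classes):
    """(reads_a, reads_b) arrays; zero where the genotype is missing."""
    n_ind, n_loci = calls.shape
    mean, k = config.mean_depth, config.depth_dispersion
    total = rng.negative_binomial(k, k / (k + mean), size=(n_ind, n_loci)) + 1
    ratio = np.full(n_loci, 0.5)
    ratio[classes == "undersplit"] = config.paralog_ratio
    reads_a = np.where(
        calls == 0,
        total,
        np.where(
            calls == 2,
            0,
            rng.binomial(total, ratio[None, :]),
        ),
    )
    reads_b = total - reads_a
    observed = calls != MISSING
    return np.where(observed, reads_a, 0), np.where(observed, reads_b, 0)


def _depths_to_table(matrix: GenotypeMatrix, depths) -> DepthTable:
    reads_a, reads_b = depths
    observed = matrix.calls != MISSING
    rows, cols = np.nonzero(observed)
    return DepthTable.from_arrays(
        [matrix.individual_ids[i] for i in rows],
        [matrix.locus_ids[j] for j in cols],
        reads_a[rows, cols],
        reads_b[rows, cols],
    )


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

@dataclass
class GrowthSimConfig:
    """True parameter values for the length-at-age generator (mm / years).

    Defaults mirror the study system: four rivers (Takwa in the north;
    Chalifour, Perch, Icon in the south), a ~24 mm decline at the
    reference location and an extra ~16 mm decline in the south, so the
    southern decline totals ~40 mm. River effects ``u0``/``u1``/``beta2``
    may be pinned explicitly; left as None they are drawn from the
    hierarchy (N(0, tau) and N(mu_beta2, sigma_beta2)) under the seed.
    """

    beta0: float = 225.0  # grand-mean intercept
    beta1: float = 25.0  # mean growth slope, mm per year
    beta3: float = 10.0  # south vs north offset
    beta4: float = -24.0  # contemporary vs historical (reference location)
    beta5: float = -16.0  # location x period interaction
    mu_beta2: float = -40.0  # mean male-vs-female effect
    sigma_beta2: float = 10.0
    tau0: float = 20.0  # sd of river intercept deviations
    tau1: float = 3.0  # sd of river age-slope deviations
    rho: float = -0.2  # intercept-slope correlation
    sigma: float = 30.0  # residual sd
    rivers: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_RIVER_LOCATION)
    )
    u0: dict[str, float] | None = None
    u1: dict[str, float] | None = None
    beta2: dict[str, float] | None = None
    n_per_cell: int = 25  # per river x history x sex
    age_range: tuple[int, int] = (3, 18)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma", "tau0", "tau1", "sigma_beta2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if not {"north", "south"} <= set(self.rivers.values()):
            raise ValueError("need at least one river per region")


def simulate_growth(config: GrowthSimConfig):
    """Generate ``(GrowthDataset, ground_truth)`` from the hierarchical model.

    Each record's mean is
    ``mu = beta0 + u0[river] + beta2[river]*male + (beta1 + u1[river])*age
    + beta3*south + beta4*contemporary + beta5*south*contemporary`` and
    lengths are drawn N(mu, sigma). ``ground_truth`` echoes every
    parameter including the realized river effects.
    """
    rng = np.random.default_rng(config.seed)
    rivers = list(config.rivers)

    if config.u0 is None or config.u1 is None:
        cov = np.array(
            [
                [config.tau0**2, config.rho * config.tau0 * config.tau1],
                [config.rho * config.tau0 * config.tau1, config.tau1**2],
            ]
        )
        draws = rng.multivariate_normal(np.zeros(2), cov, size=len(rivers))
        u0 = {r: float(draws[i, 0]) for i, r in enumerate(rivers)}
        u1 = {r: float(draws[i, 1]) for i, r in enumerate(rivers)}
    else:
        u0, u1 = dict(config.u0), dict(config.u1)
    if config.beta2 is None:
        beta2 = {
            r: float(rng.normal(config.mu_beta2, config.sigma_beta2)) for r in rivers
        }
    else:
        beta2 = dict(config.beta2)

    records = []
    for river in rivers:
        south = 1.0 if config.rivers[river] == "south" else 0.0
        for history, contemp in (("historical", 0.0), ("contemporary", 1.0)):
            for sex, male in (("female", 0.0), ("male", 1.0)):
                n = config.n_per_cell
                if n == 0:
                    continue
                ages = rng.integers(
                    config.age_range[0], config.age_range[1] + 1, size=n
                )
                mu = (
                    config.beta0
                    + u0[river]
                    + beta2[river] * male
                    + (config.beta1 + u1[river]) * ages
                    + config.beta3 * south
                    + config.beta4 * contemp
                    + config.beta5 * south * contemp
                )
                lengths = mu if config.sigma == 0 else rng.normal(mu, config.sigma)
                for age, length in zip(ages, lengths):
                    records.append(
                        (river, config.rivers[river], history, sex, int(age), float(length))
                    )

    table = pd.DataFrame.from_records(
        records, columns=["river", "location", "history", "sex", "age", "length"]
    )
    truth = {
        "beta0": config.beta0,
        "beta1": config.beta1,
        "beta3": config.beta3,
        "beta4": config.beta4,
        "beta5": config.beta5,
        "mu_beta2": config.mu_beta2,
        "sigma_beta2": config.sigma_beta2,
        "tau0": config.tau0,
        "tau1": config.tau1,
        "rho": config.rho,
        "sigma": config.sigma,
        "u0": u0,
        "u1": u1,
        "beta2": beta2,
        "rivers": dict(config.rivers),
    }
    return GrowthDataset(table), truth


def growth_to_raw_csv(data: GrowthDataset, path) -> None:
    """Write a raw-style survey CSV (river, year, sex code, age, length)
    consumable by :func:`radqc.genotype_io.read_growth_table`."""
    year_for = {"historical": 2003, "contemporary": 2016}
    out = pd.DataFrame(
        {
            "river": data.table["river"],
            "year": data.table["history"].map(year_for),
            "sex": data.table["sex"].map({"female": "F", "male": "M"}),
            "age": data.table["age"],
            "length": data.table["length"],
        }
    )
    out.to_csv(path, index=False)
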