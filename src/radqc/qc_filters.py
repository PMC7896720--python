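"""The genotype filter cascade with a full audit trail.

Steps are applied strictly in the listed order and every statistic is
recomputed on the *current* (partially filtered) matrix — the cascade
that motivates this package filters individuals on missingness before
screening loci on pooled F_IS, and the order changes the outcome.

The deliberately flawed k-of-n genotype-rate rule (retain a locus if it
meets the rate in at least k of n populations) is included so its
consequence — loci 100% missing in up to n-k populations surviving the
filter — can be demonstrated, not because it is recommended.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, DepthTable, GenotypeMatrix
from . import popgen_stats

__all__ = [
    "FilterStep",
    "IndividualMaxMissing",
    "LocusMinGenotypeRatePerPop",
    "LocusMaxMissingInPop",
    "FisMin",
    "HdplotBand",
    "FilterSpec",
    "FilterReport",
    "apply_filters",
    "hdplot",
    "flawed_kofn_rate_filter",
    "step_from_dict",
]


# ---------------------------------------------------------------------------
# step definitions
# ---------------------------------------------------------------------------

@dataclass
class FilterStep:
    name = "base"

    def check(self, matrix: GenotypeMatrix) -> None:
        """Validate references before any mutation."""

    def params(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


@dataclass
class IndividualMaxMissing(FilterStep):
    """Remove individuals whose missing fraction exceeds ``threshold``."""

    threshold: float
    name = "individual_max_missing"


@dataclass
class LocusMinGenotypeRatePerPop(FilterStep):
    """Retain loci genotyped at rate >= r in all (or >= k of n) populations."""

    r: float
    required_pops: int | str = "all"  # "all" or an integer k
    name = "locus_min_genotype_rate_per_pop"


@dataclass
class LocusMaxMissingInPop(FilterStep):
    """Remove loci whose missing fraction in ``pop`` exceeds ``threshold``."""

    pop: str
    threshold: float
    name = "locus_max_missing_in_pop"

    def check(self, matrix: GenotypeMatrix) -> None:
        if self.pop not in matrix.populations:
            raise KeyError(f"filter references absent population {self.pop!r}")


@dataclass
class FisMin(FilterStep):
    """Remove loci with pooled-pair F_IS strictly below ``threshold``.

    Loci whose F_IS is undefined on the current matrix (monomorphic, not
    estimable) are retained by this step and recorded as such.
    """

    pop_a: str
    pop_b: str
    threshold: float
    name = "fis_min"

    def check(self, matrix: GenotypeMatrix) -> None:
        for p in (self.pop_a, self.pop_b):
            if p not in matrix.populations:
                raise KeyError(f"filter references absent population {p!r}")


@dataclass
class HdplotBand(FilterStep):
    """Retain loci with read-ratio deviation D in [d_min, d_max] and
    heterozygosity <= max_het; loci with no heterozygotes are retained."""

    d_min: float
    d_max: float
    max_het: float = 1.0
    name = "hdplot_band"


_STEP_TYPES = {
    cls.name: cls
    for cls in (
        IndividualMaxMissing,
        LocusMinGenotypeRatePerPop,
        LocusMaxMissingInPop,
        FisMin,
        HdplotBand,
    )
}


def step_from_dict(d: dict) -> FilterStep:
    """Build a step from a YAML-style mapping {"step": name, **params}."""
    d = dict(d)
    name = d.pop("step")
    try:
        cls = _STEP_TYPES[name]
    except KeyError:
        raise ValueError(f"unknown filter step {name!r}") from None
    return cls(**d)


@dataclass
class FilterSpec:
    steps: list[FilterStep] = field(default_factory=list)

    @classmethod
    def from_dicts(cls, dicts: Sequence[dict]) -> "FilterSpec":
        return cls([step_from_dict(d) for d in dicts])


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class StepRecord:
    step: str
    params: dict
    n_individuals_before: int
    n_individuals_after: int
    n_loci_before: int
    n_loci_after: int
    removed: pd.DataFrame  # columns: id, kind, reason, value
    notes: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    records: list[StepRecord] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": r.step,
                    **{f"param_{k}": v for k, v in r.params.items()},
                    "individuals_before": r.n_individuals_before,
                    "individuals_after": r.n_individuals_after,
                    "loci_before": r.n_loci_before,
                    "loci_after": r.n_loci_after,
                }
                for r in self.records
            ]
        )

    def removals(self) -> pd.DataFrame:
        frames = [
            r.removed.assign(step=r.step) for r in self.records if len(r.removed)
        ]
        if not frames:
            return pd.DataFrame(columns=["id", "kind", "reason", "value", "step"])
        return pd.concat(frames, ignore_index=True)

    def to_json_dict(self) -> dict:
        return {
            "steps": [
                {
                    "step": r.step,
                    "params": {k: _jsonable(v) for k, v in r.params.items()},
                    "individuals_before": r.n_individuals_before,
                    "individuals_after": r.n_individuals_after,
                    "loci_before": r.n_loci_before,
                    "loci_after": r.n_loci_after,
                    "n_removed": int(len(r.removed)),
                    "notes": r.notes,
                }
                for r in self.records
            ]
        }


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def _removed_frame(ids, kind, reason, values) -> pd.DataFrame:
    return pd.DataFrame(
        {"id": list(ids), "kind": kind, "reason": reason, "value": list(values)}
    )


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def apply_filters(
    matrix: GenotypeMatrix,
    spec: FilterSpec,
    depths: DepthTable | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the cascade, returning the surviving matrix and its report.

    Raises before touching the matrix if a step references an absent
    population, or if an HDplot step is given without depths. An empty
    output matrix is allowed but flagged in the report notes.
    """
    for step in spec.steps:
        step.check(matrix)
        if isinstance(step, HdplotBand) and depths is None:
            raise ValueError("hdplot_band steps require a depth table")

    report = FilterReport()
    current = matrix
    for step in spec.steps:
        current = _apply_step(current, step, depths, report)
    if current.n_loci == 0 or current.n_individuals == 0:
        report.records[-1].notes.append(
            "WARNING: cascade produced an empty matrix "
            f"({current.n_individuals} individuals x {current.n_loci} loci)"
        )
    return current, report


def _apply_step(matrix, step, depths, report) -> GenotypeMatrix:
    nib, nlb = matrix.n_individuals, matrix.n_loci
    notes: list[str] = []

    if isinstance(step, IndividualMaxMissing):
        frac = (matrix.calls == MISSING).mean(axis=1)
        keep = frac <= step.threshold
        removed = _removed_frame(
            [matrix.individual_ids[i] for i in np.flatnonzero(~keep)],
            "individual",
            f"missing fraction > {step.threshold}",
            frac[~keep],
        )
        out = matrix.take_individuals(keep)

    elif isinstance(step, LocusMinGenotypeRatePerPop):
        pops = matrix.populations
        rates = np.vstack(
            [
                (matrix.calls[matrix.pop_mask(p), :] != MISSING).mean(axis=0)
                for p in pops
            ]
        )
        ok_pops = (rates >= step.r).sum(axis=0)
        k = len(pops) if step.required_pops == "all" else int(step.required_pops)
        keep = ok_pops >= k
        removed = _removed_frame(
            [matrix.locus_ids[j] for j in np.flatnonzero(~keep)],
            "locus",
            f"genotype rate >= {step.r} in only <{k}/{len(pops)} populations",
            ok_pops[~keep],
        )
        out = matrix.take_loci(keep)

    elif isinstance(step, LocusMaxMissingInPop):
        sub = matrix.calls[matrix.pop_mask(step.pop), :]
        frac = (sub == MISSING).mean(axis=0)
        keep = frac <= step.threshold
        removed = _removed_frame(
            [matrix.locus_ids[j] for j in np.flatnonzero(~keep)],
            "locus",
            f"missing fraction in {step.pop} > {step.threshold}",
            frac[~keep],
        )
        out = matrix.take_loci(keep)

    elif isinstance(step, FisMin):
        stats_df = popgen_stats.wc_pair_stats(matrix, step.pop_a, step.pop_b)
        fis = stats_df["fis_pooled"].to_numpy()
        undefined = ~np.isfinite(fis)
        keep = undefined | (fis >= step.threshold)
        if undefined.any():
            notes.append(
                f"{int(undefined.sum())} loci had undefined pooled F_IS "
                "on the current matrix and were retained by this step"
            )
        removed = _removed_frame(
            [matrix.locus_ids[j] for j in np.flatnonzero(~keep)],
            "locus",
            f"pooled F_IS({step.pop_a}+{step.pop_b}) < {step.threshold}",
            fis[~keep],
        )
        out = matrix.take_loci(keep)

    elif isinstance(step, HdplotBand):
        hd = hdplot(matrix, depths)
        hd = hd.reindex(matrix.locus_ids)
        d = hd["D"].to_numpy()
        h = hd["H"].to_numpy()
        undefined = ~np.isfinite(d)
        keep = undefined | (
            (d >= step.d_min) & (d <= step.d_max) & (h <= step.max_het)
        )
        if undefined.any():
            notes.append(
                f"{int(undefined.sum())} loci had no usable heterozygote "
                "depths and were retained by this step"
            )
        reasons = np.where(
            h > step.max_het,
            f"H > {step.max_het}",
            f"D outside [{step.d_min}, {step.d_max}]",
        )
        removed = _removed_frame(
            [matrix.locus_ids[j] for j in np.flatnonzero(~keep)],
            "locus",
            reasons[~keep],
            d[~keep],
        )
        out = matrix.take_loci(keep)

    else:  # pragma: no cover - guarded by step_from_dict
        raise TypeError(f"unknown step type {type(step)!r}")

    report.records.append(
        StepRecord(
            step=step.name,
            params=step.params(),
            n_individuals_before=nib,
            n_individuals_after=out.n_individuals,
            n_loci_before=nlb,
            n_loci_after=out.n_loci,
            removed=removed,
            notes=notes,
        )
    )
    return out


def flawed_kofn_rate_filter(
    matrix: GenotypeMatrix, r: float, k: int, n: int
) -> tuple[GenotypeMatrix, FilterReport]:
    """The k-of-n genotype-rate rule, exposed directly for demonstration.

    ``n`` must equal the number of populations present; with k < n a
    locus can be 100% missing in up to n-k populations and still
    survive.
    """
    pops = matrix.populations
    if n != len(pops):
        raise ValueError(f"n={n} but matrix has {len(pops)} populations")
    if k > n:
        raise ValueError("k must be <= n")
    spec = FilterSpec([LocusMinGenotypeRatePerPop(r=r, required_pops=k)])
    return apply_filters(matrix, spec)


# ---------------------------------------------------------------------------
# HDplot
# ---------------------------------------------------------------------------

def hdplot(matrix: GenotypeMatrix, depths: DepthTable) -> pd.DataFrame:
    """Per-locus HDplot statistics from heterozygote read depths.

    For each locus: ``H`` is the proportion of genotyped individuals
    called heterozygous; over heterozygotes only, ``allele_ratio`` is
    sum(reads_a)/sum(reads_a + reads_b) and ``D`` is the binomial
    z-score of the A-read count around a 0.5 split,
    ``(sum_a - N/2) / sqrt(N/4)`` with ``N`` the total heterozygote
    read count. Heterozygotes with zero total depth are dropped from
    the sums; loci with no usable heterozygotes get NaN ratio/D.
    """
    ind_idx = {v: i for i, v in enumerate(matrix.individual_ids)}
    loc_idx = {v: j for j, v in enumerate(matrix.locus_ids)}

    t = depths.table
    rows = t["individual"].map(ind_idx)
    cols = t["locus"].map(loc_idx)
    known = rows.notna() & cols.notna()
    rows = rows[known].astype(int).to_numpy()
    cols = cols[known].astype(int).to_numpy()
    ra = t.loc[known, "reads_a"].to_numpy()
    rb = t.loc[known, "reads_b"].to_numpy()

    is_het = matrix.calls[rows, cols] == 1
    usable = is_het & ((ra + rb) > 0)

    n_loci = matrix.n_loci
    sum_a = np.bincount(cols[usable], weights=ra[usable], minlength=n_loci)
    sum_total = np.bincount(
        cols[usable], weights=(ra + rb)[usable], minlength=n_loci
    )
    n_het_used = np.bincount(cols[usable], minlength=n_loci)
    n_het_zero_depth = np.bincount(cols[is_het & ~usable], minlength=n_loci)

    genotyped = (matrix.calls != MISSING).sum(axis=0)
    het_calls = (matrix.calls == 1).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(genotyped > 0, het_calls / genotyped, np.nan)
        allele_ratio = np.where(sum_total > 0, sum_a / sum_total, np.nan)
        D = np.where(
            sum_total > 0,
            (sum_a - sum_total / 2.0) / np.sqrt(sum_total / 4.0),
            np.nan,
        )
    return pd.DataFrame(
        {
            "H": H,
            "allele_ratio": allele_ratio,
            "D": D,
            "n_het_used": n_het_used,
            "n_het_zero_depth": n_het_zero_depth,
            "total_reads": sum_total,
        },
        index=pd.Index(matrix.locus_ids, name="locus"),
    )
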