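"""Core in-memory containers shared across the pipeline.

Genotypes are stored as unphased dosages of the second ("B") allele:
0 = homozygote A, 1 = heterozygote, 2 = homozygote B, -1 = missing.
Allele A is, by convention, the first allele code encountered for that
locus in source-file order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci with population labels.

    Parameters
    ----------
    individual_ids
        One id per row of ``calls``.
    pop_labels
        One population label per individual (e.g. ``"CHA03"``).
    locus_ids
        One id per column of ``calls``.
    calls
        ``(n_individuals, n_loci)`` int8 array of dosage codes
        {0, 1, 2, MISSING}.
    allele_names
        Per locus, the (up to two) observed allele codes from the source
        file, e.g. ``("01", "02")``. Monomorphic loci may carry a single
        observed code padded with a synthetic second code on write.
    """

    individual_ids: list[str]
    pop_labels: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    allele_names: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_ind, n_loc = self.calls.shape
        if len(self.individual_ids) != n_ind:
            raise ValueError(
                f"{len(self.individual_ids)} individual ids for {n_ind} rows"
            )
        if len(self.pop_labels) != n_ind:
            raise ValueError("every individual needs a population label")
        if len(self.locus_ids) != n_loc:
            raise ValueError(f"{len(self.locus_ids)} locus ids for {n_loc} columns")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValueError(
                f"invalid genotype code {self.calls[tuple(bad)]} at "
                f"individual {self.individual_ids[bad[0]]}, locus {self.locus_ids[bad[1]]}"
            )
        if not self.allele_names:
            self.allele_names = [("01", "02") for _ in self.locus_ids]

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pop_labels:
            seen.setdefault(p)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        mask = np.array([p == pop for p in self.pop_labels])
        if not mask.any():
            raise KeyError(f"population {pop!r} not present")
        return mask

    # -- subsetting -----------------------------------------------------
    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            individual_ids=[self.individual_ids[i] for i in index],
            pop_labels=[self.pop_labels[i] for i in index],
            locus_ids=list(self.locus_ids),
            calls=self.calls[index, :].copy(),
            allele_names=list(self.allele_names),
        )

    def take_loci(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            pop_labels=list(self.pop_labels),
            locus_ids=[self.locus_ids[i] for i in index],
            calls=self.calls[:, index].copy(),
            allele_names=[self.allele_names[i] for i in index],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.individual_ids == other.individual_ids
            and self.pop_labels == other.pop_labels
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class DepthTable:
    """Per (individual, locus) allele read depths for HDplot.

    ``reads_a``/``reads_b`` are counts of reads supporting the A and B
    allele; rows exist only for pairs present in the companion matrix.
    """

    table: pd.DataFrame  # columns: individual, locus, reads_a, reads_b

    def __post_init__(self) -> None:
        required = {"individual", "locus", "reads_a", "reads_b"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"depth table needs columns {sorted(required)}")
        if (self.table[["reads_a", "reads_b"]] < 0).any().any():
            raise ValueError("read counts must be non-negative")

    @classmethod
    def from_arrays(cls, individuals, loci, reads_a, reads_b) -> "DepthTable":
        return cls(
            pd.DataFrame(
                {
                    "individual": individuals,
                    "locus": loci,
                    "reads_a": np.asarray(reads_a, dtype=np.int64),
                    "reads_b": np.asarray(reads_b, dtype=np.int64),
                }
            )
        )


#: rivers draining the northern vs southern part of the lake; location is
#: a deterministic function of river.
DEFAULT_RIVER_LOCATION = {
    "Takwa": "north",
    "Chalifour": "south",
    "Perch": "south",
    "Icon": "south",
}

#: sampling year -> period. 2002/2003 are the historical samples,
#: 2015-2017 the contemporary resampling.
DEFAULT_YEAR_HISTORY = {
    2002: "historical",
    2003: "historical",
    2015: "contemporary",
    2016: "contemporary",
    2017: "contemporary",
}


@dataclass
class GrowthDataset:
    """Length-at-age records: river, location, history, sex, age, length."""

    table: pd.DataFrame

    COLUMNS = ("river", "location", "history", "sex", "age", "length")

    def __post_init__(self) -> None:
        missing_cols = set(self.COLUMNS) - set(self.table.columns)
        if missing_cols:
            raise ValueError(f"growth table missing columns {sorted(missing_cols)}")
        t = self.table
        if t[["age", "length"]].isna().any().any():
            raise ValueError("records with missing age or length are not allowed")
        if not set(t["location"]) <= {"north", "south"}:
            raise ValueError("location must be north/south")
        if not set(t["history"]) <= {"historical", "contemporary"}:
            raise ValueError("history must be historical/contemporary")
        if not set(t["sex"]) <= {"female", "male"}:
            raise ValueError("sex must be female/male")
        if (t["age"] < 0).any():
            raise ValueError("ages must be >= 0")
        if (t["length"] <= 0).any():
            raise ValueError("lengths must be > 0 mm")

    @property
    def rivers(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.table["river"]:
            seen.setdefault(r)
        return list(seen)

    def __len__(self) -> int:
        return len(self.table)
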