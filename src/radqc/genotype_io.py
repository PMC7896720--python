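"""Reading and writing genepop files and tabular sidecars.

The genepop text format stores codominant genotypes as fixed-width
2- or 3-digit allele codes ("0102" = heterozygote 01/02), with
populations delimited by lines consisting of the word POP and the
all-zero code denoting a missing genotype. Only biallelic loci are
accepted: the pipeline is strictly SNP-based and loci with more than
two observed alleles are rejected at parse time.
"""

from __future__ import annotations

import re
from typing import Callable

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_RIVER_LOCATION,
    DEFAULT_YEAR_HISTORY,
    MISSING,
    DepthTable,
    GenotypeMatrix,
    GrowthDataset,
)


class GenepopParseError(ValueError):
    """Malformed genepop content; message carries line/column context."""


def default_pop_label_rule(first_individual_id: str) -> str:
    """Population label = prefix of the first id in a POP block.

    The prefix is everything before the last underscore; ids without an
    underscore are used whole. Genepop files differ in how sample names
    encode the population, so this rule is a replaceable default.
    """
    head, sep, _ = first_individual_id.rpartition("_")
    return head if sep else first_individual_id


def read_genepop(
    path,
    allele_digits: int = 2,
    pop_label_rule: Callable[[str], str] = default_pop_label_rule,
) -> GenotypeMatrix:
    """Parse a genepop file into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        Genepop text file: title line, locus names (one per line or a
        single comma-separated line), then POP-delimited sample blocks.
    allele_digits
        Width of one allele code, 2 or 3.
    pop_label_rule
        Maps the first individual id of each POP block to the block's
        population label.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise GenepopParseError(f"{path}: too short to be a genepop file")

    # locus names: lines after the title up to the first POP line
    first_pop = None
    for i, line in enumerate(lines[1:], start=1):
        if line.strip().upper() == "POP":
            first_pop = i
            break
    if first_pop is None:
        raise GenepopParseError(f"{path}: no POP line found")
    locus_lines = [ln.strip() for ln in lines[1:first_pop] if ln.strip()]
    locus_ids: list[str] = []
    for ln in locus_lines:
        locus_ids.extend(tok.strip() for tok in ln.split(",") if tok.strip())
    if not locus_ids:
        raise GenepopParseError(f"{path}: no locus names before first POP")

    n_loci = len(locus_ids)
    token_width = 2 * allele_digits
    token_re = re.compile(rf"^\d{{{token_width}}}$")
    missing_allele = "0" * allele_digits

    individual_ids: list[str] = []
    pop_labels: list[str] = []
    rows: list[np.ndarray] = []
    # per locus: observed allele code -> dosage index (0 for A, 1 for B)
    alleles: list[dict[str, int]] = [dict() for _ in range(n_loci)]

    current_pop: str | None = None
    for lineno, raw in enumerate(lines[first_pop:], start=first_pop + 1):
        line = raw.strip()
        if not line:
            continue
        if line.upper() == "POP":
            current_pop = None
            continue
        if "," not in line:
            raise GenepopParseError(
                f"{path}:{lineno}: sample line lacks the comma after the name"
            )
        name, _, geno_part = line.partition(",")
        name = name.strip()
        tokens = geno_part.split()
        if len(tokens) != n_loci:
            raise GenepopParseError(
                f"{path}:{lineno}: {len(tokens)} genotype tokens for {n_loci} loci"
            )
        if current_pop is None:
            current_pop = pop_label_rule(name)
        row = np.empty(n_loci, dtype=np.int8)
        for j, tok in enumerate(tokens):
            if not token_re.match(tok):
                raise GenepopParseError(
                    f"{path}:{lineno}: malformed genotype token {tok!r} "
                    f"at locus column {j + 1} ({locus_ids[j]})"
                )
            a1, a2 = tok[:allele_digits], tok[allele_digits:]
            if a1 == missing_allele or a2 == missing_allele:
                row[j] = MISSING
                continue
            seen = alleles[j]
            for a in (a1, a2):
                if a not in seen:
                    if len(seen) == 2:
                        raise GenepopParseError(
                            f"{path}:{lineno}: locus {locus_ids[j]} has more "
                            f"than 2 alleles ({sorted(seen) + [a]}); only "
                            "biallelic loci are supported"
                        )
                    seen[a] = len(seen)
            row[j] = seen[a1] + seen[a2]
        individual_ids.append(name)
        pop_labels.append(current_pop)
        rows.append(row)

    if not rows:
        raise GenepopParseError(f"{path}: no samples found")
    allele_names = []
    for j, seen in enumerate(alleles):
        codes = sorted(seen, key=seen.get)
        if len(codes) == 0:
            codes = ["0" * (allele_digits - 1) + "1", "0" * (allele_digits - 1) + "2"]
        elif len(codes) == 1:
            pad = "0" * (allele_digits - 1)
            codes.append(pad + "2" if codes[0] != pad + "2" else pad + "1")
        allele_names.append((codes[0], codes[1]))
    return GenotypeMatrix(
        individual_ids=individual_ids,
        pop_labels=pop_labels,
        locus_ids=locus_ids,
        calls=np.vstack(rows),
        allele_names=allele_names,
    )


def write_genepop(
    matrix: GenotypeMatrix, path, allele_digits: int = 2, title: str = "radqc export"
) -> None:
    """Write a matrix as genepop text; round-trips through read_genepop."""
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    if matrix.n_loci == 0:
        raise ValueError("refusing to write a matrix with no loci")
    if matrix.n_individuals == 0:
        raise ValueError("refusing to write a matrix with no individuals")
    missing_tok = "0" * (2 * allele_digits)
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in matrix.locus_ids:
            fh.write(locus + "\n")
        last_pop = None
        for i, (ind, pop) in enumerate(zip(matrix.individual_ids, matrix.pop_labels)):
            if pop != last_pop:
                fh.write("POP\n")
                last_pop = pop
            toks = []
            for j in range(matrix.n_loci):
                g = matrix.calls[i, j]
                if g == MISSING:
                    toks.append(missing_tok)
                    continue
                a, b = matrix.allele_names[j]
                a = a.zfill(allele_digits)
                b = b.zfill(allele_digits)
                toks.append({0: a + a, 1: a + b, 2: b + b}[int(g)])
            fh.write(f"{ind} ,  " + " ".join(toks) + "\n")


DEFAULT_GROWTH_COLUMN_MAP = {
    "river": "river",
    "year": "year",
    "sex": "sex",
    "age": "age",
    "length": "length",
}

_SEX_CODES = {
    "f": "female",
    "female": "female",
    "m": "male",
    "male": "male",
}


def read_growth_table(
    path,
    column_map: dict[str, str] | None = None,
    river_location: dict[str, str] | None = None,
    year_history: dict[int, str] | None = None,
    sep: str | None = None,
) -> GrowthDataset:
    """Read a delimited length-at-age table into a :class:`GrowthDataset`.

    ``column_map`` maps the canonical fields (river, year, sex, age,
    length) to the file's column names; ``river_location`` and
    ``year_history`` map rivers to north/south and sampling years to
    historical/contemporary. Defaults follow the Mistassini Lake study
    system (Takwa -> north; Chalifour, Perch, Icon -> south; 2002/2003
    historical, 2015-2017 contemporary).
    """
    column_map = {**DEFAULT_GROWTH_COLUMN_MAP, **(column_map or {})}
    river_location = river_location or DEFAULT_RIVER_LOCATION
    year_history = year_history or DEFAULT_YEAR_HISTORY

    raw = pd.read_csv(path, sep=sep, engine="python")
    for field, col in column_map.items():
        if col not in raw.columns:
            raise ValueError(f"column {col!r} (for {field}) not in {list(raw.columns)}")

    rivers = raw[column_map["river"]].astype(str)
    bad_rivers = sorted(set(rivers) - set(river_location))
    if bad_rivers:
        raise ValueError(f"unmappable river values: {bad_rivers}")

    years = pd.to_numeric(raw[column_map["year"]], errors="coerce")
    if years.isna().any():
        rows = list(raw.index[years.isna()])
        raise ValueError(f"non-numeric year at rows {rows}")
    years = years.astype(int)
    bad_years = sorted(set(years) - set(year_history))
    if bad_years:
        raise ValueError(f"unmappable year values: {bad_years}")

    sex_raw = raw[column_map["sex"]].astype(str).str.strip().str.lower()
    bad_sex = sorted(set(sex_raw) - set(_SEX_CODES))
    if bad_sex:
        raise ValueError(f"unmappable sex codes: {bad_sex}")

    for field in ("age", "length"):
        vals = pd.to_numeric(raw[column_map[field]], errors="coerce")
        if vals.isna().any():
            rows = list(raw.index[vals.isna()])
            raise ValueError(f"non-numeric {field} at rows {rows}")

    table = pd.DataFrame(
        {
            "river": rivers.values,
            "location": rivers.map(river_location).values,
            "history": years.map(year_history).values,
            "sex": sex_raw.map(_SEX_CODES).values,
            "age": pd.to_numeric(raw[column_map["age"]]).astype(int).values,
            "length": pd.to_numeric(raw[column_map["length"]]).astype(float).values,
        }
    )
    return GrowthDataset(table)


def read_depth_table(path, sep: str = "\t") -> DepthTable:
    """Read a headered TSV of per-genotype allele depths."""
    t = pd.read_csv(path, sep=sep)
    return DepthTable(t)


def write_depth_table(depths: DepthTable, path, sep: str = "\t") -> None:
    depths.table.to_csv(path, sep=sep, index=False)


def write_growth_table(data: GrowthDataset, path) -> None:
    data.table.to_csv(path, index=False)
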