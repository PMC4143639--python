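"""Readers/writers for the GAW18-dialect cohort CSVs and the shared in-memory data model.

A cohort is two tables:

* a longitudinal **phenotype table** — one row per individual x exam with the
  binary hypertension outcome (HTN), systolic/diastolic blood pressure (mm Hg),
  and covariates (age, sex, smoking, parental hypertension, pedigree label);
* a **genotype matrix** — individuals x SNPs, each cell a diploid genotype
  token such as ``"CC"``/``"TC"``/``"TT"``, with ``"XX"`` denoting a missing
  call.  Each SNP admits at most four distinct tokens (three genotypes plus
  the missing category).

Genotype tokens are kept as strings at ingest; every numeric coding (allele
dose, genotype indicators, carrier flags) is derived downstream, because the
category-collapsing and carrier logic operate on genotype categories.

Column headers are configurable through a *dialect* mapping because upstream
files name their columns inconsistently; the default dialect is
:data:`DEFAULT_DIALECT`.
"""

from __future__ import annotations

import os
import csv
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_DIALECT",
    "MISSING_TOKEN",
    "PHENO_COLUMNS",
    "DialectError",
    "CohortFormatError",
    "Cohort",
    "read_phenotypes",
    "read_genotypes",
    "write_phenotypes",
    "write_genotypes",
    "write_cohort",
    "read_cohort",
    "check_htn_consistency",
    "genotype_rows",
]

#: token marking a missing genotype call
MISSING_TOKEN = "XX"

#: canonical (logical) phenotype column names, in file order
PHENO_COLUMNS = [
    "individual_id",
    "exam_index",
    "htn",
    "sbp",
    "dbp",
    "age",
    "sex",
    "smoke",
    "mother_htn",
    "father_htn",
    "pedigree_id",
]

#: default mapping logical name -> file header
DEFAULT_DIALECT: dict[str, str] = {
    "individual_id": "ID",
    "exam_index": "EXAM",
    "htn": "HTN",
    "sbp": "SBP",
    "dbp": "DBP",
    "age": "AGE",
    "sex": "SEX",
    "smoke": "SMOKE",
    "mother_htn": "MOTHER",
    "father_htn": "FATHER",
    "pedigree_id": "PEDIGREE",
}

_BINARY_COLUMNS = ("htn", "sex", "smoke", "mother_htn", "father_htn")
_REAL_COLUMNS = ("sbp", "dbp", "age")
_TRUE_TOKENS = {"1", "yes", "y", "true"}
_FALSE_TOKENS = {"0", "no", "n", "false"}


class DialectError(ValueError):
    """A required column is absent from the file header."""


class CohortFormatError(ValueError):
    """A cell or the file layout violates the cohort format."""


@dataclass
class Cohort:
    """Phenotype table plus genotype matrix for one set of individuals.

    ``phenotypes`` holds canonical columns (:data:`PHENO_COLUMNS`);
    ``genotypes`` is indexed by individual id with one string column per SNP.
    """

    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame

    @property
    def individual_ids(self) -> list[str]:
        return list(self.genotypes.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_rows(self) -> int:
        """Number of stacked individual x exam observations."""
        return len(self.phenotypes)

    def validate(self) -> None:
        pheno_ids = set(self.phenotypes["individual_id"])
        geno_ids = set(self.genotypes.index)
        if pheno_ids != geno_ids:
            missing = sorted(pheno_ids ^ geno_ids)[:5]
            raise CohortFormatError(
                f"phenotype/genotype individual ids disagree (e.g. {missing})"
            )
        dup = self.phenotypes.duplicated(subset=["individual_id", "exam_index"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise CohortFormatError(
                f"duplicate (individual, exam) pair at phenotype row {row + 1}"
            )


def _coerce_binary(token: str, column: str, row: int) -> int:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return 1
    if low in _FALSE_TOKENS:
        return 0
    raise CohortFormatError(
        f"cannot parse {column!r}={token!r} as binary at data row {row}"
    )


def check_htn_consistency(pheno: pd.DataFrame) -> pd.DataFrame:
    """Rows whose HTN flag disagrees with the blood-pressure rule.

    The definition is HTN = 1 exactly when SBP > 140 mm Hg or DBP > 90 mm Hg.
    Real-dialect files may deviate from it, so mismatches are reported, not
    rejected.
    """
    implied = ((pheno["sbp"] > 140) | (pheno["dbp"] > 90)).astype(int)
    return pheno.loc[implied != pheno["htn"]]


def read_phenotypes(
    path: str | os.PathLike,
    dialect: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a longitudinal phenotype CSV into canonical columns.

    Parameters
    ----------
    path
        CSV file with a header row.
    dialect
        Partial override of :data:`DEFAULT_DIALECT` (logical name -> header).

    Row order is preserved.  Missing cells are rejected: the simulated-cohort
    phenotype replicates are complete by construction, and silent imputation
    would corrupt the stacked-exam analysis downstream.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise DialectError(f"unknown dialect keys: {sorted(unknown)}")
        mapping.update(dialect)

    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    for logical, header in mapping.items():
        if header not in raw.columns:
            raise DialectError(
                f"phenotype file is missing column {header!r} (maps to {logical!r})"
            )

    out: dict[str, list] = {c: [] for c in PHENO_COLUMNS}
    for i, rec in enumerate(raw.itertuples(index=False), start=1):
        row = dict(zip(raw.columns, rec))
        for logical in PHENO_COLUMNS:
            token = str(row[mapping[logical]]).strip()
            if token == "":
                raise CohortFormatError(
                    f"missing value for {mapping[logical]!r} at data row {i}"
                )
            if logical in _BINARY_COLUMNS:
                out[logical].append(_coerce_binary(token, mapping[logical], i))
            elif logical in _REAL_COLUMNS:
                try:
                    value = float(token)
                except ValueError as exc:
                    raise CohortFormatError(
                        f"cannot parse {mapping[logical]!r}={token!r} at data row {i}"
                    ) from exc
                if value <= 0:
                    raise CohortFormatError(
                        f"{mapping[logical]!r} must be positive at data row {i}"
                    )
                out[logical].append(value)
            elif logical == "exam_index":
                try:
                    out[logical].append(int(token))
                except ValueError as exc:
                    raise CohortFormatError(
                        f"cannot parse {mapping[logical]!r}={token!r} at data row {i}"
                    ) from exc
            else:
                out[logical].append(token)

    pheno = pd.DataFrame(out, columns=PHENO_COLUMNS)
    dup = pheno.duplicated(subset=["individual_id", "exam_index"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise CohortFormatError(
            f"repeated exam_index for one individual at data row {row + 1}"
        )
    mismatches = check_htn_consistency(pheno)
    if len(mismatches):
        warnings.warn(
            f"{len(mismatches)} phenotype rows violate the HTN/blood-pressure rule "
            "(SBP > 140 or DBP > 90 iff HTN = 1); kept as read",
            stacklevel=2,
        )
    return pheno


def read_genotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genotype CSV (first column = individual id, rest = SNP ids).

    The per-SNP alphabet is inferred from the data; ``"XX"`` is always an
    admissible (missing) token.  More than four distinct tokens for one SNP,
    ragged rows, or duplicated individual/SNP ids are format errors.
    """
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise CohortFormatError("empty genotype file")
    header = rows[0]
    if len(header) < 2:
        raise CohortFormatError("genotype file needs an id column plus >=1 SNP column")
    snp_ids = [h.strip() for h in header[1:]]
    if len(set(snp_ids)) != len(snp_ids):
        raise CohortFormatError("duplicated SNP id in genotype header")

    width = len(header)
    ids: list[str] = []
    data: list[list[str]] = []
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != width:
            raise CohortFormatError(f"ragged genotype row {i}: {len(row)} != {width} cells")
        ids.append(row[0].strip())
        data.append([c.strip() for c in row[1:]])
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for i, ind in enumerate(ids, start=1):
            if ind in seen:
                raise CohortFormatError(f"duplicated individual id {ind!r} at row {i}")
            seen.add(ind)

    geno = pd.DataFrame(data, index=pd.Index(ids, name="individual_id"), columns=snp_ids)
    for snp in snp_ids:
        tokens = set(geno[snp].unique())
        if len(tokens - {MISSING_TOKEN}) > 3 or len(tokens) > 4:
            raise CohortFormatError(
                f"SNP {snp!r} has {len(tokens)} distinct tokens (max 4 incl. {MISSING_TOKEN!r})"
            )
    return geno


def write_phenotypes(
    pheno: pd.DataFrame,
    path: str | os.PathLike,
    dialect: Mapping[str, str] | None = None,
) -> None:
    if len(pheno) == 0:
        raise CohortFormatError("refusing to write an empty phenotype table")
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    out = pheno[PHENO_COLUMNS].rename(columns=mapping)
    out.to_csv(path, index=False)


def write_genotypes(geno: pd.DataFrame, path: str | os.PathLike) -> None:
    if geno.shape[0] == 0 or geno.shape[1] == 0:
        raise CohortFormatError("refusing to write an empty genotype matrix")
    geno.to_csv(path, index_label="ID")


def write_cohort(
    cohort: Cohort,
    directory: str | os.PathLike,
    prefix: str = "cohort",
) -> tuple[str, str]:
    """Write ``<prefix>.phenotypes.csv`` and ``<prefix>.genotypes.csv``; return the paths."""
    cohort.validate()
    os.makedirs(directory, exist_ok=True)
    ppath = os.path.join(directory, f"{prefix}.phenotypes.csv")
    gpath = os.path.join(directory, f"{prefix}.genotypes.csv")
    write_phenotypes(cohort.phenotypes, ppath)
    write_genotypes(cohort.genotypes, gpath)
    return ppath, gpath


def read_cohort(
    phenotype_path: str | os.PathLike,
    genotype_path: str | os.PathLike,
    dialect: Mapping[str, str] | None = None,
) -> Cohort:
    cohort = Cohort(
        phenotypes=read_phenotypes(phenotype_path, dialect=dialect),
        genotypes=read_genotypes(genotype_path),
    )
    cohort.validate()
    return cohort


def genotype_rows(cohort: Cohort, snp_id: str) -> np.ndarray:
    """Genotype tokens for one SNP, aligned with the stacked phenotype rows."""
    calls = cohort.genotypes[snp_id]
    return calls.reindex(cohort.phenotypes["individual_id"]).to_numpy()
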