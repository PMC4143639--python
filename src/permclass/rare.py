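"""Rare-variant screening: MAF filtering, carrier tables, chi-square tests.

A SNP counts as a rare variant when its minor **allele** frequency over the
whole study group is strictly below 5% (missing ``XX`` calls excluded from
the allele counts).  Screening then works on the genotype scale: the least
frequent non-missing genotype category defines the *carrier* group, and a
2 x 2 carrier vs non-carrier table against hypertension status is scored with
a Yates-corrected Pearson chi-square.  Larger (2 x k) genotype-frequency
tables are scored without the continuity correction — applying Yates only to
2 x 2 tables is what recovers the published reference p-values the test suite
pins (0.0011 for a 2 x 3 table; 4.06e-12 / 2.64e-10 for the carrier tables).

Tables count the stacked individual x exam rows, matching how the logistic
stage treats repeated exams as separate observations.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_gaw import MISSING_TOKEN, Cohort

__all__ = [
    "RARE_MAF_THRESHOLD",
    "minor_allele_frequency",
    "rare_flag",
    "genotype_htn_table",
    "carrier_table",
    "chi_square_test",
    "rare_screen",
]

logger = logging.getLogger(__name__)

#: strict upper bound on minor allele frequency for the rare-variant screen
RARE_MAF_THRESHOLD = 0.05


def minor_allele_frequency(tokens: np.ndarray) -> float:
    """Minor allele frequency from diploid genotype tokens.

    Alleles are the individual characters of each non-missing token; MAF is
    the smaller allele count over the total allele count.  Monomorphic
    columns (or columns with no non-missing call) return 0.0.
    """
    counts: Counter[str] = Counter()
    for tok in tokens:
        if tok == MISSING_TOKEN:
            continue
        if len(tok) != 2:
            raise ValueError(f"genotype token {tok!r} is not diploid")
        counts.update(tok)
    if len(counts) <= 1:
        return 0.0
    total = sum(counts.values())
    return min(counts.values()) / total


def rare_flag(tokens: np.ndarray) -> bool:
    """True iff the SNP's MAF is strictly below the 5% rare-variant bound."""
    return minor_allele_frequency(tokens) < RARE_MAF_THRESHOLD


def genotype_htn_table(tokens: np.ndarray, htn: np.ndarray) -> pd.DataFrame:
    """2 x k frequency table of HTN status (rows 0/1) by genotype category.

    Columns are ordered by genotype frequency (descending, ties by token),
    which puts the common homozygote first and ``XX`` last in typical data.
    """
    tokens = np.asarray(tokens)
    htn = np.asarray(htn).astype(int)
    counts = Counter(tokens)
    cols = sorted(counts, key=lambda t: (-counts[t], t))
    table = pd.DataFrame(
        0, index=pd.Index([0, 1], name="htn"), columns=cols, dtype=int
    )
    for status in (0, 1):
        sub = Counter(tokens[htn == status])
        for tok in cols:
            table.loc[status, tok] = sub.get(tok, 0)
    return table


def carrier_table(
    tokens: np.ndarray,
    htn: np.ndarray,
    rare_token: str | Sequence[str],
) -> pd.DataFrame | None:
    """2 x 2 table of HTN by carrier status of a rare genotype category.

    Rows are HTN 0/1; columns are the rare genotype category vs all other
    non-missing genotypes (``XX`` rows excluded).  ``rare_token`` may be a
    single genotype token (the published table layout) or a collection of
    tokens forming one carrier category.  Degenerate tables — zero carriers,
    or every non-missing call a carrier — cannot be tested; ``None`` is
    returned and the caller treats the test as skipped (p = 1).
    """
    tokens = np.asarray(tokens)
    htn = np.asarray(htn).astype(int)
    keep = tokens != MISSING_TOKEN
    tokens, htn = tokens[keep], htn[keep]
    if isinstance(rare_token, str):
        carrier = tokens == rare_token
    else:
        carrier = np.isin(tokens, list(rare_token))
        rare_token = "/".join(rare_token)
    if carrier.sum() == 0 or carrier.all():
        logger.info("degenerate carrier table for token %r; test skipped", rare_token)
        return None
    table = pd.DataFrame(
        {
            rare_token: [int(((htn == 0) & carrier).sum()), int(((htn == 1) & carrier).sum())],
            f"non-{rare_token}": [
                int(((htn == 0) & ~carrier).sum()),
                int(((htn == 1) & ~carrier).sum()),
            ],
        },
        index=pd.Index([0, 1], name="htn"),
    )
    return table


def chi_square_test(table: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of a 2 x k contingency table.

    The Yates continuity correction is applied iff the table is 2 x 2.
    Returns ``(statistic, df, p_value)``.  Tables without at least two
    nonzero rows and columns are an error.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (counts < 0).any():
        raise ValueError("contingency table has negative counts")
    if (counts.sum(axis=1) > 0).sum() < 2 or (counts.sum(axis=0) > 0).sum() < 2:
        raise ValueError("contingency table needs >=2 nonzero rows and columns")
    correction = counts.shape == (2, 2)
    result = stats.chi2_contingency(counts, correction=correction)
    return float(result.statistic), int(result.dof), float(result.pvalue)


@dataclass
class RareVariantHit:
    """One screened rare variant: its carrier genotype, table and p-value."""

    snp_id: str
    rare_genotype: str
    maf: float
    table: pd.DataFrame | None
    statistic: float
    p_value: float


def _carrier_tokens(tokens: np.ndarray) -> list[str]:
    """Genotype tokens carrying the minor allele, most frequent first.

    The carrier category of a rare SNP: every observed genotype containing
    the minor allele (for a MAF < 5% SNP this is the heterozygote and, where
    present, the rare homozygote).  When only one carrier genotype is
    observed this reduces to the single-token published table layout.
    """
    allele_counts: Counter[str] = Counter()
    geno_counts: Counter[str] = Counter()
    for tok in tokens:
        if tok == MISSING_TOKEN:
            continue
        allele_counts.update(tok)
        geno_counts[tok] += 1
    minor = min(allele_counts, key=lambda a: (allele_counts[a], a))
    carriers = [t for t in geno_counts if minor in t]
    return sorted(carriers, key=lambda t: (-geno_counts[t], t))


def rare_screen(cohort: Cohort) -> pd.DataFrame:
    """Screen every rare SNP (MAF < 5%) for carrier association with HTN.

    For each rare SNP the genotypes carrying the minor allele define the
    carrier group.  Perfect-duplicate carrier vectors are collapsed keeping
    the first SNP in column order, so the ranked list contains non-identical
    variants only.  Returns a frame sorted by ascending p-value (ties by
    column order) with the 2 x 2 cell counts ``a``/``b`` (HTN=0: carrier,
    non-carrier) and ``c``/``d`` (HTN=1).
    """
    htn = cohort.phenotypes["htn"].to_numpy(int)
    geno = cohort.genotypes.reindex(cohort.phenotypes["individual_id"])
    rows = []
    seen_carriers: set[bytes] = set()
    for order, snp in enumerate(cohort.snp_ids):
        tokens = geno[snp].to_numpy()
        maf = minor_allele_frequency(tokens)
        if not maf < RARE_MAF_THRESHOLD or maf == 0.0:
            continue
        counts = Counter(t for t in tokens if t != MISSING_TOKEN)
        if len(counts) <= 1:
            continue
        rare_token = _carrier_tokens(tokens)
        carrier_vec = np.isin(tokens, rare_token).tobytes()
        if carrier_vec in seen_carriers:
            logger.info("SNP %s duplicates an earlier carrier vector; collapsed", snp)
            continue
        seen_carriers.add(carrier_vec)
        table = carrier_table(tokens, htn, rare_token)
        if table is None:
            stat, p = float("nan"), 1.0
            a = b = c = d = 0
        else:
            stat, _, p = chi_square_test(table)
            a, b = int(table.iloc[0, 0]), int(table.iloc[0, 1])
            c, d = int(table.iloc[1, 0]), int(table.iloc[1, 1])
        rows.append((snp, "/".join(rare_token), maf, a, b, c, d, stat, p, order))

    hits = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "rare_genotype", "maf",
            "a", "b", "c", "d", "statistic", "p_value", "_order",
        ],
    )
    hits = hits.sort_values(["p_value", "_order"], kind="stable").drop(columns="_order")
    return hits.reset_index(drop=True)
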