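"""Design-matrix construction shared by the association scan and the classifiers.

The covariate part of every model is the fixed term set

    Smoke + Age + Sex + Age x Sex + Mother + Father + Pedigree

with the pedigree label expanded to indicator contrasts against its most
frequent level.  Category orders are fixed by frequency (descending), ties
broken by token order, so term expansion is deterministic given the data the
encoder was fitted on.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ordered_levels", "CovariateEncoder", "genotype_indicators"]


def ordered_levels(tokens: Sequence) -> list:
    """Distinct values ordered by frequency (desc), ties by token order (asc)."""
    counts = Counter(tokens)
    return sorted(counts, key=lambda t: (-counts[t], str(t)))


class CovariateEncoder:
    """Expand the phenotype table into the baseline numeric design.

    Fit on training data only; ``transform`` maps a pedigree level unseen at
    fit time to the reference (all indicator columns zero).
    """

    def __init__(self) -> None:
        self.pedigree_levels_: list[str] | None = None

    def fit(self, pheno: pd.DataFrame) -> "CovariateEncoder":
        self.pedigree_levels_ = ordered_levels(pheno["pedigree_id"])
        return self

    @property
    def columns(self) -> list[str]:
        if self.pedigree_levels_ is None:
            raise RuntimeError("CovariateEncoder is not fitted")
        ped = [f"pedigree[{lvl}]" for lvl in self.pedigree_levels_[1:]]
        return ["const", "smoke", "age", "sex", "age_sex", "mother_htn", "father_htn", *ped]

    def transform(self, pheno: pd.DataFrame, include_const: bool = True) -> pd.DataFrame:
        if self.pedigree_levels_ is None:
            raise RuntimeError("CovariateEncoder is not fitted")
        n = len(pheno)
        cols: dict[str, np.ndarray] = {}
        if include_const:
            cols["const"] = np.ones(n)
        cols["smoke"] = pheno["smoke"].to_numpy(float)
        cols["age"] = pheno["age"].to_numpy(float)
        cols["sex"] = pheno["sex"].to_numpy(float)
        cols["age_sex"] = cols["age"] * cols["sex"]
        cols["mother_htn"] = pheno["mother_htn"].to_numpy(float)
        cols["father_htn"] = pheno["father_htn"].to_numpy(float)
        ped = pheno["pedigree_id"].to_numpy()
        for lvl in self.pedigree_levels_[1:]:  # reference = most frequent level
            cols[f"pedigree[{lvl}]"] = (ped == lvl).astype(float)
        return pd.DataFrame(cols, index=pheno.index)

    def fit_transform(self, pheno: pd.DataFrame, **kw) -> pd.DataFrame:
        return self.fit(pheno).transform(pheno, **kw)


def genotype_indicators(
    tokens: np.ndarray,
    snp_id: str,
    levels: list | None = None,
) -> tuple[pd.DataFrame, str]:
    """Indicator columns for a genotype factor, reference = most frequent token.

    The missing token ``"XX"`` is treated as a genotype level of its own.
    Returns the indicator frame (one column per non-reference level, named
    ``snp[token]``) and the reference token.
    """
    if levels is None:
        levels = ordered_levels(tokens)
    reference = levels[0]
    cols = {
        f"{snp_id}[{tok}]": (tokens == tok).astype(float) for tok in levels[1:]
    }
    return pd.DataFrame(cols), reference
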