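"""Synthetic pedigree-cohort generator.

Emulates the statistical structure the downstream analysis consumes: ~20
pedigrees of a few hundred individuals, three exams per individual with
time-varying age and smoking, a genotype matrix with a minor-allele-frequency
spectrum that includes forced-rare SNPs (<5%), planted LD structure (noisy
copies and exactly duplicated columns), Hardy-Weinberg founders with
Mendelian transmission to offspring, and a hypertension phenotype generated
by a logistic model on the covariates plus a handful of causal SNPs.  Blood
pressures are then drawn from truncated normals on the correct side of the
140/90 mm Hg thresholds, so HTN = 1 iff SBP > 140 or DBP > 90 holds exactly
on every generated record.

Key generative choices (see docs/methods.md for rationale):

* Pedigrees are a founder couple plus full-sib offspring; kinship realism
  beyond the pedigree label is deliberately out of scope because the models
  downstream use Pedigree only as a categorical covariate.
* Causal-SNP doses and rare-carrier indicators enter the linear predictor
  centered at their expectation, so the intercept alone controls prevalence.
* Truncated-normal blood-pressure means are shifted by the individual's
  linear predictor, so SNPs with hypertension effects also leave a
  quantitative trace in SBP/DBP.
* Duplicate and LD-copy columns are sourced from non-causal SNPs so the
  truth sidecar's causal labels stay unambiguous for recovery benchmarks.
* All randomness flows from one root seed through named
  ``numpy.random.SeedSequence`` spawns: one stream for genotypes, one for
  static covariates, one per phenotype replicate.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io_gaw import MISSING_TOKEN, Cohort

__all__ = [
    "CovariateEffects",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_cohort",
    "simulate_replicates",
    "write_truth",
]

_ALLELES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CovariateEffects:
    """Log-odds contributions of the baseline covariates.

    ``age`` is per year of age centered at 50; ``age_sex`` is the extra
    per-year slope for sex = 1.
    """

    smoke: float = 0.6
    age: float = 0.04
    sex: float = 0.3
    age_sex: float = 0.02
    mother: float = 0.8
    father: float = 0.8


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_individuals: int = 400
    n_pedigrees: int = 20
    n_exams: int = 3
    n_snps: int = 500
    # causal common SNPs: additive per-minor-allele log-odds, MAF kept common
    n_causal: int = 5
    causal_log_odds: float | Sequence[float] = 1.0
    causal_maf_range: tuple[float, float] = (0.2, 0.5)
    # planted rare risk variants: carrier (dose >= 1) log-odds
    n_rare_causal: int = 1
    rare_carrier_log_odds: float = 2.0
    rare_causal_maf_range: tuple[float, float] = (0.02, 0.04)
    # MAF spectrum of the remaining SNPs
    maf_rare_fraction: float = 0.2
    maf_rare_range: tuple[float, float] = (0.005, 0.05)
    maf_common_range: tuple[float, float] = (0.05, 0.5)
    # planted LD structure
    n_ld_tagged: int = 5
    ld_block_size: int = 1
    ld_noise: float = 0.05
    n_perfect_duplicates: int = 3
    missing_rate: float = 0.005
    # phenotype model
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    pedigree_sd: float = 0.3
    intercept: float = -1.8
    parent_htn_rate: float = 0.3
    bp_coupling: float = 4.0
    # covariate dynamics
    smoke_rate: float = 0.25
    smoke_flip_rate: float = 0.05
    age_range: tuple[float, float] = (25.0, 70.0)
    age_step: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_causal + self.n_rare_causal > self.n_snps:
            raise ValueError("more causal SNPs than SNPs")
        if not 1 <= self.n_pedigrees <= self.n_individuals:
            raise ValueError("need 1 <= n_pedigrees <= n_individuals")
        for name in ("maf_rare_fraction", "ld_noise", "missing_rate",
                     "smoke_rate", "smoke_flip_rate", "parent_htn_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_exams < 1:
            raise ValueError("n_exams must be >= 1")

    def causal_effects(self) -> np.ndarray:
        if np.isscalar(self.causal_log_odds):
            return np.full(self.n_causal, float(self.causal_log_odds))
        eff = np.asarray(self.causal_log_odds, dtype=float)
        if eff.shape != (self.n_causal,):
            raise ValueError("causal_log_odds length must equal n_causal")
        return eff


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside a simulated cohort."""

    causal_snp_ids: list[str]
    rare_causal_snp_ids: list[str]
    duplicate_groups: list[list[str]]  # perfect (token-identical) copies
    ld_groups: list[list[str]]  # noisy LD copies
    maf: dict[str, float]
    linear_predictors: pd.DataFrame  # individual_id, exam_index, lp

    @property
    def expected_prevalence(self) -> float:
        """Mean of sigmoid(lp) over all individual x exam records."""
        lp = self.linear_predictors["lp"].to_numpy()
        return float(np.mean(1.0 / (1.0 + np.exp(-lp))))


# ---------------------------------------------------------------------------
# static structure: pedigrees, genotypes, covariates


def _pedigree_structure(cfg: SimulationConfig) -> pd.DataFrame:
    """Assign individuals to pedigrees built from nuclear families.

    Each pedigree is filled with founder couples and two full-sib offspring
    per couple (extended pedigrees are mostly marry-in founders plus small
    sibships; a single giant sibship would let one founder's rare allele
    dominate the pedigree).  Leftover slots become extra founders.
    """
    sizes = np.full(cfg.n_pedigrees, cfg.n_individuals // cfg.n_pedigrees)
    sizes[: cfg.n_individuals % cfg.n_pedigrees] += 1
    rows = []
    ind = 0
    for ped in range(cfg.n_pedigrees):
        ped_id = f"ped{ped + 1:02d}"
        remaining = int(sizes[ped])
        while remaining > 0:
            family = min(4, remaining)  # father, mother, up to 2 offspring
            father = mother = -1
            for k in range(family):
                role = "founder" if k < 2 else "offspring"
                if k == 0:
                    father = ind
                elif k == 1:
                    mother = ind
                rows.append(
                    {
                        "index": ind,
                        "individual_id": f"ind{ind + 1:04d}",
                        "pedigree_id": ped_id,
                        "role": role,
                        "father_index": father if k >= 2 else -1,
                        "mother_index": mother if k >= 2 else -1,
                    }
                )
                ind += 1
            remaining -= family
    return pd.DataFrame(rows)


def _draw_mafs(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MAF per base SNP plus the causal index sets (common, rare)."""
    n = cfg.n_snps
    picked = rng.choice(n, size=cfg.n_causal + cfg.n_rare_causal, replace=False)
    causal_idx = np.sort(picked[: cfg.n_causal])
    rare_causal_idx = np.sort(picked[cfg.n_causal:])
    mafs = rng.uniform(*cfg.maf_common_range, size=n)
    n_rare = int(round(cfg.maf_rare_fraction * n))
    non_causal = np.setdiff1d(np.arange(n), picked)
    n_rare_other = max(0, n_rare - cfg.n_rare_causal)
    if n_rare_other > len(non_causal):
        n_rare_other = len(non_causal)
    rare_idx = rng.choice(non_causal, size=n_rare_other, replace=False)
    mafs[rare_idx] = rng.uniform(*cfg.maf_rare_range, size=n_rare_other)
    mafs[causal_idx] = rng.uniform(*cfg.causal_maf_range, size=cfg.n_causal)
    mafs[rare_causal_idx] = rng.uniform(*cfg.rare_causal_maf_range, size=cfg.n_rare_causal)
    return mafs, causal_idx, rare_causal_idx


def _mendelian_doses(
    cfg: SimulationConfig,
    ped: pd.DataFrame,
    mafs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_individuals x n_snps) minor-allele doses: Hardy-Weinberg founders,
    one Mendelian allele draw from each parent for offspring."""
    n_ind, n_snp = cfg.n_individuals, len(mafs)
    dose = np.zeros((n_ind, n_snp), dtype=np.int8)
    is_founder = (ped["role"] == "founder").to_numpy()
    founder_rows = np.flatnonzero(is_founder)
    dose[founder_rows] = rng.binomial(
        2, mafs[None, :], size=(len(founder_rows), n_snp)
    ).astype(np.int8)
    for row in ped.itertuples(index=False):
        if row.role != "offspring":
            continue
        pf = dose[row.father_index].astype(float) / 2.0
        pm = dose[row.mother_index].astype(float) / 2.0
        dose[row.index] = (
            rng.random(n_snp) < pf
        ).astype(np.int8) + (rng.random(n_snp) < pm).astype(np.int8)
    return dose


def _genotype_frame(
    cfg: SimulationConfig,
    ped: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray, SimulationTruth]:
    """Genotype tokens, causal dose matrix and (partial) truth."""
    mafs, causal_idx, rare_causal_idx = _draw_mafs(cfg, rng)
    dose = _mendelian_doses(cfg, ped, mafs, rng)
    snp_ids = [f"snp{j + 1:04d}" for j in range(cfg.n_snps)]

    reserved = set(causal_idx) | set(rare_causal_idx)
    free = np.array(sorted(set(range(cfg.n_snps)) - reserved))

    # noisy LD copies of tagged (non-causal) SNPs
    ld_groups: list[list[str]] = []
    extra_cols: list[np.ndarray] = []
    extra_ids: list[str] = []
    extra_maf: list[float] = []
    n_tag = min(cfg.n_ld_tagged, len(free))
    tagged = rng.choice(free, size=n_tag, replace=False) if n_tag else np.array([], int)
    for tag in tagged:
        group = [snp_ids[tag]]
        for k in range(cfg.ld_block_size):
            copy = dose[:, tag].copy()
            noisy = rng.random(cfg.n_individuals) < cfg.ld_noise
            copy[noisy] = rng.binomial(2, mafs[tag], size=int(noisy.sum())).astype(np.int8)
            cid = f"{snp_ids[tag]}_ld{k + 1}"
            group.append(cid)
            extra_cols.append(copy)
            extra_ids.append(cid)
            extra_maf.append(mafs[tag])
        if cfg.ld_block_size:
            ld_groups.append(group)

    all_dose = np.column_stack([dose] + [c[:, None] for c in extra_cols]) if extra_cols else dose
    all_ids = snp_ids + extra_ids
    all_maf = np.concatenate([mafs, np.array(extra_maf)]) if extra_maf else mafs

    # tokens: hom-major "MM", het "mM" (minor first, e.g. "TC"), hom-minor "mm"
    letters = np.empty((len(all_ids), 2), dtype="<U1")
    for j in range(len(all_ids)):
        letters[j] = rng.choice(_ALLELES, size=2, replace=False)
    tokens = np.empty((cfg.n_individuals, len(all_ids)), dtype="<U2")
    for j in range(len(all_ids)):
        major, minor = letters[j]
        lut = np.array([major + major, minor + major, minor + minor])
        tokens[:, j] = lut[all_dose[:, j]]
    if cfg.missing_rate > 0:
        miss = rng.random(tokens.shape) < cfg.missing_rate
        tokens[miss] = MISSING_TOKEN

    # exactly duplicated columns (token-identical, appended last)
    dup_groups: list[list[str]] = []
    n_dup = min(cfg.n_perfect_duplicates, len(free) - n_tag)
    dup_pool = np.setdiff1d(free, tagged)
    dup_src = rng.choice(dup_pool, size=n_dup, replace=False) if n_dup > 0 else np.array([], int)
    dup_tokens = []
    for src in dup_src:
        cid = f"{snp_ids[src]}_dup"
        dup_groups.append([snp_ids[src], cid])
        dup_tokens.append(tokens[:, src])
        all_ids = all_ids + [cid]
        all_maf = np.append(all_maf, mafs[src])
    if dup_tokens:
        tokens = np.column_stack([tokens] + [t[:, None] for t in dup_tokens])

    geno = pd.DataFrame(
        tokens,
        index=pd.Index(ped["individual_id"], name="individual_id"),
        columns=all_ids,
    )
    truth = SimulationTruth(
        causal_snp_ids=[snp_ids[j] for j in causal_idx],
        rare_causal_snp_ids=[snp_ids[j] for j in rare_causal_idx],
        duplicate_groups=dup_groups,
        ld_groups=ld_groups,
        maf=dict(zip(all_ids, all_maf.astype(float))),
        linear_predictors=pd.DataFrame(),
    )
    causal_dose = dose[:, causal_idx].astype(float)
    rare_carrier = (dose[:, rare_causal_idx] >= 1).astype(float)
    causal_block = np.column_stack([causal_dose, rare_carrier]) if dose.size else causal_dose
    # expectations used for centering
    exp_dose = 2.0 * mafs[causal_idx]
    exp_carrier = 1.0 - (1.0 - mafs[rare_causal_idx]) ** 2
    centered = causal_block - np.concatenate([exp_dose, exp_carrier])[None, :]
    effects = np.concatenate(
        [cfg.causal_effects(), np.full(cfg.n_rare_causal, cfg.rare_carrier_log_odds)]
    )
    truth_genetic_lp = centered @ effects  # per-individual genetic contribution

    if cfg.n_rare_causal and (rare_carrier.sum(axis=0) == 0).any():
        warnings.warn(
            "a planted rare variant has no carriers at this sample size",
            stacklevel=3,
        )
    return geno, truth_genetic_lp, truth


def _static_covariates(
    cfg: SimulationConfig,
    ped: pd.DataFrame,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Covariates held fixed across phenotype replicates."""
    n = cfg.n_individuals
    sex = rng.integers(0, 2, size=n).astype(np.int8)
    is_father = (ped["role"] == "founder") & (ped["index"].isin(ped["father_index"]))
    is_mother = (ped["role"] == "founder") & (ped["index"].isin(ped["mother_index"]))
    sex[is_father.to_numpy()] = 1
    sex[is_mother.to_numpy()] = 0
    age1 = rng.uniform(*cfg.age_range, size=n)
    ages = age1[:, None] + cfg.age_step * np.arange(cfg.n_exams)[None, :]
    smoke = np.zeros((n, cfg.n_exams), dtype=np.int8)
    smoke[:, 0] = rng.random(n) < cfg.smoke_rate
    for e in range(1, cfg.n_exams):
        flip = rng.random(n) < cfg.smoke_flip_rate
        smoke[:, e] = np.where(flip, 1 - smoke[:, e - 1], smoke[:, e - 1])
    ped_ids = sorted(ped["pedigree_id"].unique())
    ped_int = dict(zip(ped_ids, rng.normal(0.0, cfg.pedigree_sd, size=len(ped_ids))))
    return {
        "sex": sex,
        "ages": ages,
        "smoke": smoke,
        "ped_intercepts": np.array([ped_int[p] for p in ped["pedigree_id"]]),
    }


# ---------------------------------------------------------------------------
# phenotype replicates


def _truncnorm_draw(
    rng: np.random.Generator,
    lower: float,
    upper: float,
    loc: np.ndarray,
    scale: float,
) -> np.ndarray:
    a = (lower - loc) / scale
    b = (upper - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng)


def _draw_phenotypes(
    cfg: SimulationConfig,
    ped: pd.DataFrame,
    static: dict[str, np.ndarray],
    genetic_lp: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One phenotype replicate; returns (phenotype table, linear predictors)."""
    n, n_exams = cfg.n_individuals, cfg.n_exams
    eff = cfg.covariate_effects

    mother_flag = np.zeros(n, dtype=np.int8)
    father_flag = np.zeros(n, dtype=np.int8)
    founder_mask = (ped["role"] == "founder").to_numpy()
    mother_flag[founder_mask] = rng.random(founder_mask.sum()) < cfg.parent_htn_rate
    father_flag[founder_mask] = rng.random(founder_mask.sum()) < cfg.parent_htn_rate

    def lin_pred(idx: np.ndarray) -> np.ndarray:
        """(len(idx) x n_exams) linear predictor."""
        age_c = static["ages"][idx] - 50.0
        sex = static["sex"][idx][:, None]
        return (
            cfg.intercept
            + static["ped_intercepts"][idx][:, None]
            + eff.smoke * static["smoke"][idx]
            + eff.age * age_c
            + eff.sex * sex
            + eff.age_sex * age_c * sex
            + eff.mother * mother_flag[idx][:, None]
            + eff.father * father_flag[idx][:, None]
            + genetic_lp[idx][:, None]
        )

    htn = np.zeros((n, n_exams), dtype=np.int8)
    lp = np.zeros((n, n_exams))

    # founders first: their realized first-exam HTN seeds the offspring's
    # parental-history covariates
    f_idx = np.flatnonzero(founder_mask)
    lp[f_idx] = lin_pred(f_idx)
    htn[f_idx] = rng.random((len(f_idx), n_exams)) < 1.0 / (1.0 + np.exp(-lp[f_idx]))

    o_idx = np.flatnonzero(~founder_mask)
    if len(o_idx):
        fa = ped["father_index"].to_numpy()[o_idx]
        mo = ped["mother_index"].to_numpy()[o_idx]
        father_flag[o_idx] = htn[fa, 0]
        mother_flag[o_idx] = htn[mo, 0]
        lp[o_idx] = lin_pred(o_idx)
        htn[o_idx] = rng.random((len(o_idx), n_exams)) < 1.0 / (1.0 + np.exp(-lp[o_idx]))

    # blood pressures on the correct side of the 140/90 thresholds; means are
    # shifted with the linear predictor so causal SNPs also move SBP/DBP
    shift = np.clip(cfg.bp_coupling * lp, -12.0, 12.0).ravel()
    flat_htn = htn.ravel().astype(bool)
    sbp = np.empty(n * n_exams)
    dbp = np.empty(n * n_exams)

    hyp = np.flatnonzero(flat_htn)
    nor = np.flatnonzero(~flat_htn)
    if len(nor):
        sbp[nor] = _truncnorm_draw(rng, -np.inf, 139.9, 124.0 + shift[nor], 9.0)
        dbp[nor] = _truncnorm_draw(rng, -np.inf, 89.9, 80.0 + shift[nor], 7.0)
    if len(hyp):
        pattern = rng.random(len(hyp))
        both = pattern < 0.45
        sbp_only = (pattern >= 0.45) & (pattern < 0.80)
        dbp_only = pattern >= 0.80
        hi_s = hyp[both | sbp_only]
        lo_s = hyp[dbp_only]
        sbp[hi_s] = _truncnorm_draw(rng, 140.1, np.inf, 149.0 + shift[hi_s], 8.0)
        sbp[lo_s] = _truncnorm_draw(rng, -np.inf, 139.9, 128.0 + shift[lo_s], 8.0)
        hi_d = hyp[both | dbp_only]
        lo_d = hyp[sbp_only]
        dbp[hi_d] = _truncnorm_draw(rng, 90.1, np.inf, 95.0 + shift[hi_d], 5.0)
        dbp[lo_d] = _truncnorm_draw(rng, -np.inf, 89.9, 82.0 + shift[lo_d], 6.0)

    exam = np.tile(np.arange(1, n_exams + 1), n)
    ind_rep = np.repeat(ped["individual_id"].to_numpy(), n_exams)
    pheno = pd.DataFrame(
        {
            "individual_id": ind_rep,
            "exam_index": exam,
            "htn": htn.ravel(),
            "sbp": np.round(sbp, 1),
            "dbp": np.round(dbp, 1),
            "age": np.round(static["ages"].ravel(), 1),
            "sex": np.repeat(static["sex"], n_exams),
            "smoke": static["smoke"].ravel(),
            "mother_htn": np.repeat(mother_flag, n_exams),
            "father_htn": np.repeat(father_flag, n_exams),
            "pedigree_id": np.repeat(ped["pedigree_id"].to_numpy(), n_exams),
        }
    )
    lp_frame = pd.DataFrame(
        {"individual_id": ind_rep, "exam_index": exam, "lp": lp.ravel()}
    )
    return pheno, lp_frame


# ---------------------------------------------------------------------------
# public API


def simulate_replicates(
    config: SimulationConfig,
    n_replicates: int,
    return_truth: bool = False,
):
    """Simulate ``n_replicates`` cohorts sharing one genotype matrix.

    Genotypes and the static covariates (age, sex, smoking trajectory,
    pedigree assignment) are drawn once; hypertension status, blood
    pressures and parental-history flags are re-drawn independently per
    replicate from replicate-specific sub-seeds.  With ``return_truth`` a
    parallel list of :class:`SimulationTruth` (one per replicate, sharing
    the genotype-level truth) is returned as well.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    config.validate()
    root = np.random.SeedSequence(config.seed)
    geno_ss, cov_ss, *rep_ss = root.spawn(2 + n_replicates)

    ped = _pedigree_structure(config)
    geno, genetic_lp, truth0 = _genotype_frame(config, ped, np.random.default_rng(geno_ss))
    static = _static_covariates(config, ped, np.random.default_rng(cov_ss))

    cohorts: list[Cohort] = []
    truths: list[SimulationTruth] = []
    for ss in rep_ss:
        pheno, lp_frame = _draw_phenotypes(
            config, ped, static, genetic_lp, np.random.default_rng(ss)
        )
        cohorts.append(Cohort(phenotypes=pheno, genotypes=geno))
        if return_truth:
            truths.append(
                SimulationTruth(
                    causal_snp_ids=truth0.causal_snp_ids,
                    rare_causal_snp_ids=truth0.rare_causal_snp_ids,
                    duplicate_groups=truth0.duplicate_groups,
                    ld_groups=truth0.ld_groups,
                    maf=truth0.maf,
                    linear_predictors=lp_frame,
                )
            )
    if return_truth:
        return cohorts, truths
    return cohorts


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, SimulationTruth]:
    """Simulate a single cohort plus its ground truth."""
    cohorts, truths = simulate_replicates(config, 1, return_truth=True)
    return cohorts[0], truths[0]


def write_truth(truth: SimulationTruth, path: str | os.PathLike) -> None:
    """Write the truth sidecar (JSON; linear predictors as parallel lists)."""
    payload = {
        "causal_snp_ids": truth.causal_snp_ids,
        "rare_causal_snp_ids": truth.rare_causal_snp_ids,
        "duplicate_groups": truth.duplicate_groups,
        "ld_groups": truth.ld_groups,
        "maf": truth.maf,
        "linear_predictors": {
            c: truth.linear_predictors[c].tolist()
            for c in truth.linear_predictors.columns
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
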