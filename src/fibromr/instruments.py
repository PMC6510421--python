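"""Allele-score instrument construction for Mendelian randomization.

Candidate variants with published fibrinogen associations are screened by
four criteria before entering the score:

1. imputation quality — MACH-imputed variants with quality < 0.3 and
   IMPUTE-imputed variants with quality < 0.4 are dropped (strict
   inequalities, matching standard consortium QC);
2. risk-factor independence — any variant whose dosage has |Spearman
   rho| > 0.10 with BMI, LDL, HDL, hypertension, type-2 diabetes or
   smoking in ANY cohort is dropped;
3. independence from known CHD loci — any variant with r^2 > 0.20 to a
   supplied CHD locus is dropped;
4. LD pruning — among pairs with r^2 > 0.70, the variant from the
   larger source scan is preferentially retained (ties broken by larger
   |published beta|, then lexicographic id); and a cross-cohort
   missingness screen removes variants absent from any cohort of the
   analysis set, which is what yields a smaller nested replication score.

Each filter only SETS an independent flag on the variant, so filters are
idempotent and their order is irrelevant; a variant contributes to the
score iff its flag set is empty.  Effect alleles are aligned so every
per-allele effect on fibrinogen is positive, and the score is the
unweighted sum of aligned dosages (a beta-weighted variant is available
but not the default).  A per-cohort rescaling in which one unit equals
half the observed score range makes score-based and single-variant
effect estimates directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import meta as _meta
from .synthetic_data import RISK_FACTOR_COLUMNS

__all__ = [
    "VariantInstrument",
    "AlleleScore",
    "panel_to_variants",
    "retained",
    "filter_imputation_quality",
    "filter_risk_factor_correlation",
    "filter_chd_ld",
    "prune_ld_pairs",
    "filter_cross_cohort_missingness",
    "align_effect_alleles",
    "compute_allele_score",
    "rescale_score",
    "score_risk_factor_check",
]

logger = logging.getLogger(__name__)

IMPUTATION_THRESHOLDS = {"MACH": 0.3, "IMPUTE": 0.4}
RISK_FACTOR_RHO_MAX = 0.10
CHD_LD_R2_MAX = 0.20
PRUNE_R2_MAX = 0.70

QC_FLAGS = (
    "low_imputation",
    "rf_correlated",
    "chd_ld",
    "ld_pruned",
    "missing_in_cohort",
)


@dataclass
class VariantInstrument:
    """One candidate genetic instrument with its published association."""

    variant_id: str
    effect_allele: str
    other_allele: str
    published_beta: float
    published_se: float
    source_study: str = ""
    source_rank: int = 0
    chromosome: object = None
    position: int | None = None
    imputation_quality: float | None = None
    imputation_method: str | None = None
    qc_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        if self.published_se <= 0:
            raise ValueError(f"{self.variant_id}: published_se must be > 0")

    @property
    def passes_qc(self) -> bool:
        return not self.qc_flags


@dataclass
class AlleleScore:
    """Per-individual allele score over an ordered set of retained variants."""

    values: np.ndarray
    variant_ids: list[str]
    rescaled: bool = False
    divisor: float = 1.0
    weighted: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.weighted and not self.rescaled:
            upper = 2.0 * len(self.variant_ids)
            if np.any(self.values < -1e-9) or np.any(self.values > upper + 1e-9):
                raise ValueError("scores must lie within [0, 2 * n_variants]")


def panel_to_variants(panel: pd.DataFrame) -> list[VariantInstrument]:
    """Build instruments from a variant-panel table (see synthetic_data.variant_panel)."""
    variants = []
    for row in panel.itertuples(index=False):
        variants.append(
            VariantInstrument(
                variant_id=row.variant_id,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                published_beta=float(row.beta),
                published_se=float(row.se),
                source_study=getattr(row, "source_study", ""),
                source_rank=int(getattr(row, "source_rank", 0)),
                chromosome=getattr(row, "chr", None),
                position=getattr(row, "pos", None),
            )
        )
    ids = [v.variant_id for v in variants]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate variant_id in panel")
    return variants


def retained(variants) -> list[VariantInstrument]:
    """Variants whose flag set is empty, in input order."""
    return [v for v in variants if v.passes_qc]


def filter_imputation_quality(variants, quality_table=None) -> list[VariantInstrument]:
    """Flag variants below the method-specific imputation-quality cutoff.

    ``quality_table`` maps variant_id -> (method, quality); when omitted,
    each variant's own imputation fields are used.  MACH quality < 0.3 or
    IMPUTE quality < 0.4 sets the ``low_imputation`` flag (strict
    inequality: a MACH quality of exactly 0.3 is retained).
    """
    for v in variants:
        if quality_table is not None and v.variant_id in quality_table:
            method, quality = quality_table[v.variant_id]
        elif v.imputation_method is not None:
            method, quality = v.imputation_method, v.imputation_quality
        else:
            continue
        if method not in IMPUTATION_THRESHOLDS:
            raise ValueError(f"unknown imputation method {method!r}")
        if quality < IMPUTATION_THRESHOLDS[method]:
            v.qc_flags.add("low_imputation")
    return list(variants)


def _rank_matrix(frame: pd.DataFrame) -> np.ndarray:
    return frame.rank(method="average").to_numpy(dtype=float)


def filter_risk_factor_correlation(variants, cohorts) -> list[VariantInstrument]:
    """Flag variants Spearman-correlated with any CVD risk factor anywhere.

    For every cohort the dosage of each variant is rank-correlated with
    BMI, LDL, HDL, hypertension (0/1), type-2 diabetes (0/1) and smoking
    (ordinal never < former < current); |rho| > 0.10 for any (cohort,
    trait) pair sets ``rf_correlated`` (strict inequality).  A trait that
    is constant within a cohort is skipped with a logged warning.
    """
    by_id = {v.variant_id: v for v in variants}
    for cohort in cohorts:
        present = [vid for vid in by_id if vid in cohort.dosages.columns]
        if not present:
            continue
        traits = cohort.phenotypes[list(RISK_FACTOR_COLUMNS)]
        keep_traits = []
        for t in traits.columns:
            if traits[t].nunique(dropna=True) < 2:
                logger.warning(
                    "trait %s constant in cohort %s; skipped", t, cohort.label
                )
            else:
                keep_traits.append(t)
        if not keep_traits:
            continue
        dr = _rank_matrix(cohort.dosages[present])
        tr = _rank_matrix(traits[keep_traits])
        dr = (dr - dr.mean(axis=0)) / dr.std(axis=0)
        tr = (tr - tr.mean(axis=0)) / tr.std(axis=0)
        rho = dr.T @ tr / len(dr)  # Spearman = Pearson on ranks
        for i, vid in enumerate(present):
            if np.any(np.abs(rho[i]) > RISK_FACTOR_RHO_MAX):
                by_id[vid].qc_flags.add("rf_correlated")
    return list(variants)


def filter_chd_ld(variants, ld_to_chd_loci: pd.DataFrame) -> list[VariantInstrument]:
    """Flag variants in LD (r^2 > 0.20) with any known CHD locus.

    ``ld_to_chd_loci`` is long-format with columns (variant_id, locus_id,
    r2); an empty table flags nothing.
    """
    if len(ld_to_chd_loci) == 0:
        return list(variants)
    r2 = ld_to_chd_loci["r2"].to_numpy(dtype=float)
    if np.any((r2 < 0) | (r2 > 1)):
        raise ValueError("r2 values must lie in [0, 1]")
    worst = ld_to_chd_loci.groupby("variant_id")["r2"].max()
    for v in variants:
        if worst.get(v.variant_id, 0.0) > CHD_LD_R2_MAX:
            v.qc_flags.add("chd_ld")
    return list(variants)


def _prune_keep_key(v: VariantInstrument):
    # retain the largest source scan; ties -> larger |beta|; then smallest id
    return (-v.source_rank, -abs(v.published_beta), v.variant_id)


def prune_ld_pairs(variants, pairwise_r2: pd.DataFrame) -> list[VariantInstrument]:
    """Prune high-LD groups, keeping one variant per connected component.

    Edges are pairs with r^2 > 0.70 (strict) from a long-format symmetric
    table (id1, id2, r2).  Within each connected component the variant
    from the highest-ranked source study is retained (ties: larger
    |published beta|, then lexicographically smallest id); the rest get
    the ``ld_pruned`` flag.
    """
    import networkx as nx

    by_id = {v.variant_id: v for v in variants}
    if len(pairwise_r2) > 0:
        r2 = pairwise_r2["r2"].to_numpy(dtype=float)
        if np.any((r2 < 0) | (r2 > 1)):
            raise ValueError("r2 values must lie in [0, 1]")
    g = nx.Graph()
    g.add_nodes_from(by_id)
    for row in pairwise_r2.itertuples(index=False):
        if row.id1 in by_id and row.id2 in by_id and row.r2 > PRUNE_R2_MAX:
            g.add_edge(row.id1, row.id2)
    for component in nx.connected_components(g):
        if len(component) < 2:
            continue
        members = sorted((by_id[vid] for vid in component), key=_prune_keep_key)
        for v in members[1:]:
            v.qc_flags.add("ld_pruned")
    return list(variants)


def filter_cross_cohort_missingness(variants, cohorts) -> list[VariantInstrument]:
    """Flag variants whose dosage column is absent in any cohort of the set.

    Applying this to the discovery cohorts and then to the replication
    cohorts yields the nested replication score.
    """
    for v in variants:
        for cohort in cohorts:
            if v.variant_id not in cohort.dosages.columns:
                v.qc_flags.add("missing_in_cohort")
                break
    return list(variants)


def align_effect_alleles(
    variants, dosages: pd.DataFrame
) -> tuple[list[VariantInstrument], pd.DataFrame]:
    """Orient each variant so its effect allele raises fibrinogen.

    Variants with negative published beta have their dosage reflected
    (d -> 2 - d), allele labels swapped and beta negated; a zero beta is
    an error because the direction is undefined.  Returns aligned copies;
    inputs are not modified, and aligning twice restores the original
    dosages.
    """
    aligned_variants = []
    aligned = dosages.copy()
    for v in variants:
        if v.published_beta == 0:
            raise ValueError(f"{v.variant_id}: published beta of 0 has no direction")
        if v.published_beta < 0:
            w = replace(
                v,
                effect_allele=v.other_allele,
                other_allele=v.effect_allele,
                published_beta=-v.published_beta,
                qc_flags=set(v.qc_flags),
            )
            if v.variant_id in aligned.columns:
                aligned[v.variant_id] = 2.0 - aligned[v.variant_id]
        else:
            w = replace(v, qc_flags=set(v.qc_flags))
        aligned_variants.append(w)
    return aligned_variants, aligned


def compute_allele_score(
    aligned_dosages: pd.DataFrame, variants, weighted: bool = False
) -> AlleleScore:
    """Sum aligned dosages over QC-passing variants.

    Per-individual missing dosages within an available variant are mean
    imputed (2 x the within-cohort effect-allele frequency), preserving
    the score scale.  ``weighted=True`` weights each dosage by the
    published per-allele beta instead of counting alleles.
    """
    keep = [v for v in retained(variants) if v.variant_id in aligned_dosages.columns]
    if not keep:
        raise ValueError("no retained variants available to score")
    cols = [v.variant_id for v in keep]
    mat = aligned_dosages[cols].to_numpy(dtype=float)
    col_means = np.nanmean(mat, axis=0)
    mat = np.where(np.isnan(mat), col_means, mat)
    if weighted:
        values = mat @ np.array([v.published_beta for v in keep])
    else:
        values = mat.sum(axis=1)
    return AlleleScore(values=values, variant_ids=cols, weighted=weighted)


def rescale_score(score: AlleleScore) -> AlleleScore:
    """Rescale within-cohort so one score unit spans 50% of the range.

    divisor = (max - min) / 2; a degenerate (constant) score is an error.
    The rescaled score range is exactly 2 within the cohort.
    """
    lo, hi = float(np.min(score.values)), float(np.max(score.values))
    if hi == lo:
        raise ValueError("cannot rescale a constant score (zero range)")
    divisor = (hi - lo) / 2.0
    return AlleleScore(
        values=score.values / divisor,
        variant_ids=list(score.variant_ids),
        rescaled=True,
        divisor=divisor,
        weighted=score.weighted,
    )


def _single_fit(y: np.ndarray, x: np.ndarray, binary: bool):
    import statsmodels.api as sm

    exog = sm.add_constant(x)
    if binary:
        model = sm.Logit(y, exog)
        res = model.fit(disp=0, maxiter=200)
    else:
        res = sm.OLS(y, exog).fit()
    return float(res.params[1]), float(res.bse[1])


def score_risk_factor_check(scores: dict, cohorts: dict, alpha: float = 0.05):
    """Test the allele score against the six CVD risk factors.

    ``scores`` and ``cohorts`` map cohort label -> AlleleScore (or array)
    and CohortData.  Each risk factor is regressed on the score within
    each cohort (linear for continuous traits and ordinal smoking,
    logistic for binary traits), the per-cohort coefficients are pooled
    by fixed-effects meta-analysis, and each pooled P is compared with
    the Bonferroni cutoff alpha / 6.  Returns a DataFrame with one row
    per trait and the threshold in ``.attrs["threshold"]``.
    """
    if not cohorts:
        raise ValueError("at least one cohort required")
    threshold = alpha / len(RISK_FACTOR_COLUMNS)
    rows = []
    for trait in RISK_FACTOR_COLUMNS:
        per_cohort = []
        binary = trait in ("hypertension", "diabetes")
        for label, cohort in cohorts.items():
            s = scores[label]
            x = s.values if isinstance(s, AlleleScore) else np.asarray(s, dtype=float)
            y = cohort.phenotypes[trait].to_numpy(dtype=float)
            if len(np.unique(y)) < 2:
                logger.warning("trait %s constant in cohort %s; skipped", trait, label)
                continue
            try:
                per_cohort.append(_single_fit(y, x, binary))
            except Exception as exc:  # e.g. perfect separation in tiny cohorts
                logger.warning("fit failed for %s in %s: %s", trait, label, exc)
        if not per_cohort:
            raise ValueError(f"no cohort could be fit for trait {trait}")
        pooled = _meta.fixed_effects_meta(per_cohort)
        rows.append(
            {
                "trait": trait,
                "estimate": pooled.estimate,
                "se": pooled.se,
                "p": pooled.p,
                "q": pooled.q,
                "p_q": pooled.p_q,
                "k": pooled.k,
                "significant": pooled.p < threshold,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    return out
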