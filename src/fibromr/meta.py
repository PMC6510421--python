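"""Fixed- and random-effects meta-analysis of per-cohort estimates.

Implements inverse-variance-weighted pooling on the log hazard-ratio /
log odds-ratio scale with Cochran's Q heterogeneity diagnostics, the
DerSimonian-Laird between-study variance for the random-effects variant,
and the discovery / replication / combined split used when an allele
score is validated in cohorts that played no part in selecting its
variants.  All confidence intervals are normal-approximation 95%
intervals (multiplier 1.96) and P-values are two-sided on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "MetaResult",
    "fixed_effects_meta",
    "random_effects_meta",
    "combine_discovery_replication",
    "forest_plot",
]

_Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass
class MetaResult:
    """Pooled estimate with heterogeneity diagnostics."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float
    p_q: float
    k: int
    weights: np.ndarray = field(repr=False)
    tau2: float = 0.0
    model: str = "fixed"

    @property
    def ratio(self) -> float:
        """exp(estimate): hazard or odds ratio depending on the input scale."""
        return float(np.exp(self.estimate))

    @property
    def ratio_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _validate(estimates) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray([(float(e), float(s)) for e, s in estimates], dtype=float)
    if arr.size == 0:
        raise ValueError("at least one study is required")
    est, se = arr[:, 0], arr[:, 1]
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    if not np.all(np.isfinite(est)) or not np.all(np.isfinite(se)):
        raise ValueError("estimates and standard errors must be finite")
    return est, se


def _result(est, se, pooled, pooled_se, tau2, model) -> MetaResult:
    k = len(est)
    w_fixed = 1.0 / se**2
    q = float(np.sum(w_fixed * (est - np.sum(w_fixed * est) / np.sum(w_fixed)) ** 2))
    p_q = float(stats.chi2.sf(q, k - 1)) if k > 1 else 1.0
    z = pooled / pooled_se
    w = 1.0 / (se**2 + tau2)
    return MetaResult(
        estimate=float(pooled),
        se=float(pooled_se),
        ci_low=float(pooled - _Z95 * pooled_se),
        ci_high=float(pooled + _Z95 * pooled_se),
        p=float(2.0 * stats.norm.sf(abs(z))),
        q=q,
        p_q=p_q,
        k=k,
        weights=w / np.sum(w),
        tau2=float(tau2),
        model=model,
    )


def fixed_effects_meta(estimates) -> MetaResult:
    """Inverse-variance fixed-effects pooling of (estimate, se) pairs.

    pooled = sum(est_i / se_i^2) / sum(1 / se_i^2),
    pooled_se = 1 / sqrt(sum(1 / se_i^2)),
    Q = sum(((est_i - pooled) / se_i)^2) ~ chi2(k-1) under homogeneity.
    """
    est, se = _validate(estimates)
    w = 1.0 / se**2
    pooled = np.sum(w * est) / np.sum(w)
    pooled_se = 1.0 / np.sqrt(np.sum(w))
    return _result(est, se, pooled, pooled_se, 0.0, "fixed")


def random_effects_meta(estimates) -> MetaResult:
    """DerSimonian-Laird random-effects pooling (k >= 2).

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with fixed
    weights w = 1/se^2; studies are then re-weighted by 1/(se^2 + tau^2).
    Homogeneous inputs (Q <= k-1) truncate to tau^2 = 0 and reproduce the
    fixed-effects result exactly.
    """
    est, se = _validate(estimates)
    k = len(est)
    if k < 2:
        raise ValueError("random-effects meta-analysis requires k >= 2 studies")
    w = 1.0 / se**2
    pooled_f = np.sum(w * est) / np.sum(w)
    q = float(np.sum(w * (est - pooled_f) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    pooled = np.sum(w_re * est) / np.sum(w_re)
    pooled_se = 1.0 / np.sqrt(np.sum(w_re))
    return _result(est, se, pooled, pooled_se, tau2, "random")


def combine_discovery_replication(discovery, replication) -> dict[str, MetaResult | None]:
    """Meta-analyze labelled (label, estimate, se) triples by arm.

    Returns fixed-effects results for the discovery arm, the replication
    arm (None when empty) and the combined analysis, which pools all
    per-cohort estimates directly — for fixed effects this coincides with
    pooling the two pooled results, an identity the tests assert.
    """
    discovery = list(discovery)
    replication = list(replication)
    d_labels = [lab for lab, _, _ in discovery]
    r_labels = [lab for lab, _, _ in replication]
    if len(set(d_labels)) != len(d_labels) or len(set(r_labels)) != len(r_labels):
        raise ValueError("cohort labels must be unique within each arm")
    overlap = set(d_labels) & set(r_labels)
    if overlap:
        raise ValueError(f"cohort labels appear in both arms: {sorted(overlap)}")
    if not discovery:
        raise ValueError("discovery arm must contain at least one cohort")
    disc = fixed_effects_meta([(e, s) for _, e, s in discovery])
    repl = fixed_effects_meta([(e, s) for _, e, s in replication]) if replication else None
    combined = fixed_effects_meta([(e, s) for _, e, s in discovery + replication])
    return {"discovery": disc, "replication": repl, "combined": combined}


def forest_plot(studies, pooled: MetaResult | None = None, ax=None, exponentiate: bool = True):
    """Simple forest plot of labelled (label, estimate, se) triples.

    Labels may carry "(N events; N total)" annotations; the pooled
    diamond, when given, is drawn at the bottom.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    studies = list(studies)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * (len(studies) + 2) + 1))
    tf = np.exp if exponentiate else (lambda x: x)
    ys = np.arange(len(studies), 0, -1)
    for y, (label, est, se) in zip(ys, studies):
        ax.plot(
            [tf(est - _Z95 * se), tf(est + _Z95 * se)], [y, y], color="k", lw=1
        )
        ax.plot([tf(est)], [y], marker="s", color="k", ms=5)
        ax.text(-0.02, y, label, ha="right", va="center", transform=ax.get_yaxis_transform())
    if pooled is not None:
        lo, hi = (pooled.ratio_ci if exponentiate else (pooled.ci_low, pooled.ci_high))
        c = pooled.ratio if exponentiate else pooled.estimate
        ax.fill([lo, c, hi, c], [0, 0.25, 0, -0.25], color="0.3")
        ax.text(-0.02, 0, f"FE pooled (k={pooled.k})", ha="right", va="center",
                transform=ax.get_yaxis_transform())
    ax.axvline(1.0 if exponentiate else 0.0, color="0.6", lw=0.8, ls="--")
    ax.set_yticks([])
    ax.set_xlabel("hazard ratio" if exponentiate else "log hazard ratio")
    for side in ("left", "right", "top"):
        ax.spines[side].set_visible(False)
    return ax
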