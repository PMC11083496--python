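"""Two-group statistics and the three-stage candidate-selection cascade.

Candidate biomarkers are selected by a funnel over the three cohorts:

* Analysis 1 — detectability: every feature surviving the preprocessing
  detection filter enters the screen.
* Analysis 2 — AEC vs HC: Mann-Whitney p below ``alpha`` AND |Cohen's d|
  above ``d_min``, split into increased and decreased sets by the sign of
  the log2 fold-change.
* Analysis 3 — tumour-burden concordance: the SEC-vs-HC change must point
  the same way as the AEC-vs-HC change (and, by default, also be
  significant at the same alpha).

The effect-size gate is applied to |d|, so both increased and decreased
miRNAs can survive.  No multiple-testing correction gates selection; a
Benjamini-Hochberg adjusted p-value is carried in the audit table for
reference only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import COHORTS


@dataclass(frozen=True)
class CascadeThresholds:
    """Selection gates of the cascade (defaults: p < 5%, |d| > 0.5)."""

    alpha: float = 0.05
    d_min: float = 0.5
    require_sec_significance: bool = True
    require_magnitude_monotone: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.d_min < 0:
            raise ValueError(f"d_min must be >= 0, got {self.d_min}")


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U is computed from rank sums (midranks under ties) for the first group.
    The p-value is exact (full enumeration) for tie-free data with
    n1 + n2 <= 12, otherwise a tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"both groups need >= 2 values, got {a.size} and {b.size}")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # all observations identical: U at its null mean, no evidence
        return a.size * b.size / 2.0, 1.0
    method = "exact" if (not ties and a.size + b.size <= 12) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), min(float(res.pvalue), 1.0)


def cohens_d(a, b) -> float:
    """Standardized mean difference (a minus b) with the pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both groups need >= 2 values, got {n1} and {n2}")
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise ValueError("zero pooled variance: groups are degenerate (constant values)")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def _cohort_columns(meta: pd.DataFrame, cohort: str) -> list[str]:
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort label {cohort!r}; expected one of {COHORTS}")
    return meta.loc[meta["cohort"] == cohort, "sample_id"].tolist()


def compare_groups(
    expr: pd.DataFrame, meta: pd.DataFrame, g1: str, g2: str
) -> pd.DataFrame:
    """Per-feature two-group comparison (g1 minus g2) on log2 expression.

    Returns one row per feature, in input feature order, with log2 fold
    change (difference of group means), Mann-Whitney U and two-sided p, and
    Cohen's d.  Features constant across both groups cannot be tested; they
    are flagged ``tested=False`` with NaN statistics.
    """
    cols1 = [c for c in _cohort_columns(meta, g1) if c in expr.columns]
    cols2 = [c for c in _cohort_columns(meta, g2) if c in expr.columns]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValueError(
            f"cohorts {g1}/{g2} need >= 2 samples in the matrix, got {len(cols1)}/{len(cols2)}"
        )
    x1 = expr[cols1].to_numpy(dtype=float)
    x2 = expr[cols2].to_numpy(dtype=float)
    records = []
    for i, fid in enumerate(expr.index):
        a, b = x1[i], x2[i]
        log2fc = float(a.mean() - b.mean())
        if np.ptp(np.concatenate([a, b])) == 0:
            records.append((fid, log2fc, np.nan, np.nan, np.nan, False))
            continue
        u, p = mann_whitney_u(a, b)
        try:
            d = cohens_d(a, b)
        except ValueError:
            # identical constants within each group but different between:
            # infinite standardized effect, flag as untestable
            records.append((fid, log2fc, u, p, np.nan, False))
            continue
        records.append((fid, log2fc, u, p, d, True))
    return pd.DataFrame(
        records, columns=["feature_id", "log2fc", "u_stat", "p_value", "cohens_d", "tested"]
    )


@dataclass
class CascadeResult:
    """Feature sets surviving each analysis stage, plus a full audit trail.

    ``analysis3`` carries the final selection with per-feature direction
    labels (sign of the AEC-vs-HC log2 fold change).  ``audit`` has one row
    per Analysis-1 feature recording every statistic and, for removed
    features, which gate removed it.
    """

    analysis1: list[str]
    analysis2_up: list[str]
    analysis2_down: list[str]
    analysis3: pd.DataFrame
    audit: pd.DataFrame
    thresholds: CascadeThresholds = field(default_factory=CascadeThresholds)

    @property
    def analysis3_selected(self) -> list[str]:
        return self.analysis3["feature_id"].tolist()

    @property
    def directions(self) -> dict[str, str]:
        return dict(zip(self.analysis3["feature_id"], self.analysis3["direction"]))

    @property
    def stage_counts(self) -> dict[str, int]:
        return {
            "analysis1": len(self.analysis1),
            "analysis2_up": len(self.analysis2_up),
            "analysis2_down": len(self.analysis2_down),
            "analysis3": len(self.analysis3),
        }

    def summary(self) -> str:
        c = self.stage_counts
        return (
            "Candidate-selection cascade\n"
            f"  Analysis 1 (detected)          : {c['analysis1']}\n"
            f"  Analysis 2 (AEC vs HC, up)     : {c['analysis2_up']}\n"
            f"  Analysis 2 (AEC vs HC, down)   : {c['analysis2_down']}\n"
            f"  Analysis 3 (SEC concordant)    : {c['analysis3']}"
        )


def run_cascade(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    thresholds: CascadeThresholds = CascadeThresholds(),
) -> CascadeResult:
    """Run the Analysis-1/2/3 funnel on a preprocessed expression matrix."""
    present = set(meta.loc[meta["sample_id"].isin(expr.columns), "cohort"])
    missing = [c for c in COHORTS if c not in present]
    if missing:
        raise ValueError(f"cascade requires all cohorts; missing {missing}")

    aec_hc = compare_groups(expr, meta, "AEC", "HC").set_index("feature_id")
    sec_hc = compare_groups(expr, meta, "SEC", "HC").set_index("feature_id")
    aec_sec = compare_groups(expr, meta, "AEC", "SEC").set_index("feature_id")

    audit = pd.DataFrame(index=aec_hc.index)
    for name, cmp_df in (("aec_hc", aec_hc), ("sec_hc", sec_hc), ("aec_sec", aec_sec)):
        for col in ("log2fc", "u_stat", "p_value", "cohens_d"):
            audit[f"{col}_{name}"] = cmp_df[col]
    audit["tested"] = aec_hc["tested"] & sec_hc["tested"]

    # BH-adjusted AEC-vs-HC p over testable features, audit-only
    audit["p_bh_aec_hc"] = np.nan
    testable = aec_hc["tested"].to_numpy()
    if testable.any():
        audit.loc[testable, "p_bh_aec_hc"] = multipletests(
            aec_hc.loc[testable, "p_value"], method="fdr_bh"
        )[1]

    alpha, d_min = thresholds.alpha, thresholds.d_min
    sig = aec_hc["tested"] & (aec_hc["p_value"] < alpha)
    big = aec_hc["cohens_d"].abs() > d_min
    pass2 = sig & big
    up2 = pass2 & (aec_hc["log2fc"] > 0)
    down2 = pass2 & (aec_hc["log2fc"] < 0)

    concordant = np.sign(sec_hc["log2fc"]) == np.sign(aec_hc["log2fc"])
    pass3 = pass2 & concordant & (aec_hc["log2fc"] != 0)
    if thresholds.require_sec_significance:
        pass3 &= sec_hc["tested"] & (sec_hc["p_value"] < alpha)
    if thresholds.require_magnitude_monotone:
        pass3 &= aec_hc["log2fc"].abs() >= sec_hc["log2fc"].abs()

    reason = pd.Series("", index=audit.index, dtype=object)
    reason[~aec_hc["tested"]] = "constant feature (AEC vs HC untestable)"
    gate = aec_hc["tested"] & ~sig
    reason[gate & (reason == "")] = "not significant (AEC vs HC)"
    gate = sig & ~big
    reason[gate & (reason == "")] = "effect size below threshold"
    gate = pass2 & ~(concordant & (aec_hc["log2fc"] != 0))
    reason[gate & (reason == "")] = "direction discordant (SEC vs HC)"
    if thresholds.require_sec_significance:
        gate = pass2 & concordant & ~(sec_hc["tested"] & (sec_hc["p_value"] < alpha))
        reason[gate & (reason == "")] = "not significant (SEC vs HC)"
    if thresholds.require_magnitude_monotone:
        gate = pass2 & concordant & ~(aec_hc["log2fc"].abs() >= sec_hc["log2fc"].abs())
        reason[gate & (reason == "")] = "magnitude not monotone"
    reason[pass3] = ""

    audit["pass_analysis2"] = pass2
    audit["pass_analysis3"] = pass3
    audit["direction"] = np.where(aec_hc["log2fc"] > 0, "up",
                                  np.where(aec_hc["log2fc"] < 0, "down", "none"))
    audit["removal_reason"] = reason
    audit = audit.reset_index()

    selected = audit.loc[audit["pass_analysis3"],
                         ["feature_id", "direction",
                          "log2fc_aec_hc", "p_value_aec_hc", "cohens_d_aec_hc",
                          "log2fc_sec_hc", "p_value_sec_hc"]].reset_index(drop=True)
    return CascadeResult(
        analysis1=list(expr.index),
        analysis2_up=audit.loc[up2.to_numpy(), "feature_id"].tolist(),
        analysis2_down=audit.loc[down2.to_numpy(), "feature_id"].tolist(),
        analysis3=selected,
        audit=audit,
        thresholds=thresholds,
    )
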