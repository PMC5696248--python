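"""Verification-stage marker filters.

The filters reproduce the multi-criteria funnel used to reduce a broad MRM
candidate list to an analyzable marker set:

* **cv** — a peptide whose median replicate CV exceeds a cutoff (default
  10%) is too unstable to quantify.
* **range** — the median relative peptide level (endogenous:SIS ratio)
  must lie inside an open reference interval, default (0.1, 10); outside
  it the assay is outside its reliable response range.
* **audit** — transition-interference detection: for each peptide-sample,
  each transition's fractional contribution to the total light area is
  compared against its contribution to the total heavy (SIS) area by a
  paired t-test across replicates, and the replicate CV of the
  light:heavy ratio is checked.  Because an additive contamination on one
  transition's light channel also *deflates* the fractional contribution
  of its sibling transitions, a significant discordance is attributed
  only to positively shifted transitions (contamination inflates the
  analyte channel; deflated siblings are passengers).  A transition is
  declared interfered when it is
  flagged in more than a configurable fraction of samples, and a peptide
  fails when its signature transition is interfered.
* **confounder** — a rank-based (Kruskal-Wallis) test of the peptide
  level against clinical center and against preparation batch, run within
  the control group only (so disease effects cannot masquerade as batch
  effects), with Benjamini-Hochberg correction across peptides.
* **auc_screen** — single-marker screening: the orientation-free AUC
  (max(AUC, 1-AUC)) in a configured group comparison must exceed a
  threshold (default 0.60).

Each rule is computed on the full input independently, so the surviving
set does not depend on the order in which rules are applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mrmpanel import quantitation, rocstats

__all__ = [
    "QCConfig",
    "QCVerdict",
    "cv_filter",
    "range_filter",
    "audit_flag",
    "confounder_filter",
    "single_marker_screen",
    "run_qc",
]

PASS, FAIL, UNEVALUABLE, SKIPPED = "pass", "fail", "unevaluable", "skipped"


@dataclass(frozen=True)
class QCConfig:
    cv_threshold: float = 0.10
    level_range: tuple[float, float] = (0.1, 10.0)
    audit_pvalue_threshold: float = 0.05
    audit_cv_threshold: float = 0.20
    audit_sample_fraction: float = 0.2
    confounder_alpha: float = 0.05
    auc_screen_threshold: float = 0.60
    screen_comparisons: tuple[tuple[str, str], ...] = (("NL", "PDAC"), ("PB", "PDAC"))
    screen_gate: tuple[str, str] = ("NL", "PDAC")
    control_group: str = "NL"

    def __post_init__(self):
        if self.cv_threshold <= 0:
            raise ValueError("cv_threshold must be positive")
        lo, hi = self.level_range
        if lo >= hi:
            raise ValueError("level_range lower bound must be below upper bound")
        for name, v in [("audit_pvalue_threshold", self.audit_pvalue_threshold),
                        ("audit_sample_fraction", self.audit_sample_fraction),
                        ("confounder_alpha", self.confounder_alpha)]:
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.5 <= self.auc_screen_threshold <= 1.0:
            raise ValueError("auc_screen_threshold must be in [0.5, 1]")


@dataclass(frozen=True)
class QCVerdict:
    peptide: str
    passed: bool
    failed_rules: frozenset[str]
    stats: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# simple per-peptide filters


def cv_filter(quant: pd.DataFrame, threshold: float = 0.10) -> pd.DataFrame:
    """Median-replicate-CV rule: one row per peptide with status and statistic."""
    summ = quantitation.qc_summary(quant)
    med = summ["median_cv"].to_numpy(dtype=float)
    status = np.where(~np.isfinite(med), UNEVALUABLE,
                      np.where(med > threshold, FAIL, PASS))
    return pd.DataFrame({"peptide": summ["peptide"], "protein": summ["protein"],
                         "median_cv": med, "cv_status": status})


def range_filter(quant: pd.DataFrame,
                 level_range: tuple[float, float] = (0.1, 10.0)) -> pd.DataFrame:
    """Reference-range rule on the median relative level (open interval)."""
    lo, hi = level_range
    summ = quantitation.qc_summary(quant)
    med = summ["median_level"].to_numpy(dtype=float)
    inside = (med > lo) & (med < hi)  # open interval: boundary values fail
    status = np.where(~np.isfinite(med), UNEVALUABLE,
                      np.where(inside, PASS, FAIL))
    return pd.DataFrame({"peptide": summ["peptide"], "protein": summ["protein"],
                         "median_level": med, "range_status": status})


# ---------------------------------------------------------------------------
# transition-interference detection


def audit_flag(records: pd.DataFrame, config: QCConfig = QCConfig()) -> pd.DataFrame:
    """Interference verdict per (peptide, transition).

    Returns one row per transition with the fraction of evaluable samples
    in which it was flagged and the resulting ``interfered`` call.
    Peptides observed with a single transition are reported as
    ``evaluable=False`` (relative contributions are degenerate there).
    """
    df = records.copy()
    need = {"sample_id", "peptide", "transition_id", "replicate",
            "area_light", "area_heavy"}
    missing_cols = need - set(df.columns)
    if missing_cols:
        raise ValueError(f"records missing columns: {sorted(missing_cols)}")

    grp_rep = df.groupby(["sample_id", "peptide", "replicate"], sort=False)
    tot_light = grp_rep["area_light"].transform("sum")
    tot_heavy = grp_rep["area_heavy"].transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        df["_d"] = (df["area_light"] / tot_light - df["area_heavy"] / tot_heavy)
        df["_ratio"] = df["area_light"] / df["area_heavy"]
    df["_ntrans"] = grp_rep["transition_id"].transform("size")

    per = (df.groupby(["sample_id", "peptide", "transition_id"], sort=False)
             .agg(n=("_d", "count"), mean_d=("_d", "mean"), sd_d=("_d", "std"),
                  ratio_mean=("_ratio", "mean"), ratio_sd=("_ratio", "std"),
                  ntrans=("_ntrans", "max"))
             .reset_index())

    n = per["n"].to_numpy(dtype=float)
    mean_d = per["mean_d"].to_numpy(dtype=float)
    sd_d = per["sd_d"].to_numpy(dtype=float)
    evaluable = (per["ntrans"].to_numpy() >= 2) & (n >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_d / (sd_d / np.sqrt(n))
        cv = per["ratio_sd"].to_numpy(dtype=float) / per["ratio_mean"].to_numpy(dtype=float)
    # exact replicate agreement (sd 0, mean 0) is the null case, p = 1
    t = np.where((sd_d == 0) & (mean_d == 0), 0.0, t)
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 1, 1)), 0.0)
    p = np.where((sd_d == 0) & (mean_d != 0), 0.0, p)

    per["p_discordance"] = p
    per["ratio_cv"] = cv
    per["evaluable"] = evaluable

    # Interference is an additive contamination of the analyte (light)
    # channel, so the affected transition's light contribution shifts *up*
    # while its siblings are passively deflated.  Attribute a significant
    # discordance only to positively shifted transitions; this keeps the
    # passively deflated siblings unflagged and still catches peptides
    # with more than one contaminated transition.
    t_flag = (per["p_discordance"] < config.audit_pvalue_threshold) & (mean_d > 0)
    cv_flag = per["ratio_cv"] > config.audit_cv_threshold
    per["flagged"] = evaluable & (t_flag | cv_flag)

    out = (per.groupby(["peptide", "transition_id"], sort=True)
              .agg(n_samples=("sample_id", "size"),
                   n_evaluable=("evaluable", "sum"),
                   n_flagged=("flagged", "sum"))
              .reset_index())
    n_eval = out["n_evaluable"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_eval > 0, out["n_flagged"] / n_eval, np.nan)
    out["flag_fraction"] = frac
    out["evaluable"] = n_eval > 0
    out["interfered"] = out["evaluable"] & (frac > config.audit_sample_fraction)
    return out


def _audit_peptide_status(audit: pd.DataFrame, signatures: pd.Series) -> pd.DataFrame:
    rows = []
    for peptide, grp in audit.groupby("peptide", sort=True):
        sig = signatures.get(peptide)
        sig_rows = grp[grp["transition_id"] == sig]
        if sig is None or sig_rows.empty or not sig_rows["evaluable"].iloc[0]:
            status, frac = UNEVALUABLE, np.nan
        else:
            frac = float(sig_rows["flag_fraction"].iloc[0])
            status = FAIL if bool(sig_rows["interfered"].iloc[0]) else PASS
        rows.append(dict(peptide=peptide, audit_status=status,
                         signature_flag_fraction=frac))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# confounder screen


def confounder_filter(quant: pd.DataFrame, meta: pd.DataFrame,
                      config: QCConfig = QCConfig(),
                      factors: Sequence[str] = ("center", "batch")) -> pd.DataFrame:
    """Kruskal-Wallis screen of peptide levels against nuisance factors.

    Runs within the control group only; BH-adjusts p-values across
    peptides per factor; a peptide fails when any factor's adjusted p is
    below ``confounder_alpha``.  Factors with a single observed level are
    skipped with a warning.
    """
    merged = quant.merge(meta[["sample_id", "group"] + list(factors)], on="sample_id")
    ctrl = merged[merged["group"] == config.control_group]
    peptides = sorted(quant["peptide"].unique())
    result = pd.DataFrame({"peptide": peptides})

    any_tested = np.zeros(len(peptides), dtype=bool)
    fail = np.zeros(len(peptides), dtype=bool)
    for factor in factors:
        levels = ctrl[factor].dropna().unique()
        if len(levels) < 2:
            warnings.warn(
                f"confounder factor {factor!r} has fewer than two levels in the "
                f"control group; skipped", stacklevel=2)
            result[f"p_{factor}"] = np.nan
            result[f"q_{factor}"] = np.nan
            continue
        pvals = []
        for pep in peptides:
            sub = ctrl[ctrl["peptide"] == pep]
            groups = [g["relative_level"].dropna().to_numpy()
                      for _, g in sub.groupby(factor, sort=True)]
            groups = [g for g in groups if g.size > 0]
            if len(groups) < 2 or sum(g.size for g in groups) < 3:
                pvals.append(np.nan)
                continue
            try:
                pvals.append(stats.kruskal(*groups).pvalue)
            except ValueError:  # all values identical
                pvals.append(1.0)
        pvals = np.asarray(pvals, dtype=float)
        finite = np.isfinite(pvals)
        qvals = np.full_like(pvals, np.nan)
        if finite.any():
            qvals[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        result[f"p_{factor}"] = pvals
        result[f"q_{factor}"] = qvals
        any_tested |= finite
        fail |= finite & (qvals < config.confounder_alpha)

    result["confounder_status"] = np.where(~any_tested, UNEVALUABLE,
                                           np.where(fail, FAIL, PASS))
    return result


# ---------------------------------------------------------------------------
# single-marker AUC screen


def single_marker_screen(qmat: pd.DataFrame, meta: pd.DataFrame,
                         config: QCConfig = QCConfig(),
                         strict: bool = True) -> pd.DataFrame:
    """Orientation-free single-marker AUCs for the configured comparisons.

    One row per (peptide, comparison) with the raw AUC (case oriented as
    the second group of the comparison), the oriented AUC
    ``max(AUC, 1 - AUC)``, the direction of change, and whether the
    peptide is kept under the strictly-greater screening rule.
    """
    groups = meta.set_index("sample_id")["group"]
    rows = []
    for control_g, case_g in config.screen_comparisons:
        mask = groups.isin([control_g, case_g])
        if groups[mask].nunique() < 2:
            if strict:
                raise ValueError(
                    f"comparison {control_g} vs {case_g}: both groups must be present")
            warnings.warn(f"comparison {control_g} vs {case_g} skipped: "
                          f"both groups must be present", stacklevel=2)
            continue
        for pep in qmat.columns:
            values = qmat.loc[qmat.index.intersection(groups[mask].index), pep]
            values = values.dropna()
            y = (groups.loc[values.index] == case_g).to_numpy()
            if values.empty or y.all() or not y.any():
                rows.append(dict(peptide=pep, comparison=f"{control_g}_vs_{case_g}",
                                 auc_raw=np.nan, auc_oriented=np.nan,
                                 direction="na", kept=False))
                continue
            a = rocstats.auc(values.to_numpy(dtype=float), y)
            oriented = max(a, 1.0 - a)
            rows.append(dict(
                peptide=pep, comparison=f"{control_g}_vs_{case_g}",
                auc_raw=a, auc_oriented=oriented,
                direction="up" if a >= 0.5 else "down",
                kept=bool(oriented > config.auc_screen_threshold)))
    out = pd.DataFrame(rows)
    return out.sort_values(["comparison", "auc_oriented"],
                           ascending=[True, False]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# combined report


def run_qc(records: pd.DataFrame, quant: pd.DataFrame, meta: pd.DataFrame,
           config: QCConfig = QCConfig()) -> tuple[pd.DataFrame, list[QCVerdict]]:
    """All filters on one dataset: per-peptide report plus verdict objects.

    The surviving set is the peptides whose rules are all ``pass`` (or
    unevaluable/skipped — only an explicit ``fail`` removes a peptide;
    unevaluable rules are visible in the report for manual review).
    """
    cv = cv_filter(quant, config.cv_threshold)
    rng_ = range_filter(quant, config.level_range)
    audit = audit_flag(records, config)
    signatures = quantitation.signature_transitions(records)
    audit_pep = _audit_peptide_status(audit, signatures)
    conf = confounder_filter(quant, meta, config)

    qmat = quantitation.quant_matrix(quant, by="peptide")
    screen = single_marker_screen(qmat, meta, config, strict=False)
    gate = f"{config.screen_gate[0]}_vs_{config.screen_gate[1]}"
    if screen.empty:
        screen = pd.DataFrame(columns=["peptide", "comparison", "auc_oriented", "kept"])
    gate_rows = screen[screen["comparison"] == gate][["peptide", "auc_oriented", "kept"]]
    gate_rows = gate_rows.rename(columns={"auc_oriented": "screen_auc"})
    gate_rows["screen_status"] = np.where(
        ~np.isfinite(gate_rows["screen_auc"]), UNEVALUABLE,
        np.where(gate_rows["kept"], PASS, FAIL))

    report = (cv.merge(rng_[["peptide", "median_level", "range_status"]], on="peptide")
                .merge(audit_pep, on="peptide", how="left")
                .merge(conf[["peptide", "confounder_status"]
                            + [c for c in conf.columns if c.startswith(("p_", "q_"))]],
                       on="peptide", how="left")
                .merge(gate_rows[["peptide", "screen_auc", "screen_status"]],
                       on="peptide", how="left"))
    report["audit_status"] = report["audit_status"].fillna(UNEVALUABLE)
    report["confounder_status"] = report["confounder_status"].fillna(UNEVALUABLE)
    report["screen_status"] = report["screen_status"].fillna(UNEVALUABLE)

    rule_cols = {"cv": "cv_status", "range": "range_status", "audit": "audit_status",
                 "confounder": "confounder_status", "auc_screen": "screen_status"}
    verdicts = []
    passed_col = []
    failed_col = []
    for _, row in report.iterrows():
        failed = frozenset(rule for rule, col in rule_cols.items() if row[col] == FAIL)
        verdicts.append(QCVerdict(
            peptide=row["peptide"], passed=not failed, failed_rules=failed,
            stats={"median_cv": row["median_cv"], "median_level": row["median_level"],
                   "screen_auc": row.get("screen_auc", np.nan)}))
        passed_col.append(not failed)
        failed_col.append(",".join(sorted(failed)))
    report["passed"] = passed_col
    report["failed_rules"] = failed_col
    return report, verdicts
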