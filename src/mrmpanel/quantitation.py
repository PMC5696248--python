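"""Transition-level peak areas -> per-sample relative peptide levels.

Quantitation follows the signature-transition rule used in targeted MRM
panels: for each peptide, the transition with the highest total light-peak
intensity is chosen once, globally, and its light:heavy (endogenous:SIS)
peak-area ratio is the relative peptide level.  Peak areas can instead be
normalized to a spiked external standard (beta-galactosidase) when no SIS
peptide is available.  Replicate ratios are aggregated to a mean level and
a coefficient of variation (sample SD / mean on the untransformed ratios).

Missing denominators never raise: they propagate as flagged missing
quantitations so a single bad run cannot abort a batch.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "NORMALIZATION_MODES",
    "select_signature_transition",
    "signature_transitions",
    "compute_relative_level",
    "aggregate_replicates",
    "quantify",
    "quant_matrix",
    "qc_summary",
]

NORMALIZATION_MODES = ("sis", "external_standard")
_DENOMINATOR = {"sis": "area_heavy", "external_standard": "area_external_standard"}


class NoSignalError(ValueError):
    """All light areas for a peptide are missing or non-finite."""


def select_signature_transition(records: pd.DataFrame) -> str:
    """Signature transition of one peptide: largest summed light area.

    Ties break deterministically to the lexicographically smallest
    transition id.
    """
    if records.empty:
        raise NoSignalError("no transition records supplied")
    finite = records[np.isfinite(records["area_light"])]
    if finite.empty:
        peptide = records["peptide"].iloc[0] if "peptide" in records else "?"
        raise NoSignalError(f"peptide {peptide!r} has no finite light areas")
    totals = finite.groupby("transition_id")["area_light"].sum()
    best = totals.max()
    return str(sorted(totals.index[totals == best])[0])


def signature_transitions(records: pd.DataFrame) -> pd.Series:
    """Signature transition per peptide over a full transition table."""
    return records.groupby("peptide", sort=True).apply(
        select_signature_transition, include_groups=False).rename("signature_transition")


def compute_relative_level(record, mode: str = "sis"):
    """Normalized level of one transition record: light / denominator.

    ``record`` is a mapping with ``area_light`` and the denominator channel.
    Returns ``(level, flag)`` where flag is ``"ok"``, ``"below_detection"``
    (zero light), or ``"missing_denominator"`` (level is NaN).
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}, got {mode!r}")
    light = record["area_light"]
    denom = record.get(_DENOMINATOR[mode], np.nan)
    if light is None or not np.isfinite(light) or light < 0:
        return float("nan"), "missing_light"
    if denom is None or not np.isfinite(denom) or denom <= 0:
        return float("nan"), "missing_denominator"
    level = float(light) / float(denom)
    return level, ("below_detection" if light == 0 else "ok")


def aggregate_replicates(levels) -> tuple[float, float]:
    """(mean level, replicate CV) across technical replicates.

    CV = sample SD (n-1 denominator) / mean on the untransformed ratios.
    A single replicate or a zero mean yields ``CV = nan``.
    """
    x = np.asarray([v for v in np.asarray(levels, dtype=float) if np.isfinite(v)])
    if x.size == 0:
        return float("nan"), float("nan")
    mean = float(x.mean())
    if x.size < 2 or mean == 0.0:
        return mean, float("nan")
    return mean, float(x.std(ddof=1) / mean)


def quantify(records: pd.DataFrame, mode: str = "sis") -> pd.DataFrame:
    """Per-sample relative peptide levels from a transition table.

    One output row per (sample, peptide): the signature transition's mean
    light:denominator ratio across replicates, the replicate CV, and QC
    flags.  Column ``relative_level`` is NaN (never silently zero) when no
    replicate had a usable denominator.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"mode must be one of {NORMALIZATION_MODES}, got {mode!r}")
    if records.empty:
        return pd.DataFrame(columns=[
            "sample_id", "protein", "peptide", "relative_level", "replicate_cv",
            "n_replicates", "signature_transition", "normalization_mode", "flag"])
    denom_col = _DENOMINATOR[mode]
    sig = signature_transitions(records)
    df = records.merge(sig, left_on="peptide", right_index=True)
    df = df[df["transition_id"] == df["signature_transition"]].copy()

    light = df["area_light"].to_numpy(dtype=float)
    denom = df[denom_col].to_numpy(dtype=float) if denom_col in df else np.full(len(df), np.nan)
    ok_denom = np.isfinite(denom) & (denom > 0)
    level = np.where(ok_denom & np.isfinite(light), light / denom, np.nan)
    df["level"] = level

    out = (df.groupby(["sample_id", "peptide"], sort=True)
             .agg(protein=("protein", "first"),
                  relative_level=("level", "mean"),
                  _sd=("level", "std"),
                  n_replicates=("level", "count"),
                  signature_transition=("signature_transition", "first"))
             .reset_index())
    mean = out["relative_level"].to_numpy(dtype=float)
    sd = out["_sd"].to_numpy(dtype=float)
    n = out["n_replicates"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where((n >= 2) & (mean != 0.0), sd / mean, np.nan)
    out["replicate_cv"] = cv
    out["flag"] = np.where(n == 0, "missing_denominator",
                           np.where(mean == 0.0, "below_detection", "ok"))
    out["normalization_mode"] = mode
    return out[["sample_id", "protein", "peptide", "relative_level",
                "replicate_cv", "n_replicates", "signature_transition",
                "normalization_mode", "flag"]]


def quant_matrix(quant: pd.DataFrame, value: str = "relative_level",
                 by: str = "protein") -> pd.DataFrame:
    """Samples-as-rows wide matrix of relative levels (NaN where missing)."""
    if quant.empty:
        return pd.DataFrame()
    return quant.pivot_table(index="sample_id", columns=by, values=value,
                             aggfunc="first")


def qc_summary(quant: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide summary: median level, median replicate CV, missingness."""
    if quant.empty:
        return pd.DataFrame(columns=["peptide", "protein", "median_level",
                                     "median_cv", "n_samples", "n_missing"])
    q = quant.copy()
    q["_missing"] = ~np.isfinite(q["relative_level"].to_numpy(dtype=float))
    out = (q.groupby("peptide", sort=True)
            .agg(protein=("protein", "first"),
                 median_level=("relative_level", "median"),
                 median_cv=("replicate_cv", "median"),
                 n_samples=("sample_id", "size"),
                 n_missing=("_missing", "sum"))
            .reset_index())
    out["n_missing"] = out["n_missing"].astype(int)
    return out
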