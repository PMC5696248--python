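"""Scenario-based validation of a frozen panel model against the anchor.

The validation design follows the multi-center study layout: the cohort is
split 4:1 into training and test sets, stratified by group, tumor stage
(within the cancer cases) and center; other-cancer samples are reserved
entirely for the test set, matching a training set composed of cancer,
benign and normal samples only.  Models and decision cutoffs are frozen on
the training set and applied unchanged to the test set.

The report mirrors the standard panel-vs-anchor table: for each evaluation
scenario (all cancer vs controls, early-stage only, vs other cancers, vs
benign disease, and the low-CA19-9 variants restricted to subjects within
the clinical normal range of CA19-9 < 37 U/mL) it lists AUC, sensitivity
and specificity at the frozen cutoffs for the panel and the anchor, the
paired DeLong and McNemar tests, and positive predictive values at a
configurable population prevalence (default 12.9 per 100,000).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mrmpanel import rocstats
from mrmpanel.panels import PanelModel

__all__ = [
    "ScenarioSpec",
    "default_scenarios",
    "split_train_test",
    "evaluate_scenarios",
    "render_report",
    "DEFAULT_PREVALENCE",
    "CA199_NORMAL_RANGE",
]

DEFAULT_PREVALENCE = 12.9e-5  # pancreatic-cancer prevalence per person
CA199_NORMAL_RANGE = 37.0  # U/mL, upper bound of the clinical normal range


@dataclass(frozen=True)
class ScenarioSpec:
    """One evaluation scenario: case/control filters plus an optional
    subject-level CA19-9 restriction (applied to cases AND controls)."""

    name: str
    case_groups: tuple[str, ...] = ("PDAC",)
    control_groups: tuple[str, ...] = ("NL",)
    case_stages: tuple[str, ...] | None = None
    ca199_max: float | None = None

    def __post_init__(self):
        if set(self.case_groups) & set(self.control_groups):
            raise ValueError(
                f"scenario {self.name!r}: case and control groups overlap")


def default_scenarios() -> list[ScenarioSpec]:
    """The standard eight panel-vs-anchor comparisons."""
    base = [
        ScenarioSpec("control_vs_pdac"),
        ScenarioSpec("control_vs_pdac_stage12", case_stages=("I", "II")),
        ScenarioSpec("othercancer_vs_pdac", control_groups=("OC",)),
        ScenarioSpec("benign_vs_pdac", control_groups=("PB",)),
    ]
    low = [
        ScenarioSpec(s.name + "_lowca199", case_groups=s.case_groups,
                     control_groups=s.control_groups, case_stages=s.case_stages,
                     ca199_max=CA199_NORMAL_RANGE)
        for s in base
    ]
    return base + low


# ---------------------------------------------------------------------------
# train/test split


def split_train_test(meta: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0,
                     test_only_groups: Sequence[str] = ("OC",)
                     ) -> tuple[list[str], list[str]]:
    """Stratified train/test split, deterministic under the seed.

    Strata are (group, stage, center); within each stratum the test count
    is the rounded fraction.  Groups in ``test_only_groups`` go wholly to
    the test set.  Strata smaller than two samples are assigned to
    training with a warning.  The returned id lists are disjoint and
    together exhaustive.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    df = meta[["sample_id", "group", "stage", "center"]].copy()
    df["stage"] = df["stage"].fillna("-")
    for (group, stage, center), stratum in df.groupby(["group", "stage", "center"],
                                                      sort=True, dropna=False):
        ids = np.sort(stratum["sample_id"].to_numpy())
        if group in test_only_groups:
            test.extend(ids.tolist())
            continue
        if len(ids) < 2:
            warnings.warn(f"stratum {(group, stage, center)} has fewer than two "
                          f"samples; assigned wholly to training", stacklevel=2)
            train.extend(ids.tolist())
            continue
        rng.shuffle(ids)
        n_test = int(round(len(ids) * test_fraction))
        test.extend(sorted(ids[:n_test].tolist()))
        train.extend(sorted(ids[n_test:].tolist()))
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# scenario evaluation


def _scenario_mask(meta: pd.DataFrame, spec: ScenarioSpec):
    is_case = meta["group"].isin(spec.case_groups)
    if spec.case_stages is not None:
        is_case &= meta["stage"].isin(spec.case_stages)
    is_control = meta["group"].isin(spec.control_groups)
    keep = is_case | is_control
    if spec.ca199_max is not None:
        keep &= meta["ca199"].notna() & (meta["ca199"] < spec.ca199_max)
    return keep, is_case


def evaluate_scenarios(model: PanelModel, features: pd.DataFrame,
                       meta: pd.DataFrame, anchor_cutoff: float,
                       scenarios: Sequence[ScenarioSpec] | None = None,
                       anchor: str = "CA19-9",
                       prevalence: float = DEFAULT_PREVALENCE) -> pd.DataFrame:
    """Frozen-model evaluation of each scenario on a (test) cohort.

    ``features`` must be the same log-scale feature matrix construction
    used at training time, restricted to the evaluation cohort.  The
    anchor score is the anchor feature itself with ``anchor_cutoff``
    frozen from training.  Scenarios with fewer than two samples in
    either class are reported as unevaluable rather than aborting.
    """
    if model.cutoff is None:
        raise ValueError("the panel model's cutoff must be frozen before evaluation")
    scenarios = list(scenarios) if scenarios is not None else default_scenarios()
    meta = meta.set_index("sample_id").loc[features.index].reset_index()
    cols = list(model.markers)
    complete = ~features[cols].isna().any(axis=1)
    rows = []
    for spec in scenarios:
        keep, is_case = _scenario_mask(meta, spec)
        keep = keep.to_numpy() & complete.to_numpy()
        y = is_case.to_numpy()[keep]
        n_case, n_control = int(y.sum()), int((~y).sum())
        row = dict(scenario=spec.name, n_case=n_case, n_control=n_control,
                   evaluable=True)
        if n_case < 2 or n_control < 2:
            row.update(evaluable=False)
            rows.append(row)
            continue
        X = features.loc[keep, cols].to_numpy(dtype=float)
        panel_scores = model.decision_function(X)
        anchor_scores = features.loc[keep, anchor].to_numpy(dtype=float)

        dl = rocstats.delong_test(panel_scores, anchor_scores, y)
        p_sens, p_spec, p_pred = rocstats.apply_cutoff(panel_scores, y, model.cutoff)
        a_sens, a_spec, a_pred = rocstats.apply_cutoff(anchor_scores, y, anchor_cutoff)
        mc = rocstats.mcnemar_test(p_pred, a_pred, y, scope="cases")
        row.update(
            panel_auc=dl.auc_a, anchor_auc=dl.auc_b,
            auc_gain=dl.auc_a - dl.auc_b, delong_p=dl.p_value,
            panel_sensitivity=p_sens, panel_specificity=p_spec,
            anchor_sensitivity=a_sens, anchor_specificity=a_spec,
            sens_gain=p_sens - a_sens, mcnemar_p=mc.p_value,
            panel_ppv=rocstats.ppv(p_sens, p_spec, prevalence),
            anchor_ppv=rocstats.ppv(a_sens, a_spec, prevalence),
        )
        rows.append(row)
    report = pd.DataFrame(rows)
    report.attrs["prevalence"] = prevalence
    report.attrs["panel"] = "+".join(model.markers)
    return report


# ---------------------------------------------------------------------------
# rendering


def render_report(report: pd.DataFrame, outdir,
                  features: pd.DataFrame | None = None,
                  meta: pd.DataFrame | None = None,
                  model: PanelModel | None = None,
                  anchor: str = "CA19-9") -> dict[str, Path]:
    """Write the report TSV and, when data are supplied, the figures.

    Produces ``report.tsv`` always; with ``features``/``meta``/``model``
    also per-marker box plots by clinical group (log-scale levels) and ROC
    overlays (panel vs anchor) per evaluable scenario.  Outputs are
    deterministic given the inputs.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    path = out / "report.tsv"
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")
    written["report"] = path

    if features is None or meta is None or model is None:
        return written

    m = meta.set_index("sample_id").loc[features.index]
    order = [g for g in ("NL", "PB", "OC", "PDAC") if (m["group"] == g).any()]

    fig, axes = plt.subplots(1, len(model.markers),
                             figsize=(3.2 * len(model.markers), 3.4))
    axes = np.atleast_1d(axes)
    for ax, marker in zip(axes, model.markers):
        data = [features.loc[(m["group"] == g).to_numpy(), marker].dropna()
                for g in order]
        ax.boxplot(data, tick_labels=order)
        ax.set_title(marker)
        ax.set_ylabel("log level")
    fig.tight_layout()
    box_path = out / "marker_boxplots.png"
    fig.savefig(box_path, dpi=120)
    plt.close(fig)
    written["boxplots"] = box_path

    evaluable = report[report["evaluable"]] if "evaluable" in report else report
    if not evaluable.empty:
        n = len(evaluable)
        ncol = min(4, n)
        nrow = int(np.ceil(n / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 3.2 * nrow),
                                 squeeze=False)
        scen_by_name = {s.name: s for s in default_scenarios()}
        for ax, (_, row) in zip(axes.ravel(), evaluable.iterrows()):
            spec = scen_by_name.get(row["scenario"])
            if spec is None:
                ax.axis("off")
                continue
            keep, is_case = _scenario_mask(m.reset_index(), spec)
            keep = keep.to_numpy() & (~features[list(model.markers)].isna().any(axis=1)).to_numpy()
            y = is_case.to_numpy()[keep]
            X = features.loc[keep, list(model.markers)].to_numpy(dtype=float)
            for label, scores in [("panel", model.decision_function(X)),
                                  (anchor, features.loc[keep, anchor].to_numpy(float))]:
                fpr, tpr = rocstats.roc_curve(scores, y)
                ax.plot(fpr, tpr, label=label)
            ax.plot([0, 1], [0, 1], "k:", lw=0.8)
            ax.set_title(row["scenario"], fontsize=8)
            ax.legend(fontsize=7)
        for ax in axes.ravel()[n:]:
            ax.axis("off")
        fig.tight_layout()
        roc_path = out / "roc_curves.png"
        fig.savefig(roc_path, dpi=120)
        plt.close(fig)
        written["roc"] = roc_path
    return written
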