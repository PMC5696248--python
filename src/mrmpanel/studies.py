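"""Replication studies: seeded simulation experiments over the pipeline.

Each function here runs one replicate (or one batch) of a named
simulation experiment against the synthetic-data generator and returns
plain dictionaries of measurements.  The experiments mirror the study's
validation logic:

* null calibration of the paired tests,
* recovery of planted QC defects by the verification filters,
* recovery of a planted informative panel by the anchored search
  (and its false-positive behavior on signal-free cohorts),
* the qualitative panel-vs-anchor performance pattern across the
  evaluation scenarios.

Problem sizes follow the study design (684 training samples for the
panel search); the scenario-pattern experiment triples the cohort so
that the low-CA19-9 test subset is large enough for its AUC to be
estimated to within a few points (at study scale that subset holds only
~28 cases).
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as _sps

from mrmpanel import evaluation, panels, qc, quantitation, rocstats, synthetic

__all__ = [
    "delong_null_calibration",
    "mcnemar_null_calibration",
    "qc_recovery_replicate",
    "panel_recovery_replicate",
    "scenario_pattern_replicate",
]

PANEL_MARKERS = ("CA19-9", "LRG1", "TTR")


# ---------------------------------------------------------------------------
# null calibration of the paired tests


def delong_null_calibration(seed: int, n_reps: int = 1000, n: int = 100,
                            alpha: float = 0.05) -> float:
    """Fraction of null replicates where DeLong's test rejects.

    Both score vectors are independent noise on a balanced cohort, so the
    AUCs are equal in truth and the rejection rate estimates the type-I
    error at level ``alpha``.
    """
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=bool)
    y[: n // 2] = True
    rej = 0
    for _ in range(n_reps):
        sa = rng.standard_normal(n)
        sb = rng.standard_normal(n)
        if rocstats.delong_test(sa, sb, y).p_value < alpha:
            rej += 1
    return rej / n_reps


def mcnemar_null_calibration(seed: int, n_reps: int = 1000, n: int = 100,
                             alpha: float = 0.05) -> float:
    """Fraction of null replicates where McNemar's test rejects.

    Predictions come from two independent noise scores dichotomized at a
    fixed cutoff, so per-sample correctness is independent between the
    classifiers and equally probable — the exchangeable null.
    """
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=bool)
    y[: n // 2] = True
    rej = 0
    for _ in range(n_reps):
        pa = rng.standard_normal(n) >= 0.0
        pb = rng.standard_normal(n) >= 0.0
        if rocstats.mcnemar_test(pa, pb, y, scope="all").p_value < alpha:
            rej += 1
    return rej / n_reps


# ---------------------------------------------------------------------------
# QC-filter recovery


def _qc_planted_config(seed: int) -> synthetic.CohortConfig:
    """Small two-group cohort with planted quantitation defects.

    37 well-behaved markers plus 5 high-replicate-CV markers, 5 markers
    whose median relative level falls outside (0.1, 10), and 3 markers
    with a two-fold batch effect; 4 batches with 30 control samples each.
    """
    specs = [synthetic.MarkerSpec(f"CLEAN{i:02d}") for i in range(1, 38)]
    specs += [synthetic.MarkerSpec(f"HIGHCV{i}", replicate_cv=0.20)
              for i in range(1, 6)]
    specs += [synthetic.MarkerSpec(f"LOWRANGE{i}",
                                   group_loc={g: np.log(0.01) for g in synthetic.GROUPS})
              for i in range(1, 4)]
    specs += [synthetic.MarkerSpec(f"HIGHRANGE{i}",
                                   group_loc={g: np.log(50.0) for g in synthetic.GROUPS})
              for i in range(1, 3)]
    specs += [synthetic.MarkerSpec(f"BATCHFX{i}", batch_effect_fold=2.0)
              for i in range(1, 4)]
    return synthetic.CohortConfig(
        seed=seed,
        group_sizes={("NL", "SNUH"): 120, ("PDAC", "NCC"): 60},
        stage_distribution={"NCC": {"I": 10, "II": 20, "III": 15, "IV": 15}},
        marker_specs=specs,
        n_batches=4,
        interference_rate=0.0,
    )


def _recovery_counts(flagged: set, truth: set, universe: set) -> dict:
    tp = len(flagged & truth)
    fp = len(flagged - truth)
    return dict(tp=tp, fn=len(truth) - tp, fp=fp,
                tn=len(universe - truth) - fp)


def qc_recovery_replicate(seed: int) -> dict[str, dict]:
    """One replicate of planted-defect recovery for each QC filter.

    Returns per-filter confusion counts against the generator's ground
    truth.  The interference filter runs on its own replicate cohort
    (interference injected at rate 0.1 over 50 peptides x 3 transitions,
    defaults otherwise) so that flags caused by one kind of injected
    defect are not charged against another filter's false-flag rate.
    """
    cfg = _qc_planted_config(seed)
    meta, gt = synthetic.generate_cohort(cfg)
    records = synthetic.generate_transition_data(meta, cfg, gt)
    quant = quantitation.quantify(records)
    qcfg = qc.QCConfig()
    pep2prot = dict(zip(quant["peptide"], quant["protein"]))
    universe = set(pep2prot.values())

    cv = qc.cv_filter(quant, qcfg.cv_threshold)
    cv_flagged = {pep2prot[p] for p in cv.loc[cv["cv_status"] == qc.FAIL, "peptide"]}
    rng_ = qc.range_filter(quant, qcfg.level_range)
    rng_flagged = {pep2prot[p] for p in rng_.loc[rng_["range_status"] == qc.FAIL, "peptide"]}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        conf = qc.confounder_filter(quant, meta, qcfg)
    conf_flagged = {pep2prot[p] for p in
                    conf.loc[conf["confounder_status"] == qc.FAIL, "peptide"]}

    out = {
        "cv": _recovery_counts(cv_flagged, gt.high_cv_markers, universe),
        "range": _recovery_counts(rng_flagged, gt.out_of_range_markers, universe),
        "confounder": _recovery_counts(conf_flagged, gt.batch_affected_markers, universe),
    }

    # separate interference replicate: 50 clean peptides, rate 0.1
    icfg = synthetic.CohortConfig(
        seed=seed + 1_000_000,
        group_sizes={("NL", "SNUH"): 120, ("PDAC", "NCC"): 60},
        stage_distribution={"NCC": {"I": 10, "II": 20, "III": 15, "IV": 15}},
        marker_specs=[synthetic.MarkerSpec(f"PEP{i:02d}") for i in range(1, 51)],
        n_batches=4,
        interference_rate=0.1,
    )
    imeta, igt = synthetic.generate_cohort(icfg)
    irec = synthetic.generate_transition_data(imeta, icfg, igt)
    audit = qc.audit_flag(irec, qcfg)
    prot_of = dict(zip(irec["peptide"], irec["protein"]))
    flagged_pairs = {(prot_of[r.peptide], r.transition_id)
                     for r in audit.itertuples() if r.interfered}
    pair_universe = {(prot_of[r.peptide], r.transition_id)
                     for r in audit.itertuples()}
    out["audit"] = _recovery_counts(flagged_pairs, igt.interfered_transitions,
                                    pair_universe)
    return out


# ---------------------------------------------------------------------------
# panel recovery


def _pipeline_features(cfg: synthetic.CohortConfig):
    meta, gt = synthetic.generate_cohort(cfg)
    records = synthetic.generate_transition_data(meta, cfg, gt)
    quant = quantitation.quantify(records)
    qmat = quantitation.quant_matrix(quant)
    feats = panels.build_feature_matrix(qmat, meta)
    return meta, gt, feats


def panel_recovery_replicate(seed: int, null: bool = False) -> dict:
    """One replicate of the anchored panel search on the training split.

    With ``null=False`` the default cohort plants LRG1-up and TTR-down
    among 20 decoys; the measurements record whether the planted triple
    ranks first and survives both selection stages.  With ``null=True``
    the cohort carries no signal anywhere and the measurement of interest
    is the number of selected (false-positive) panels.
    """
    cfg = (synthetic.null_cohort_config(seed) if null
           else synthetic.default_cohort_config(seed))
    meta, gt, feats = _pipeline_features(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train_ids, _ = evaluation.split_train_test(meta, seed=seed)
    ftr = feats.loc[train_ids]
    ytr = meta.set_index("sample_id").loc[train_ids, "group"] == "PDAC"
    results = panels.search_panels(ftr, ytr, seed=seed, min_size=3, max_size=3)
    planted = "+".join(sorted(PANEL_MARKERS[1:]))
    planted = f"CA19-9+{planted}"
    row = results[results["markers"] == planted]
    out = dict(
        n_panels=len(results),
        n_selected=int(results["selected"].sum()),
        n_train=results.attrs["n_samples"],
    )
    if not row.empty:
        r = row.iloc[0]
        out.update(
            planted_first=bool(results.iloc[0]["markers"] == planted),
            planted_selected=bool(r["selected"]),
            planted_stage1=bool(r["survived_stage1"]),
            planted_stage2=bool(r["survived_stage2"]),
            planted_auc_gain=float(r["auc_gain"]),
            planted_sens_gain=float(r["sens_gain"]),
        )
    return out


# ---------------------------------------------------------------------------
# scenario pattern


def scenario_pattern_replicate(seed: int, scale: int = 3) -> dict:
    """One replicate of the panel-vs-anchor scenario comparison.

    Generates a cohort at ``scale`` times the study group sizes, trains
    and freezes the three-marker panel and the anchor cutoff on the
    training split, and evaluates the frozen models on the test split.
    Returns the overall cancer-vs-control AUCs and the low-CA19-9
    (normal-range) scenario AUCs.
    """
    cfg = synthetic.default_cohort_config(seed, scale=scale)
    meta, gt, feats = _pipeline_features(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train_ids, test_ids = evaluation.split_train_test(meta, seed=seed)
    y = meta.set_index("sample_id")["group"] == "PDAC"
    cols = list(PANEL_MARKERS)
    ftr = feats.loc[train_ids, cols].dropna()
    ytr = y.loc[ftr.index]
    model = panels.train_panel(ftr, ytr, seed=seed)
    model = panels.freeze_cutoff(model, ftr, ytr, 0.90)
    anchor_cut = rocstats.sensitivity_at_specificity(
        ftr["CA19-9"].to_numpy(), ytr.to_numpy(), 0.90)
    report = evaluation.evaluate_scenarios(
        model, feats.loc[test_ids], meta[meta["sample_id"].isin(test_ids)],
        anchor_cut.cutoff)
    overall = report[report["scenario"] == "control_vs_pdac"].iloc[0]
    low = report[report["scenario"] == "control_vs_pdac_lowca199"].iloc[0]
    return dict(
        panel_auc=float(overall["panel_auc"]),
        anchor_auc=float(overall["anchor_auc"]),
        auc_gain=float(overall["auc_gain"]),
        panel_sensitivity=float(overall["panel_sensitivity"]),
        anchor_sensitivity=float(overall["anchor_sensitivity"]),
        panel_specificity=float(overall["panel_specificity"]),
        panel_ppv=float(overall["panel_ppv"]),
        low_anchor_auc=float(low["anchor_auc"]),
        low_panel_auc=float(low["panel_auc"]),
        low_n_case=int(low["n_case"]),
        report=report,
    )
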