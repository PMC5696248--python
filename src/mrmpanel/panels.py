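"""Anchored combinatorial panel search with SVM classification.

Candidate panels are all marker subsets that contain the anchor marker
(the established clinical marker the panel must beat).  Each panel is
scored by a two-class support-vector machine whose continuous decision
value ``sum_i alpha_i y_i K(x, x_i) + b`` is used for ROC construction
(the sign function is applied only at the frozen decision cutoff).
Markers are standardized with training-set statistics only; stratified
k-fold cross-validation produces one out-of-fold score vector per panel,
on which the two selection stages run:

* stage 1 — cross-validated AUC at least ``min_auc_gain`` above the
  anchor's, with DeLong's paired test significant;
* stage 2 — sensitivity at the fixed-specificity cutoff more than
  ``min_sens_gain`` above the anchor's, with McNemar's paired test
  (cases-only scope) significant.

Every candidate is evaluated on the same complete-case sample set and the
same fold assignment, so the paired tests are valid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from mrmpanel import rocstats

__all__ = [
    "SvmSpec",
    "SelectionCriteria",
    "PanelModel",
    "enumerate_panels",
    "build_feature_matrix",
    "train_panel",
    "make_folds",
    "cross_validate_panel",
    "search_panels",
    "select_panels",
]

DEFAULT_ANCHOR = "CA19-9"


@dataclass(frozen=True)
class SvmSpec:
    """Kernel specification: default is a linear kernel with C fixed at 1."""

    kernel: str = "linear"
    c: float = 1.0
    gamma: float | str = "scale"

    def __post_init__(self):
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"kernel must be 'linear' or 'rbf', got {self.kernel!r}")
        if self.c <= 0:
            raise ValueError("C must be positive")


@dataclass(frozen=True)
class SelectionCriteria:
    min_auc_gain: float = 0.07
    delong_alpha: float = 0.05
    min_sens_gain: float = 0.10
    mcnemar_alpha: float = 0.05
    spec_target: float = 0.90
    cv_folds: int = 5

    def __post_init__(self):
        if self.min_auc_gain < 0 or self.min_sens_gain < 0:
            raise ValueError("gains must be non-negative")
        for name, a in [("delong_alpha", self.delong_alpha),
                        ("mcnemar_alpha", self.mcnemar_alpha)]:
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if not 0.0 < self.spec_target <= 1.0:
            raise ValueError("spec_target must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


# ---------------------------------------------------------------------------
# panel model


@dataclass
class PanelModel:
    """A trained panel classifier frozen for test-set application.

    The decision function is reproducible bit-for-bit from the stored
    parameters: standardization constants, support vectors (in the
    standardized feature space), dual coefficients ``alpha_i * y_i``, and
    the bias.  ``cutoff`` is the decision threshold frozen on the training
    cohort; it must be set before the model is applied to any test data.
    """

    markers: tuple[str, ...]
    kernel: str
    c: float
    gamma: float
    center: np.ndarray
    scale: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    cutoff: float | None = None
    cutoff_specificity: float | None = None
    metadata: dict = field(default_factory=dict)

    def decision_function(self, X) -> np.ndarray:
        """Continuous margin scores; higher means more case-like."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.markers):
            raise ValueError(
                f"expected {len(self.markers)} features {self.markers}, "
                f"got {X.shape[1]}")
        Z = (X - self.center) / self.scale
        if self.kernel == "linear":
            K = Z @ self.support_vectors.T
        else:  # rbf
            d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(-1)
            K = np.exp(-self.gamma * d2)
        return K @ self.dual_coef + self.intercept

    def predict(self, X) -> np.ndarray:
        if self.cutoff is None:
            raise ValueError("cutoff has not been frozen on a training cohort")
        return self.decision_function(X) >= self.cutoff

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "kernel": self.kernel,
            "c": self.c,
            "gamma": float(self.gamma),
            "center": [float(v) for v in self.center],
            "scale": [float(v) for v in self.scale],
            "support_vectors": [[float(v) for v in row] for row in self.support_vectors],
            "dual_coef": [float(v) for v in self.dual_coef],
            "intercept": float(self.intercept),
            "cutoff": None if self.cutoff is None else float(self.cutoff),
            "cutoff_specificity": (None if self.cutoff_specificity is None
                                   else float(self.cutoff_specificity)),
            "metadata": self.metadata,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PanelModel":
        return cls(
            markers=tuple(d["markers"]), kernel=d["kernel"], c=d["c"],
            gamma=d["gamma"],
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            support_vectors=np.asarray(d["support_vectors"], dtype=float),
            dual_coef=np.asarray(d["dual_coef"], dtype=float),
            intercept=float(d["intercept"]),
            cutoff=d.get("cutoff"),
            cutoff_specificity=d.get("cutoff_specificity"),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def load(cls, path) -> "PanelModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# enumeration and features


def enumerate_panels(marker_list, anchor: str = DEFAULT_ANCHOR,
                     min_size: int = 1, max_size: int = 3) -> list[tuple[str, ...]]:
    """All subsets containing the anchor, sizes in [min_size, max_size].

    Deterministic order: by panel size, then lexicographically over the
    sorted non-anchor markers; the anchor is always the first element.
    """
    markers = list(marker_list)
    if len(set(markers)) != len(markers):
        raise ValueError("marker_list contains duplicates")
    if anchor not in markers:
        raise ValueError(f"anchor {anchor!r} not in marker list")
    if not 1 <= min_size <= max_size:
        raise ValueError("need 1 <= min_size <= max_size")
    if max_size > len(markers):
        raise ValueError(
            f"max_size {max_size} exceeds the {len(markers)} available markers")
    others = sorted(m for m in markers if m != anchor)
    panels = []
    for size in range(min_size, max_size + 1):
        for combo in combinations(others, size - 1):
            panels.append((anchor,) + combo)
    return panels


def build_feature_matrix(qmat: pd.DataFrame, meta: pd.DataFrame,
                         markers=None, anchor: str = DEFAULT_ANCHOR) -> pd.DataFrame:
    """Log-scale classifier features: anchor from the clinical assay, the
    rest from the MRM quant matrix.

    The anchor column is log10 of the measured CA19-9 (censored values
    participate at their clamped value; missing values stay NaN).  MRM
    relative levels are natural-log transformed; non-positive levels
    become NaN.  No rows are dropped here — missingness handling is the
    caller's decision and should be logged.
    """
    idx = meta["sample_id"]
    feats = pd.DataFrame(index=pd.Index(idx, name="sample_id"))
    ca = meta.set_index("sample_id")["ca199"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        feats[anchor] = np.where(ca > 0, np.log10(ca), np.nan)
    if markers is None:
        markers = [c for c in qmat.columns]
    for m in markers:
        if m == anchor:
            continue
        if m not in qmat.columns:
            raise ValueError(f"marker {m!r} not present in the quant matrix")
        v = qmat[m].reindex(feats.index).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            feats[m] = np.where(v > 0, np.log(v), np.nan)
    return feats


# ---------------------------------------------------------------------------
# training and cross-validation


def _check_panel_markers(markers) -> tuple[str, ...]:
    markers = tuple(markers)
    if len(set(markers)) != len(markers):
        raise ValueError(f"panel contains duplicate markers: {markers}")
    return markers


def train_panel(X: pd.DataFrame, y, svm_spec: SvmSpec = SvmSpec(),
                seed: int = 0) -> PanelModel:
    """Fit the panel SVM on complete-case training rows.

    Rows with any missing panel feature are dropped (their count is kept
    in the model metadata).  Features are standardized with statistics of
    the used training rows only.  The decision cutoff is *not* set here;
    freeze it explicitly with :func:`freeze_cutoff`.
    """
    markers = _check_panel_markers(X.columns)
    if not isinstance(y, pd.Series):
        y = pd.Series(np.asarray(y), index=X.index)
    X = X.sort_index()
    y = y.loc[X.index]
    keep = ~X.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    Xc = X.loc[keep].to_numpy(dtype=float)
    yc = rocstats.as_case_indicator(y.loc[keep].to_numpy())
    if len(np.unique(yc)) < 2:
        raise ValueError(
            f"panel {markers}: training data has a single class after "
            f"dropping incomplete rows")
    scaler = StandardScaler().fit(Xc)
    Z = scaler.transform(Xc)
    clf = SVC(kernel=svm_spec.kernel, C=svm_spec.c, gamma=svm_spec.gamma,
              random_state=seed)
    clf.fit(Z, yc)
    gamma_val = clf._gamma if svm_spec.kernel == "rbf" else 0.0
    return PanelModel(
        markers=markers, kernel=svm_spec.kernel, c=svm_spec.c,
        gamma=float(gamma_val),
        center=scaler.mean_.copy(), scale=scaler.scale_.copy(),
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        metadata={"seed": int(seed), "n_train": int(keep.sum()),
                  "n_dropped_missing": n_dropped,
                  "n_case": int(yc.sum()), "n_control": int((~yc).sum())},
    )


def freeze_cutoff(model: PanelModel, X: pd.DataFrame, y,
                  spec_target: float = 0.90) -> PanelModel:
    """Freeze the decision cutoff at a fixed training specificity."""
    if isinstance(y, pd.Series):
        y = y.loc[X.index].to_numpy()
    keep = ~X.isna().any(axis=1)
    scores = model.decision_function(X.loc[keep].to_numpy(dtype=float))
    yk = rocstats.as_case_indicator(np.asarray(y)[keep.to_numpy()])
    cut = rocstats.sensitivity_at_specificity(scores, yk, spec_target)
    out = replace(model, cutoff=cut.cutoff, cutoff_specificity=cut.specificity)
    out.metadata = dict(model.metadata, spec_target=spec_target)
    return out


def make_folds(y, n_folds: int = 5, seed: int = 0, strata=None) -> np.ndarray:
    """Stratified fold assignment (by class, and extra strata when given).

    Returns an integer fold id per sample.  If a composite class-by-strata
    cell is smaller than the fold count, stratification silently falls
    back to class-only (with a warning).
    """
    y = rocstats.as_case_indicator(y)
    if n_folds > min(int(y.sum()), int((~y).sum())):
        raise ValueError("fold count exceeds the minority class size")
    if strata is not None:
        key = np.char.add(y.astype(int).astype(str),
                          np.asarray(strata, dtype=str))
        counts = pd.Series(key).value_counts()
        if counts.min() < n_folds:
            warnings.warn("some class-by-stratum cells are smaller than the fold "
                          "count; stratifying by class only", stacklevel=2)
            key = y.astype(int)
    else:
        key = y.astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for k, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), key)):
        folds[test_idx] = k
    return folds


def cross_validate_panel(X: np.ndarray, y: np.ndarray, folds: np.ndarray,
                         svm_spec: SvmSpec = SvmSpec(), seed: int = 0,
                         spec_target: float = 0.90):
    """Out-of-fold decision values concatenated into one score vector.

    Standardization is refit inside every fold (leak-free).  Raw SVM
    decision values are not comparable across folds (each fold's model has
    its own offset), so each fold's out-of-fold scores are centered at
    that fold's fixed-specificity training cutoff before concatenation.
    A pooled score of 0 then corresponds to the frozen training cutoff in
    every fold, and the pooled vector supports both AUC and
    sensitivity-at-cutoff comparisons across panels.

    Returns ``(scores, auc)`` with scores aligned to the input rows.
    """
    scores = np.empty(len(y), dtype=float)
    for k in np.unique(folds):
        tr, te = folds != k, folds == k
        scaler = StandardScaler().fit(X[tr])
        clf = SVC(kernel=svm_spec.kernel, C=svm_spec.c, gamma=svm_spec.gamma,
                  random_state=seed)
        clf.fit(scaler.transform(X[tr]), y[tr])
        train_scores = clf.decision_function(scaler.transform(X[tr]))
        cut = rocstats.sensitivity_at_specificity(train_scores, y[tr], spec_target)
        scores[te] = clf.decision_function(scaler.transform(X[te])) - cut.cutoff
    return scores, rocstats.auc(scores, y)


# ---------------------------------------------------------------------------
# search


def search_panels(features: pd.DataFrame, y, anchor: str = DEFAULT_ANCHOR,
                  criteria: SelectionCriteria = SelectionCriteria(),
                  svm_spec: SvmSpec = SvmSpec(), seed: int = 0,
                  min_size: int = 2, max_size: int = 3,
                  strata=None) -> pd.DataFrame:
    """Evaluate every anchored panel and apply the two selection stages.

    ``features`` is the log-scale feature matrix (samples x markers,
    anchor included).  All candidates are evaluated on the complete-case
    subset over the *union* of candidate markers, with one shared fold
    assignment, so DeLong and McNemar comparisons are properly paired.

    Returns one row per candidate panel: markers, cross-validated AUC,
    AUC gain over the anchor, DeLong p, sensitivity gain at the fixed
    specificity, McNemar p, stage survival flags and final rank (NaN for
    unselected panels).
    """
    y = pd.Series(rocstats.as_case_indicator(y), index=features.index)
    keep = ~features.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    feats = features.loc[keep].sort_index()
    yv = y.loc[feats.index].to_numpy()
    strat = None
    if strata is not None:
        strat = pd.Series(np.asarray(strata), index=features.index).loc[feats.index].to_numpy()

    panels = enumerate_panels(list(feats.columns), anchor, min_size, max_size)
    folds = make_folds(yv, criteria.cv_folds, seed=seed, strata=strat)

    anchor_X = feats[[anchor]].to_numpy(dtype=float)
    anchor_scores, anchor_auc = cross_validate_panel(
        anchor_X, yv, folds, svm_spec, seed, criteria.spec_target)
    # fold-centered scores put every fold's frozen training cutoff at 0
    anchor_sens, anchor_spec, anchor_pred = rocstats.apply_cutoff(
        anchor_scores, yv, 0.0)

    rows = []
    for markers in panels:
        X = feats[list(markers)].to_numpy(dtype=float)
        scores, cv_auc = cross_validate_panel(X, yv, folds, svm_spec, seed,
                                              criteria.spec_target)
        dl = rocstats.delong_test(scores, anchor_scores, yv)
        sens, spec, pred = rocstats.apply_cutoff(scores, yv, 0.0)
        mc = rocstats.mcnemar_test(pred, anchor_pred, yv, scope="cases")
        rows.append(dict(
            markers="+".join(markers), size=len(markers),
            cv_auc=cv_auc, anchor_auc=anchor_auc,
            auc_gain=cv_auc - anchor_auc, delong_p=dl.p_value,
            sensitivity=sens, anchor_sensitivity=anchor_sens,
            sens_gain=sens - anchor_sens,
            specificity=spec, mcnemar_p=mc.p_value,
        ))
    results = pd.DataFrame(rows)
    results.attrs["n_dropped_missing"] = n_dropped
    results.attrs["n_samples"] = int(keep.sum())
    results.attrs["anchor"] = anchor
    return select_panels(results, criteria)


def select_panels(results: pd.DataFrame,
                  criteria: SelectionCriteria = SelectionCriteria()) -> pd.DataFrame:
    """Apply the two-stage rule and rank the survivors.

    Stage 1 keeps panels whose AUC gain is at least ``min_auc_gain``
    (inclusive) with DeLong p below ``delong_alpha``; stage 2 keeps panels
    whose sensitivity gain strictly exceeds ``min_sens_gain`` with McNemar
    p below ``mcnemar_alpha``.  Survivors of both stages are ranked by
    cross-validated AUC, then sensitivity gain, then marker names.
    """
    res = results.copy()
    res["survived_stage1"] = ((res["auc_gain"] >= criteria.min_auc_gain)
                              & (res["delong_p"] < criteria.delong_alpha))
    res["survived_stage2"] = ((res["sens_gain"] > criteria.min_sens_gain)
                              & (res["mcnemar_p"] < criteria.mcnemar_alpha))
    res["selected"] = res["survived_stage1"] & res["survived_stage2"]
    res = res.sort_values(["selected", "cv_auc", "sens_gain", "markers"],
                          ascending=[False, False, False, True],
                          kind="mergesort").reset_index(drop=True)
    res["rank"] = np.where(res["selected"], np.arange(1, len(res) + 1), np.nan)
    res.attrs.update(results.attrs)
    return res
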