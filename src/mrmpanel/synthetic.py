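"""Synthetic multi-center plasma cohort and MRM transition-level data.

This module generates the study conditions the rest of the pipeline
assumes: a four-group case-control cohort (pancreatic ductal
adenocarcinoma, normal controls, other cancers, benign pancreatic disease)
recruited across five centers, with CA19-9 immunoassay values calibrated to
the per-center medians and dispersions of the validation-population
demographics table, plus Skyline-style transition-level MRM peak areas for
a configurable marker set (stable-isotope-dilution light/heavy channels,
triplicate technical noise, blocked batch randomization, and optional
injected transition interference).

Every latent quantity that a downstream filter or search step is supposed
to recover — which markers are informative, which transitions are
interfered, which markers carry batch effects, which cases are CA19-9
non-expressors — is emitted in a :class:`GroundTruth` object so that
recovery can be tested against the truth rather than eyeballed.

Scale conventions
-----------------
Marker abundances are log-normal within each clinical group: ``group_loc``
and ``group_scale`` of a :class:`MarkerSpec` are the mean and SD of the
natural-log relative level (light:heavy ratio).  CA19-9 is kept on its
clinical U/mL scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MarkerSpec",
    "CohortConfig",
    "GroundTruth",
    "SecondPlatformModel",
    "default_marker_specs",
    "default_cohort_config",
    "null_cohort_config",
    "generate_cohort",
    "generate_transition_data",
    "generate_second_platform",
    "effect_for_auc",
    "lognormal_sigma_from_mad",
    "write_cohort",
]

GROUPS = ("PDAC", "NL", "OC", "PB")
STAGES = ("I", "II", "III", "IV")

# Validation-population demographics: per (group, center) sample counts,
# CA19-9 median and MAD-style dispersion (U/mL), age and BMI moments, male
# fraction, and the AJCC stage counts of the cancer cases.
DEFAULT_CENTER_TABLE: dict[tuple[str, str], dict] = {
    ("PDAC", "NCC"): dict(n=128, ca199=(312.5, 8032.5), age=(62.94, 9.81),
                          bmi=(23.32, 2.88), male=0.6563,
                          stages={"I": 3, "II": 27, "III": 25, "IV": 73}),
    ("PDAC", "AMC"): dict(n=75, ca199=(51.7, 415.05), age=(62.2, 10.59),
                          bmi=(22.94, 3.23), male=0.6133,
                          stages={"I": 10, "II": 63, "III": 1, "IV": 1}),
    ("PDAC", "SNUH"): dict(n=50, ca199=(82.85, 358.68), age=(59.44, 9.34),
                           bmi=(22.4, 3.32), male=0.56,
                           stages={"I": 3, "II": 45, "III": 2, "IV": 0}),
    ("PDAC", "YSH"): dict(n=47, ca199=(59.3, 328.9), age=(64.6, 8.56),
                          bmi=(23.13, 2.85), male=0.617,
                          stages={"I": 3, "II": 43, "III": 1, "IV": 0}),
    ("PDAC", "SMC"): dict(n=101, ca199=(363.45, 1531.29), age=(59.76, 11.48),
                          bmi=(22.52, 2.95), male=0.6337,
                          stages={"I": 1, "II": 50, "III": 2, "IV": 48}),
    ("NL", "SNUH"): dict(n=349, ca199=(7.4, 3.6), age=(56.94, 8.07),
                         bmi=(23.84, 3.06), male=0.5587),
    ("OC", "SNUH"): dict(n=149, ca199=(9.5, 12.5), age=(55.22, 11.51),
                         bmi=(23.44, 3.41), male=0.255,
                         subgroups={"breast": 52, "colon": 45, "thyroid": 52}),
    ("PB", "YSH"): dict(n=27, ca199=(7.5, 9.55), age=(59.96, 14.15),
                        bmi=(23.69, 3.01), male=0.5185),
    ("PB", "AMC"): dict(n=47, ca199=(7.0, 17.3), age=(50.6, 12.86),
                        bmi=(23.26, 4.71), male=0.3404),
    ("PB", "SMC"): dict(n=30, ca199=(9.33, 8.38), age=(49.99, 15.22),
                        bmi=(22.89, 3.04), male=0.3333),
    ("PB", "SNU"): dict(n=5, ca199=(11.0, 27.9), age=(55.2, 8.93),
                        bmi=(23.38, 2.08), male=0.8),
}

ANCHOR_MARKER = "CA19-9"


def lognormal_sigma_from_mad(median: float, mad: float) -> float:
    """Log-scale SD of a log-normal with the given median and dispersion.

    The demographics table reports a "MAD" that exceeds the median for the
    cancer groups, which no positive-valued distribution permits for a true
    median absolute deviation; it is treated here as the *mean* absolute
    deviation about the mean, for which the log-normal identity
    ``E|X - EX| = 2 EX (2 Phi(sigma/2) - 1)`` gives
    ``mad / median = exp(sigma^2 / 2) * 2 (2 Phi(sigma/2) - 1)``,
    solved numerically for sigma.
    """
    if median <= 0 or mad <= 0:
        raise ValueError("median and mad must be positive")
    ratio = mad / median

    def f(s):
        return np.exp(s * s / 2.0) * 2.0 * (2.0 * stats.norm.cdf(s / 2.0) - 1.0) - ratio

    return float(optimize.brentq(f, 1e-9, 8.0))


def effect_for_auc(target_auc: float, scale: float) -> float:
    """Log-scale location shift giving a target single-marker AUC.

    For two normals with common SD ``scale`` separated by ``delta``,
    ``AUC = Phi(delta / (scale * sqrt(2)))``.
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError("target_auc must be in [0.5, 1)")
    return float(stats.norm.ppf(target_auc) * scale * np.sqrt(2.0))


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class MarkerSpec:
    """Generative model of one MRM marker (protein with one proteotypic peptide).

    ``group_loc``/``group_scale`` parameterize the per-group log-normal
    relative level; groups absent from ``group_loc`` default to 0 (median
    ratio 1, inside the 0.1-10 reference range).
    """

    name: str
    direction: str = "null"  # up | down | null, bookkeeping for reports
    group_loc: Mapping[str, float] = field(default_factory=dict)
    group_scale: float = 0.5
    nonexpressor_fraction: float = 0.0
    n_transitions: int = 3
    replicate_cv: float | None = None  # overrides CohortConfig.replicate_cv
    batch_effect_fold: float = 1.0  # multiplicative shift on odd batches
    transition_responses: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.direction not in ("up", "down", "null"):
            raise ValueError(f"direction must be up/down/null, got {self.direction!r}")
        if self.group_scale <= 0:
            raise ValueError("group_scale must be positive")
        if not 0.0 <= self.nonexpressor_fraction <= 1.0:
            raise ValueError("nonexpressor_fraction must be in [0, 1]")
        if self.n_transitions < 1:
            raise ValueError("n_transitions must be positive")
        if self.replicate_cv is not None and self.replicate_cv < 0:
            raise ValueError("replicate_cv must be non-negative")
        if self.batch_effect_fold <= 0:
            raise ValueError("batch_effect_fold must be positive")
        if self.transition_responses is not None:
            if len(self.transition_responses) != self.n_transitions:
                raise ValueError("transition_responses length must equal n_transitions")
            if any(r <= 0 for r in self.transition_responses):
                raise ValueError("transition responses must be positive")

    def loc(self, group: str) -> float:
        return float(self.group_loc.get(group, 0.0))


def default_marker_specs(n_decoys: int = 20,
                         informative_auc: float = 0.73,
                         scale: float = 0.5) -> list[MarkerSpec]:
    """Two informative markers (one up, one down in PDAC) plus decoys.

    Effect sizes are set so each informative marker alone separates PDAC
    from controls with the given AUC.  The default (0.73 per marker,
    i.e. a two-marker combination AUC of ~0.81) is back-calculated from
    the reported triple-panel performance: with ~35% of cancer cases
    presenting CA19-9 in the normal range, an overall panel AUC of ~0.93
    alongside an anchor AUC of ~0.83 requires the two protein markers to
    contribute a combined AUC of ~0.81 in the anchor-blind subset.
    """
    delta = effect_for_auc(informative_auc, scale)
    specs = [
        MarkerSpec("LRG1", direction="up", group_loc={"PDAC": +delta},
                   group_scale=scale),
        MarkerSpec("TTR", direction="down", group_loc={"PDAC": -delta},
                   group_scale=scale),
    ]
    specs += [
        MarkerSpec(f"DECOY{i:02d}", direction="null", group_scale=scale)
        for i in range(1, n_decoys + 1)
    ]
    return specs


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs; ``seed`` is mandatory.

    CA19-9 in cancer cases is a three-part mixture: flagged non-expressors
    (Lewis-antigen-negative; drawn from the control distribution),
    unflagged low expressors (also control-like, so that the
    normal-range case subset carries essentially no CA19-9 signal, as
    observed clinically), and elevated expressors drawn from a log-normal
    truncated above the clinical normal range (37 U/mL) whose location is
    solved so the overall mixture median matches the configured per-center
    median.  The default normal-range case fraction (non-expressors plus
    low expressors, 0.125 + 0.225) reproduces the observed share of cancer
    cases presenting within the CA19-9 normal range.
    """

    seed: int
    group_sizes: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {k: v["n"] for k, v in DEFAULT_CENTER_TABLE.items()})
    stage_distribution: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {k[1]: dict(v["stages"])
                                 for k, v in DEFAULT_CENTER_TABLE.items()
                                 if k[0] == "PDAC"})
    marker_specs: Sequence[MarkerSpec] = field(default_factory=default_marker_specs)
    ca199_table: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: {k: v["ca199"] for k, v in DEFAULT_CENTER_TABLE.items()})
    ca199_nonexpressor_fraction: float = 0.125
    ca199_low_expressor_fraction: float = 0.225
    ca199_normal_range: float = 37.0
    ca199_censor_bounds: tuple[float, float] = (1.2, 10_000.0)
    missing_rate: float = 0.02
    n_replicates: int = 3
    n_decoy_markers: int = 0  # extra null markers appended to marker_specs
    interference_rate: float = 0.0
    interference_strength: float = 1.0
    replicate_cv: float = 0.08
    heavy_cv: float = 0.02
    n_batches: int = 12
    heavy_area: float = 1.0e5
    external_standard_area: float = 2.0e5

    def __post_init__(self):
        for key, n in self.group_sizes.items():
            if n < 0:
                raise ValueError(f"negative group size for {key}: {n}")
            if key[0] not in GROUPS:
                raise ValueError(f"unknown group {key[0]!r}")
        for name, frac in [
            ("ca199_nonexpressor_fraction", self.ca199_nonexpressor_fraction),
            ("ca199_low_expressor_fraction", self.ca199_low_expressor_fraction),
            ("missing_rate", self.missing_rate),
            ("interference_rate", self.interference_rate),
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if self.ca199_nonexpressor_fraction + self.ca199_low_expressor_fraction >= 0.5:
            raise ValueError(
                "non-expressor plus low-expressor fraction must stay below 0.5 "
                "for the elevated-median calibration to be solvable")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        if self.n_decoy_markers < 0:
            raise ValueError("n_decoy_markers must be non-negative")
        if self.replicate_cv < 0 or self.heavy_cv < 0:
            raise ValueError("technical CVs must be non-negative")
        if self.n_batches < 1:
            raise ValueError("n_batches must be positive")
        lo, hi = self.ca199_censor_bounds
        if lo >= hi:
            raise ValueError("censor bounds must satisfy low < high")
        # stage counts must sum to the per-center PDAC count
        for center, stage_counts in self.stage_distribution.items():
            n_pdac = self.group_sizes.get(("PDAC", center), 0)
            total = sum(stage_counts.values())
            if total != n_pdac:
                raise ValueError(
                    f"stage counts for center {center} sum to {total}, "
                    f"but PDAC size there is {n_pdac}")

    @property
    def all_marker_specs(self) -> list[MarkerSpec]:
        extra = [
            MarkerSpec(f"XDECOY{i:02d}", direction="null")
            for i in range(1, self.n_decoy_markers + 1)
        ]
        return list(self.marker_specs) + extra

    @property
    def total_samples(self) -> int:
        return int(sum(self.group_sizes.values()))


def default_cohort_config(seed: int, scale: int = 1, **overrides) -> CohortConfig:
    """The multi-center validation cohort at (optionally scaled) default size."""
    if scale != 1:
        sizes = {k: v["n"] * scale for k, v in DEFAULT_CENTER_TABLE.items()}
        stages = {k[1]: {s: c * scale for s, c in v["stages"].items()}
                  for k, v in DEFAULT_CENTER_TABLE.items() if k[0] == "PDAC"}
        overrides.setdefault("group_sizes", sizes)
        overrides.setdefault("stage_distribution", stages)
    return CohortConfig(seed=seed, **overrides)


def null_cohort_config(seed: int, **overrides) -> CohortConfig:
    """A cohort with no informative signal anywhere.

    All marker effects are removed and CA19-9 in every group is drawn from
    the control distribution, so any panel that survives selection on such
    a cohort is a false positive.
    """
    nl_params = DEFAULT_CENTER_TABLE[("NL", "SNUH")]["ca199"]
    table = {k: nl_params for k in DEFAULT_CENTER_TABLE}
    specs = [replace(s, group_loc={}, direction="null")
             for s in default_marker_specs()]
    overrides.setdefault("ca199_table", table)
    overrides.setdefault("marker_specs", specs)
    overrides.setdefault("ca199_nonexpressor_fraction", 0.0)
    overrides.setdefault("ca199_low_expressor_fraction", 0.0)
    return CohortConfig(seed=seed, **overrides)


def _truncated_elevated_draw(rng: np.random.Generator, n: int,
                             mixture_median: float, sigma: float,
                             w_low: float, lower: float) -> np.ndarray:
    """Elevated-expressor CA19-9: log-normal truncated above ``lower``.

    The log-location ``mu`` is solved so that, mixed with a ``w_low``
    control-like mass sitting (essentially entirely) below ``lower``, the
    overall mixture median equals ``mixture_median``.  Falls back to an
    untruncated quantile-shifted log-normal when the target median is not
    clearly above the truncation point.
    """
    q = (0.5 - w_low) / (1.0 - w_low)
    big_m = np.log(mixture_median)
    t = np.log(lower)
    if big_m <= t + 0.05:  # target median at/below the normal range: no truncation
        mu = big_m - sigma * stats.norm.ppf(q)
    else:
        def h(mu_):
            fb = stats.norm.cdf((t - mu_) / sigma)
            fa = stats.norm.cdf((big_m - mu_) / sigma)
            return (fa - fb) / max(1.0 - fb, 1e-300) - q

        # conditional-median is monotone in mu; scan down for a bracket
        lo = big_m
        while h(lo) < 0 and lo > t - 12.0 * sigma:
            lo -= sigma
        mu = optimize.brentq(h, lo, big_m + 12.0 * sigma)
    fb = stats.norm.cdf((t - mu) / sigma)
    u = fb + rng.random(n) * (1.0 - fb)
    return np.exp(mu + sigma * stats.norm.ppf(u))


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Latent labels emitted alongside generated data, for recovery tests."""

    informative_markers: set[str] = field(default_factory=set)
    interfered_transitions: set[tuple[str, str]] = field(default_factory=set)
    batch_affected_markers: set[str] = field(default_factory=set)
    high_cv_markers: set[str] = field(default_factory=set)
    out_of_range_markers: set[str] = field(default_factory=set)
    nonexpressors: set[str] = field(default_factory=set)  # sample ids (CA19-9)
    ca199_control_like: set[str] = field(default_factory=set)
    class_labels: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    transition_responses: dict[tuple[str, str], float] = field(default_factory=dict)
    latent_abundance: pd.DataFrame | None = None  # samples x markers, log scale


# ---------------------------------------------------------------------------
# cohort generation


def _rng_streams(seed: int, n: int = 4) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _control_ca199_params(config: CohortConfig) -> tuple[float, float]:
    """Pooled control (NL) CA19-9 median and log-SD."""
    nl = [(k, config.ca199_table[k]) for k in config.group_sizes if k[0] == "NL"]
    if not nl:
        raise ValueError("config has no NL group to define the control CA19-9 distribution")
    # size-weighted log-median; sigma from the largest NL center
    key, (median, mad) = max(nl, key=lambda kv: config.group_sizes[kv[0]])
    return median, lognormal_sigma_from_mad(median, mad)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """One row per sample: clinical annotation plus CA19-9 with flags.

    Returns the sample-metadata table and a :class:`GroundTruth` carrying
    the latent CA19-9 expressor labels.  Batches are assigned by blocked
    randomization: each group's samples are dealt round-robin over batches,
    so per-batch group composition deviates from the global composition by
    at most one sample per group.
    """
    rng_cohort, rng_batch = _rng_streams(config.seed, 4)[:2]
    gt = GroundTruth()
    rows: list[dict] = []

    w_low = config.ca199_nonexpressor_fraction + config.ca199_low_expressor_fraction
    ctrl_median, ctrl_sigma = (None, None)
    if any(k[0] == "NL" for k in config.group_sizes):
        ctrl_median, ctrl_sigma = _control_ca199_params(config)

    counter = 0
    for (group, center), n in sorted(config.group_sizes.items()):
        if n == 0:
            continue
        demo = DEFAULT_CENTER_TABLE.get((group, center), {})
        median, mad = config.ca199_table.get((group, center), (None, None))
        sigma = lognormal_sigma_from_mad(median, mad) if median else None

        # stage assignment (PDAC only), exact counts then shuffled
        stages = np.array([None] * n, dtype=object)
        if group == "PDAC":
            counts = config.stage_distribution.get(center, {})
            pool = [s for s, c in counts.items() for _ in range(c)]
            stages = np.array(pool, dtype=object)
            rng_cohort.shuffle(stages)
        subgroups = np.array([None] * n, dtype=object)
        if "subgroups" in demo:
            # proportional (largest-remainder) allocation of cosmetic subtypes
            items = sorted(demo["subgroups"].items())
            total = sum(c for _, c in items)
            exact = [(name, c * n / total) for name, c in items]
            counts = {name: int(np.floor(x)) for name, x in exact}
            leftover = n - sum(counts.values())
            for name, _ in sorted(exact, key=lambda kv: kv[1] - np.floor(kv[1]),
                                  reverse=True)[:leftover]:
                counts[name] += 1
            pool = [s for s, c in counts.items() for _ in range(c)]
            subgroups = np.array(pool, dtype=object)
            rng_cohort.shuffle(subgroups)

        # latent expressor class for cancer cases
        is_nonexpr = np.zeros(n, dtype=bool)
        is_lowexpr = np.zeros(n, dtype=bool)
        if group == "PDAC" and ctrl_median is not None:
            u = rng_cohort.random(n)
            is_nonexpr = u < config.ca199_nonexpressor_fraction
            is_lowexpr = (~is_nonexpr) & (
                u < config.ca199_nonexpressor_fraction + config.ca199_low_expressor_fraction)

        # CA19-9 draws
        ca199 = np.full(n, np.nan)
        if median is not None:
            z = rng_cohort.standard_normal(n)
            if group == "PDAC" and w_low > 0 and ctrl_median is not None:
                elevated = _truncated_elevated_draw(
                    rng_cohort, n, median, sigma, w_low,
                    config.ca199_normal_range)
                ctrl_draw = ctrl_median * np.exp(ctrl_sigma * rng_cohort.standard_normal(n))
                control_like = is_nonexpr | is_lowexpr
                ca199 = np.where(control_like, ctrl_draw, elevated)
            else:
                ca199 = median * np.exp(sigma * z)

        lo, hi = config.ca199_censor_bounds
        censored = np.where(ca199 < lo, "low", np.where(ca199 > hi, "high", "none"))
        ca199 = np.clip(ca199, lo, hi)
        missing = rng_cohort.random(n) < config.missing_rate
        ca199 = np.where(missing, np.nan, ca199)
        censored = np.where(missing, "none", censored)

        age_mu, age_sd = demo.get("age", (60.0, 10.0))
        bmi_mu, bmi_sd = demo.get("bmi", (23.0, 3.0))
        male = demo.get("male", 0.5)

        for i in range(n):
            sid = f"S{counter:05d}"
            counter += 1
            rows.append(dict(
                sample_id=sid, group=group, center=center,
                subgroup=subgroups[i], stage=stages[i],
                age=float(age_mu + age_sd * rng_cohort.standard_normal()),
                sex="M" if rng_cohort.random() < male else "F",
                bmi=float(bmi_mu + bmi_sd * rng_cohort.standard_normal()),
                ca199=float(ca199[i]) if not missing[i] else np.nan,
                ca199_censored=str(censored[i]),
                ca199_missing=bool(missing[i]),
            ))
            if is_nonexpr[i]:
                gt.nonexpressors.add(sid)
            if is_nonexpr[i] or is_lowexpr[i]:
                gt.ca199_control_like.add(sid)

    meta = pd.DataFrame(rows, columns=[
        "sample_id", "group", "center", "subgroup", "stage", "age", "sex",
        "bmi", "ca199", "ca199_censored", "ca199_missing"])
    if meta.empty:
        meta["batch"] = pd.Series(dtype=object)
        gt.class_labels = pd.Series(dtype=object)
        return meta, gt

    # blocked randomization of batches within groups
    batch = pd.Series(index=meta["sample_id"], dtype=object)
    for group in meta["group"].unique():
        ids = meta.loc[meta["group"] == group, "sample_id"].to_numpy().copy()
        rng_batch.shuffle(ids)
        for j, sid in enumerate(ids):
            batch[sid] = f"B{j % config.n_batches + 1:02d}"
    meta["batch"] = meta["sample_id"].map(batch)

    gt.class_labels = meta.set_index("sample_id")["group"]
    # marker-level truth is filled in by generate_transition_data
    return meta, gt


# ---------------------------------------------------------------------------
# transition-level data


def generate_transition_data(meta: pd.DataFrame, config: CohortConfig,
                             ground_truth: GroundTruth | None = None) -> pd.DataFrame:
    """Skyline-export-style transition table for each sample x marker.

    For every sample and marker, ``n_transitions`` transitions x
    ``n_replicates`` replicates are produced.  Heavy (SIS) areas are
    constant per transition up to technical noise; light areas are latent
    abundance x transition response x multiplicative replicate noise, plus
    an additive light-channel-only contamination on interfered transitions.

    When ``ground_truth`` is passed, the latent abundances, transition
    responses and interfered-transition set are recorded on it.
    """
    if meta.empty:
        raise ValueError("meta must be non-empty")
    specs = config.all_marker_specs
    if not specs:
        raise ValueError("config contains no marker specs")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate marker names in config")

    rng = _rng_streams(config.seed, 4)[2]
    n_samples = len(meta)
    n_rep = config.n_replicates
    sample_ids = meta["sample_id"].to_numpy()
    groups = meta["group"].to_numpy()
    batches = meta["batch"].to_numpy()
    batch_idx = np.array([int(str(b)[1:]) for b in batches])

    gt = ground_truth if ground_truth is not None else GroundTruth()
    latent_cols: dict[str, np.ndarray] = {}
    frames: list[pd.DataFrame] = []

    for spec in specs:
        if spec.group_loc:
            gt.informative_markers.add(spec.name)
        if spec.batch_effect_fold != 1.0:
            gt.batch_affected_markers.add(spec.name)
        cv = config.replicate_cv if spec.replicate_cv is None else spec.replicate_cv
        if cv > 0.15:
            gt.high_cv_markers.add(spec.name)

        loc = np.array([spec.loc(g) for g in groups])
        if spec.nonexpressor_fraction > 0:
            is_case = groups == "PDAC"
            nonexpr = is_case & (rng.random(n_samples) < spec.nonexpressor_fraction)
            loc = np.where(nonexpr, spec.loc("NL"), loc)
        if spec.batch_effect_fold != 1.0:
            loc = loc + np.where(batch_idx % 2 == 1, np.log(spec.batch_effect_fold), 0.0)
        latent = loc + spec.group_scale * rng.standard_normal(n_samples)
        latent_cols[spec.name] = latent
        med_level = float(np.exp(np.median(latent)))
        if not (0.1 < med_level < 10.0):
            gt.out_of_range_markers.add(spec.name)

        nt = spec.n_transitions
        if spec.transition_responses is not None:
            resp = np.asarray(spec.transition_responses, dtype=float)
        else:
            resp = rng.uniform(0.2, 1.0, size=nt)
            resp = resp / resp.sum()
        tids = [f"t{k + 1}" for k in range(nt)]
        for tid, r in zip(tids, resp):
            gt.transition_responses[(spec.name, tid)] = float(r)

        interfered = rng.random(nt) < config.interference_rate
        for tid, hit in zip(tids, interfered):
            if hit:
                gt.interfered_transitions.add((spec.name, tid))

        # areas: (samples, transitions, replicates)
        sigma_l = np.sqrt(np.log1p(cv ** 2))
        sigma_h = np.sqrt(np.log1p(config.heavy_cv ** 2))
        shape = (n_samples, nt, n_rep)
        light_noise = np.exp(sigma_l * rng.standard_normal(shape)) if sigma_l > 0 else np.ones(shape)
        heavy_noise = np.exp(sigma_h * rng.standard_normal(shape)) if sigma_h > 0 else np.ones(shape)
        base = config.heavy_area * resp[None, :, None]
        heavy = base * heavy_noise
        light = np.exp(latent)[:, None, None] * base * light_noise
        if interfered.any():
            ref = config.interference_strength * config.heavy_area * resp \
                * float(np.exp(np.median(latent)))
            jitter = np.exp(0.25 * rng.standard_normal(shape))
            light = light + np.where(interfered[None, :, None], ref[None, :, None] * jitter, 0.0)

        ext = config.external_standard_area * np.exp(
            sigma_h * rng.standard_normal(shape)) if sigma_h > 0 \
            else np.full(shape, config.external_standard_area)

        frames.append(pd.DataFrame({
            "sample_id": np.repeat(sample_ids, nt * n_rep),
            "replicate": np.tile(np.arange(1, n_rep + 1), n_samples * nt),
            "batch": np.repeat(batches, nt * n_rep),
            "protein": spec.name,
            "peptide": f"{spec.name}.p1",
            "transition_id": np.tile(np.repeat(tids, n_rep), n_samples),
            "area_light": light.reshape(-1),
            "area_heavy": heavy.reshape(-1),
            "area_external_standard": ext.reshape(-1),
        }))

    gt.latent_abundance = pd.DataFrame(latent_cols, index=sample_ids)
    records = pd.concat(frames, ignore_index=True)
    return records


# ---------------------------------------------------------------------------
# second measurement platform (immunoassay-like)


@dataclass(frozen=True)
class SecondPlatformModel:
    """Monotone transform of the MRM ratio plus independent log-scale noise.

    ``log C = intercept + slope * log R + e`` with ``sd(e)`` chosen per
    marker so the log-log Pearson correlation with the MRM ratio equals
    ``target_correlation`` (1.0 means no added noise).
    """

    target_correlation: float = 0.9
    slope: float = 1.0
    intercept: float = float(np.log(500.0))  # ~ng/mL-like units

    def __post_init__(self):
        if not 0.0 < self.target_correlation <= 1.0:
            raise ValueError("target_correlation must be in (0, 1]")
        if self.slope <= 0:
            raise ValueError("slope must be positive (monotone increasing)")


def generate_second_platform(meta: pd.DataFrame, quant: pd.DataFrame,
                             noise_model: SecondPlatformModel | None = None,
                             seed: int | None = None,
                             config: CohortConfig | None = None) -> pd.DataFrame:
    """Immunoassay-like concentrations for the quantified markers.

    ``quant`` is the long-format peptide quantitation table (one row per
    sample x peptide with a ``relative_level`` column).  Returns a long
    table of sample_id, protein, concentration.
    """
    model = noise_model or SecondPlatformModel()
    if seed is None:
        if config is None:
            raise ValueError("pass either seed or config")
        seed = config.seed
    rng = _rng_streams(seed, 4)[3]
    if quant.empty:
        return pd.DataFrame(columns=["sample_id", "protein", "concentration"])

    out = []
    for protein, grp in quant.groupby("protein", sort=True):
        levels = grp["relative_level"].to_numpy(dtype=float)
        ok = np.isfinite(levels) & (levels > 0)
        logr = np.full(levels.shape, np.nan)
        logr[ok] = np.log(levels[ok])
        r = model.target_correlation
        if r < 1.0:
            sd_x = np.nanstd(logr)
            noise_sd = model.slope * sd_x * np.sqrt(1.0 / r ** 2 - 1.0)
        else:
            noise_sd = 0.0
        logc = model.intercept + model.slope * logr
        if noise_sd > 0:
            logc = logc + noise_sd * rng.standard_normal(len(logc))
        out.append(pd.DataFrame({
            "sample_id": grp["sample_id"].to_numpy(),
            "protein": protein,
            "concentration": np.exp(logc),
        }))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# file output


def write_cohort(outdir, meta: pd.DataFrame, records: pd.DataFrame | None = None) -> None:
    """Write sample metadata as TSV and transition data as Skyline-style CSV."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    meta.to_csv(out / "sample_meta.tsv", sep="\t", index=False)
    if records is not None:
        cols = ["sample_id", "replicate", "batch", "protein", "peptide",
                "transition_id", "area_light", "area_heavy",
                "area_external_standard"]
        records[cols].to_csv(out / "transitions.csv", index=False)
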