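"""Synthetic cohorts of paediatric TBI and control subjects.

Real inputs to the analysis are per-subject connectivity matrices (78x78
streamline counts from probabilistic tractography; 59x59 Pearson correlation
matrices from task fMRI) plus demographic and Conners 3-PS symptom data.
None are publicly deposited, so this module generates cohorts with the
statistical structure the downstream analysis assumes:

* two groups with group-matched demographics drawn around published-style
  means and SDs;
* streamline counts from a negative-binomial model over a fixed random
  topology shared by all subjects, so planted group effects act
  multiplicatively on a designated node's connections;
* correlation matrices computed from simulated ROI time series under a
  module-factor model, guaranteeing positive semidefiniteness;
* optional planted group effects on chosen nodes (calibrated to a target
  Cohen's d on the node's strength/degree) and planted couplings between
  chosen topological features and symptom T-scores.

Group-comparison statistics (Pearson chi-square without continuity
correction, Welch's unequal-variance t) live here too because the cohort
table is where they are reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics as _metrics
from .networks import binarize_at_cost, build_structural_network

__all__ = [
    "MotionSummary",
    "SubjectRecord",
    "CohortConfig",
    "Cohort",
    "StructuralProfile",
    "FunctionalProfile",
    "generate_cohort",
    "generate_structural_counts",
    "generate_functional_correlations",
    "apply_motion_exclusion",
    "chi_square_independence",
    "welch_t_from_summary",
    "DEFAULT_DEMOGRAPHICS",
]

# Group means (SDs) in the style of a matched TBI/control cohort table:
# age in years, SES in years of parental education, IQ on the WASI-II scale,
# symptom scales as Conners 3-PS T-scores (population mean 50, SD 10).
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"control": (13.06, 2.03), "tbi": (13.63, 2.28)},
    "ses": {"control": (16.47, 2.13), "tbi": (15.70, 2.09)},
    "iq": {"control": (113.00, 11.23), "tbi": (110.97, 13.72)},
    "inattention_t": {"control": (46.15, 6.02), "tbi": (64.73, 13.49)},
    "hyperactivity_t": {"control": (48.38, 5.42), "tbi": (58.44, 14.43)},
}
_SEX_P_MALE = {"control": 30 / 55, "tbi": 33 / 55}
_ETHNICITY_P = {
    "control": {"Caucasian": 30 / 55, "Hispanic": 8 / 55, "Others": 17 / 55},
    "tbi": {"Caucasian": 36 / 55, "Hispanic": 11 / 55, "Others": 8 / 55},
}
_TSCORE_RANGE = (30.0, 100.0)

# Head-motion inclusion cutoffs (exceeding any one excludes the scan).
MOTION_CUTOFFS = {"max_translation": 2.0, "max_rotation": 5.0,
                  "mean_vol_displacement": 0.2}

# Multiplicative effect calibration: a planted effect of Cohen's d scales the
# designated node's expected streamline counts by exp(-_STRUCT_EFFECT_SCALE*d)
# (TBI group), or its module-factor loading by exp(-_FUNC_EFFECT_SCALE*d).
# Constants chosen by simulation so the measured d on the node's downstream
# strength/degree approximates the requested d at the default generator
# settings (see docs/methods.md).
_STRUCT_EFFECT_SCALE = 0.145
_FUNC_EFFECT_SCALE = 0.85


@dataclass(frozen=True)
class MotionSummary:
    """Scan-quality summary in mm / degrees / mm."""

    max_translation: float
    max_rotation: float
    mean_vol_displacement: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass
class SubjectRecord:
    id: str
    group: Literal["tbi", "control"]
    age: float
    sex: Literal["M", "F"]
    ethnicity: str
    ses: float
    iq: float
    inattention_t: float
    hyperactivity_t: float
    motion: MotionSummary
    handedness: str = "right"  # right-handedness is an inclusion criterion


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort generator.

    ``effect_nodes`` lists (network kind, node index) pairs; for TBI subjects
    the generator attenuates those nodes' connectivity so that the node's
    downstream strength (structural) or degree (functional) differs between
    groups by approximately ``effect_size`` in Cohen's d units.
    ``symptom_coupling`` lists (feature id, target scale, slope) triples; the
    named topological feature, z-scored across the cohort, is added to the
    target T-score with the given slope (T-score points per SD of feature).
    """

    n_per_group: int = 55
    n_struct_nodes: int = 78
    n_func_nodes: int = 59
    effect_nodes: Sequence[tuple[str, int]] = ()
    effect_size: float = 0.0
    symptom_coupling: Sequence[tuple[str, str, float]] = ()
    demographic_means_sds: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()})
    seed: int = 0
    # structural count model
    struct_density: float = 0.35
    count_log_mean: float = 3.2
    count_log_sd: float = 0.9
    nb_dispersion: float = 10.0
    subject_scale_sd: float = 0.08
    # functional time-series model
    n_modules: int = 5
    loading_module: float = 0.6
    loading_global: float = 0.3
    ts_noise_sd: float = 1.0
    ts_length: int = 300
    #: reference cost at which functional features are evaluated for couplings
    coupling_cost: float = 0.25

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for kind, node in self.effect_nodes:
            limit = {"struct": self.n_struct_nodes, "func": self.n_func_nodes}.get(kind)
            if limit is None:
                raise ValueError(f"unknown network kind {kind!r} (use 'struct' or 'func')")
            if not (0 <= node < limit):
                raise ValueError(f"effect node {node} out of range for {kind} ({limit} nodes)")
        for feat, scale, _slope in self.symptom_coupling:
            if scale not in ("inattention_t", "hyperactivity_t"):
                raise ValueError(f"unknown symptom scale {scale!r}")
            _parse_feature_id(feat, self.n_struct_nodes, self.n_func_nodes)


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    structural_counts: list[np.ndarray]
    functional_corr: list[np.ndarray]
    ground_truth: dict

    @property
    def labels(self) -> np.ndarray:
        """Binary group labels, 1 = TBI."""
        return np.array([1 if s.group == "tbi" else 0 for s in self.subjects])

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            row = {k: v for k, v in asdict(s).items() if k != "motion"}
            row.update(asdict(s.motion))
            rows.append(row)
        return pd.DataFrame(rows)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cols = ["id", "group", "age", "sex", "ethnicity", "ses", "iq",
                "handedness", "inattention_t", "hyperactivity_t",
                "max_translation", "max_rotation", "mean_vol_displacement"]
        self.metadata_frame()[cols].to_csv(directory / "metadata.csv", index=False)
        for s, counts, corr in zip(self.subjects, self.structural_counts,
                                   self.functional_corr):
            np.savetxt(directory / f"{s.id}_struct.csv", counts,
                       delimiter=",", fmt="%d")
            np.savetxt(directory / f"{s.id}_func.csv", corr,
                       delimiter=",", fmt="%.10f")
        with open(directory / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2)

    @classmethod
    def load(cls, directory: str | Path) -> "Cohort":
        directory = Path(directory)
        meta = pd.read_csv(directory / "metadata.csv")
        subjects, s_counts, f_corrs = [], [], []
        for _, row in meta.iterrows():
            subjects.append(SubjectRecord(
                id=row["id"], group=row["group"], age=row["age"],
                sex=row["sex"], ethnicity=row["ethnicity"], ses=row["ses"],
                iq=row["iq"], inattention_t=row["inattention_t"],
                hyperactivity_t=row["hyperactivity_t"],
                handedness=row["handedness"],
                motion=MotionSummary(row["max_translation"], row["max_rotation"],
                                     row["mean_vol_displacement"])))
            s_counts.append(np.loadtxt(directory / f"{row['id']}_struct.csv",
                                       delimiter=","))
            f_corrs.append(np.loadtxt(directory / f"{row['id']}_func.csv",
                                      delimiter=","))
        gt_path = directory / "ground_truth.json"
        gt = json.loads(gt_path.read_text()) if gt_path.exists() else {}
        return cls(subjects, s_counts, f_corrs, gt)


@dataclass
class StructuralProfile:
    """Cohort-level streamline-count model shared by every subject."""

    mask: np.ndarray         # symmetric boolean edge support
    base_mean: np.ndarray    # expected count per supported edge
    dispersion: float


@dataclass
class FunctionalProfile:
    """Cohort-level ROI time-series factor model."""

    module_of: np.ndarray    # module index per ROI
    loading_module: float
    loading_global: float
    noise_sd: float
    ts_length: int


def _parse_feature_id(feature_id: str, n_struct: int, n_func: int
                      ) -> tuple[str, str, int]:
    parts = feature_id.split("_")
    if len(parts) < 3 or parts[0] not in ("struct", "func"):
        raise ValueError(f"bad feature id {feature_id!r}; expected "
                         "'<struct|func>_<metric>_<node>'")
    kind = parts[0]
    metric = "_".join(parts[1:-1])
    if metric not in _metrics.METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r} in {feature_id!r}")
    node = int(parts[-1])
    limit = n_struct if kind == "struct" else n_func
    if not (0 <= node < limit):
        raise ValueError(f"node {node} out of range in {feature_id!r}")
    return kind, metric, node


def make_structural_profile(config: CohortConfig,
                            rng: np.random.Generator) -> StructuralProfile:
    n = config.n_struct_nodes
    iu = np.triu_indices(n, k=1)
    mask = np.zeros((n, n), dtype=bool)
    mask[iu] = rng.random(len(iu[0])) < config.struct_density
    mask |= mask.T
    base = np.zeros((n, n))
    base[iu] = np.exp(rng.normal(config.count_log_mean, config.count_log_sd,
                                 size=len(iu[0])))
    base = base + base.T
    base[~mask] = 0.0
    return StructuralProfile(mask=mask, base_mean=base,
                             dispersion=config.nb_dispersion)


def generate_structural_counts(profile: StructuralProfile, config: CohortConfig,
                               seed: int | np.random.Generator,
                               node_multipliers: dict[int, float] | None = None
                               ) -> np.ndarray:
    """One subject's symmetric integer streamline-count matrix.

    Supported edges draw ``1 + NegBin`` around the profile mean (so density
    1.0 yields a complete positive matrix); ``node_multipliers`` scales the
    expected counts of every edge incident to the given nodes, which is how
    group effects are planted.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = profile.base_mean.shape[0]
    mean = profile.base_mean * np.exp(rng.normal(0.0, config.subject_scale_sd))
    if node_multipliers:
        factor = np.ones(n)
        for node, mult in node_multipliers.items():
            factor[node] *= mult
        mean = mean * factor[:, None] * factor[None, :]
    counts = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    sup = profile.mask[iu]
    mu = np.clip(mean[iu][sup] - 1.0, 1e-9, None)
    r = profile.dispersion
    p = r / (r + mu)
    draws = 1 + rng.negative_binomial(r, p)
    vals = np.zeros(len(iu[0]))
    vals[sup] = draws
    counts[iu] = vals
    counts = counts + counts.T
    return counts


def make_functional_profile(config: CohortConfig,
                            rng: np.random.Generator) -> FunctionalProfile:
    module_of = rng.integers(0, config.n_modules, size=config.n_func_nodes)
    return FunctionalProfile(module_of=module_of,
                             loading_module=config.loading_module,
                             loading_global=config.loading_global,
                             noise_sd=config.ts_noise_sd,
                             ts_length=config.ts_length)


def generate_functional_correlations(profile: FunctionalProfile,
                                     config: CohortConfig,
                                     seed: int | np.random.Generator,
                                     node_loading_multipliers: dict[int, float] | None = None
                                     ) -> np.ndarray:
    """One subject's ROI-by-ROI correlation matrix.

    Built as the empirical correlation of simulated time series
    ``x_i(t) = lg*g(t) + lm_i*f_{m(i)}(t) + sd*eps_i(t)`` (shared global
    factor, module factor, independent noise), so the result is symmetric
    positive semidefinite with unit diagonal by construction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(profile.module_of)
    T = profile.ts_length
    n_modules = int(profile.module_of.max()) + 1 if n else 0
    g = rng.standard_normal(T)
    fm = rng.standard_normal((n_modules, T))
    lm = np.full(n, profile.loading_module)
    if node_loading_multipliers:
        for node, mult in node_loading_multipliers.items():
            lm[node] *= mult
    X = (profile.loading_global * g[None, :]
         + lm[:, None] * fm[profile.module_of]
         + profile.noise_sd * rng.standard_normal((n, T)))
    corr = np.corrcoef(X)
    np.fill_diagonal(corr, 1.0)
    return corr


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int, lo: float, hi: float) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


def _draw_motion(rng: np.random.Generator) -> MotionSummary:
    # typical compliant paediatric values, occasionally brushing the cutoffs
    return MotionSummary(
        max_translation=float(np.exp(rng.normal(-0.6, 0.55))),
        max_rotation=float(np.exp(rng.normal(0.0, 0.6))),
        mean_vol_displacement=float(np.exp(rng.normal(-3.0, 0.55))),
    )


def apply_motion_exclusion(motion: MotionSummary) -> bool:
    """True when the scan passes the head-motion inclusion cutoffs.

    A scan is excluded only when a summary strictly exceeds its cutoff
    (> 2 mm translation, > 5 deg rotation, > 0.2 mm mean volume-by-volume
    displacement); values exactly at a cutoff are included.
    """
    return not (motion.max_translation > MOTION_CUTOFFS["max_translation"]
                or motion.max_rotation > MOTION_CUTOFFS["max_rotation"]
                or motion.mean_vol_displacement > MOTION_CUTOFFS["mean_vol_displacement"])


def _feature_values(cohort_matrices: list[np.ndarray], kind: str, metric: str,
                    node: int, coupling_cost: float) -> np.ndarray:
    """One topological feature evaluated per subject (for planted couplings)."""
    vals = np.empty(len(cohort_matrices))
    for i, M in enumerate(cohort_matrices):
        if kind == "struct":
            W = build_structural_network(M).weights
            vals[i] = _metrics.compute_nodal_metrics(W, weighted=True)[metric][node]
        else:
            A = binarize_at_cost(M, coupling_cost)
            vals[i] = _metrics.compute_nodal_metrics(A, weighted=False)[metric][node]
    return vals


def generate_cohort(config: CohortConfig) -> Cohort:
    """Deterministically generate a full two-group cohort from one config."""
    ss = np.random.SeedSequence(config.seed)
    rng_demo, rng_profile, rng_struct, rng_func, rng_couple = (
        np.random.default_rng(s) for s in ss.spawn(5))

    groups = ["control"] * config.n_per_group + ["tbi"] * config.n_per_group
    n_total = len(groups)

    struct_profile = make_structural_profile(config, rng_profile)
    func_profile = make_functional_profile(config, rng_profile)

    struct_mult = np.exp(-_STRUCT_EFFECT_SCALE * config.effect_size)
    func_mult = np.exp(-_FUNC_EFFECT_SCALE * config.effect_size)
    struct_effects = {node: struct_mult for kind, node in config.effect_nodes
                      if kind == "struct"}
    func_effects = {node: func_mult for kind, node in config.effect_nodes
                    if kind == "func"}

    structural_counts, functional_corr = [], []
    for g in groups:
        s_eff = struct_effects if g == "tbi" else None
        f_eff = func_effects if g == "tbi" else None
        structural_counts.append(
            generate_structural_counts(struct_profile, config, rng_struct, s_eff))
        functional_corr.append(
            generate_functional_correlations(func_profile, config, rng_func, f_eff))

    demo = config.demographic_means_sds
    lo, hi = _TSCORE_RANGE
    records: list[SubjectRecord] = []
    tscores = {"inattention_t": np.empty(n_total),
               "hyperactivity_t": np.empty(n_total)}
    for i, g in enumerate(groups):
        vals = {}
        for var in ("age", "ses", "iq"):
            m, sd = demo[var][g]
            vals[var] = float(rng_demo.normal(m, sd))
        for var in ("inattention_t", "hyperactivity_t"):
            m, sd = demo[var][g]
            tscores[var][i] = _truncated_normal(rng_demo, m, sd, 1, lo, hi)[0]
        sex = "M" if rng_demo.random() < _SEX_P_MALE[g] else "F"
        eth_names = list(_ETHNICITY_P[g])
        eth = eth_names[rng_demo.choice(len(eth_names),
                                        p=list(_ETHNICITY_P[g].values()))]
        records.append(SubjectRecord(
            id=f"sub-{i:03d}", group=g, age=vals["age"], sex=sex,
            ethnicity=eth, ses=vals["ses"], iq=vals["iq"],
            inattention_t=0.0, hyperactivity_t=0.0,
            motion=_draw_motion(rng_demo)))

    # planted feature -> symptom couplings, added on the z-scored feature
    for feature_id, scale, slope in config.symptom_coupling:
        kind, metric, node = _parse_feature_id(
            feature_id, config.n_struct_nodes, config.n_func_nodes)
        mats = structural_counts if kind == "struct" else functional_corr
        vals = _feature_values(mats, kind, metric, node, config.coupling_cost)
        z = (vals - vals.mean()) / (vals.std() if vals.std() > 0 else 1.0)
        tscores[scale] = tscores[scale] + slope * z
    for var in tscores:
        tscores[var] = np.clip(tscores[var], lo, hi)
    for i, rec in enumerate(records):
        rec.inattention_t = float(tscores["inattention_t"][i])
        rec.hyperactivity_t = float(tscores["hyperactivity_t"][i])

    ground_truth = {
        "seed": config.seed,
        "effect_nodes": [list(e) for e in config.effect_nodes],
        "effect_size": config.effect_size,
        "struct_count_multiplier": struct_mult,
        "func_loading_multiplier": func_mult,
        "symptom_coupling": [list(c) for c in config.symptom_coupling],
    }
    return Cohort(records, structural_counts, functional_corr, ground_truth)


def chi_square_independence(table: Sequence[Sequence[float]]
                            ) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, degrees of freedom, p-value).  The Yates correction
    is deliberately off: the matched-cohort table statistics this mirrors
    (sex 0.334, ethnicity 4.259) are plain Pearson chi-squares.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has a zero row or column total")
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), int(df), float(p)


def welch_t_from_summary(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int
                         ) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from group summary statistics.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
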