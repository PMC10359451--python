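"""Synthetic control and surgical cohorts with known ground truth.

The generator works on the oriented (higher = better) scale: per-parameter
baseline levels are equicorrelated Gaussian, retest change is a per-parameter
learning effect plus equicorrelated Gaussian noise, and impairment is
injected as an additive downward shift on a random subset of parameters.
Raw tables are produced by inverting the orientation transform, so timed
parameters come out log-normal and strictly positive.

Default moments mimic an elderly elective-surgery cohort: baseline battery
levels from the unimpaired column of the study-shaped defaults, covariates
with age 72.4 (4.9) years, 43.5% female, thalamus 12.9 (1.6) cm³ and
intracranial volume 1339 (212.4) cm³ correlated 0.5 with thalamus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from cogrci.battery import CANONICAL_BATTERY, PARAMETER_NAMES, unorient_value

_N_PARAMS = len(PARAMETER_NAMES)

# Oriented-scale defaults.  Count/span parameters keep their raw moments;
# timed parameters use -ln(raw) with a delta-method SD (sd_raw / mean_raw).
_RAW_BASELINE = {
    "PAL_memory": (14.0, 4.2),
    "VRM_free_recall": (6.3, 1.9),
    "VRM_delayed_recognition": (21.8, 1.9),
    "SSP_span": (4.9, 0.9),
    "GPT_time": (93.1, 24.7),
    "SRT_time": (309.0, 89.6),
    "TMTB_time": (112.3, 39.1),
}
_TIMED = {"GPT_time", "SRT_time", "TMTB_time"}

DEFAULT_BASELINE_MEAN = {
    p: (-math.log(m) if p in _TIMED else m) for p, (m, s) in _RAW_BASELINE.items()
}
DEFAULT_BASELINE_SD = {
    p: (s / m if p in _TIMED else s) for p, (m, s) in _RAW_BASELINE.items()
}
# Mean retest improvement (practice effect), oriented units.
DEFAULT_LEARNING_EFFECT = {
    "PAL_memory": 1.5,
    "VRM_free_recall": 0.1,
    "VRM_delayed_recognition": 0.0,
    "SSP_span": 0.1,
    "GPT_time": 0.056,
    "SRT_time": 0.0,
    "TMTB_time": 0.089,
}
# Retest change SD, oriented units (~60% of baseline spread).
DEFAULT_NOISE_SD = {p: 0.6 * sd for p, sd in DEFAULT_BASELINE_SD.items()}

DEFAULT_COVARIATES = {
    "age_mean": 72.4,
    "age_sd": 4.9,
    "female_frac": 0.435,
    "thalamus_mean": 12.9,
    "thalamus_sd": 1.6,
    "icv_mean": 1339.0,
    "icv_sd": 212.4,
    "thalamus_icv_corr": 0.5,
    "surgery_duration_mean": 183.9,
    "surgery_duration_sd": 116.3,
}
SURGERY_TYPES = (
    "musculoskeletal", "gastrointestinal", "cardiovascular_thoracic", "genitourinary",
    "otorhinolaryngology", "oral_maxillofacial", "ophthalmology", "neurosurgery", "other",
)
_SURGERY_PROBS = np.array([85, 51, 17, 66, 23, 16, 22, 6, 15], dtype=float)
_SURGERY_PROBS /= _SURGERY_PROBS.sum()

_COUNT_PARAMS = tuple(p for p in PARAMETER_NAMES if p not in _TIMED)


def _as_param_map(value, name: str) -> dict[str, float]:
    """Broadcast a scalar, or validate a per-parameter mapping."""
    if isinstance(value, Mapping):
        unknown = set(value) - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"{name} has unknown parameters: {sorted(unknown)}")
        missing = set(PARAMETER_NAMES) - set(value)
        if missing:
            raise ValueError(f"{name} lacks parameters: {sorted(missing)}")
        return {p: float(value[p]) for p in PARAMETER_NAMES}
    return {p: float(value) for p in PARAMETER_NAMES}


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; see module docstring for scales."""

    n_surgical: int = 301
    n_control: int = 114
    prevalence_preCI: float = 0.113
    prevalence_POCD: float = 0.083
    followup_rate: float = 0.704
    learning_effect: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_LEARNING_EFFECT))
    noise_sd: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD))
    intertest_corr: float = 0.3
    decline_magnitude: float = 3.0
    n_affected_params: int = 3
    missing_rate_item: float = 0.0
    thalamus_effect_logOR: float = 0.0
    seed: int = 0
    baseline_mean: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_MEAN))
    baseline_sd: Mapping[str, float] | float = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_SD))
    covariates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_COVARIATES))
    # optional informative-dropout weight (log-odds of dropout per year of
    # age); 0 keeps loss-to-follow-up completely at random
    dropout_age_weight: float = 0.0

    def __post_init__(self) -> None:
        for name in ("prevalence_preCI", "prevalence_POCD", "followup_rate", "missing_rate_item"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.prevalence_preCI + self.prevalence_POCD > 1.0:
            raise ValueError("prevalence_preCI + prevalence_POCD must not exceed 1")
        if self.n_surgical <= 0 or self.n_control <= 0:
            raise ValueError("cohort sizes must be positive")
        if not 2 <= self.n_affected_params <= _N_PARAMS:
            raise ValueError(f"n_affected_params must be in 2..{_N_PARAMS}")
        # equicorrelation PD bound: -1/(p-1) < rho < 1; spec restricts to [0, 1)
        if not 0.0 <= self.intertest_corr < 1.0:
            raise ValueError(
                f"intertest_corr={self.intertest_corr} does not give a positive-definite "
                f"equicorrelation matrix on [0, 1)"
            )
        self.learning_effect = _as_param_map(self.learning_effect, "learning_effect")
        self.noise_sd = _as_param_map(self.noise_sd, "noise_sd")
        self.baseline_mean = _as_param_map(self.baseline_mean, "baseline_mean")
        self.baseline_sd = _as_param_map(self.baseline_sd, "baseline_sd")
        for label, sds in (("noise_sd", self.noise_sd), ("baseline_sd", self.baseline_sd)):
            bad = {p: s for p, s in sds.items() if s < 0}
            if bad:
                raise ValueError(f"negative {label}: {bad}")
        cov = dict(DEFAULT_COVARIATES)
        cov.update(self.covariates)
        self.covariates = cov

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        """Load from a YAML (or JSON, a YAML subset) config file."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _equicorr_normal(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """n × 7 standard-normal draws with pairwise correlation rho."""
    if rho == 0.0:
        return rng.standard_normal((n, _N_PARAMS))
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, _N_PARAMS))
    return math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * own


def _to_raw(oriented: np.ndarray) -> pd.DataFrame:
    """Invert orientation column-wise; clip count parameters at zero."""
    raw = np.empty_like(oriented)
    for j, spec in enumerate(CANONICAL_BATTERY):
        if spec.transform == "log":
            raw[:, j] = np.exp(-oriented[:, j] if spec.direction == "lower_better" else oriented[:, j])
        else:
            raw[:, j] = np.clip(oriented[:, j], 0.0, None)
    return pd.DataFrame(raw, columns=list(PARAMETER_NAMES))


def _param_arrays(cfg: SimulationConfig):
    mean = np.array([cfg.baseline_mean[p] for p in PARAMETER_NAMES])
    sd = np.array([cfg.baseline_sd[p] for p in PARAMETER_NAMES])
    learn = np.array([cfg.learning_effect[p] for p in PARAMETER_NAMES])
    noise = np.array([cfg.noise_sd[p] for p in PARAMETER_NAMES])
    return mean, sd, learn, noise


def _simulate_sessions(rng, cfg: SimulationConfig, n: int):
    """Oriented (baseline, retest) matrices without impairment."""
    mean, sd, learn, noise = _param_arrays(cfg)
    base = mean + sd * _equicorr_normal(rng, n, cfg.intertest_corr)
    change = learn + noise * _equicorr_normal(rng, n, cfg.intertest_corr)
    return base, base + change


def generate_control_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired raw (baseline, retest) frames for the non-surgical controls.

    Retest = baseline + learning effect + equicorrelated Gaussian noise on
    the oriented scale; no impairment injected.  Indexed by subject_id.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    base, retest = _simulate_sessions(rng, config, config.n_control)
    ids = [f"C{i:05d}" for i in range(config.n_control)]
    out = []
    for mat in (base, retest):
        df = _to_raw(mat)
        df.index = pd.Index(ids, name="subject_id")
        out.append(df)
    return out[0], out[1]


def _impairment_probability(base_prevalence: float, thalamus: np.ndarray,
                            center: float, log_or: float) -> np.ndarray:
    if base_prevalence in (0.0, 1.0) or log_or == 0.0:
        return np.full(thalamus.shape, base_prevalence)
    logit = math.log(base_prevalence / (1.0 - base_prevalence)) + log_or * (thalamus - center)
    return 1.0 / (1.0 + np.exp(-logit))


def generate_covariates(rng: np.random.Generator, cfg: SimulationConfig, ids) -> pd.DataFrame:
    c = cfg.covariates
    n = len(ids)
    age = rng.normal(c["age_mean"], c["age_sd"], n)
    sex = rng.binomial(1, c["female_frac"], n)
    zt = rng.standard_normal(n)
    zi = c["thalamus_icv_corr"] * zt + math.sqrt(1 - c["thalamus_icv_corr"] ** 2) * rng.standard_normal(n)
    thal = c["thalamus_mean"] + c["thalamus_sd"] * zt
    icv = c["icv_mean"] + c["icv_sd"] * zi
    dur = np.clip(rng.normal(c["surgery_duration_mean"], c["surgery_duration_sd"], n), 15.0, None)
    stype = rng.choice(SURGERY_TYPES, size=n, p=_SURGERY_PROBS)
    return pd.DataFrame(
        {
            "age_years": age,
            "sex": sex,
            "thalamus_cm3": thal,
            "icv_cm3": icv,
            "surgery_duration_min": dur,
            "surgery_type": stype,
        },
        index=pd.Index(ids, name="subject_id"),
    )


def generate_surgical_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Surgical cohort: (baseline_raw, followup_raw, covariates, truth).

    Impairment is injected on the oriented scale before inverting to raw
    units: subjects with ``true_preCI`` have baseline shifted down by
    ``decline_magnitude`` baseline SDs on ``n_affected_params`` random
    parameters; subjects with ``true_POCD`` have their retest change shifted
    down by the same multiple of the control change SD.  Thalamus volume
    enters both impairment probabilities through ``thalamus_effect_logOR``.
    A fraction (1 − followup_rate) has follow-up rows withheld (NaN rows
    dropped from the follow-up frame).
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x51]))
    ids = [f"S{i:05d}" for i in range(cfg.n_surgical)]
    cov = generate_covariates(rng, cfg, ids)

    mean, sd, learn, noise = _param_arrays(cfg)
    base = mean + sd * _equicorr_normal(rng, cfg.n_surgical, cfg.intertest_corr)
    change = learn + noise * _equicorr_normal(rng, cfg.n_surgical, cfg.intertest_corr)

    thal = cov["thalamus_cm3"].to_numpy()
    center = cfg.covariates["thalamus_mean"]
    p_pre = _impairment_probability(cfg.prevalence_preCI, thal, center, cfg.thalamus_effect_logOR)
    p_pocd = _impairment_probability(cfg.prevalence_POCD, thal, center, cfg.thalamus_effect_logOR)
    u = rng.random(cfg.n_surgical)
    true_pre = u < p_pre
    true_pocd = (~true_pre) & (u < p_pre + p_pocd)

    affected: list[frozenset[str]] = []
    for i in range(cfg.n_surgical):
        if not (true_pre[i] or true_pocd[i]):
            affected.append(frozenset())
            continue
        which = rng.choice(_N_PARAMS, size=cfg.n_affected_params, replace=False)
        affected.append(frozenset(PARAMETER_NAMES[j] for j in which))
        cols = np.asarray(sorted(which))
        if true_pre[i]:
            base[i, cols] -= cfg.decline_magnitude * sd[cols]
        if true_pocd[i]:
            change[i, cols] -= cfg.decline_magnitude * noise[cols]

    followup = base + change
    baseline_raw = _to_raw(base)
    followup_raw = _to_raw(followup)
    baseline_raw.index = followup_raw.index = pd.Index(ids, name="subject_id")

    if cfg.dropout_age_weight == 0.0:
        has_followup = rng.random(cfg.n_surgical) < cfg.followup_rate
    else:
        # informative dropout: age shifts the log-odds of being followed
        base_logit = math.log(cfg.followup_rate / (1 - cfg.followup_rate)) if 0 < cfg.followup_rate < 1 else None
        if base_logit is None:
            has_followup = np.full(cfg.n_surgical, bool(round(cfg.followup_rate)))
        else:
            logit = base_logit - cfg.dropout_age_weight * (cov["age_years"].to_numpy() - cfg.covariates["age_mean"])
            has_followup = rng.random(cfg.n_surgical) < 1.0 / (1.0 + np.exp(-logit))
    followup_raw = followup_raw.loc[has_followup]

    truth = pd.DataFrame(
        {
            "true_preCI": true_pre,
            "true_POCD": true_pocd,
            "affected_parameters": ["|".join(sorted(s)) for s in affected],
        },
        index=pd.Index(ids, name="subject_id"),
    )
    return baseline_raw, followup_raw, cov, truth


def apply_missingness(
    frame: pd.DataFrame, missing_rate_item: float, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Blank each parameter value independently with the given rate.

    Only battery parameter columns are eligible; identity and covariates
    are never blanked.
    """
    if not 0.0 <= missing_rate_item <= 1.0:
        raise ValueError("missing_rate_item must be in [0, 1]")
    if missing_rate_item == 0.0:
        return frame.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = frame.copy()
    cols = [c for c in frame.columns if c in PARAMETER_NAMES]
    mask = rng.random((len(frame), len(cols))) < missing_rate_item
    values = out[cols].to_numpy(dtype=float)
    values[mask] = np.nan
    out[cols] = values
    return out


def write_cohort_tables(outdir, baseline, followup, covariates, truth) -> None:
    """Write assessments.csv / covariates.csv / truth.csv under outdir."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for session, frame in (("baseline", baseline), ("followup", followup)):
        block = frame.reset_index()
        block.insert(1, "session", session)
        rows.append(block)
    pd.concat(rows, ignore_index=True).to_csv(outdir / "assessments.csv", index=False)
    covariates.reset_index().to_csv(outdir / "covariates.csv", index=False)
    truth.reset_index().to_csv(outdir / "truth.csv", index=False)
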