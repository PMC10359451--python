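"""Control-referenced reliable-change scoring and dichotomization.

A non-surgical control cohort tested twice supplies, per parameter, the
mean and SD of retest change (capturing practice/learning effects and
natural variability) and of baseline level.  A subject's change or
baseline vector is standardized against those moments with deterioration
oriented positive:

    z_p = (control_mean_p − x_p) / control_sd_p

The composite is the sum of available per-parameter z's rescaled by the
control SD of that same sum, so its null SD is 1.  The dichotomous verdict
fires when the composite exceeds the threshold or when at least two
individual parameters do (strict inequality).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from cogrci.battery import PARAMETER_NAMES, OrientedVector

DEFAULT_THRESHOLD = 1.96
#: Minimum number of available parameters for a subject to be classifiable.
DEFAULT_MIN_AVAILABLE = 5

Criterion = Literal["composite_only", "multi_test_only", "both", "none"]


class UnclassifiableError(ValueError):
    """Raised when a subject has too few available parameters to classify."""


@dataclass
class ZPanel:
    subject_id: str
    z: dict[str, float | None]
    composite_z: float | None
    n_available: int

    @property
    def classifiable(self) -> bool:
        return self.composite_z is not None


@dataclass
class OutcomeLabel:
    subject_id: str
    impaired: bool
    criterion: Criterion
    threshold: float
    outcome_kind: Literal["preCI", "POCD"]

    def __post_init__(self) -> None:
        if self.impaired != (self.criterion != "none"):
            raise ValueError("impaired flag inconsistent with criterion")


def _subset_key(params: Iterable[str]) -> str:
    return "|".join(sorted(params))


@dataclass
class ControlReference:
    """Per-parameter control moments plus composite scaling constants.

    ``subset_scalings`` maps a sorted ``'|'``-joined parameter subset to the
    control SD of the z-sum over that subset, separately for change and
    baseline z's.  Subsets are computed lazily from the stored control
    z-matrices and cached.
    """

    mean_change: dict[str, float]
    sd_change: dict[str, float]
    mean_baseline: dict[str, float]
    sd_baseline: dict[str, float]
    sd_sum_z_change: float
    sd_sum_z_baseline: float
    n_control: int
    subset_scalings_change: dict[str, float] = field(default_factory=dict)
    subset_scalings_baseline: dict[str, float] = field(default_factory=dict)
    # control z-matrices retained for on-demand subset scalings
    _z_change: pd.DataFrame | None = field(default=None, repr=False)
    _z_baseline: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.mean_change)

    def subset_scaling(self, params: Iterable[str], kind: Literal["change", "baseline"]) -> float:
        """Control SD of the z-sum over a parameter subset (cached)."""
        params = sorted(params)
        key = _subset_key(params)
        cache = self.subset_scalings_change if kind == "change" else self.subset_scalings_baseline
        if key in cache:
            return cache[key]
        zmat = self._z_change if kind == "change" else self._z_baseline
        if zmat is None:
            raise ValueError(
                f"subset scaling for {key!r} not cached and control z-matrix unavailable"
            )
        complete = zmat[params].dropna()
        if len(complete) < 2:
            raise ValueError(f"fewer than 2 complete controls on subset {key!r}")
        value = float(complete.sum(axis=1).std(ddof=1))
        if value <= 0:
            raise ValueError(f"degenerate z-sum SD on subset {key!r}")
        cache[key] = value
        return value

    def to_dict(self) -> dict:
        return {
            "mean_change": self.mean_change,
            "sd_change": self.sd_change,
            "mean_baseline": self.mean_baseline,
            "sd_baseline": self.sd_baseline,
            "sd_sum_z_change": self.sd_sum_z_change,
            "sd_sum_z_baseline": self.sd_sum_z_baseline,
            "n_control": self.n_control,
            "subset_scalings_change": self.subset_scalings_change,
            "subset_scalings_baseline": self.subset_scalings_baseline,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ControlReference":
        return cls(
            mean_change=dict(d["mean_change"]),
            sd_change=dict(d["sd_change"]),
            mean_baseline=dict(d["mean_baseline"]),
            sd_baseline=dict(d["sd_baseline"]),
            sd_sum_z_change=float(d["sd_sum_z_change"]),
            sd_sum_z_baseline=float(d["sd_sum_z_baseline"]),
            n_control=int(d["n_control"]),
            subset_scalings_change=dict(d.get("subset_scalings_change", {})),
            subset_scalings_baseline=dict(d.get("subset_scalings_baseline", {})),
        )

    @classmethod
    def from_json(cls, path) -> "ControlReference":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _moments(frame: pd.DataFrame, what: str) -> tuple[dict[str, float], dict[str, float]]:
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for p in frame.columns:
        col = frame[p].dropna()
        if len(col) < 2:
            raise ValueError(f"fewer than 2 controls with {what} data on {p!r}")
        sd = float(col.std(ddof=1))
        if sd <= 0:
            raise ValueError(f"zero control variance for {what} on {p!r}: Z undefined")
        means[p] = float(col.mean())
        sds[p] = sd
    return means, sds


def fit_control_reference(
    control_change: pd.DataFrame,
    control_baseline: pd.DataFrame,
) -> ControlReference:
    """Fit the control normalizers from oriented control frames.

    Both frames are subject × parameter with NaN for missing items.  Means
    and SDs (sample SD, n−1) are computed per parameter over available
    controls; composite scalings over controls with complete batteries.
    """
    if list(control_change.columns) != list(control_baseline.columns):
        raise ValueError("change and baseline frames must share the same parameter columns")
    mean_change, sd_change = _moments(control_change, "change")
    mean_baseline, sd_baseline = _moments(control_baseline, "baseline")

    z_change = (control_change - pd.Series(mean_change)) / pd.Series(sd_change) * -1.0
    z_baseline = (control_baseline - pd.Series(mean_baseline)) / pd.Series(sd_baseline) * -1.0

    ref = ControlReference(
        mean_change=mean_change,
        sd_change=sd_change,
        mean_baseline=mean_baseline,
        sd_baseline=sd_baseline,
        sd_sum_z_change=np.nan,
        sd_sum_z_baseline=np.nan,
        n_control=int(len(control_change)),
        _z_change=z_change,
        _z_baseline=z_baseline,
    )
    all_params = list(control_change.columns)
    ref.sd_sum_z_change = ref.subset_scaling(all_params, "change")
    ref.sd_sum_z_baseline = ref.subset_scaling(all_params, "baseline")
    return ref


def _zscore(
    vec: OrientedVector | Mapping[str, float | None],
    means: Mapping[str, float],
    sds: Mapping[str, float],
    ref: ControlReference,
    kind: Literal["change", "baseline"],
    min_available: int,
) -> ZPanel:
    if isinstance(vec, OrientedVector):
        subject_id, values = vec.subject_id, vec.values
    else:
        subject_id, values = "<anonymous>", vec
    z: dict[str, float | None] = {}
    for p in means:
        x = values.get(p)
        if x is None or (isinstance(x, float) and np.isnan(x)):
            z[p] = None
        else:
            z[p] = (means[p] - float(x)) / sds[p]
    available = [p for p, v in z.items() if v is not None]
    composite = None
    if len(available) >= min_available:
        composite = sum(z[p] for p in available) / ref.subset_scaling(available, kind)
    return ZPanel(subject_id=subject_id, z=z, composite_z=composite, n_available=len(available))


def zscore_change(
    change: OrientedVector | Mapping[str, float | None],
    ref: ControlReference,
    min_available: int = DEFAULT_MIN_AVAILABLE,
) -> ZPanel:
    """Reliable-change z-panel for a pre-to-post change vector.

    ``z = (control_mean_change − Δx) / control_sd_change``: deterioration
    beyond the control learning effect is positive.
    """
    return _zscore(change, ref.mean_change, ref.sd_change, ref, "change", min_available)


def zscore_baseline(
    baseline: OrientedVector | Mapping[str, float | None],
    ref: ControlReference,
    min_available: int = DEFAULT_MIN_AVAILABLE,
) -> ZPanel:
    """Baseline-level z-panel against the control baseline distribution."""
    return _zscore(baseline, ref.mean_baseline, ref.sd_baseline, ref, "baseline", min_available)


def classify(
    panel: ZPanel,
    threshold: float = DEFAULT_THRESHOLD,
    outcome_kind: Literal["preCI", "POCD"] = "POCD",
) -> OutcomeLabel:
    """Dichotomize a z-panel: impaired iff composite_z > threshold or at
    least two individual z's exceed the threshold (strict inequality).

    Raises :class:`UnclassifiableError` on a panel whose composite is
    unavailable; an unclassifiable subject is never silently 'not impaired'.
    """
    if not panel.classifiable:
        raise UnclassifiableError(
            f"subject {panel.subject_id!r} has only {panel.n_available} available parameters"
        )
    composite_hit = panel.composite_z > threshold
    n_individual = sum(1 for v in panel.z.values() if v is not None and v > threshold)
    multi_hit = n_individual >= 2
    if composite_hit and multi_hit:
        criterion: Criterion = "both"
    elif composite_hit:
        criterion = "composite_only"
    elif multi_hit:
        criterion = "multi_test_only"
    else:
        criterion = "none"
    return OutcomeLabel(
        subject_id=panel.subject_id,
        impaired=criterion != "none",
        criterion=criterion,
        threshold=threshold,
        outcome_kind=outcome_kind,
    )


def zscore_frame(
    oriented: pd.DataFrame,
    ref: ControlReference,
    kind: Literal["change", "baseline"],
    min_available: int = DEFAULT_MIN_AVAILABLE,
) -> pd.DataFrame:
    """Vectorized z-panel for a cohort frame.

    Returns a frame with one z-column per parameter plus ``composite_z``
    and ``n_available`` (composite NaN where unclassifiable).
    """
    means = ref.mean_change if kind == "change" else ref.mean_baseline
    sds = ref.sd_change if kind == "change" else ref.sd_baseline
    z = (pd.Series(means) - oriented[list(means)]) / pd.Series(sds)
    n_avail = z.notna().sum(axis=1)
    composite = pd.Series(np.nan, index=z.index)
    avail_patterns = z.notna().apply(lambda r: tuple(z.columns[r.values]), axis=1)
    for pattern in avail_patterns.unique():
        if len(pattern) < min_available:
            continue
        mask = avail_patterns == pattern
        scale = ref.subset_scaling(pattern, kind)
        composite[mask] = z.loc[mask, list(pattern)].sum(axis=1) / scale
    out = z.copy()
    out["composite_z"] = composite
    out["n_available"] = n_avail
    return out


def classify_frame(
    zpanel: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    outcome_kind: Literal["preCI", "POCD"] = "POCD",
) -> pd.DataFrame:
    """Classify every row of a :func:`zscore_frame` result.

    Unclassifiable subjects get ``impaired = NA`` and criterion
    ``'unclassifiable'`` rather than a silent negative.
    """
    params = [c for c in zpanel.columns if c not in ("composite_z", "n_available")]
    composite_hit = zpanel["composite_z"] > threshold
    multi_hit = (zpanel[params] > threshold).sum(axis=1) >= 2
    classifiable = zpanel["composite_z"].notna()
    criterion = pd.Series("none", index=zpanel.index)
    criterion[composite_hit & ~multi_hit] = "composite_only"
    criterion[~composite_hit & multi_hit] = "multi_test_only"
    criterion[composite_hit & multi_hit] = "both"
    criterion[~classifiable] = "unclassifiable"
    impaired = (composite_hit | multi_hit).astype("boolean")
    impaired[~classifiable] = pd.NA
    return pd.DataFrame(
        {
            "outcome_kind": outcome_kind,
            "impaired": impaired,
            "criterion": criterion,
            "composite_z": zpanel["composite_z"],
            "n_available": zpanel["n_available"],
        },
        index=zpanel.index,
    )


def null_false_positive_rate(
    n_params: int,
    threshold: float = DEFAULT_THRESHOLD,
    n_sims: int = 100_000,
    seed: int | np.random.Generator = 0,
    composite_clause: bool = True,
    multi_clause: bool = True,
) -> float:
    """Monte-Carlo impairment rate under the independent standard-normal null.

    Per-parameter z's are i.i.d. N(0,1); the composite is their sum divided
    by √n_params (its null SD).  Clauses can be toggled to isolate either
    half of the rule.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be at least 1000")
    if not (composite_clause or multi_clause):
        raise ValueError("at least one clause must be enabled")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = np.zeros(n_sims, dtype=bool)
    # chunked to bound memory at large n_sims
    chunk = 1_000_000 // max(n_params, 1)
    done = 0
    while done < n_sims:
        m = min(chunk, n_sims - done)
        z = rng.standard_normal((m, n_params))
        flag = np.zeros(m, dtype=bool)
        if composite_clause:
            flag |= z.sum(axis=1) / np.sqrt(n_params) > threshold
        if multi_clause:
            flag |= (z > threshold).sum(axis=1) >= 2
        hits[done : done + m] = flag
        done += m
    return float(hits.mean())
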