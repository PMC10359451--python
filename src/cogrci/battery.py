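"""Battery definition and preprocessing.

Seven analysis parameters are carried through the pipeline on a common
oriented scale in which *higher is always better*: count/span scores pass
through unchanged, timed scores are natural-log transformed and negated.
Raw values are what is stored in tables and summaries; orientation lives
only inside the analysis path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Direction = Literal["higher_better", "lower_better"]
Transform = Literal["none", "log"]
Session = Literal["baseline", "followup"]

#: Trail-making termination limits in seconds, by part.
TMT_TIMEOUT_S = {"A": 180.0, "B": 300.0}


@dataclass(frozen=True)
class TestParameterSpec:
    """Orientation/transform rules for one battery parameter."""

    name: str
    direction: Direction
    transform: Transform
    units: str
    timeout_s: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("higher_better", "lower_better"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.transform not in ("none", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.timeout_s is not None and self.timeout_s <= 0:
            raise ValueError("timeout_s must be positive")


#: The canonical seven-parameter battery.  Timed measures (pegboard,
#: reaction time, trail-making B) are log-transformed and reversed; the
#: four count/span scores are used as-is.
CANONICAL_BATTERY: tuple[TestParameterSpec, ...] = (
    TestParameterSpec("PAL_memory", "higher_better", "none", "score"),
    TestParameterSpec("VRM_free_recall", "higher_better", "none", "words"),
    TestParameterSpec("VRM_delayed_recognition", "higher_better", "none", "responses"),
    TestParameterSpec("SSP_span", "higher_better", "none", "span"),
    TestParameterSpec("GPT_time", "lower_better", "log", "s"),
    TestParameterSpec("SRT_time", "lower_better", "log", "ms"),
    TestParameterSpec("TMTB_time", "lower_better", "log", "s", timeout_s=TMT_TIMEOUT_S["B"]),
)

PARAMETER_NAMES: tuple[str, ...] = tuple(s.name for s in CANONICAL_BATTERY)

_SPEC_BY_NAME: dict[str, TestParameterSpec] = {s.name: s for s in CANONICAL_BATTERY}


def battery_spec(name: str) -> TestParameterSpec:
    """Return the canonical spec for a parameter name."""
    try:
        return _SPEC_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown battery parameter {name!r}") from None


@dataclass
class AssessmentRecord:
    """Raw parameter values for one subject-session; None marks missing."""

    subject_id: str
    session: Session
    values: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.session not in ("baseline", "followup"):
            raise ValueError(f"session must be baseline/followup, got {self.session!r}")


@dataclass
class OrientedVector:
    """Oriented (higher = better) values per parameter; None marks missing."""

    subject_id: str
    kind: Literal["baseline_level", "pre_post_change"]
    values: dict[str, float | None] = field(default_factory=dict)


def orient_value(raw: float | None, spec: TestParameterSpec) -> float | None:
    """Map a raw score onto the oriented (higher = better) scale.

    ``transform='log'`` applies the natural log; ``direction='lower_better'``
    negates after the transform.  Non-positive values under a log transform
    are invalid and are treated as missing (with a warning) rather than
    raising.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    x = float(raw)
    if spec.transform == "log":
        if x <= 0:
            logger.warning("non-positive value %r for log-transformed %s treated as missing", raw, spec.name)
            return None
        x = math.log(x)
    if spec.direction == "lower_better":
        x = -x
    return x


def unorient_value(oriented: float, spec: TestParameterSpec) -> float:
    """Inverse of :func:`orient_value` on its valid domain."""
    x = float(oriented)
    if spec.direction == "lower_better":
        x = -x
    if spec.transform == "log":
        x = math.exp(x)
    return x


def apply_timeout_rule(raw_seconds: float, part: str = "B") -> float | None:
    """Trail-making termination rule: times at/over the part limit are
    excluded (returned as missing); shorter times pass through."""
    if part not in TMT_TIMEOUT_S:
        raise ValueError(f"part must be 'A' or 'B', got {part!r}")
    if raw_seconds <= 0:
        raise ValueError("raw_seconds must be positive")
    limit = TMT_TIMEOUT_S[part]
    if raw_seconds >= limit:
        return None
    return float(raw_seconds)


def _validated_battery(battery: tuple[TestParameterSpec, ...] | None) -> tuple[TestParameterSpec, ...]:
    return CANONICAL_BATTERY if battery is None else tuple(battery)


def assemble_baseline_vector(
    baseline: AssessmentRecord,
    battery: tuple[TestParameterSpec, ...] | None = None,
) -> OrientedVector:
    """Oriented per-parameter baseline levels for one subject."""
    battery = _validated_battery(battery)
    values = {spec.name: orient_value(baseline.values.get(spec.name), spec) for spec in battery}
    return OrientedVector(subject_id=baseline.subject_id, kind="baseline_level", values=values)


def assemble_change_vector(
    baseline: AssessmentRecord,
    followup: AssessmentRecord,
    battery: tuple[TestParameterSpec, ...] | None = None,
) -> OrientedVector:
    """Oriented pre-to-post change (followup − baseline) per parameter.

    Orientation is applied before differencing so that deterioration is
    negative on every parameter.  A parameter missing on either side is
    missing in the change vector.
    """
    if baseline.subject_id != followup.subject_id:
        raise ValueError(
            f"subject mismatch: baseline {baseline.subject_id!r} vs followup {followup.subject_id!r}"
        )
    battery = _validated_battery(battery)
    values: dict[str, float | None] = {}
    for spec in battery:
        pre = orient_value(baseline.values.get(spec.name), spec)
        post = orient_value(followup.values.get(spec.name), spec)
        values[spec.name] = None if pre is None or post is None else post - pre
    return OrientedVector(subject_id=baseline.subject_id, kind="pre_post_change", values=values)


# ---------------------------------------------------------------------------
# Frame-level helpers (cohort scale)
# ---------------------------------------------------------------------------

def orient_frame(
    raw: pd.DataFrame,
    battery: tuple[TestParameterSpec, ...] | None = None,
    apply_timeouts: bool = True,
) -> pd.DataFrame:
    """Orient a frame of raw values (columns = parameter names, NaN = missing).

    Timeout exclusions are applied to parameters that carry a limit before
    the transform.
    """
    battery = _validated_battery(battery)
    out = pd.DataFrame(index=raw.index)
    for spec in battery:
        col = pd.to_numeric(raw[spec.name], errors="coerce").astype(float)
        if apply_timeouts and spec.timeout_s is not None:
            col = col.where(col < spec.timeout_s)
        if spec.transform == "log":
            bad = col <= 0
            if bad.any():
                logger.warning(
                    "%d non-positive value(s) for log-transformed %s treated as missing",
                    int(bad.sum()), spec.name,
                )
            col = np.log(col.where(~bad))
        if spec.direction == "lower_better":
            col = -col
        out[spec.name] = col
    return out


def change_frame(
    baseline_raw: pd.DataFrame,
    followup_raw: pd.DataFrame,
    battery: tuple[TestParameterSpec, ...] | None = None,
    apply_timeouts: bool = True,
) -> pd.DataFrame:
    """Oriented change (followup − baseline) for subjects with both sessions."""
    battery = _validated_battery(battery)
    common = baseline_raw.index.intersection(followup_raw.index)
    pre = orient_frame(baseline_raw.loc[common], battery, apply_timeouts)
    post = orient_frame(followup_raw.loc[common], battery, apply_timeouts)
    return post - pre


def load_assessments(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read ``assessments.csv`` (subject_id, session, 7 parameter columns).

    Returns (baseline, followup) frames indexed by subject_id.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "session", *PARAMETER_NAMES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assessments table lacks columns: {sorted(missing)}")
    frames = {}
    for session in ("baseline", "followup"):
        sub = df[df["session"] == session].set_index("subject_id")[list(PARAMETER_NAMES)]
        if sub.index.duplicated().any():
            dupes = sub.index[sub.index.duplicated()].tolist()
            raise ValueError(f"duplicate {session} records for subjects {dupes}")
        frames[session] = sub.astype(float)
    return frames["baseline"], frames["followup"]


def records_to_frame(records: list[AssessmentRecord]) -> pd.DataFrame:
    """Stack records of one session into a subject × parameter frame."""
    data = {rec.subject_id: {p: rec.values.get(p) for p in PARAMETER_NAMES} for rec in records}
    frame = pd.DataFrame.from_dict(data, orient="index", columns=list(PARAMETER_NAMES))
    frame.index.name = "subject_id"
    return frame.astype(float)


def frame_to_records(frame: pd.DataFrame, session: Session) -> list[AssessmentRecord]:
    out = []
    for sid, row in frame.iterrows():
        values = {p: (None if pd.isna(row[p]) else float(row[p])) for p in PARAMETER_NAMES}
        out.append(AssessmentRecord(subject_id=str(sid), session=session, values=values))
    return out
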