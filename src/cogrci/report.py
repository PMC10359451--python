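"""Cohort accounting and presentation.

Flow-ledger counts are computed purely by counting subject statuses; all
percentages printed in reports come from a single rounding path
(:func:`percentage`, half-up).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Terminal flow states for subjects without follow-up testing.
LOSS_STATUSES = ("dropped_out", "died_pre_followup", "not_reachable", "alive_not_tested", "paused")
FLOW_STATUSES = ("followup_tested",) + LOSS_STATUSES


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100·n/d rounded half-up to the given number of decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must be in [0, denominator]")
    quantum = Decimal(1).scaleb(-decimals)
    value = (Decimal(100) * Decimal(numerator) / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass
class FlowLedger:
    """STROBE-style enrollment/follow-up accounting."""

    enrolled: int
    baseline_tested: int
    followup_tested: int
    dropped_out: int
    died_pre_followup: int
    not_reachable: int
    alive_not_tested: int
    paused: int
    preCI: int
    POCD: int
    POD: int
    preCI_and_POCD: int
    POCD_and_POD: int
    preCI_and_POD: int
    preCI_and_followup: int

    @property
    def lost_total(self) -> int:
        return (
            self.dropped_out
            + self.died_pre_followup
            + self.not_reachable
            + self.alive_not_tested
            + self.paused
        )

    def validate(self) -> None:
        if self.followup_tested + self.lost_total != self.baseline_tested:
            raise ValueError(
                f"flow does not reconcile: followup {self.followup_tested} + lost "
                f"{self.lost_total} != baseline {self.baseline_tested}"
            )
        for name, margin_a, margin_b in (
            ("preCI_and_POCD", self.preCI, self.POCD),
            ("POCD_and_POD", self.POCD, self.POD),
            ("preCI_and_POD", self.preCI, self.POD),
            ("preCI_and_followup", self.preCI, self.followup_tested),
        ):
            overlap = getattr(self, name)
            if overlap > min(margin_a, margin_b):
                raise ValueError(f"{name}={overlap} exceeds a margin ({margin_a}, {margin_b})")

    def percentages(self, denominator: str = "baseline_tested") -> dict[str, float]:
        """Percentages of the named denominator (explicit, never guessed)."""
        d = getattr(self, denominator)
        out = {}
        for name in ("followup_tested", *LOSS_STATUSES, "preCI", "POCD", "POD"):
            n = getattr(self, name)
            if n <= d:
                out[name] = percentage(n, d)
        out["lost_total"] = percentage(self.lost_total, d)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = {
            name: getattr(self, name)
            for name in (
                "enrolled", "baseline_tested", "followup_tested", "lost_total",
                *LOSS_STATUSES, "preCI", "POCD", "POD",
                "preCI_and_POCD", "POCD_and_POD", "preCI_and_POD", "preCI_and_followup",
            )
        }
        return pd.DataFrame({"count": rows})


def build_flow(status: pd.DataFrame) -> FlowLedger:
    """Count a per-subject status table into a validated FlowLedger.

    ``status`` is indexed by subject_id with columns: ``status`` (one of
    FLOW_STATUSES), and boolean ``preCI``, ``POCD``, ``POD`` (POCD may be
    NA for subjects without follow-up).  Inconsistent rows — e.g. a POCD
    verdict for a subject not followed up — are rejected with the subject
    list.
    """
    if status.index.duplicated().any():
        dupes = status.index[status.index.duplicated()].tolist()
        raise ValueError(f"multiple statuses for subjects {dupes}")
    bad = status[~status["status"].isin(FLOW_STATUSES)]
    if len(bad):
        raise ValueError(f"unknown status values for subjects {bad.index.tolist()}")
    pocd = status["POCD"].astype("boolean")
    followed = status["status"] == "followup_tested"
    inconsistent = status.index[(pocd == True) & ~followed]  # noqa: E712
    if len(inconsistent):
        raise ValueError(
            f"subjects with POCD verdict but no follow-up test: {inconsistent.tolist()}"
        )
    counts = status["status"].value_counts()
    pre = status["preCI"].fillna(False).astype(bool)
    pod = status["POD"].fillna(False).astype(bool)
    pocd_b = pocd.fillna(False).astype(bool)
    ledger = FlowLedger(
        enrolled=int(len(status)),
        baseline_tested=int(len(status)),
        followup_tested=int(counts.get("followup_tested", 0)),
        dropped_out=int(counts.get("dropped_out", 0)),
        died_pre_followup=int(counts.get("died_pre_followup", 0)),
        not_reachable=int(counts.get("not_reachable", 0)),
        alive_not_tested=int(counts.get("alive_not_tested", 0)),
        paused=int(counts.get("paused", 0)),
        preCI=int(pre.sum()),
        POCD=int(pocd_b.sum()),
        POD=int(pod.sum()),
        preCI_and_POCD=int((pre & pocd_b).sum()),
        POCD_and_POD=int((pocd_b & pod).sum()),
        preCI_and_POD=int((pre & pod).sum()),
        preCI_and_followup=int((pre & followed).sum()),
    )
    ledger.validate()
    return ledger


def quartiles(values, method: str = "weibull") -> tuple[float, float, float]:
    """(Q1, median, Q3) under a configurable quantile convention.

    The default interpolates linearly at (n+1)·q order-statistic positions
    (numpy's ``weibull`` method); any numpy quantile method name works.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no data for quartiles")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method=method)
    return float(q1), float(med), float(q3)


def _median_iqr(col: pd.Series, method: str) -> str:
    q1, med, q3 = quartiles(col.to_numpy(), method)
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


#: Continuous rows summarized as median (IQR) instead of mean (SD).
MEDIAN_ROWS = ("bmi", "mmse", "length_of_stay_days")


def characteristics_table(
    covariates: pd.DataFrame,
    groups: dict[str, pd.Index],
    quantile_method: str = "weibull",
) -> pd.DataFrame:
    """Table-1-style summary: one column per group, one row per variable.

    Continuous variables are mean (SD) except those in ``MEDIAN_ROWS``
    which use median (IQR, (n+1)-position linear-interpolated quartiles
    by default, configurable);
    categorical/binary variables are n (%).  Available N is annotated when
    a variable has missing data within a group.
    """
    out: dict[str, dict[str, str]] = {}
    for gname, idx in groups.items():
        sub = covariates.loc[covariates.index.intersection(idx)]
        col_out: dict[str, str] = {"N": str(len(sub))}
        if len(sub) == 0:
            out[gname] = col_out
            continue
        for var in covariates.columns:
            col = sub[var].dropna()
            suffix = "" if len(col) == len(sub) else f" [N={len(col)}]"
            if len(col) == 0:
                col_out[var] = "—"
            elif covariates[var].dtype == object:
                top = col.value_counts()
                col_out[var] = "; ".join(
                    f"{k}: {v} ({percentage(int(v), len(col))}%)" for k, v in top.items()
                ) + suffix
            elif set(pd.unique(col.dropna())) <= {0, 1, True, False}:
                n = int(col.sum())
                col_out[var] = f"{n} ({percentage(n, len(col))}%)" + suffix
            elif var in MEDIAN_ROWS:
                col_out[var] = _median_iqr(col, quantile_method) + suffix
            else:
                col_out[var] = f"{col.mean():.1f} ({col.std(ddof=1):.1f})" + suffix
        out[gname] = col_out
    return pd.DataFrame(out)


def boxplot_groups(volumes: pd.Series, groups: dict[str, pd.Index], path) -> None:
    """One box of thalamus volume per group, written as a vector figure.

    Empty groups are dropped with a warning; group sizes are annotated.
    Colors follow a colorblind-safe palette.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels, data = [], []
    for gname, idx in groups.items():
        vals = volumes.loc[volumes.index.intersection(idx)].dropna()
        if len(vals) == 0:
            logger.warning("group %r is empty; omitted from boxplot", gname)
            continue
        labels.append(f"{gname}\n(n={len(vals)})")
        data.append(vals.to_numpy())
    if not data:
        raise ValueError("all groups empty; nothing to plot")
    palette = ["#000000", "#CC79A7", "#009E73", "#0072B2", "#E69F00"]
    fig, ax = plt.subplots(figsize=(1.8 + 1.4 * len(data), 4))
    bp = ax.boxplot(data, tick_labels=labels, patch_artist=True)
    for patch, color in zip(bp["boxes"], palette):
        patch.set_facecolor(color)
        patch.set_alpha(0.6)
    ax.set_ylabel("Thalamus volume [cm³]")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
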