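"""Shared test helper: a per-subject status table with the study-shaped
flow counts (301 baseline, 212 followed, itemized losses, outcome overlaps)."""

import pandas as pd


def study_status_table() -> pd.DataFrame:
    n = 301
    statuses = (
        ["followup_tested"] * 212
        + ["dropped_out"] * 19
        + ["died_pre_followup"] * 15
        + ["not_reachable"] * 19
        + ["alive_not_tested"] * 26
        + ["paused"] * 10
    )
    df = pd.DataFrame(
        {"status": statuses},
        index=pd.Index([f"P{i:03d}" for i in range(n)], name="subject_id"),
    )
    df["preCI"] = False
    df["POCD"] = pd.array([None] * n, dtype="boolean")
    df.loc[df["status"] == "followup_tested", "POCD"] = False
    df["POD"] = False
    # 34 preCI: 20 followed (one of whom has POCD), 14 lost
    followed = df.index[:212]
    lost = df.index[212:]
    pre_ids = list(followed[:20]) + list(lost[:14])
    df.loc[pre_ids, "preCI"] = True
    # 25 POCD among the followed, exactly 1 overlapping preCI
    pocd_ids = [followed[0]] + list(followed[20:44])
    df.loc[pocd_ids, "POCD"] = True
    # 44 POD: 7 preCI (not the preCI+POCD subject), 1 POCD-only, 36 others
    pod_ids = list(followed[1:8]) + [followed[20]] + list(followed[44:80])
    df.loc[pod_ids, "POD"] = True
    return df
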