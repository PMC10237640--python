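"""Reduce per-frame detections to per-subject observations and per-day counts.

Consecutive survey frames overlap heavily, so one subject appears in many
frames.  Only the first frame a subject is encountered in contributes an
observation (its position and distance come from that frame alone), and
distinct sharks are counted conservatively: an individual is only added when
a single frame, or a unique mark, proves it cannot be a repeat sighting.
"""

from __future__ import annotations

import pandas as pd

from .config import GROUPS

__all__ = [
    "first_observation_filter",
    "distinct_shark_count",
    "build_survey_day_table",
]

OBSERVATION_COLUMNS = ["key", "group", "beach", "survey_id", "day", "timestamp",
                       "x", "y"]


def first_observation_filter(detections: pd.DataFrame) -> pd.DataFrame:
    """Keep the earliest detection of each subject key within each survey.

    Requires time-ordered detections carrying a ``survey_id``; a multi-survey
    batch without survey ids cannot be deduplicated and raises.
    """
    if detections.empty:
        return pd.DataFrame(columns=OBSERVATION_COLUMNS)
    if "survey_id" not in detections.columns or detections["survey_id"].isna().any():
        if detections.get("day", pd.Series(dtype=object)).nunique() > 1:
            raise ValueError("detections span multiple surveys but carry no survey_id")
        raise ValueError("detections must carry a survey_id")
    obs = (detections.sort_values(["survey_id", "timestamp", "frame_id"], kind="stable")
           .groupby(["survey_id", "key"], as_index=False, sort=False)
           .first())
    cols = [c for c in OBSERVATION_COLUMNS if c in obs.columns]
    extra = [c for c in ("dist_break_m", "mark_id", "subject_id") if c in obs.columns]
    return obs[cols + extra].reset_index(drop=True)


def distinct_shark_count(shark_detections: pd.DataFrame) -> int:
    """Conservative number of distinct sharks proven by a survey day's detections.

    Evidence comes from two sources that cannot double-count: unique marks
    (scarring, tags, distinctive size) identify individuals outright, and
    unmarked sharks co-visible in a single frame are necessarily distinct.
    The count is (number of distinct mark ids) + (maximum number of unmarked
    sharks in any one frame); an unmarked shark seen repeatedly but never
    co-visible with another collapses to one.  Never exceeds the true number
    of sharks present.
    """
    if shark_detections.empty:
        return 0
    d = shark_detections
    if "group" in d.columns:
        d = d[d["group"] == "shark"]
    if d.empty:
        return 0
    marked = d["mark_id"].notna() if "mark_id" in d.columns else pd.Series(False, index=d.index)
    n_marks = d.loc[marked, "mark_id"].nunique() if marked.any() else 0
    unmarked = d.loc[~marked]
    max_covisible = int(unmarked.groupby("frame_id").size().max()) if len(unmarked) else 0
    return int(n_marks + max_covisible)


def build_survey_day_table(observations: pd.DataFrame,
                           surveys_flown: pd.DataFrame | None = None,
                           distinct_sharks: pd.DataFrame | None = None) -> pd.DataFrame:
    """One row per beach-day: per-group counts, distinct sharks, surveys flown.

    ``surveys_flown`` (beach, day, n_surveys) supplies the flown beach-days
    so days with no observations are retained as zero rows ("empty beach"
    surveys); without it, only beach-days present in the observations
    appear.  ``distinct_sharks`` (beach, day, shark_distinct) attaches the
    conservative individual counts; otherwise the column mirrors the shark
    observation count capped by nothing (observation counts are sightings,
    not individuals).
    """
    if observations.empty and surveys_flown is None:
        raise ValueError("no observations and no record of surveys flown")
    if not observations.empty:
        counts = (observations.groupby(["beach", "day", "group"], observed=True)
                  .size().unstack(fill_value=0))
    else:
        counts = pd.DataFrame()
    for g in GROUPS:
        if g not in counts.columns:
            counts[g] = 0
    counts = counts[list(GROUPS)].reset_index() if len(counts) else pd.DataFrame(
        columns=["beach", "day", *GROUPS])

    if surveys_flown is not None:
        base = surveys_flown[["beach", "day"]].drop_duplicates()
        table = base.merge(counts, on=["beach", "day"], how="left").fillna(0)
        nsurv = surveys_flown.groupby(["beach", "day"], as_index=False)["n_surveys"].sum() \
            if "n_surveys" in surveys_flown.columns else \
            surveys_flown.groupby(["beach", "day"], as_index=False).size().rename(
                columns={"size": "n_surveys"})
        table = table.merge(nsurv, on=["beach", "day"], how="left")
    else:
        table = counts
        table["n_surveys"] = 1

    if distinct_sharks is not None:
        table = table.merge(distinct_sharks, on=["beach", "day"], how="left")
        table["shark_distinct"] = table["shark_distinct"].fillna(0).astype(int)
    else:
        table["shark_distinct"] = table["shark"].astype(int)
    for g in GROUPS:
        table[g] = table[g].astype(int)
    return table.sort_values(["beach", "day"]).reset_index(drop=True)
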