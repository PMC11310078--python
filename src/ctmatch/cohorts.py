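"""Treatment and control cohort construction with auditable exclusions.

A tract is *treated* for a given protection arrangement when at least
``protect_threshold`` (default 10%) of its area overlaps that
arrangement and protection was gazetted inside the study window. A
tract is a *control candidate* when every arrangement covers less than
``control_ceiling`` (default 1%) of it. Tracts in between are excluded
as ambiguous, and tracts overlapping an arrangement other than the one
of interest are excluded outright, so treated and control groups are
cleanly separated.

Controls are then subset by alternative land use: all non-protected
tracts, sparsely settled tracts, tracts dominated by one of four
landholding-size classes, or tracts with post-baseline mining licences.
Each comparison applies symmetric treated-side exclusions (e.g. mining
comparisons drop tracts with baseline mines on either side).

Every input tract ends up in exactly one of {treated, control,
excluded}; the exclusion log records the rule that fired, which makes
cohorts auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ARRANGEMENTS, HOLDING_CLASSES

CONTROL_TYPES = ("all_nonPA", "sparse", "very_small", "small", "medium", "large",
                 "mining")

OVERLAP_COL = {"SPA": "overlap_spa", "SUPA": "overlap_supa", "IT": "overlap_it"}

__all__ = ["CONTROL_TYPES", "CohortSpec", "Cohort", "CohortError",
           "assign_treatment", "classify_dominant_holding", "build_controls",
           "build_cohort"]


class CohortError(RuntimeError):
    pass


@dataclass(frozen=True)
class CohortSpec:
    arrangement: str
    control_type: str = "all_nonPA"
    protect_threshold: float = 0.10
    control_ceiling: float = 0.01
    settled_threshold: float = 0.10
    window: tuple = (2000, 2010)

    def __post_init__(self) -> None:
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.control_type not in CONTROL_TYPES:
            raise ValueError(f"unknown control type {self.control_type!r}")
        if not self.control_ceiling < self.protect_threshold:
            raise ValueError("control_ceiling must be below protect_threshold")


@dataclass
class Cohort:
    spec: CohortSpec
    treated_ids: list = field(default_factory=list)
    control_ids: list = field(default_factory=list)
    exclusion_log: list = field(default_factory=list)  # (tract_id, rule)

    def validate_partition(self, all_ids) -> None:
        t, c = set(self.treated_ids), set(self.control_ids)
        e = {tid for tid, _ in self.exclusion_log}
        if t & c or t & e or c & e:
            raise CohortError("cohort roles overlap")
        if t | c | e != set(all_ids):
            raise CohortError("cohort does not partition the input tracts")

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [(i, "treated", "") for i in self.treated_ids]
            + [(i, "control", "") for i in self.control_ids]
            + [(i, "excluded", r) for i, r in self.exclusion_log]
        )
        return pd.DataFrame(rows, columns=["tract_id", "role", "rule"])


def assign_treatment(tracts: pd.DataFrame, spec: CohortSpec) -> Cohort:
    """Partition tracts into treated / control-candidate / excluded.

    The control side returned here is the *candidate* pool (all overlaps
    below the ceiling); land-use subsetting happens in
    :func:`build_controls`.
    """
    cohort = Cohort(spec)
    a = spec.arrangement
    own = tracts[OVERLAP_COL[a]].to_numpy(dtype=float)
    others = np.column_stack(
        [tracts[OVERLAP_COL[x]].to_numpy(dtype=float) for x in ARRANGEMENTS if x != a]
    )
    gaz = tracts["gazette_year"].to_numpy(dtype=float)
    y0, y1 = spec.window

    protected_any = (own >= spec.control_ceiling) | (
        others >= spec.control_ceiling
    ).any(axis=1)
    if np.any(protected_any & np.isnan(gaz)):
        bad = tracts.loc[protected_any & np.isnan(gaz), "tract_id"].iloc[0]
        raise CohortError(f"protected tract {bad!r} lacks a gazettement year")

    for tid, o_own, o_other, g in zip(
        tracts["tract_id"], own, (others >= spec.control_ceiling).any(axis=1), gaz
    ):
        if o_other:
            cohort.exclusion_log.append((tid, "overlaps other arrangement"))
        elif o_own >= spec.protect_threshold:
            if y0 < g <= y1:
                cohort.treated_ids.append(tid)
            else:
                cohort.exclusion_log.append((tid, "gazetted outside window"))
        elif o_own >= spec.control_ceiling:
            cohort.exclusion_log.append((tid, "ambiguous band"))
        else:
            cohort.control_ids.append(tid)
    return cohort


def classify_dominant_holding(holdings) -> str:
    """Dominant landholding-size class: the class with the most properties.

    ``holdings`` maps class name -> property count (or a 4-sequence in
    class order very_small..large). Ties break toward the larger size
    class. A tract with no properties is not an agricultural control.
    """
    if not isinstance(holdings, dict):
        holdings = dict(zip(HOLDING_CLASSES, holdings))
    counts = [float(holdings.get(c, 0)) for c in HOLDING_CLASSES]
    if any(c < 0 for c in counts):
        raise ValueError("negative holding counts")
    if sum(counts) == 0:
        raise ValueError("tract has no agricultural properties")
    best = max(range(4), key=lambda k: (counts[k], k))  # tie -> larger class
    return HOLDING_CLASSES[best]


def build_controls(tracts: pd.DataFrame, cohort: Cohort) -> Cohort:
    """Subset control candidates by land use and apply symmetric
    treated-side exclusions for the comparison at hand."""
    spec = cohort.spec
    ct = spec.control_type
    idx = tracts.set_index("tract_id")
    out = Cohort(spec, treated_ids=list(cohort.treated_ids),
                 exclusion_log=list(cohort.exclusion_log))

    hold = idx[[f"holdings_{c}" for c in HOLDING_CLASSES]]

    def dominant(tid):
        counts = hold.loc[tid].to_numpy(dtype=float)
        if counts.sum() == 0:
            return None
        return classify_dominant_holding(counts)

    for tid in cohort.control_ids:
        r = idx.loc[tid]
        if ct == "all_nonPA":
            out.control_ids.append(tid)
        elif ct == "sparse":
            if (
                r["settled_fraction"] < spec.settled_threshold
                and not r["mine_baseline"]
                and not r["mine_post"]
            ):
                out.control_ids.append(tid)
            else:
                out.exclusion_log.append((tid, "not sparsely populated"))
        elif ct in HOLDING_CLASSES:
            if r["settled_fraction"] < spec.settled_threshold:
                out.exclusion_log.append((tid, "below settled threshold"))
            elif r["mine_post"]:
                # keeps agricultural and mining control classes disjoint
                out.exclusion_log.append((tid, "post-baseline mine"))
            elif dominant(tid) != ct:
                out.exclusion_log.append((tid, "different dominant class"))
            else:
                out.control_ids.append(tid)
        elif ct == "mining":
            if r["mine_baseline"]:
                out.exclusion_log.append((tid, "baseline mine"))
            elif not r["mine_post"]:
                out.exclusion_log.append((tid, "no post-baseline mine"))
            else:
                out.control_ids.append(tid)

    # symmetric treated-side exclusions
    kept = []
    for tid in out.treated_ids:
        r = idx.loc[tid]
        if ct in HOLDING_CLASSES or ct == "sparse":
            if r["settled_fraction"] >= spec.settled_threshold:
                out.exclusion_log.append((tid, "treated settled above threshold"))
                continue
        if ct == "mining":
            if r["mine_baseline"]:
                out.exclusion_log.append((tid, "baseline mine"))
                continue
            if r["mine_post"]:
                out.exclusion_log.append((tid, "treated post-baseline mine"))
                continue
        kept.append(tid)
    out.treated_ids = kept

    if not out.control_ids or not out.treated_ids:
        raise CohortError(
            f"empty cohort for {spec.arrangement} vs {ct}: "
            f"{len(out.treated_ids)} treated, {len(out.control_ids)} controls "
            f"({len(out.exclusion_log)} exclusions)"
        )
    out.validate_partition(tracts["tract_id"])
    return out


def build_cohort(tracts: pd.DataFrame, spec: CohortSpec) -> Cohort:
    """Treatment assignment followed by control subsetting, in one call."""
    return build_controls(tracts, assign_treatment(tracts, spec))
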