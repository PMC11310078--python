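"""Tract-table preprocessing: small-tract merging and boundary harmonization.

The analysis unit is the census tract on baseline boundaries. Two
preprocessing steps are provided:

* :func:`merge_small_tracts` — iteratively absorbs tracts below a minimum
  area into a same-municipality neighbor (longest shared border), so that
  tightly-drawn village tracts do not dilute the panel.
* :func:`harmonize_boundaries` — areal interpolation of attributes reported
  on later boundaries back onto the baseline tracts, assuming people are
  homogeneously distributed within each source unit.

Tract tables are pandas DataFrames with one row per tract (``tract_id`` as
a column); adjacency is a long DataFrame ``(tract_id, neighbor_id,
border_km)`` containing both directions of every edge.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MergeResult",
    "default_weight_registry",
    "merge_small_tracts",
    "harmonize_boundaries",
]

#: Aggregation rules when tract B is absorbed into tract A.
#:   sum        — extensive (count-type) fields: add
#:   area_mean  — intensive (rate-type) fields: area-weighted mean
#:   pop_mean   — intensive fields tied to people: population-weighted mean
#:               (falls back to area weights when no population column)
#:   or         — boolean presence flags
#:   keep       — take the absorbing tract's value (labels)
#:   min        — earliest (e.g. gazettement year)
VALID_RULES = {"sum", "area_mean", "pop_mean", "or", "keep", "min"}


def default_weight_registry(columns, dtypes=None) -> dict[str, str]:
    """Infer a merge rule per column from naming conventions and dtypes.

    Explicit registries should be passed for production runs; this default
    covers the canonical tract-table schema. Non-numeric columns keep the
    absorbing tract's value.
    """
    reg: dict[str, str] = {}
    for c in columns:
        if dtypes is not None and not pd.api.types.is_numeric_dtype(dtypes[c]) \
                and not pd.api.types.is_bool_dtype(dtypes[c]):
            reg[c] = "keep"
        elif c in ("tract_id", "state", "municipality"):
            reg[c] = "keep"
        elif c == "area_km2":
            reg[c] = "sum"
        elif c.startswith(("holdings_", "n_", "income_bin_")) or c.endswith(
            ("_count", "_km2", "_heads", "_households")
        ):
            reg[c] = "sum"
        elif c.startswith("mine_") or c.endswith("_flag"):
            reg[c] = "or"
        elif c.startswith("gazette_year"):
            reg[c] = "min"
        elif c in ("cx", "cy"):
            reg[c] = "area_mean"
        elif c.endswith(("_rate", "_pct")) or c.startswith(
            ("literacy", "sanitation", "income_2", "gini")
        ):
            reg[c] = "pop_mean"
        else:
            reg[c] = "area_mean"
    return reg


@dataclass
class MergeResult:
    tracts: pd.DataFrame
    adjacency: pd.DataFrame
    merge_log: list = field(default_factory=list)
    isolated: list = field(default_factory=list)

    def log_as_json(self) -> str:
        return json.dumps(
            {
                "merges": [
                    {"merged": str(a), "into": str(b)} for a, b in self.merge_log
                ],
                "isolated_below_threshold": [str(t) for t in self.isolated],
            },
            indent=2,
        )


def _check_symmetric(adj: pd.DataFrame) -> None:
    fwd = set(zip(adj["tract_id"], adj["neighbor_id"]))
    rev = set(zip(adj["neighbor_id"], adj["tract_id"]))
    if fwd != rev:
        raise ValueError("adjacency relation is not symmetric")


def merge_small_tracts(
    tracts: pd.DataFrame,
    adjacency: pd.DataFrame,
    min_area_km2: float = 50.0,
    registry: dict[str, str] | None = None,
    population_col: str = "n_households",
) -> MergeResult:
    """Merge tracts below ``min_area_km2`` into same-municipality neighbors.

    Iteratively: pick the smallest tract below the threshold, merge it into
    the neighbor in the same municipality with which it shares the longest
    border (ties broken toward the lowest neighbor id, for determinism).
    Extensive fields add, intensive fields average with area or population
    weights per ``registry``, adjacency lists union with shared borders
    summed. A sub-threshold tract with no same-municipality neighbor is
    retained and logged rather than dropped.
    """
    if min_area_km2 <= 0:
        raise ValueError("min_area_km2 must be positive")
    if tracts["tract_id"].duplicated().any():
        raise ValueError("duplicate tract ids")
    if tracts["municipality"].isna().any():
        raise ValueError("municipality must be defined for every tract")
    _check_symmetric(adjacency)

    registry = dict(registry) if registry is not None else default_weight_registry(
        tracts.columns, tracts.dtypes
    )
    bad = {c: r for c, r in registry.items() if r not in VALID_RULES}
    if bad:
        raise ValueError(f"unknown merge rules: {bad}")

    rows: dict = {r["tract_id"]: dict(r) for _, r in tracts.iterrows()}
    # neighbor map: id -> {neighbor_id: border_km}
    nbrs: dict = {tid: {} for tid in rows}
    for _, e in adjacency.iterrows():
        a, b = e["tract_id"], e["neighbor_id"]
        if a not in rows or b not in rows:
            raise ValueError(f"adjacency references unknown tract {a!r} or {b!r}")
        nbrs[a][b] = nbrs[a].get(b, 0.0) + float(e["border_km"])

    merge_log: list[tuple] = []
    isolated: list = []

    def weight(row) -> float:
        if population_col in row and pd.notna(row.get(population_col)):
            w = float(row[population_col])
            if w > 0:
                return w
        return float(row["area_km2"])

    while True:
        candidates = [
            tid
            for tid, r in rows.items()
            if r["area_km2"] < min_area_km2 and tid not in isolated
        ]
        if not candidates:
            break
        # smallest first; id tie-break keeps runs reproducible
        small = min(candidates, key=lambda t: (rows[t]["area_km2"], str(t)))
        muni = rows[small]["municipality"]
        eligible = [
            (nb, length)
            for nb, length in nbrs[small].items()
            if rows[nb]["municipality"] == muni
        ]
        if not eligible:
            isolated.append(small)
            continue
        target = min(eligible, key=lambda e: (-e[1], str(e[0])))[0]

        a, b = rows[target], rows[small]
        merged = {}
        for col in tracts.columns:
            rule = registry.get(col, "area_mean")
            va, vb = a[col], b[col]
            if rule == "sum":
                merged[col] = va + vb
            elif rule == "or":
                merged[col] = bool(va) or bool(vb)
            elif rule == "keep":
                merged[col] = va
            elif rule == "min":
                vals = [v for v in (va, vb) if pd.notna(v)]
                merged[col] = min(vals) if vals else np.nan
            else:
                if rule == "pop_mean":
                    wa, wb = weight(a), weight(b)
                else:
                    wa, wb = float(a["area_km2"]), float(b["area_km2"])
                if wa + wb == 0:
                    merged[col] = np.nan
                elif pd.isna(va) or pd.isna(vb):
                    merged[col] = va if pd.notna(va) else vb
                else:
                    merged[col] = (wa * va + wb * vb) / (wa + wb)
        merged["tract_id"] = target

        # rewire adjacency: union of both neighbor sets, borders summed
        new_nb: dict = {}
        for src in (target, small):
            for nb, length in nbrs[src].items():
                if nb in (target, small):
                    continue
                new_nb[nb] = new_nb.get(nb, 0.0) + length
        for nb in nbrs[small]:
            if nb not in (target, small):
                nbrs[nb].pop(small, None)
        for nb, length in new_nb.items():
            nbrs[nb][target] = length
            # remove stale reverse edge amounts; forward map rebuilt below
        for nb in list(nbrs[target]):
            if nb not in new_nb:
                nbrs[nb].pop(target, None)
        nbrs[target] = new_nb
        del nbrs[small]
        del rows[small]
        rows[target] = merged
        merge_log.append((small, target))
        # a previously isolated tract may gain an eligible neighbor
        isolated = [
            t
            for t in isolated
            if not any(
                rows[nb]["municipality"] == rows[t]["municipality"]
                for nb in nbrs[t]
            )
        ]

    if isolated:
        warnings.warn(
            f"{len(isolated)} sub-threshold tract(s) have no same-municipality "
            "neighbor and were retained",
            stacklevel=2,
        )

    out = pd.DataFrame([rows[t] for t in rows]).reset_index(drop=True)
    adj_rows = [
        {"tract_id": a, "neighbor_id": b, "border_km": L}
        for a, nb in nbrs.items()
        for b, L in nb.items()
    ]
    out_adj = pd.DataFrame(adj_rows, columns=["tract_id", "neighbor_id", "border_km"])
    return MergeResult(out, out_adj, merge_log, isolated)


def harmonize_boundaries(
    target_ids,
    source_units: pd.DataFrame,
    value_kind: str,
) -> pd.Series:
    """Areal interpolation of later-period values onto baseline tracts.

    ``source_units`` has one row per (source unit, target tract)
    intersection with columns ``unit_id``, ``value``, ``target_id``,
    ``overlap_area`` and ``unit_area``. Under the assumption that people
    are homogeneously distributed within each source unit:

    * counts are allocated to each target in proportion to the share of
      the source unit's area that falls inside it;
    * rates are overlap-area-weighted averages over the sources
      intersecting each target.

    Targets with zero total overlap are returned as NaN (flagged missing,
    never zero-filled). The same routine serves any later-period census
    whose boundaries shifted relative to baseline.
    """
    if value_kind not in ("count", "rate"):
        raise ValueError("value_kind must be 'count' or 'rate'")
    s = source_units
    if (s["overlap_area"] < 0).any():
        raise ValueError("negative overlap areas")
    per_unit = s.groupby("unit_id")["overlap_area"].sum()
    unit_area = s.groupby("unit_id")["unit_area"].first()
    if ((per_unit - unit_area) / unit_area > 0.01).any():
        raise ValueError("source-unit overlaps exceed unit area beyond 1% tolerance")

    out = pd.Series(np.nan, index=pd.Index(target_ids, name="target_id"), dtype=float)
    if value_kind == "count":
        alloc = s["value"] * s["overlap_area"] / s["unit_id"].map(unit_area)
        summed = alloc.groupby(s["target_id"]).sum()
        covered = s.groupby("target_id")["overlap_area"].sum()
        summed = summed[covered[summed.index] > 0]
        out.loc[summed.index] = summed
    else:
        num = (s["value"] * s["overlap_area"]).groupby(s["target_id"]).sum()
        den = s.groupby("target_id")["overlap_area"].sum()
        ok = den > 0
        out.loc[den.index[ok]] = (num[ok] / den[ok]).to_numpy()
    missing = out.index[out.isna()]
    if len(missing):
        logger.warning("%d target tract(s) have no overlap; left missing", len(missing))
    return out
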