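"""End-to-end orchestration: preprocess -> outcomes -> cohorts -> matching
-> estimation -> robustness, for every arrangement x control-type x
outcome combination, from a single config.

The pipeline is deterministic given the config (including the seed) and
emits a manifest (config hash, seed, package versions) alongside the
results grid, balance reports and exclusion logs so that any results
row can be traced to its cohort and matched set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohorts as coh
from . import estimation as est
from . import matching as mat
from . import outcomes as out
from . import preprocess as pre
from . import robustness as rob
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "attach_outcome_panel",
           "BASE_COVARIATES"]

#: Theory-of-change covariates shared by every comparison: geography and
#: suitability, baseline pressure, and baseline levels of every outcome.
BASE_COVARIATES = [
    "area_km2",
    "slope_deg",
    "elevation_m",
    "flood_risk",
    "travel_time_h",
    "pop_density",
    "forest_pct_2000",
    "income_2000",
    "gini_2000",
    "literacy_2000",
    "sanitation_2000",
]

OUTCOME_COLS = {
    "forest": ("forest_pct_2000", "forest_pct_2010"),
    "income": ("income_2000", "income_2010"),
    "gini": ("gini_2000", "gini_2010"),
    "literacy": ("literacy_2000", "literacy_2010"),
    "sanitation": ("sanitation_2000", "sanitation_2010"),
}


@dataclass
class RunConfig:
    simulation: syn.SimulationConfig | None = None
    tracts_path: str | None = None
    adjacency_path: str | None = None
    arrangements: tuple = syn.ARRANGEMENTS
    control_types: tuple = coh.CONTROL_TYPES
    outcomes: tuple = syn.OUTCOMES
    covariates: list = field(default_factory=lambda: list(BASE_COVARIATES))
    protect_threshold: float = 0.10
    control_ceiling: float = 0.01
    settled_threshold: float = 0.10
    min_area_km2: float = 50.0
    smd_threshold: float = 0.25
    caliper: float | None = None
    max_ratio: int = 10
    deflator: float = 1.0
    income_edges: tuple | None = None  # required for external tract tables
    prune: bool = True
    window: tuple = (2000, 2010)
    run_robustness: bool = False
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            if "grid_shape" in sim:
                sim["grid_shape"] = tuple(sim["grid_shape"])
            cfg.simulation = syn.SimulationConfig(**sim)
        return cfg

    def manifest(self) -> dict:
        import scipy
        import statsmodels

        def jsonable(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                o = dataclasses.asdict(o)
            if isinstance(o, dict):
                return {str(k): jsonable(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [jsonable(v) for v in o]
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, (str, int, float, bool)) or o is None:
                return o
            return str(o)

        blob = json.dumps(jsonable(self), sort_keys=True)
        return {
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "seed": self.seed,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "scipy": scipy.__version__,
                "statsmodels": statsmodels.__version__,
            },
        }


@dataclass
class ResultsBundle:
    results: pd.DataFrame
    balance: dict  # (arrangement, control_type) -> balance DataFrame
    cohorts: dict  # (arrangement, control_type) -> cohort audit DataFrame
    matched: dict  # (arrangement, control_type) -> matched-set DataFrame
    robustness: dict
    manifest: dict
    tracts: pd.DataFrame
    truth: syn.SimulationTruth | None = None
    skipped: list = field(default_factory=list)

    def write(self, outdir) -> None:
        outp = Path(outdir)
        outp.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(outp / "results.csv", index=False)
        (outp / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        (outp / "robustness.json").write_text(
            json.dumps(self.robustness, indent=2, default=float)
        )
        from .matching import love_plot

        for (a, ct), df in self.balance.items():
            df.to_csv(outp / f"balance_{a}_{ct}.csv")
            love_plot(df, outp / f"balance_{a}_{ct}.png")
        for (a, ct), df in self.cohorts.items():
            df.to_csv(outp / f"cohort_{a}_{ct}.csv", index=False)
        for (a, ct), df in self.matched.items():
            df.to_csv(outp / f"matched_{a}_{ct}.csv", index=False)


def _read_table(path) -> pd.DataFrame:
    p = Path(path)
    if p.suffix in (".parquet", ".pq"):
        return pd.read_parquet(p)
    return pd.read_csv(p)


def attach_outcome_panel(tracts: pd.DataFrame, income_edges,
                         deflator: float = 1.0) -> pd.DataFrame:
    """Construct the five outcome variables (baseline and endline columns)
    from raw tract attributes: forest areas, income-bin counts, literacy
    and sanitation head counts."""
    t = tracts.copy()
    t["forest_pct_2000"] = np.clip(
        out.endline_forest_pct(t["forest_2000_km2"], t["area_km2"]), 0, 100
    )
    t["forest_pct_2010"] = np.clip(
        out.endline_forest_pct(t["forest_2010_km2"], t["area_km2"]), 0, 100
    )
    t["defor_pct"] = out.deforestation_pct(
        t["forest_2000_km2"], t["forest_2010_km2"], t["area_km2"]
    )
    nbins = len(income_edges)
    for year in (2000, 2010):
        cols = [f"income_bin_{year}_{j}" for j in range(nbins)]
        counts = t[cols].to_numpy(dtype=float)
        means, ginis = np.empty(len(t)), np.empty(len(t))
        for i in range(len(t)):
            table = out.IncomeBinTable(income_edges, counts[i])
            means[i] = out.mean_income_from_bins(table)
            ginis[i] = out.gini_from_bins(table)
        t[f"income_{year}"] = means
        t[f"gini_{year}"] = ginis
        t[f"literacy_{year}"] = out.literacy_rate(
            t[f"literate_heads_{year}"], t["n_households"]
        )
        t[f"sanitation_{year}"] = out.poor_sanitation_pct(
            t[f"sanitation_without_{year}"], t["n_households"]
        )
    t["income_2010"] = out.deflate_income(t["income_2010"], deflator)
    return t


def _comparison_covariates(config: RunConfig, control_type: str) -> list:
    cov = list(config.covariates)
    if control_type in ("sparse", *coh.HOLDING_CLASSES):
        # mining during the window can confound the agriculture contrast
        cov.append("mine_post")
    if control_type == "mining":
        # settled land can confound the mining contrast
        cov.append("settled_fraction")
    return cov


def run_pipeline(config: RunConfig, stages=("match", "estimate", "robustness")):
    """Execute the configured analysis; returns a :class:`ResultsBundle`.

    ``stages`` can stop the pipeline early ("match" alone produces
    cohorts, matches and balance; "estimate" adds the results grid;
    "robustness" the robustness report, if enabled in the config).
    """
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        tracts, adjacency, truth = syn.generate_landscape(sim)
        income_edges = sim.income_bins
    else:
        if config.tracts_path is None:
            raise ValueError("need either a simulation config or a tracts path")
        if config.income_edges is None:
            raise ValueError("income_edges must be configured for external tables")
        tracts = _read_table(config.tracts_path)
        adjacency = (
            _read_table(config.adjacency_path)
            if config.adjacency_path
            else pd.DataFrame(columns=["tract_id", "neighbor_id", "border_km"])
        )
        truth = None
        income_edges = tuple(config.income_edges)

    merged = pre.merge_small_tracts(tracts, adjacency, config.min_area_km2)
    t = attach_outcome_panel(merged.tracts, income_edges, config.deflator)

    results_rows: list = []
    balance: dict = {}
    cohort_frames: dict = {}
    matched_frames: dict = {}
    robustness_report: dict = {}
    skipped: list = []
    matched_cache: dict = {}

    for a in config.arrangements:
        for ct in config.control_types:
            spec = coh.CohortSpec(
                arrangement=a,
                control_type=ct,
                protect_threshold=config.protect_threshold,
                control_ceiling=config.control_ceiling,
                settled_threshold=config.settled_threshold,
                window=config.window,
            )
            try:
                cohort = coh.build_cohort(t, spec)
            except coh.CohortError as err:
                warnings.warn(f"comparison {a} vs {ct} skipped: {err}",
                              stacklevel=2)
                skipped.append((a, ct, str(err)))
                continue
            cohort_frames[(a, ct)] = cohort.to_frame()
            data = t[t["tract_id"].isin(cohort.treated_ids + cohort.control_ids)]
            data = data.assign(treated=data["tract_id"].isin(cohort.treated_ids))
            covs = _comparison_covariates(config, ct)
            exact = ("state", "mine_baseline") if ct != "mining" else ("state",)
            try:
                if config.prune:
                    model, matched, report, _plog = mat.prune_covariates(
                        data, covs, exact, config.smd_threshold, config.caliper,
                        config.max_ratio,
                    )
                else:
                    model = mat.fit_propensity(data, covs)
                    matched = mat.full_match(data, model, exact, config.caliper,
                                             config.max_ratio)
                    report = mat.balance_report(data, covs, matched,
                                                threshold=config.smd_threshold)
            except mat.MatchingError as err:
                warnings.warn(f"comparison {a} vs {ct} unmatchable: {err}",
                              stacklevel=2)
                skipped.append((a, ct, str(err)))
                continue
            balance[(a, ct)] = report
            matched_frames[(a, ct)] = matched.to_frame()
            matched_cache[(a, ct)] = (data, matched, covs)

            if "estimate" not in stages and "robustness" not in stages:
                continue
            for outcome in config.outcomes:
                base_col, end_col = OUTCOME_COLS[outcome]
                eff = est.estimate_effect(
                    data,
                    outcome_endline=end_col,
                    outcome_baseline=base_col,
                    covariates=covs,
                    weights=matched.weights,
                    arrangement=a,
                    control_type=ct,
                    outcome=outcome,
                    loss_baseline="forest_pct_2000" if outcome == "forest" else None,
                )
                results_rows.append(dataclasses.asdict(eff))

    results = pd.DataFrame(results_rows)
    if len(results):
        results["p_fdr"] = est.fdr_adjust(results["p"], results["outcome"])

    if "robustness" in stages and config.run_robustness and matched_cache:
        robustness_report = _run_robustness(config, t, matched_cache, results)

    bundle = ResultsBundle(
        results=results,
        balance=balance,
        cohorts=cohort_frames,
        matched=matched_frames,
        robustness=robustness_report,
        manifest=config.manifest(),
        tracts=t,
        truth=truth,
        skipped=skipped,
    )
    if config.outdir:
        bundle.write(config.outdir)
    return bundle


def _run_robustness(config, tracts, matched_cache, results) -> dict:
    """Oster bounds, residual Moran's I and panel-FE cross-check for the
    all-non-protected comparisons; post-matching settled-land and pasture
    ANOVAs across landholding classes."""
    report: dict = {}
    for a in config.arrangements:
        key = (a, "all_nonPA")
        if key not in matched_cache:
            continue
        data, matched, covs = matched_cache[key]
        d = data.set_index("tract_id").loc[matched.weights.index]
        w = matched.weights.loc[d.index]
        entry: dict = {}
        for outcome in config.outcomes:
            base_col, end_col = OUTCOME_COLS[outcome]
            y = d[end_col].to_numpy(dtype=float)
            tr = d["treated"].astype(float).to_numpy()
            wv = w.to_numpy(dtype=float)
            # short model: treatment only
            Xs = np.column_stack([np.ones(len(d)), tr])
            rs = est.weighted_ols(Xs, y, wv, ["intercept", "treated"])
            # long model: full covariate set + baseline
            cols = [c for c in dict.fromkeys([base_col, *covs]) if c != end_col]
            Xl = np.column_stack([np.ones(len(d)), tr,
                                  d[cols].to_numpy(dtype=float)])
            rl = est.weighted_ols(Xl, y, wv, ["intercept", "treated"] + cols)

            def wr2(r):
                mu = np.average(r.y, weights=r.w)
                return 1 - np.sum(r.w * r.residuals**2) / np.sum(
                    r.w * (r.y - mu) ** 2
                )

            r_s, r_l = wr2(rs), wr2(rl)
            o: dict = {}
            if r_l > r_s:
                o = rob.oster_bound(rob.OsterInputs(
                    beta_short=float(rs.params["treated"]), r_short=float(r_s),
                    beta_long=float(rl.params["treated"]), r_long=float(r_l),
                ))
            fe = rob.panel_fe(d[base_col], d[end_col], tr, wv)
            entry[outcome] = {"oster": o, "panel_fe": fe}
            if outcome == "forest":
                coords = d[["cx", "cy"]].to_numpy(dtype=float)
                sub = slice(None)
                if len(d) > 1200:  # cap the dense distance matrix
                    rng = np.random.default_rng(config.seed)
                    sub = np.sort(rng.choice(len(d), 1200, replace=False))
                entry[outcome]["morans_i"] = rob.morans_i(
                    rl.residuals[sub], coords[sub], seed=config.seed
                )
        report[a] = entry

        # post-matching land-use composition checks over the matched
        # agricultural controls of this arrangement
        ag = []
        for ct in coh.HOLDING_CLASSES:
            k = (a, ct)
            if k not in matched_cache:
                continue
            data_ct, matched_ct, _ = matched_cache[k]
            dd = data_ct.set_index("tract_id").loc[matched_ct.weights.index]
            ctrl = dd[~dd["treated"]]
            ag.append(pd.DataFrame({
                "settled": ctrl["settled_fraction"],
                "pasture": ctrl["pasture_fraction"],
                "class": ct,
                "w": matched_ct.weights.loc[ctrl.index],
            }))
        if len(ag) >= 2:
            pooled = pd.concat(ag)
            report[a]["landuse_anova"] = {
                "settled": rob.group_means_anova(pooled["settled"],
                                                 pooled["class"], pooled["w"]),
                "pasture": rob.group_means_anova(pooled["pasture"],
                                                 pooled["class"], pooled["w"]),
            }
    return report
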