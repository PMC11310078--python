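"""Synthetic census-tract landscapes with known treatment structure.

The generator emulates the statistical features of a tract-level
protected-area evaluation panel so that every downstream stage —
preprocessing, cohort construction, matching, estimation, robustness —
can be exercised against a known ground truth without any download:

* right-skewed tract areas (lognormal) on a rectangular lattice with
  rook adjacency and shared-border lengths;
* contiguous state strata and block municipalities;
* spatially correlated covariate fields (kernel smoothing of i.i.d.
  normals; the correlation range is the kernel bandwidth in cells);
* protection assignment through a logistic propensity on covariates, so
  treated and control tracts genuinely differ at baseline (confounding);
* a land-use mosaic over untreated tracts (sparsely settled, four
  landholding-size classes, post-baseline mining licences);
* household income reported only as counts per income category, as in
  census microdata aggregates;
* endline outcomes = baseline + secular trend + additive treatment
  effect + heteroscedastic noise.

The defaults are the study conditions for all recovery and calibration
tests; see docs/methods.md for how each was chosen.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

ARRANGEMENTS = ("SPA", "SUPA", "IT")
OUTCOMES = ("forest", "income", "gini", "literacy", "sanitation")
LANDUSE_CLASSES = ("sparse", "very_small", "small", "medium", "large", "mining")
HOLDING_CLASSES = ("very_small", "small", "medium", "large")

__all__ = [
    "ARRANGEMENTS",
    "OUTCOMES",
    "LANDUSE_CLASSES",
    "HOLDING_CLASSES",
    "CovariateSpec",
    "SimulationConfig",
    "SimulationTruth",
    "generate_landscape",
    "bin_household_incomes",
    "write_landscape",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One spatially correlated covariate field.

    ``corr_range`` is the Gaussian kernel bandwidth in lattice cells
    (0 = i.i.d.); ``clip`` bounds the field after scaling.
    """

    name: str
    corr_range: float
    mean: float
    sd: float
    clip: tuple | None = None


def _default_covariates() -> list[CovariateSpec]:
    return [
        CovariateSpec("slope_deg", 3.0, 8.0, 6.0, (0.0, 45.0)),
        CovariateSpec("elevation_m", 5.0, 150.0, 80.0, (0.0, None)),
        CovariateSpec("flood_risk", 3.0, 0.2, 0.15, (0.0, 1.0)),
        CovariateSpec("travel_time_h", 6.0, 10.0, 6.0, (0.2, None)),
        CovariateSpec("pop_density", 4.0, 5.0, 4.0, (0.05, None)),
        CovariateSpec("baseline_forest_pct", 4.0, 75.0, 18.0, (5.0, 100.0)),
    ]


def _default_propensity() -> dict:
    # Remote, forested, steep, sparsely populated tracts are more likely to
    # be gazetted — the same features that predict slower deforestation and
    # slower income growth, which is what makes the naive contrast biased.
    base = {
        "intercept": -2.9,
        "travel_time_h": 0.55,
        "baseline_forest_pct": 0.55,
        "pop_density": -0.45,
        "slope_deg": 0.2,
    }
    return {a: dict(base) for a in ARRANGEMENTS}


def _default_effects() -> dict:
    # Additive effects on the endline outcome, in outcome units. Forest is
    # endline forest cover %: positive = avoided deforestation. The income
    # and literacy entries encode the "both improve, treated improves less"
    # pattern for Indigenous territories.
    return {
        ("SPA", "forest"): 5.0,
        ("SPA", "income"): 60.0,
        ("SUPA", "forest"): 4.0,
        ("SUPA", "literacy"): 2.0,
        ("IT", "forest"): 7.0,
        ("IT", "income"): -60.0,
        ("IT", "literacy"): -2.0,
    }


def _default_noise() -> dict:
    return {"forest": 3.5, "income": 50.0, "gini": 0.03, "literacy": 4.0,
            "sanitation": 4.0}


def _default_trend() -> dict:
    # Secular 2000->2010 drift applied to every tract: forest is lost
    # everywhere, real incomes and literacy rise, poor sanitation falls.
    return {"forest": -18.0, "income": 150.0, "gini": -0.02, "literacy": 8.0,
            "sanitation": -10.0}


def _default_mixture() -> dict:
    return {"sparse": 0.30, "very_small": 0.18, "small": 0.15, "medium": 0.10,
            "large": 0.15, "mining": 0.12}


@dataclass
class SimulationConfig:
    n_tracts: int = 2000
    n_states: int = 4
    grid_shape: tuple = (50, 40)
    area_lognormal_params: tuple = (6.4, 1.0)
    covariate_spec: list = field(default_factory=_default_covariates)
    propensity_coefs: dict = field(default_factory=_default_propensity)
    true_effects: dict = field(default_factory=_default_effects)
    noise_sd: dict = field(default_factory=_default_noise)
    secular_trend: dict = field(default_factory=_default_trend)
    heteroscedasticity_factor: float = 0.5
    income_bins: tuple = (0.0, 100.0, 200.0, 400.0, 800.0, 1600.0, 3200.0)
    landuse_mixture: dict = field(default_factory=_default_mixture)
    exclusion_band_frac: float = 0.05
    window: tuple = (2000, 2010)
    seed: int = 0

    def __post_init__(self) -> None:
        nr, nc = self.grid_shape
        if self.n_tracts <= 0 or self.n_states <= 0 or nr <= 0 or nc <= 0:
            raise ValueError("dimensions must be positive")
        if nr * nc != self.n_tracts:
            raise ValueError("grid_shape must multiply to n_tracts")
        mix = sum(self.landuse_mixture.get(c, 0.0) for c in LANDUSE_CLASSES)
        if abs(mix - 1.0) > 1e-12:
            raise ValueError("landuse_mixture must sum to 1")
        edges = np.asarray(self.income_bins, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("income_bins must be strictly increasing")
        for k, v in self.noise_sd.items():
            if v <= 0:
                raise ValueError(f"noise_sd[{k}] must be positive")
        for cs in self.covariate_spec:
            if cs.sd <= 0:
                raise ValueError(f"covariate {cs.name} needs positive sd")
        if self.heteroscedasticity_factor < 0:
            raise ValueError("heteroscedasticity_factor must be nonnegative")


@dataclass
class SimulationTruth:
    """Ground truth of one generated landscape."""

    propensity: pd.DataFrame          # per-tract P(treated) per arrangement
    arrangement: pd.Series            # assigned arrangement or "" for none
    true_effects: dict                # (arrangement, outcome) -> effect
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "true_effects": {
                    f"{a}:{o}": v for (a, o), v in self.true_effects.items()
                },
                "n_treated": {
                    a: int((self.arrangement == a).sum()) for a in ARRANGEMENTS
                },
            },
            indent=2,
        )


def bin_household_incomes(incomes, edges) -> np.ndarray:
    """Count households per income category; the top category is open.

    ``edges`` are the lower edges of each category; incomes below the
    first interior edge fall into the first category.
    """
    incomes = np.asarray(incomes, dtype=float)
    if incomes.size == 0:
        raise ValueError("no incomes to bin")
    if np.any(incomes < 0):
        raise ValueError("negative incomes")
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    idx = np.digitize(incomes, edges[1:], right=False)
    return np.bincount(idx, minlength=len(edges))


def _smooth_field(rng, shape, bandwidth) -> np.ndarray:
    f = rng.standard_normal(shape)
    if bandwidth > 0:
        f = ndimage.gaussian_filter(f, sigma=bandwidth, mode="reflect")
    f = (f - f.mean()) / f.std()
    return f


def _sigma_from_gini(g: np.ndarray) -> np.ndarray:
    # Lognormal identity: G = 2*Phi(sigma/sqrt(2)) - 1
    return np.sqrt(2.0) * stats.norm.ppf((np.clip(g, 0.02, 0.95) + 1.0) / 2.0)


def _draw_binned_incomes(rng, n_households, mean_income, gini, edges):
    """Draw lognormal household incomes per tract and return the bin-count
    matrix (n_tracts x n_bins). Fully vectorized across tracts."""
    sigma = _sigma_from_gini(gini)
    mu = np.log(np.maximum(mean_income, 1.0)) - 0.5 * sigma**2
    rep_mu = np.repeat(mu, n_households)
    rep_sig = np.repeat(sigma, n_households)
    incomes = rng.lognormal(rep_mu, rep_sig)
    tract_idx = np.repeat(np.arange(len(n_households)), n_households)
    nbins = len(edges)
    bin_idx = np.digitize(incomes, np.asarray(edges)[1:], right=False)
    flat = np.bincount(tract_idx * nbins + bin_idx, minlength=len(n_households) * nbins)
    return flat.reshape(len(n_households), nbins)


def generate_landscape(config: SimulationConfig):
    """Generate one synthetic landscape.

    Returns ``(tracts, adjacency, truth)``: the canonical tract table
    (one row per tract), the symmetric adjacency table ``(tract_id,
    neighbor_id, border_km)``, and a :class:`SimulationTruth`.
    """
    rng = np.random.default_rng(config.seed)
    nr, nc = config.grid_shape
    n = config.n_tracts
    row, col = np.divmod(np.arange(n), nc)

    mu, sg = config.area_lognormal_params
    area = rng.lognormal(mu, sg, size=n)
    side = np.sqrt(area)
    mean_side = side.mean()
    cx, cy = col * mean_side, row * mean_side

    states = np.minimum(col * config.n_states // nc, config.n_states - 1)
    state = np.array([f"S{s + 1}" for s in states])
    muni = (row // 5) * ((nc + 4) // 5) + (col // 5)
    municipality = np.array([f"M{m:04d}" for m in muni])

    cov = {}
    zcov = {}
    for cs in config.covariate_spec:
        f = _smooth_field(rng, (nr, nc), cs.corr_range)[row, col]
        x = cs.mean + cs.sd * f
        if cs.clip is not None:
            lo, hi = cs.clip
            x = np.clip(x, lo if lo is not None else -np.inf,
                        hi if hi is not None else np.inf)
        cov[cs.name] = x
        zcov[cs.name] = (x - cs.mean) / cs.sd

    # --- protection assignment through the logistic propensity ------------
    prop = {}
    for a in ARRANGEMENTS:
        coefs = config.propensity_coefs[a]
        lp = np.full(n, float(coefs.get("intercept", 0.0)))
        for name, b in coefs.items():
            if name == "intercept":
                continue
            lp += b * zcov[name]
        prop[a] = 1.0 / (1.0 + np.exp(-lp))
    prop_df = pd.DataFrame(prop)
    sat = ((prop_df.to_numpy() < 1e-3) | (prop_df.to_numpy() > 1 - 1e-3)).any(axis=1)
    if sat.mean() > 0.05:
        warnings.warn(
            f"propensity saturates at 0/1 for {100 * sat.mean():.1f}% of tracts; "
            "the design is close to degenerate",
            stacklevel=2,
        )

    arrangement = np.full(n, "", dtype=object)
    u = rng.uniform(size=(n, len(ARRANGEMENTS)))
    for j, a in enumerate(ARRANGEMENTS):
        hit = (arrangement == "") & (u[:, j] < prop[a])
        arrangement[hit] = a
    treated = arrangement != ""

    overlap = {a: np.zeros(n) for a in ARRANGEMENTS}
    gazette = np.full(n, np.nan)
    y0, y1 = config.window
    for a in ARRANGEMENTS:
        m = arrangement == a
        overlap[a][m] = rng.uniform(0.10, 1.0, size=m.sum())
        gazette[m] = rng.integers(y0 + 1, y1, endpoint=True, size=m.sum())
    # a small share of treated tracts also brush another arrangement, to
    # exercise the cross-arrangement exclusion
    brush = treated & (rng.uniform(size=n) < 0.03)
    for i in np.flatnonzero(brush):
        others = [a for a in ARRANGEMENTS if a != arrangement[i]]
        overlap[others[rng.integers(len(others))]][i] = rng.uniform(0.01, 0.3)
    # untreated tracts: mostly clean controls, plus an explicit 1-10% band
    untreated = np.flatnonzero(~treated)
    band = untreated[rng.uniform(size=len(untreated)) < config.exclusion_band_frac]
    for i in band:
        a = ARRANGEMENTS[rng.integers(len(ARRANGEMENTS))]
        overlap[a][i] = rng.uniform(0.01, 0.10)
        gazette[i] = rng.integers(y0 + 1, y1, endpoint=True)
    clean = np.setdiff1d(untreated, band)
    for a in ARRANGEMENTS:
        overlap[a][clean] = np.minimum(
            overlap[a][clean], rng.uniform(0.0, 0.01, size=len(clean))
        )

    # --- land-use mosaic over untreated tracts ----------------------------
    classes = np.array(
        [config.landuse_mixture[c] for c in LANDUSE_CLASSES], dtype=float
    )
    landuse = np.full(n, "", dtype=object)
    landuse[untreated] = np.array(LANDUSE_CLASSES)[
        rng.choice(len(LANDUSE_CLASSES), size=len(untreated), p=classes / classes.sum())
    ]

    settled = np.empty(n)
    settled[treated] = rng.uniform(0.0, 0.25, size=treated.sum()) ** 2 * 4  # skew low
    holdings = np.zeros((n, 4), dtype=int)
    pasture = np.zeros(n)
    mine_post = np.zeros(n, dtype=bool)
    for i in untreated:
        c = landuse[i]
        if c == "sparse":
            settled[i] = rng.uniform(0.0, 0.09)
            holdings[i] = rng.multinomial(rng.poisson(3), [0.4, 0.3, 0.2, 0.1])
        elif c == "mining":
            settled[i] = rng.uniform(0.0, 0.4)
            mine_post[i] = True
            holdings[i] = rng.multinomial(rng.poisson(10), [0.4, 0.3, 0.2, 0.1])
        else:
            settled[i] = rng.uniform(0.12, 0.7)
            k = HOLDING_CLASSES.index(c)
            p = np.full(4, 0.15)
            p[k] = 0.55
            holdings[i] = rng.multinomial(20 + rng.poisson(80), p)
            pasture[i] = settled[i] * rng.uniform(0.2, 0.8)
    mine_post |= (rng.uniform(size=n) < 0.01)  # rare mines inside protected tracts
    mine_baseline = rng.uniform(size=n) < 0.02
    settled = np.clip(settled, 0.0, 0.95)

    # --- outcomes ----------------------------------------------------------
    eff = {a: {o: config.true_effects.get((a, o), 0.0) for o in OUTCOMES}
           for a in ARRANGEMENTS}

    def effect_for(outcome):
        e = np.zeros(n)
        for a in ARRANGEMENTS:
            e[arrangement == a] = eff[a][outcome]
        return e

    zhet = np.clip(zcov["pop_density"], -2.0, 2.0)
    het = np.exp(config.heteroscedasticity_factor * zhet)

    def noise(outcome):
        return rng.normal(0.0, config.noise_sd[outcome] * het)

    tr = config.secular_trend
    # forest: covariate-driven loss (accessible, settled tracts lose more)
    forest0_pct = cov["baseline_forest_pct"]
    # loss depends only on covariates the analyst can match on, so that
    # "matching on the true confounders" is achievable by design; the
    # secular loss level is kept well above effect + noise so the
    # cumulative-loss floor (endline <= baseline) almost never binds and
    # additive effects survive intact
    base_loss = (
        -tr["forest"]
        - 1.5 * zcov["travel_time_h"]
        - 0.5 * zcov["slope_deg"]
        + 1.25 * zcov["pop_density"]
        - 0.4 * zcov["flood_risk"]
    )
    forest1_pct = np.clip(
        forest0_pct - np.clip(base_loss, 0.0, None) + effect_for("forest")
        + noise("forest"),
        0.0,
        forest0_pct,
    )
    forest0_km2 = forest0_pct / 100.0 * area
    forest1_km2 = forest1_pct / 100.0 * area

    # income & inequality: realized through household draws and binning
    income0 = np.clip(
        400.0 + 60.0 * zcov["pop_density"] - 40.0 * zcov["travel_time_h"]
        + rng.normal(0, 40, n),
        60.0,
        None,
    )
    income1 = np.clip(
        income0 + tr["income"] - 30.0 * zcov["travel_time_h"]
        + effect_for("income") + noise("income"),
        40.0,
        None,
    )
    gini0 = np.clip(0.55 + 0.03 * zcov["pop_density"] + rng.normal(0, 0.02, n),
                    0.25, 0.85)
    gini1 = np.clip(gini0 + tr["gini"] + effect_for("gini") + noise("gini"),
                    0.1, 0.9)
    n_households = np.clip(
        np.round(cov["pop_density"] * area / 3.5), 30, 400
    ).astype(int)
    edges = config.income_bins
    bins0 = _draw_binned_incomes(rng, n_households, income0, gini0, edges)
    bins1 = _draw_binned_incomes(rng, n_households, income1, gini1, edges)

    lit0 = np.clip(70.0 - 4.0 * zcov["travel_time_h"] + rng.normal(0, 5, n), 5, 95)
    lit1 = np.clip(lit0 + tr["literacy"] + effect_for("literacy")
                   + noise("literacy"), 1, 99)
    san0 = np.clip(60.0 + 5.0 * zcov["travel_time_h"] - 4.0 * zcov["pop_density"]
                   + rng.normal(0, 5, n), 5, 95)
    san1 = np.clip(san0 + tr["sanitation"] + effect_for("sanitation")
                   + noise("sanitation"), 1, 99)
    lit_heads0 = rng.binomial(n_households, lit0 / 100.0)
    lit_heads1 = rng.binomial(n_households, lit1 / 100.0)
    san_wo0 = rng.binomial(n_households, san0 / 100.0)
    san_wo1 = rng.binomial(n_households, san1 / 100.0)

    tract_id = np.array([f"T{i:05d}" for i in range(n)])
    data = {
        "tract_id": tract_id,
        "state": state,
        "municipality": municipality,
        "area_km2": area,
        "cx": cx,
        "cy": cy,
        **cov,
        "settled_fraction": settled,
        "pasture_fraction": pasture,
        "landuse_class": landuse,
        **{f"holdings_{c}": holdings[:, k] for k, c in enumerate(HOLDING_CLASSES)},
        "mine_baseline": mine_baseline,
        "mine_post": mine_post,
        "overlap_spa": overlap["SPA"],
        "overlap_supa": overlap["SUPA"],
        "overlap_it": overlap["IT"],
        "gazette_year": gazette,
        "n_households": n_households,
        "forest_2000_km2": forest0_km2,
        "forest_2010_km2": forest1_km2,
        "literate_heads_2000": lit_heads0,
        "literate_heads_2010": lit_heads1,
        "sanitation_without_2000": san_wo0,
        "sanitation_without_2010": san_wo1,
    }
    for j in range(len(edges)):
        data[f"income_bin_2000_{j}"] = bins0[:, j]
        data[f"income_bin_2010_{j}"] = bins1[:, j]
    tracts = pd.DataFrame(data)

    # rook adjacency on the lattice; shared border = side of the smaller cell
    e_from, e_to, e_len = [], [], []
    for i in range(n):
        r, c = row[i], col[i]
        for rr, cc in ((r, c + 1), (r + 1, c)):
            if rr < nr and cc < nc:
                j = rr * nc + cc
                L = float(min(side[i], side[j]))
                e_from += [tract_id[i], tract_id[j]]
                e_to += [tract_id[j], tract_id[i]]
                e_len += [L, L]
    adjacency = pd.DataFrame(
        {"tract_id": e_from, "neighbor_id": e_to, "border_km": e_len}
    )

    truth = SimulationTruth(
        propensity=prop_df.assign(tract_id=tract_id).set_index("tract_id"),
        arrangement=pd.Series(arrangement, index=tract_id, name="arrangement"),
        true_effects={(a, o): eff[a][o] for a in ARRANGEMENTS for o in OUTCOMES},
        seed=config.seed,
    )
    return tracts, adjacency, truth


def write_landscape(outdir, tracts, adjacency, truth) -> None:
    """Write the canonical tract table, adjacency and a truth sidecar."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tracts.to_csv(out / "tracts.csv", index=False)
    adjacency.to_csv(out / "adjacency.csv", index=False)
    (out / "truth.json").write_text(truth.to_json())
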