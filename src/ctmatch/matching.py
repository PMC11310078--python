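"""Propensity-score full matching with exact strata and balance pruning.

Full matching partitions the units of each exact stratum (state x
baseline-mining status) into subclasses, each containing either one
treated unit and one or more controls, or one control and one or more
treated units, minimizing the total within-subclass distance between
treated and control propensity scores. Distances are absolute
differences of the *linear predictor* (logit of the propensity score),
the usual convention.

The optimum is found exactly as a minimum-cost flow on the bipartite
treated-control graph: every treated and every control node carries a
unit lower bound on its degree, treated->control arcs cost the pair
distance, and subclass-size bounds cap node degrees. The flow LP has a
totally unimodular constraint matrix, so solving it with a simplex
method (HiGHS) yields an integral vertex — the exact optimum. Because
arc costs are nonnegative, an optimal solution is a forest of stars
(any edge both of whose endpoints are otherwise covered could be
removed without increasing cost); a cleanup pass enforces the star
structure where zero-cost ties leave slack.

Weights implement the ATT estimand: treated weight 1; each control in a
subclass with t treated and c controls gets t/c, so control weights sum
to the treated count within every stratum.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, sparse

logger = logging.getLogger(__name__)

__all__ = [
    "PropensityModel",
    "MatchedSet",
    "MatchingError",
    "fit_propensity",
    "full_match",
    "standardized_mean_difference",
    "balance_report",
    "prune_covariates",
]

_SPARSE_EDGE_LIMIT = 20_000  # above this many pair distances, sparsify
_SPARSE_K = 30  # nearest controls kept per treated when sparsifying


class MatchingError(RuntimeError):
    pass


@dataclass
class PropensityModel:
    included_covariates: list
    coefficients: pd.Series  # on the standardized-covariate scale
    scores: pd.Series  # P(treated | X), indexed by tract_id
    linear_predictor: pd.Series
    dropped_missing: list = field(default_factory=list)


@dataclass
class MatchedSet:
    subclasses: list  # list of (treated_ids, control_ids)
    weights: pd.Series  # tract_id -> ATT weight
    estimand: str = "ATT"
    exact_strata: tuple = ()
    total_distance: float = 0.0
    dropped: list = field(default_factory=list)  # (tract_id, reason)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (ts, cs) in enumerate(self.subclasses):
            for t in ts:
                rows.append((t, k, self.weights[t]))
            for c in cs:
                rows.append((c, k, self.weights[c]))
        return pd.DataFrame(rows, columns=["tract_id", "subclass", "weight"])


def fit_propensity(
    data: pd.DataFrame,
    covariates,
    treated_col: str = "treated",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> PropensityModel:
    """Logistic regression of treatment on (internally standardized)
    covariates, fitted by iteratively reweighted least squares.

    Rows with missing covariate values are excluded listwise and logged.
    Perfect separation and non-convergence raise :class:`MatchingError`.
    """
    covariates = list(covariates)
    sub = data[["tract_id", treated_col] + covariates].copy()
    missing = sub[covariates].isna().any(axis=1)
    dropped = list(sub.loc[missing, "tract_id"])
    if dropped:
        logger.info("listwise exclusion of %d tract(s) with missing covariates",
                    len(dropped))
    sub = sub.loc[~missing]
    y = sub[treated_col].astype(float).to_numpy()
    X = sub[covariates].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    Zc = sm.add_constant(Z, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.GLM(y, Zc, family=sm.families.Binomial()).fit(
                maxiter=maxiter, tol=tol
            )
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
            raise MatchingError(
                "perfect separation in the propensity model; consider a caliper "
                "or trimming the cohort"
            ) from err
    if not res.converged:
        raise MatchingError(f"propensity IRLS did not converge in {maxiter} iters")
    lp = pd.Series(Zc @ res.params, index=sub["tract_id"], name="lp")
    scores = pd.Series(res.fittedvalues, index=sub["tract_id"], name="pscore")
    coef = pd.Series(res.params, index=["intercept"] + covariates)
    return PropensityModel(covariates, coef, scores, lp, dropped)


def _solve_stratum(lp_t, lp_c, max_ratio):
    """Optimal full match of one stratum; returns list of (i, j) treated ->
    control index pairs (each pair one edge of the star forest)."""
    nt, nc = len(lp_t), len(lp_c)
    cap_t = max(max_ratio, int(np.ceil(nc / nt)))  # controls per treated
    cap_c = max(max_ratio, int(np.ceil(nt / nc)))  # treated per control
    if cap_t > max_ratio or cap_c > max_ratio:
        logger.warning(
            "subclass ratio bound %d infeasible for %d treated / %d controls; "
            "relaxed to %d", max_ratio, nt, nc, max(cap_t, cap_c),
        )

    dense = nt * nc <= _SPARSE_EDGE_LIMIT
    if dense:
        edges = [(i, j) for i in range(nt) for j in range(nc)]
    else:
        # k nearest by score for match quality, plus a rank-aligned
        # backbone that keeps the degree-capped cover feasible (block r of
        # the sorted controls is reachable from the rank-matched treated)
        edges = set()
        order_c = np.argsort(lp_c, kind="stable")
        sorted_c = lp_c[order_c]
        for i in range(nt):
            pos = np.searchsorted(sorted_c, lp_t[i])
            lo, hi = max(0, pos - _SPARSE_K), min(nc, pos + _SPARSE_K)
            edges.update((i, int(order_c[j])) for j in range(lo, hi))
        order_t = np.argsort(lp_t, kind="stable")
        if nc >= nt:
            block = (np.arange(nc) * nt) // nc
            edges.update(
                (int(order_t[block[r]]), int(order_c[r])) for r in range(nc)
            )
        else:
            block = (np.arange(nt) * nc) // nt
            edges.update(
                (int(order_t[r]), int(order_c[block[r]])) for r in range(nt)
            )
        edges = sorted(edges)

    def attempt(edge_list):
        ti = np.fromiter((e[0] for e in edge_list), dtype=np.int64)
        cj = np.fromiter((e[1] for e in edge_list), dtype=np.int64)
        cost = np.abs(lp_t[ti] - lp_c[cj])
        m = len(edge_list)
        rows = np.concatenate([ti, nt + cj])
        cols = np.concatenate([np.arange(m), np.arange(m)])
        A = sparse.csr_matrix(
            (np.ones(2 * m), (rows, cols)), shape=(nt + nc, m)
        )
        # 1 <= degree(t_i) <= cap_t, 1 <= degree(c_j) <= cap_c
        A_ub = sparse.vstack([A, -A])
        b_ub = np.concatenate([
            np.full(nt, cap_t), np.full(nc, cap_c),
            -np.ones(nt + nc),
        ])
        res = optimize.linprog(
            cost, A_ub=A_ub, b_ub=b_ub, bounds=(0, 1), method="highs-ds"
        )
        if res.status != 0:
            return None
        x = res.x
        if np.max(np.abs(x - np.round(x))) > 1e-6:
            raise MatchingError("flow LP returned a non-integral vertex")
        chosen = np.round(x).astype(bool)
        return [(int(i), int(j)) for i, j in zip(ti[chosen], cj[chosen])]

    pairs = attempt(edges)
    if pairs is None:
        if dense:
            raise MatchingError("full match infeasible even with relaxed bounds")
        pairs = attempt([(i, j) for i in range(nt) for j in range(nc)])
        if pairs is None:
            raise MatchingError("full match infeasible even with relaxed bounds")

    # star cleanup: drop edges whose two endpoints both stay covered
    deg_t = np.bincount([i for i, _ in pairs], minlength=nt)
    deg_c = np.bincount([j for _, j in pairs], minlength=nc)
    kept = []
    for i, j in sorted(pairs, key=lambda e: -abs(lp_t[e[0]] - lp_c[e[1]])):
        if deg_t[i] > 1 and deg_c[j] > 1:
            deg_t[i] -= 1
            deg_c[j] -= 1
        else:
            kept.append((i, j))
    return kept


def full_match(
    data: pd.DataFrame,
    model: PropensityModel,
    exact_keys=("state", "mine_baseline"),
    caliper: float | None = None,
    max_ratio: int = 10,
    treated_col: str = "treated",
) -> MatchedSet:
    """Optimal full matching within exact strata.

    ``caliper``, when given, is a maximum treated-control distance in SD
    units of the propensity linear predictor; treated units with no
    control in range are discarded and logged (as are controls no
    treated unit can reach, which full matching could not otherwise
    place). Strata lacking either side are dropped with a log entry.
    ``max_ratio`` bounds both controls-per-treated and
    treated-per-control subclass sizes; infeasible bounds are relaxed
    with a warning rather than dropping units.
    """
    exact_keys = tuple(exact_keys)
    d = data.set_index("tract_id")
    d = d.loc[d.index.intersection(model.linear_predictor.index)]
    lp = model.linear_predictor.loc[d.index]
    lp_sd = float(lp.std(ddof=1))
    max_dist = caliper * lp_sd if caliper is not None else np.inf

    subclasses: list = []
    weights: dict = {}
    dropped: list = []
    total = 0.0

    strata = d.groupby(list(exact_keys), sort=True, observed=True) if exact_keys \
        else [((), d)]
    for key, grp in strata:
        t_ids = grp.index[grp[treated_col].astype(bool)].to_numpy()
        c_ids = grp.index[~grp[treated_col].astype(bool)].to_numpy()
        if len(t_ids) == 0 or len(c_ids) == 0:
            side = "control" if len(c_ids) == 0 else "treated"
            logger.info("stratum %r lacks %s units; dropped", key, side)
            dropped += [(i, f"stratum lacks {side}s") for i in grp.index]
            continue
        lp_t, lp_c = lp[t_ids].to_numpy(), lp[c_ids].to_numpy()
        if np.isfinite(max_dist):
            dist = np.abs(lp_t[:, None] - lp_c[None, :])
            ok_t = (dist <= max_dist).any(axis=1)
            ok_c = (dist <= max_dist).any(axis=0)
            dropped += [(i, "caliper: no control in range") for i in t_ids[~ok_t]]
            dropped += [(j, "caliper: no treated in range") for j in c_ids[~ok_c]]
            t_ids, c_ids = t_ids[ok_t], c_ids[ok_c]
            lp_t, lp_c = lp_t[ok_t], lp_c[ok_c]
            if len(t_ids) == 0 or len(c_ids) == 0:
                continue
        pairs = _solve_stratum(lp_t, lp_c, max_ratio)

        # connected components of the star forest = subclasses
        comp: dict = {}
        parent = {}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, j in pairs:
            for node in (("t", i), ("c", j)):
                parent.setdefault(node, node)
            ri, rj = find(("t", i)), find(("c", j))
            if ri != rj:
                parent[ri] = rj
        for i, j in pairs:
            comp.setdefault(find(("t", i)), []).append((i, j))
            total += abs(lp_t[i] - lp_c[j])
        for members in comp.values():
            ts = sorted({i for i, _ in members})
            cs = sorted({j for _, j in members})
            t_names = [t_ids[i] for i in ts]
            c_names = [c_ids[j] for j in cs]
            subclasses.append((t_names, c_names))
            for tname in t_names:
                weights[tname] = 1.0
            w = len(t_names) / len(c_names)
            for cname in c_names:
                weights[cname] = w

    if not subclasses:
        raise MatchingError("no matchable units remain (caliper or strata too strict)")
    return MatchedSet(
        subclasses=subclasses,
        weights=pd.Series(weights, name="weight"),
        exact_strata=exact_keys,
        total_distance=float(total),
        dropped=dropped,
    )


def standardized_mean_difference(
    values,
    treated_flag,
    weights=None,
    denom_sd: float | None = None,
) -> float:
    """(weighted treated mean - weighted control mean) / SD.

    The denominator defaults to the *unweighted, pre-match* treated-group
    SD, and callers comparing before/after balance should pass the same
    ``denom_sd`` to both so the change is attributable to the weights
    alone (ATT convention). A degenerate (zero-SD) denominator yields
    NaN.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(treated_flag, dtype=bool)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if t.sum() == 0 or (~t).sum() == 0:
        raise ValueError("both groups must be nonempty")
    if denom_sd is None:
        denom_sd = float(np.std(v[t], ddof=1)) if t.sum() > 1 else 0.0
    mt = np.average(v[t], weights=w[t])
    mc = np.average(v[~t], weights=w[~t])
    if denom_sd == 0 or not np.isfinite(denom_sd):
        return np.nan
    return float((mt - mc) / denom_sd)


def balance_report(
    data: pd.DataFrame,
    covariates,
    matched: MatchedSet,
    treated_col: str = "treated",
    threshold: float = 0.25,
) -> pd.DataFrame:
    """Per-covariate SMD before and after matching (same denominator)."""
    d = data.set_index("tract_id")
    rows = []
    m = d.loc[matched.weights.index]
    for c in covariates:
        v_all = d[c].to_numpy(dtype=float)
        t_all = d[treated_col].to_numpy(dtype=bool)
        sd = float(np.std(v_all[t_all], ddof=1))
        before = standardized_mean_difference(v_all, t_all, denom_sd=sd)
        after = standardized_mean_difference(
            m[c], m[treated_col], matched.weights.loc[m.index], denom_sd=sd
        )
        rows.append((c, before, after, bool(abs(after) > threshold)))
    return pd.DataFrame(rows, columns=["covariate", "smd_before", "smd_after",
                                       "unbalanced"]).set_index("covariate")


def love_plot(report: pd.DataFrame, path, threshold: float = 0.25) -> None:
    """Dot plot of |SMD| before/after matching, one row per covariate."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = report.iloc[::-1]
    y = np.arange(len(rep))
    fig, ax = plt.subplots(figsize=(6, 0.5 + 0.35 * len(rep)))
    ax.scatter(rep["smd_before"].abs(), y, marker="o", facecolors="none",
               edgecolors="tab:red", label="before matching")
    ax.scatter(rep["smd_after"].abs(), y, marker="o", color="tab:blue",
               label="after matching")
    ax.axvline(threshold, color="grey", ls="--", lw=1)
    ax.set_yticks(y, rep.index)
    ax.set_xlabel("|standardized mean difference|")
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _max_abs_smd(report: pd.DataFrame) -> float:
    vals = report["smd_after"].abs()
    return float(vals.max()) if len(vals) else 0.0


def prune_covariates(
    data: pd.DataFrame,
    covariates,
    exact_keys=("state", "mine_baseline"),
    smd_threshold: float = 0.25,
    caliper: float | None = None,
    max_ratio: int = 10,
    treated_col: str = "treated",
):
    """Greedy covariate pruning of the propensity model to optimize balance.

    While any covariate's post-match SMD exceeds the threshold and more
    than one covariate remains in the propensity model: tentatively drop
    each remaining covariate, rematch, and keep the drop that minimizes
    the maximum post-match |SMD| over the FULL covariate set; stop when
    balanced or when no drop improves. The outcome regression always
    receives the full covariate set regardless of what was pruned here.

    Returns ``(model, matched, report, pruning_log)``; if balance is
    never reached the best-found match is returned with its
    ``unbalanced`` flags set.
    """
    covariates = list(covariates)
    if len(covariates) < 2:
        raise ValueError("pruning needs at least two covariates")

    def evaluate(included):
        model = fit_propensity(data, included, treated_col)
        matched = full_match(data, model, exact_keys, caliper, max_ratio,
                             treated_col)
        report = balance_report(data, covariates, matched, treated_col,
                                smd_threshold)
        return model, matched, report

    included = list(covariates)
    model, matched, report = evaluate(included)
    best = _max_abs_smd(report)
    log: list = []
    while best > smd_threshold and len(included) > 1:
        trial_best = None
        for drop in included:
            remaining = [c for c in included if c != drop]
            try:
                cand = evaluate(remaining)
            except MatchingError:
                continue
            score = _max_abs_smd(cand[2])
            if trial_best is None or score < trial_best[0]:
                trial_best = (score, drop, cand)
        if trial_best is None or trial_best[0] >= best:
            break
        best, dropped_cov, (model, matched, report) = (
            trial_best[0], trial_best[1], trial_best[2])
        included = [c for c in included if c != dropped_cov]
        log.append({"dropped": dropped_cov, "max_abs_smd": best})
    if best > smd_threshold:
        logger.warning("balance not reached: max |SMD| = %.3f", best)
    return model, matched, report, log
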