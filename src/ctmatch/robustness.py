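"""Robustness computations for the matched evaluation.

Four checks on the headline estimates:

* **Oster bounds** — how much a treatment coefficient could move if
  selection on unobservables were proportional to selection on
  observables, using the movement in coefficient and R^2 between the
  uncontrolled and controlled regressions.
* **Moran's I** — residual spatial autocorrelation, with
  row-standardized inverse-distance weights and a permutation null.
* **Two-period fixed-effects panel** — the within (tract-demeaned)
  estimator on stacked baseline/endline data, which for two periods
  must coincide with the first-difference estimator.
* **Weighted one-way ANOVA** — post-matching equality of group means
  (e.g. settled land across landholding-size classes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OsterInputs",
    "oster_bound",
    "morans_i",
    "inverse_distance_weights",
    "panel_fe",
    "group_means_anova",
]


@dataclass(frozen=True)
class OsterInputs:
    beta_short: float  # coefficient with no controls
    r_short: float     # its R^2
    beta_long: float   # coefficient with controls
    r_long: float      # its R^2
    r_max: float | None = None  # defaults to min(1.3 * r_long, 1)
    delta: float = 1.0  # proportionality of selection

    def __post_init__(self) -> None:
        rmax = self.resolved_r_max
        if not (0.0 <= self.r_short <= self.r_long <= rmax <= 1.0):
            raise ValueError("need 0 <= r_short <= r_long <= r_max <= 1")

    @property
    def resolved_r_max(self) -> float:
        if self.r_max is not None:
            return self.r_max
        return min(1.3 * self.r_long, 1.0)


def oster_bound(inputs: OsterInputs) -> dict:
    """Bias-adjusted coefficient under proportional selection.

        beta* = beta_long - delta * (beta_short - beta_long)
                          * (r_max - r_long) / (r_long - r_short)

    Also reports ``delta_for_zero``, the degree of proportional
    selection that would drive the adjusted coefficient to exactly 0.
    A controlled regression that adds no explanatory power
    (r_long == r_short) leaves the adjustment undefined.
    """
    rmax = inputs.resolved_r_max
    dr = inputs.r_long - inputs.r_short
    if dr <= 0:
        raise ValueError("r_long must exceed r_short for the bound to exist")
    movement = (inputs.beta_short - inputs.beta_long) * (rmax - inputs.r_long) / dr
    beta_star = inputs.beta_long - inputs.delta * movement
    delta_zero = inputs.beta_long / movement if movement != 0 else np.inf
    return {"beta_star": float(beta_star), "delta_for_zero": float(delta_zero)}


def inverse_distance_weights(
    coords: np.ndarray,
    cutoff_quantile: float = 0.10,
) -> np.ndarray:
    """Row-standardized inverse-distance weight matrix.

    Pairs farther apart than the ``cutoff_quantile`` of the off-diagonal
    distance distribution get weight 0; rows with no neighbor inside the
    cutoff (islands) come back all-zero and are the caller's to drop.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    off = d[~np.eye(n, dtype=bool)]
    cutoff = np.quantile(off, cutoff_quantile)
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    w[~np.isfinite(w)] = 0.0
    w[d > cutoff] = 0.0
    np.fill_diagonal(w, 0.0)
    rows = w.sum(axis=1)
    nz = rows > 0
    w[nz] = w[nz] / rows[nz, None]
    return w


def morans_i(
    residuals,
    coords=None,
    weights: np.ndarray | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> dict:
    """Moran's I of regression residuals with a permutation p-value.

        I = (n / S0) * (e'We) / (e'e)

    ``weights`` defaults to row-standardized inverse-distance weights
    built from ``coords``. Islands (all-zero weight rows) are dropped
    with a note; the expectation under the null is -1/(n-1).
    """
    e = np.asarray(residuals, dtype=float)
    if weights is None:
        if coords is None:
            raise ValueError("need coords or an explicit weight matrix")
        weights = inverse_distance_weights(np.asarray(coords))
    W = np.asarray(weights, dtype=float)
    live = W.sum(axis=1) > 0
    n_islands = int((~live).sum())
    if n_islands:
        W = W[np.ix_(live, live)]
        e = e[live]
    n = len(e)
    if n < 3:
        raise ValueError("need at least 3 connected units")
    if np.allclose(e, e[0]):
        raise ValueError("Moran's I undefined for constant residuals")
    ec = e - e.mean()
    s0 = W.sum()

    def stat(v):
        return (n / s0) * (v @ W @ v) / (v @ v)

    i_obs = float(stat(ec))
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for b in range(n_permutations):
        perms[b] = stat(rng.permutation(ec))
    if alternative == "greater":
        extreme = perms >= i_obs
    elif alternative == "less":
        extreme = perms <= i_obs
    else:
        extreme = np.abs(perms - expected) >= abs(i_obs - expected)
    p = float((1 + extreme.sum()) / (1 + n_permutations))
    return {"I": i_obs, "expected": expected, "p": p, "n": n,
            "n_islands_dropped": n_islands}


def panel_fe(
    y_baseline,
    y_endline,
    treated,
    weights=None,
) -> dict:
    """Two-period fixed-effects (within) estimator of the Tr x post term.

    Stacks baseline and endline observations, demeans within tract, and
    regresses on the period effect and the treatment-by-post
    interaction. With two periods this is algebraically the
    first-difference estimator: a weighted regression of (Y_end -
    Y_base) on Tr. Tracts missing either period are dropped and
    counted.
    """
    y0 = np.asarray(y_baseline, dtype=float)
    y1 = np.asarray(y_endline, dtype=float)
    tr = np.asarray(treated, dtype=float)
    w = np.ones_like(y0) if weights is None else np.asarray(weights, dtype=float)
    ok = np.isfinite(y0) & np.isfinite(y1)
    n_dropped = int((~ok).sum())
    y0, y1, tr, w = y0[ok], y1[ok], tr[ok], w[ok]

    # within transformation on the stacked 2-period panel
    yd = np.concatenate([y0, y1])
    post = np.concatenate([np.zeros_like(y0), np.ones_like(y1)])
    trpost = np.concatenate([np.zeros_like(y0), tr])
    ww = np.concatenate([w, w])
    unit = np.concatenate([np.arange(len(y0)), np.arange(len(y0))])
    for v in (yd, post, trpost):
        means = np.bincount(unit, v) / 2.0
        v -= means[unit]
    X = np.column_stack([post, trpost])
    sw = np.sqrt(ww)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], yd * sw, rcond=None)
    resid = yd - X @ beta
    # dof: 2n obs - n unit effects - 2 slopes
    n = len(y0)
    dof = 2 * n - n - 2
    xtx_inv = np.linalg.inv((X * ww[:, None]).T @ X)
    if dof > 0:
        sigma2 = float(np.sum(ww * resid**2) / dof)
        se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    else:
        se = np.nan
    return {"beta_fe": float(beta[1]), "se": se, "n_dropped": n_dropped, "n": n}


def group_means_anova(values, groups, weights=None) -> dict:
    """Weighted one-way ANOVA of group-mean equality.

    Groups with fewer than 2 units are excluded and reported. The F
    statistic uses weighted between/within sums of squares with
    unit-count degrees of freedom, reducing to the classical one-way
    ANOVA when all weights are equal.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    labels, counts = np.unique(g, return_counts=True)
    excluded = [str(lab) for lab, c in zip(labels, counts) if c < 2]
    keep = ~np.isin(g, excluded)
    v, g, w = v[keep], g[keep], w[keep]
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least two groups with >= 2 units")
    grand = np.average(v, weights=w)
    ssb = ssw = 0.0
    means = {}
    for lab in labels:
        m = g == lab
        mu = np.average(v[m], weights=w[m])
        means[str(lab)] = float(mu)
        ssb += w[m].sum() * (mu - grand) ** 2
        ssw += float(np.sum(w[m] * (v[m] - mu) ** 2))
    df_b = len(labels) - 1
    df_w = len(v) - len(labels)
    # normalize weights so the error df carries the unit count, not the
    # weight total
    scale = len(v) / w.sum()
    f = (ssb * scale / df_b) / (ssw * scale / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return {"F": float(f), "p": p, "group_means": means,
            "excluded_groups": excluded, "df": (df_b, df_w)}
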