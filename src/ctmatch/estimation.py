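"""Post-matching estimation: weighted OLS with robust inference.

The outcome model regresses the *endline* outcome on the treatment
indicator and the full covariate set (including the baseline outcome),
weighting observations by the matching weights:

    Y_i = b0 + b1 Tr_i + b2' X_i + e_i

Endline-on-baseline adjustment is used rather than a change score, to
avoid the spurious correlation induced by having the baseline on both
sides. Inference uses HC1 heteroscedasticity-robust standard errors
with the matching weights carried into the meat of the sandwich;
Breusch-Pagan diagnostics motivate that choice per model. Treatment
effects are also expressed as percentages of the counterfactual control
level for the treated, and p-values are adjusted for multiplicity by
Benjamini-Hochberg within declared families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WeightedOLSResult",
    "EffectEstimate",
    "weighted_ols",
    "hc1_se",
    "breusch_pagan",
    "percent_effect",
    "fdr_adjust",
    "estimate_effect",
]


@dataclass
class WeightedOLSResult:
    params: pd.Series
    residuals: np.ndarray  # raw (unweighted) residuals
    fitted: np.ndarray
    X: np.ndarray
    y: np.ndarray
    w: np.ndarray
    xtwx_inv: np.ndarray
    names: list
    dropped_collinear: list


@dataclass
class EffectEstimate:
    arrangement: str
    control_type: str
    outcome: str
    beta1: float
    se_hc1: float
    t: float
    p: float
    percent_effect: float
    counterfactual_mean: float
    n_treated: int
    n_control: int
    bp_stat: float
    bp_p: float
    p_fdr: float = np.nan


def weighted_ols(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                 names=None) -> WeightedOLSResult:
    """Minimize sum w_i (y_i - x_i'b)^2.

    Collinear columns are dropped (and logged on the result) so the
    design is full rank; negative weights raise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weights")
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]

    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    # rank-revealing QR via pivoted scipy? numpy lstsq handles rank but we
    # need to know which columns to drop; use incremental rank check.
    keep, dropped = [], []
    for j in range(X.shape[1]):
        trial = Xw[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            dropped.append(names[j])
    Xk = X[:, keep]
    Xwk = Xw[:, keep]
    xtwx = Xwk.T @ Xwk
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ (Xwk.T @ (y * sw))
    fitted = Xk @ beta
    resid = y - fitted
    return WeightedOLSResult(
        params=pd.Series(beta, index=[names[j] for j in keep]),
        residuals=resid,
        fitted=fitted,
        X=Xk,
        y=y,
        w=w,
        xtwx_inv=xtwx_inv,
        names=[names[j] for j in keep],
        dropped_collinear=dropped,
    )


def hc1_se(res: WeightedOLSResult) -> pd.Series:
    """HC1 robust standard errors, with the matching weights inside the meat:

        Var = n/(n-k) (X'WX)^-1 X'W diag(e^2) WX (X'WX)^-1
    """
    n, k = res.X.shape
    if n <= k:
        raise ValueError("need more observations than parameters")
    we = res.w * res.residuals
    meat = (res.X * (we**2)[:, None]).T @ res.X
    cov = res.xtwx_inv @ meat @ res.xtwx_inv * (n / (n - k))
    return pd.Series(np.sqrt(np.diag(cov)), index=res.names)


def breusch_pagan(res: WeightedOLSResult) -> tuple[float, float]:
    """Studentized Breusch-Pagan LM test on the whitened residuals.

    Auxiliary regression of squared (weight-scaled) residuals on the
    design; LM = n R^2, p from chi2 with (k-1) df. Constant residuals
    are degenerate and return p = 1.
    """
    n, k = res.X.shape
    if k < 2:
        raise ValueError("Breusch-Pagan needs at least one non-constant regressor")
    u2 = res.w * res.residuals**2
    if np.allclose(u2, u2[0]):
        return 0.0, 1.0
    X = res.X
    beta, *_ = np.linalg.lstsq(X, u2, rcond=None)
    pred = X @ beta
    ss_res = np.sum((u2 - pred) ** 2)
    ss_tot = np.sum((u2 - u2.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot
    lm = n * r2
    p = float(stats.chi2.sf(lm, df=k - 1))
    return float(lm), p


def percent_effect(
    beta1: float,
    counterfactual_mean: float,
    tol: float = 1e-8,
) -> float:
    """Treatment effect as % of the counterfactual control level.

    ``counterfactual_mean`` is the (matching-weighted) mean fitted
    outcome for treated units with the treatment indicator set to 0.
    Near-zero denominators are flagged by returning NaN.
    """
    if abs(counterfactual_mean) < tol:
        return np.nan
    return float(100.0 * beta1 / abs(counterfactual_mean))


def fdr_adjust(pvalues: pd.Series, families: pd.Series | None = None) -> pd.Series:
    """Benjamini-Hochberg step-up, applied within each declared family.

    ``families`` assigns each p-value a family label (default: one
    family). Adjusted values are monotone in rank and capped at 1.
    """
    p = pd.Series(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.Series(np.nan, index=p.index)
    fam = pd.Series("all", index=p.index) if families is None \
        else pd.Series(families).reindex(p.index)
    for _, idx in fam.groupby(fam).groups.items():
        mask = p.loc[idx].notna()
        if mask.sum() == 0:
            continue
        adj = multipletests(p.loc[idx][mask], method="fdr_bh")[1]
        out.loc[p.loc[idx][mask].index] = adj
    return out


def estimate_effect(
    data: pd.DataFrame,
    outcome_endline: str,
    outcome_baseline: str,
    covariates,
    weights: pd.Series,
    arrangement: str = "",
    control_type: str = "",
    outcome: str = "",
    treated_col: str = "treated",
    loss_baseline: str | None = None,
) -> EffectEstimate:
    """One matched-weight regression with robust inference.

    ``data`` holds the matched units only; ``weights`` are the ATT
    matching weights indexed by tract_id.

    ``loss_baseline`` switches the percentage effect to a loss scale:
    when the response is endline forest cover % and ``loss_baseline``
    names the baseline forest cover column, the effect on the
    *deforested share* is -beta1 and its denominator is the
    counterfactual deforested share of the treated (baseline minus
    counterfactual endline), so "avoided deforestation" comes out as a
    negative percentage.
    """
    d = data.set_index("tract_id").loc[weights.index]
    cols = [c for c in dict.fromkeys([outcome_baseline, *covariates])
            if c != outcome_endline]
    X = np.column_stack([
        np.ones(len(d)),
        d[treated_col].astype(float).to_numpy(),
        d[cols].to_numpy(dtype=float),
    ])
    names = ["intercept", "treated"] + cols
    y = d[outcome_endline].to_numpy(dtype=float)
    w = weights.loc[d.index].to_numpy(dtype=float)

    res = weighted_ols(X, y, w, names)
    se = hc1_se(res)
    beta1 = float(res.params["treated"])
    se1 = float(se["treated"])
    n, k = res.X.shape
    tval = beta1 / se1 if se1 > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(tval), df=n - k))
    bp_stat, bp_p = breusch_pagan(res)

    tmask = d[treated_col].astype(bool).to_numpy()
    j = res.names.index("treated")
    cf_fitted = res.fitted - res.X[:, j] * beta1  # fitted with Tr := 0
    if loss_baseline is not None:
        base = d[loss_baseline].to_numpy(dtype=float)
        cf_base = np.average(base[tmask] - cf_fitted[tmask], weights=w[tmask])
        pct = percent_effect(-beta1, cf_base)
    else:
        cf_base = np.average(cf_fitted[tmask], weights=w[tmask])
        pct = percent_effect(beta1, cf_base)

    return EffectEstimate(
        arrangement=arrangement,
        control_type=control_type,
        outcome=outcome,
        beta1=beta1,
        se_hc1=se1,
        t=float(tval),
        p=p,
        percent_effect=pct,
        counterfactual_mean=float(cf_base),
        n_treated=int(tmask.sum()),
        n_control=int((~tmask).sum()),
        bp_stat=bp_stat,
        bp_p=bp_p,
    )
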