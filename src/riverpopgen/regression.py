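"""Linear-model layer: genetic responses vs network connectivity metrics,
and the isolation-by-distance power-term scan.

Models are ordinary least squares on a design built from named terms.  A
term is a tuple of predictor names whose columns are multiplied (an
interaction); the empty tuple is the intercept.  The categorical ``species``
predictor is treatment-coded (two levels -> one 0/1 column).

Information criteria use the full Gaussian log-likelihood convention

    AIC  = n ln(2 pi RSS / n) + n + 2 (k + 1)
    AICc = AIC + 2 (k + 1)(k + 2) / (n - k - 2)

with k the number of estimated mean coefficients (the +1 counts the residual
variance).  Only differences between models on the same data matter, so the
constant convention is pinned once and used everywhere.

Customary transforms for river-network predictors: natural log for total
catchment area and log(x + 1) for directed betweenness (leaves have
betweenness 0).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelFit",
    "LOG_TRANSFORMS",
    "build_design",
    "fit_lm",
    "kendall_screen",
    "backward_stepwise",
    "all_subsets",
    "vif",
    "power_scan",
]

Term = tuple  # tuple of predictor names; () is the intercept

LOG_TRANSFORMS = {
    "catchment_area": np.log,
    "betweenness_directed": np.log1p,
}


@dataclass
class ModelFit:
    """OLS fit summary for one response and one set of terms."""

    response: str
    terms: list
    coefficients: pd.Series
    rss: float
    n: int
    k: int  # estimated mean coefficients incl. intercept
    sigma2: float
    aic: float
    aicc: float
    r2: float
    r2_adj: float
    f_stat: float
    f_df: tuple
    vif: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __repr__(self) -> str:  # compact, lm-style
        terms = " + ".join(":".join(t) for t in self.terms if t) or "1"
        return (
            f"ModelFit({self.response} ~ {terms}; n={self.n}, k={self.k}, "
            f"R2_adj={self.r2_adj:.3f}, AIC={self.aic:.2f})"
        )


def _term_name(term: Term) -> str:
    return ":".join(term) if term else "(Intercept)"


def build_design(data: pd.DataFrame, terms: list, transforms: dict | None = None):
    """Design matrix for a list of terms over a predictor table.

    ``transforms`` maps predictor name -> callable applied columnwise before
    any products are formed.  Categorical (object/category) columns with two
    levels are treatment-coded against the alphabetically first level.
    """
    transforms = transforms or {}
    cols: dict[str, np.ndarray] = {}

    def column(name: str) -> np.ndarray:
        if name in cols:
            return cols[name]
        raw = data[name]
        if raw.dtype == object or isinstance(raw.dtype, pd.CategoricalDtype):
            levels = sorted(raw.unique())
            if len(levels) != 2:
                raise ValueError(
                    f"categorical predictor {name!r} must have 2 levels, "
                    f"got {levels}"
                )
            v = (raw == levels[1]).to_numpy(dtype=float)
        else:
            v = raw.to_numpy(dtype=float)
            if name in transforms:
                v = transforms[name](v)
        cols[name] = v
        return v

    X = np.empty((len(data), len(terms)))
    names = []
    for j, term in enumerate(terms):
        if not term:
            X[:, j] = 1.0
        else:
            X[:, j] = np.prod([column(name) for name in term], axis=0)
        names.append(_term_name(term))
    return X, names


def fit_lm(
    y,
    data: pd.DataFrame,
    terms: list | None = None,
    transforms: dict | None = None,
    response_name: str = "y",
    with_vif: bool = True,
) -> ModelFit:
    """Fit an OLS model of ``y`` on the given terms (default: intercept plus
    every column of ``data`` as a main effect)."""
    y = np.asarray(y, dtype=float)
    if terms is None:
        terms = [()] + [(c,) for c in data.columns]
    terms = [tuple(t) for t in terms]
    if () not in terms:
        terms = [()] + terms
    X, names = build_design(data, terms, transforms)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} rows cannot identify k={k} coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise ValueError(
            f"design is rank deficient ({rank} < {k}); collinear terms: {names}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k) if n > k else np.nan
    sigma2 = rss / n
    aic = n * math.log(2 * math.pi * max(sigma2, 1e-300)) + n + 2 * (k + 1)
    aicc = aic + (
        2 * (k + 1) * (k + 2) / (n - k - 2) if n - k - 2 > 0 else np.inf
    )
    if k > 1 and r2 < 1.0:
        f_stat = (r2 / (k - 1)) / ((1.0 - r2) / (n - k))
    else:
        f_stat = np.inf if r2 >= 1.0 and k > 1 else np.nan
    fit = ModelFit(
        response=response_name,
        terms=terms,
        coefficients=pd.Series(beta, index=names),
        rss=rss,
        n=n,
        k=k,
        sigma2=sigma2,
        aic=aic,
        aicc=aicc,
        r2=r2,
        r2_adj=r2_adj,
        f_stat=float(f_stat),
        f_df=(k - 1, n - k),
    )
    main = [t for t in terms if len(t) == 1]
    if with_vif and len(main) >= 2:
        Xm, mnames = build_design(data, main, transforms)
        fit.vif = vif(pd.DataFrame(Xm, columns=mnames))
    return fit


# ---------------------------------------------------------------------------
# Collinearity screens
# ---------------------------------------------------------------------------

def kendall_screen(
    predictors: pd.DataFrame, tau_threshold: float = 0.8
) -> tuple[list, list]:
    """Drop predictors until no pair has |Kendall tau| above the threshold.

    Among offending pairs the member with the larger mean |tau| against all
    remaining predictors is dropped first (the more redundant one).  Returns
    (retained, dropped-in-order).
    """
    cols = list(predictors.columns)
    for c in cols:
        if predictors[c].nunique() <= 1:
            raise ValueError(f"constant predictor {c!r}: Kendall tau undefined")
    dropped = []
    while True:
        taus = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
        for a, b in itertools.combinations(cols, 2):
            t = stats.kendalltau(predictors[a], predictors[b]).statistic
            taus.loc[a, b] = taus.loc[b, a] = t
        offending = [
            (a, b)
            for a, b in itertools.combinations(cols, 2)
            if abs(taus.loc[a, b]) > tau_threshold
        ]
        if not offending:
            return cols, dropped
        # mean |tau| vs all other retained predictors
        mean_abs = {
            c: np.mean([abs(taus.loc[c, o]) for o in cols if o != c]) for c in cols
        }
        candidates = {c for pair in offending for c in pair}
        victim = max(sorted(candidates), key=lambda c: mean_abs[c])
        cols.remove(victim)
        dropped.append(victim)
        if len(cols) < 2:
            return cols, dropped


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance-inflation factor 1/(1 - R^2_j) per predictor, from the OLS
    of column j on the remaining columns (with intercept)."""
    out = {}
    cols = list(X.columns)
    arr = X.to_numpy(dtype=float)
    for j, c in enumerate(cols):
        others = np.column_stack(
            [np.ones(len(X))] + [arr[:, i] for i in range(len(cols)) if i != j]
        )
        yj = arr[:, j]
        beta, _, _, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        rss = float(resid @ resid)
        tss = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def _removable(terms: list) -> list:
    """Terms droppable under marginality: not contained in a higher-order
    term that is still in the model (the intercept is never dropped)."""
    out = []
    for t in terms:
        if not t:
            continue
        if any(set(t) < set(u) for u in terms if u != t):
            continue
        out.append(t)
    return out


def backward_stepwise(
    y,
    data: pd.DataFrame,
    terms: list,
    transforms: dict | None = None,
    criterion: str = "aic",
    response_name: str = "y",
) -> ModelFit:
    """Backward elimination: repeatedly drop the single term whose removal
    most decreases the criterion, respecting marginality, until no drop
    improves it."""
    terms = [tuple(t) for t in terms]
    if () not in terms:
        terms = [()] + terms
    current = fit_lm(y, data, terms, transforms, response_name, with_vif=False)
    while True:
        best = None
        for t in _removable(current.terms):
            cand_terms = [u for u in current.terms if u != t]
            cand = fit_lm(
                y, data, cand_terms, transforms, response_name, with_vif=False
            )
            if best is None or getattr(cand, criterion) < getattr(best, criterion):
                best = cand
        if best is not None and getattr(best, criterion) < getattr(
            current, criterion
        ):
            current = best
        else:
            return current


def all_subsets(
    y,
    data: pd.DataFrame,
    predictors: list | None = None,
    transforms: dict | None = None,
    criterion: str = "aicc",
    response_name: str = "y",
) -> tuple[pd.DataFrame, ModelFit]:
    """Dredge-style exhaustive fit of every main-effects subset, ranked by
    the criterion (default AICc).  Returns (ranked table, best ModelFit)."""
    predictors = list(predictors or data.columns)
    if len(predictors) > 15:
        raise ValueError("more than 15 predictors: 2^p enumeration refused")
    rows = []
    best = None
    for r in range(len(predictors) + 1):
        for subset in itertools.combinations(predictors, r):
            terms = [()] + [(p,) for p in subset]
            fit = fit_lm(y, data, terms, transforms, response_name, with_vif=False)
            rows.append(
                {
                    "predictors": "+".join(subset) or "(Intercept)",
                    "k": fit.k,
                    "aic": fit.aic,
                    "aicc": fit.aicc,
                    "r2_adj": fit.r2_adj,
                }
            )
            if best is None or getattr(fit, criterion) < getattr(best, criterion):
                best = fit
    table = (
        pd.DataFrame(rows).sort_values(criterion).reset_index(drop=True)
    )
    table["delta"] = table[criterion] - table[criterion].min()
    return table, best


# ---------------------------------------------------------------------------
# Isolation-by-distance power scan
# ---------------------------------------------------------------------------

def power_scan(
    fst,
    distance,
    species=None,
    powers=None,
    zero_negative: bool = True,
) -> tuple[float, ModelFit, pd.DataFrame]:
    """Scan the distance exponent of the isolation-by-distance model.

    Fits F_ST ~ distance^p (x species, with interaction, when a two-level
    ``species`` factor is given) for each p on the grid (default 0 to 1 in
    steps of 0.01) and returns (best p by minimum AIC, its fit, the
    p-vs-AIC curve).  Negative F_ST estimates — small-sample artefacts — are
    set to zero before fitting (``zero_negative``).  At p = 0 the distance
    term is constant and is dropped from the design.
    """
    fst = np.asarray(fst, dtype=float)
    distance = np.asarray(distance, dtype=float)
    if fst.size == 0:
        raise ValueError("empty pair set")
    if fst.shape != distance.shape:
        raise ValueError("fst and distance must have equal length")
    if zero_negative:
        fst = np.where(fst < 0, 0.0, fst)
    if powers is None:
        powers = np.round(np.arange(0, 101) * 0.01, 2)
    have_species = species is not None
    records = []
    best_p, best_fit = None, None
    for p in powers:
        df = pd.DataFrame({"dist_p": distance**p})
        if have_species:
            df["species"] = np.asarray(species)
        if p == 0:
            terms = [()] + ([("species",)] if have_species else [])
        elif have_species:
            terms = [(), ("dist_p",), ("species",), ("dist_p", "species")]
        else:
            terms = [(), ("dist_p",)]
        fit = fit_lm(fst, df, terms, response_name="fst", with_vif=False)
        records.append({"power": float(p), "aic": fit.aic, "r2_adj": fit.r2_adj})
        if best_fit is None or fit.aic < best_fit.aic:
            best_p, best_fit = float(p), fit
    return best_p, best_fit, pd.DataFrame(records)
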