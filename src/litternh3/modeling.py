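"""Regression layers of the litter-ammonia analysis.

Three stages mirror the study's statistical workflow:

1. a fixed-effects two-way factorial ANOVA screening for a reuse-cycle ×
   air-temperature interaction (none is expected; the response surfaces are
   additive in cycle and temperature);
2. per-temperature univariate fits of each litter variable against the reuse
   cycle (linear or quadratic, the quadratic dropped when non-significant);
3. multiple polynomial models in T and C reduced by backward elimination at
   α = 0.05, with the intercept itself eligible for deletion — the published
   generation/emission models all end up intercept-free with terms
   {T, C, C²}.

Conventions: terms are tested by their partial t/F p-value; at each step the
single term with the largest p > α is removed (ties broken by deleting the
higher-degree term first).  Without an intercept, R² is computed against the
uncorrected total sum of squares.  SEE = √(SSE/(n − k)) with k the number of
estimated coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .terms import DEFAULT_CANDIDATE_TERMS, TERM_DEGREE, TERM_ORDER, design_matrix, evaluate_terms, sort_terms

# Relative SSE threshold below which a fit is treated as numerically perfect
# and p-values are replaced by exact-reproduction partial tests.
_ZERO_SSE_RTOL = 1e-12


@dataclass
class FittedModel:
    """A polynomial model in T and/or C after term selection.

    ``coefficients``, ``std_errors`` and ``p_values`` are keyed by retained
    term name ("1" denotes the intercept).
    """

    response_name: str
    candidate_terms: tuple
    retained_terms: tuple
    coefficients: dict
    std_errors: dict
    p_values: dict
    r2: float
    see: float
    n_obs: int
    alpha: float = 0.05
    warnings: list = field(default_factory=list)

    @property
    def has_intercept(self) -> bool:
        return "1" in self.retained_terms

    def predict(self, T, C) -> np.ndarray:
        """Evaluate the retained model on temperature/cycle arrays."""
        return evaluate_terms(self.coefficients, T, C)

    # --- serialization (JSON summary + CSV coefficient table) -------------
    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["candidate_terms"] = list(payload["candidate_terms"])
        payload["retained_terms"] = list(payload["retained_terms"])
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "FittedModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        payload["candidate_terms"] = tuple(payload["candidate_terms"])
        payload["retained_terms"] = tuple(payload["retained_terms"])
        return cls(**payload)

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.retained_terms),
                "coefficient": [self.coefficients[t] for t in self.retained_terms],
                "se": [self.std_errors[t] for t in self.retained_terms],
                "p": [self.p_values[t] for t in self.retained_terms],
            }
        )


@dataclass
class AnovaTable:
    """Two-way fixed-effects ANOVA summary: one row per factor plus residual."""

    table: pd.DataFrame  # index: cycle, temperature, interaction, residual

    def p_value(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])

    def __getitem__(self, factor: str) -> pd.Series:
        return self.table.loc[factor]


def anova_interaction(
    data: pd.DataFrame,
    response: str = "response",
    cycle: str = "cycle",
    temperature: str = "temperature",
) -> AnovaTable:
    """Screen for a cycle × temperature interaction on a factorial table.

    Fits the fixed-effects two-way ANOVA with interaction on a (near-)balanced
    design and returns sums of squares, degrees of freedom, F and p for the
    cycle, temperature and interaction effects.  At least two replicates per
    cell are required, otherwise the interaction is confounded with the
    residual.
    """
    counts = data.groupby([cycle, temperature]).size()
    if counts.min() < 2:
        raise ValueError(
            "interaction untestable: at least one design cell has a single "
            "replicate, leaving no residual degrees of freedom"
        )
    df = data.rename(columns={response: "_y", cycle: "_c", temperature: "_t"})
    fit = smf.ols("_y ~ C(_c) * C(_t)", data=df).fit()
    raw = anova_lm(fit, typ=2)
    mapping = {
        "C(_c)": "cycle",
        "C(_t)": "temperature",
        "C(_c):C(_t)": "interaction",
        "Residual": "residual",
    }
    table = raw.rename(index=mapping).rename(
        columns={"sum_sq": "ss", "PR(>F)": "p"}
    )[["ss", "df", "F", "p"]]
    return AnovaTable(table=table)


# --------------------------------------------------------------------------
# OLS helpers shared by the univariate and multiple fitters
# --------------------------------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray):
    """Fit OLS on an explicit design matrix; no implicit intercept."""
    return sm.OLS(y, X).fit()


def _sse(terms: Sequence[str], T, C, y: np.ndarray) -> float:
    if not terms:
        return float(y @ y)
    X = design_matrix(terms, T, C)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _highest_powers(terms: Sequence[str], test_intercept: bool) -> list:
    """Terms eligible for removal under the hierarchy rule: the intercept
    (when testable) and, per variable, only the highest remaining power."""
    eligible = []
    for t in terms:
        if t == "1":
            if test_intercept:
                eligible.append(t)
            continue
        base, deg = t[0], TERM_DEGREE[t]
        if not any(u != t and u[0] == base and TERM_DEGREE[u] > deg for u in terms):
            eligible.append(t)
    return eligible


def _selection_pvalues(
    terms: Sequence[str], removable: Sequence[str], T, C, y: np.ndarray
) -> dict:
    """Partial-test p-value of each removable term in the current model.

    In the regular case these are the usual OLS two-sided t p-values.  When
    the current model reproduces the data to numerical precision (SSE ≈ 0)
    the t statistics are 0/0 noise, so each term is instead judged by whether
    the fit stays numerically perfect without it (removable → p = 1,
    indispensable → p = 0).
    """
    scale = max(float(y @ y), np.finfo(float).tiny)
    sse_full = _sse(terms, T, C, y)
    if sse_full <= _ZERO_SSE_RTOL * scale:
        out = {}
        for t in removable:
            reduced = [u for u in terms if u != t]
            out[t] = 1.0 if _sse(reduced, T, C, y) <= _ZERO_SSE_RTOL * scale else 0.0
        return out
    res = _ols(design_matrix(terms, T, C), y)
    pvals = np.nan_to_num(np.asarray(res.pvalues), nan=1.0)
    by_term = dict(zip(terms, pvals))
    return {t: float(by_term[t]) for t in removable}


def _is_perfect_fit(terms: Sequence[str], T, C, y: np.ndarray) -> bool:
    scale = max(float(y @ y), np.finfo(float).tiny)
    return _sse(terms, T, C, y) <= _ZERO_SSE_RTOL * scale


def _removal_key(term_p):
    term, p = term_p
    # remove the largest p; ties → higher polynomial degree, then later
    # canonical position (C-side before T-side)
    return (p, TERM_DEGREE[term], TERM_ORDER.index(term))


def _finalize(
    response_name: str,
    candidate_terms: Sequence[str],
    terms: Sequence[str],
    T,
    C,
    y: np.ndarray,
    alpha: float,
    warnings: list,
) -> FittedModel:
    """Refit the retained terms and package coefficients and fit statistics."""
    n = len(y)
    if not terms:
        return FittedModel(
            response_name=response_name,
            candidate_terms=tuple(candidate_terms),
            retained_terms=(),
            coefficients={},
            std_errors={},
            p_values={},
            r2=0.0,
            see=float(np.sqrt(y @ y / n)),
            n_obs=n,
            alpha=alpha,
            warnings=warnings,
        )
    X = design_matrix(terms, T, C)
    res = _ols(X, y)
    k = X.shape[1]
    sse = float(res.ssr)
    dof = n - k
    see = float(np.sqrt(sse / dof)) if dof > 0 else 0.0

    if "1" in terms:
        tss = float(np.sum((y - y.mean()) ** 2))
    else:
        tss = float(y @ y)
    r2 = 0.0 if tss == 0.0 else max(0.0, 1.0 - sse / tss)

    scale = max(float(y @ y), np.finfo(float).tiny)
    if sse <= _ZERO_SSE_RTOL * scale:
        # numerically perfect reproduction: report exact-fit statistics
        se = {t: 0.0 for t in terms}
        pv = {t: 0.0 for t in terms}
        r2, see = 1.0 if tss > 0 else 0.0, 0.0
    else:
        se = dict(zip(terms, np.asarray(res.bse, dtype=float)))
        pv = dict(zip(terms, np.nan_to_num(np.asarray(res.pvalues), nan=1.0)))
    return FittedModel(
        response_name=response_name,
        candidate_terms=tuple(candidate_terms),
        retained_terms=tuple(terms),
        coefficients=dict(zip(terms, np.asarray(res.params, dtype=float))),
        std_errors=se,
        p_values={t: float(p) for t, p in pv.items()},
        r2=float(r2),
        see=see,
        n_obs=n,
        alpha=alpha,
        warnings=warnings,
    )


def fit_univariate_cycle(
    cycle,
    y,
    max_degree: int = 2,
    alpha: float = 0.05,
    response_name: str = "response",
) -> FittedModel:
    """Fit a litter variable against the reuse cycle, dropping a
    non-significant quadratic.

    Ordinary least squares with intercept on C (and C² when
    ``max_degree == 2``); slope terms whose p-value exceeds ``alpha`` are
    removed highest degree first, so noiseless quadratic data recover the
    generating coefficients exactly and constant data collapse to the
    intercept (with R² defined as 0).
    """
    c = np.asarray(cycle, dtype=float)
    y = np.asarray(y, dtype=float)
    if max_degree not in (1, 2):
        raise ValueError("max_degree must be 1 or 2")
    if len(np.unique(c)) < max_degree + 2:
        raise ValueError(
            f"need at least {max_degree + 2} distinct cycle values to fit and "
            f"test a degree-{max_degree} polynomial"
        )
    T = np.zeros_like(c)  # temperature plays no role here
    candidates = ["1", "C"] + (["C2"] if max_degree == 2 else [])

    X = design_matrix(candidates, T, c)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design: collinear terms among {candidates}")

    terms = list(candidates)
    while True:
        if _is_perfect_fit(terms, T, c, y):
            removable = [t for t in terms if t != "1"]
        else:
            removable = [t for t in _highest_powers(terms, test_intercept=False)]
        if not removable:
            break
        pvals = _selection_pvalues(terms, removable, T, c, y)
        over = [(t, p) for t, p in pvals.items() if p > alpha]
        if not over:
            break
        worst, _ = max(over, key=_removal_key)
        terms.remove(worst)
    return _finalize(response_name, candidates, terms, T, c, y, alpha, [])


def fit_polynomial_backward(
    data: pd.DataFrame,
    response: str = "response",
    candidate_terms: Iterable[str] = DEFAULT_CANDIDATE_TERMS,
    alpha: float = 0.05,
    test_intercept: bool = True,
    strategy: str = "hierarchical",
    cycle: str = "cycle",
    temperature: str = "temperature",
) -> FittedModel:
    """Backward-eliminate a polynomial response surface in T and C.

    Starts from the full candidate model (by default intercept plus linear,
    quadratic and cubic powers of temperature and cycle) and repeatedly
    deletes the eligible term with the largest partial p-value above
    ``alpha`` until every eligible term is significant.  The intercept
    competes for removal like any other term when ``test_intercept`` is set;
    the model is refit through the origin once it leaves.

    Under the default ``strategy="hierarchical"`` only the highest remaining
    power of each variable (plus the intercept) is testable at each step —
    the classical polynomial degree-testing order, which keeps the heavily
    collinear raw powers of temperature from displacing one another.  With
    ``strategy="max_p"`` every retained term is eligible every step.  In
    either mode, a model that reproduces the data to numerical precision is
    pruned of exactly redundant terms wherever they sit in the hierarchy, so
    noiseless data from any candidate-term model recover the generator
    exactly.

    If every term is eliminated the null (zero) model is returned with a
    warning rather than raising.
    """
    candidates = sort_terms(set(candidate_terms))
    y = np.asarray(data[response], dtype=float)
    T = np.asarray(data[temperature], dtype=float)
    C = np.asarray(data[cycle], dtype=float)
    if len(y) <= len(candidates):
        raise ValueError("need more observations than candidate terms")

    X = design_matrix(candidates, T, C)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design: collinear terms among {candidates}")

    if strategy not in ("hierarchical", "max_p"):
        raise ValueError("strategy must be 'hierarchical' or 'max_p'")
    terms = list(candidates)
    warnings: list[str] = []
    while terms:
        if strategy == "max_p" or _is_perfect_fit(terms, T, C, y):
            removable = [t for t in terms if test_intercept or t != "1"]
        else:
            removable = _highest_powers(terms, test_intercept)
        if not removable:
            break
        pvals = _selection_pvalues(terms, removable, T, C, y)
        over = [(t, p) for t, p in pvals.items() if p > alpha]
        if not over:
            break
        worst, _ = max(over, key=_removal_key)
        terms.remove(worst)
    if not terms:
        warnings.append("all candidate terms eliminated; returning the null model")
    return _finalize(response, candidates, terms, T, C, y, alpha, warnings)
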