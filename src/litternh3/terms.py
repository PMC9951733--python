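"""Polynomial term pool shared by the model fitter and the response generator.

Candidate regressors are powers of air temperature T (°C) and litter reuse
cycle C, up to the cubic, plus an optional intercept.  No T×C cross term is
included: the factorial screen treats cycle and temperature as additive.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

#: Canonical ordering of the candidate terms (intercept first, then T powers,
#: then C powers).  All reporting and tie-breaking uses this ordering.
TERM_ORDER: tuple[str, ...] = ("1", "T", "T2", "T3", "C", "C2", "C3")

#: Polynomial degree of each term (intercept = 0); backward elimination breaks
#: p-value ties by removing the higher-degree term first.
TERM_DEGREE: dict[str, int] = {
    "1": 0, "T": 1, "T2": 2, "T3": 3, "C": 1, "C2": 2, "C3": 3,
}

DEFAULT_CANDIDATE_TERMS: tuple[str, ...] = TERM_ORDER


def term_column(term: str, T, C) -> np.ndarray:
    """Evaluate a single term on (broadcastable) T and C arrays."""
    T = np.asarray(T, dtype=float)
    C = np.asarray(C, dtype=float)
    if term == "1":
        return np.ones(np.broadcast(T, C).shape)
    base, power = term[0], int(term[1:] or 1)
    if base == "T":
        return T ** power
    if base == "C":
        return C ** power
    raise ValueError(f"unknown term {term!r}; expected one of {TERM_ORDER}")


def design_matrix(terms: Iterable[str], T, C) -> np.ndarray:
    """Column-stack the requested terms into an OLS design matrix."""
    terms = list(terms)
    if not terms:
        raise ValueError("empty term list")
    return np.column_stack([term_column(t, T, C) for t in terms])


def evaluate_terms(coefficients: Mapping[str, float], T, C) -> np.ndarray:
    """Evaluate a linear combination of terms, e.g. a fitted or published model."""
    out = np.zeros(np.broadcast(np.asarray(T, float), np.asarray(C, float)).shape)
    for term, coef in coefficients.items():
        out = out + coef * term_column(term, T, C)
    return out


def sort_terms(terms: Iterable[str]) -> list[str]:
    """Return terms in canonical order."""
    return sorted(terms, key=TERM_ORDER.index)
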