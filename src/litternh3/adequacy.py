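"""Model-adequacy engine: prediction-error decomposition and concordance.

Predictive adequacy of a fitted response model is judged by repeated random
50/50 splits of the data: the model is selected and fitted on one half
(generation subset) and evaluated on the other (test subset), and the
adequacy statistics are averaged over many such splits.

Per split, with observed o and predicted p (population ÷n moments s_o, s_p
and Pearson correlation r):

* **QMEP** — mean square of prediction error, mean((o − p)²) — partitioned
  exactly into
    - mean deviation       (ō − p̄)²            central-tendency bias,
    - systematic deviation (s_p − r·s_o)²       slope-from-1 bias,
    - random error         (1 − r²)·s_o²        unexplained variation;
* **CCC** — Lin's concordance correlation coefficient
  2·r·s_o·s_p / (s_o² + s_p² + (ō − p̄)²), decomposed as CCC = ρ·C_b with
  ρ = r (precision) and C_b = 2/(v + 1/v + u²) (accuracy; v = s_o/s_p,
  u = (ō − p̄)/√(s_o·s_p));
* **R²** — squared Pearson correlation between observed and predicted
  (an SSE-based alternative is available).

Population (÷n) standard deviations make the three-way partition an exact
identity; with sample (÷(n−1)) moments it holds only approximately.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .modeling import fit_polynomial_backward
from .terms import DEFAULT_CANDIDATE_TERMS


@dataclass
class AdequacyReport:
    """Cross-validation adequacy statistics averaged over random splits."""

    n_sim: int
    qmep: float
    pct_mean_deviation: float
    pct_systematic_deviation: float
    pct_random_error: float
    ccc: float
    rho: float
    cb: float
    r2: float
    seed: int | None = None
    n_failed: int = 0
    n_degenerate: int = 0
    response_name: str = "response"

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "AdequacyReport":
        text = str(source)
        if text.lstrip().startswith("{"):
            payload = json.loads(text)
        else:
            with open(text) as fh:
                payload = json.load(fh)
        return cls(**payload)

    def to_row(self) -> pd.DataFrame:
        """One-row table in the layout of the published adequacy summaries."""
        return pd.DataFrame(
            [
                {
                    "mean_deviation_pct": self.pct_mean_deviation,
                    "systematic_deviation_pct": self.pct_systematic_deviation,
                    "random_error_pct": self.pct_random_error,
                    "ccc": self.ccc,
                    "rho": self.rho,
                    "cb": self.cb,
                    "r2": self.r2,
                }
            ]
        )


def _moments(obs: np.ndarray, pred: np.ndarray):
    so = float(np.std(obs))  # population (÷n)
    sp = float(np.std(pred))
    if so > 0 and sp > 0:
        r = float(np.corrcoef(obs, pred)[0, 1])
    else:
        r = np.nan
    return so, sp, r


def qmep_partition(obs, pred):
    """Three-way decomposition of the mean square of prediction error.

    Returns ``(qmep, mean_dev, systematic_dev, random_err)``; the three
    components sum to QMEP exactly (an algebraic identity under population
    moments).  If either vector has zero variance the Pearson correlation is
    undefined: the mean-deviation component is still returned and the two
    correlation-based components are NaN (degenerate partition).
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 3:
        raise ValueError("obs and pred must be equal-length 1-D vectors, length >= 3")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("obs and pred must be finite")
    qmep = float(np.mean((obs - pred) ** 2))
    mean_dev = float((obs.mean() - pred.mean()) ** 2)
    so, sp, r = _moments(obs, pred)
    if np.isnan(r):
        return qmep, mean_dev, np.nan, np.nan
    systematic = float((sp - r * so) ** 2)
    random_err = float((1.0 - r**2) * so**2)
    return qmep, mean_dev, systematic, random_err


def lin_ccc(obs, pred):
    """Lin's concordance correlation coefficient and its ρ·C_b decomposition.

    Returns ``(ccc, rho, cb)``.  ρ is the Pearson correlation (precision);
    C_b ∈ (0, 1] penalizes location and scale shifts (accuracy) and is
    computed stably as 2/(v + 1/v + u²) so that ccc = rho·cb holds to
    rounding error.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 3:
        raise ValueError("obs and pred must be equal-length 1-D vectors, length >= 3")
    so, sp, r = _moments(obs, pred)
    if np.isnan(r):
        raise ValueError("concordance undefined: zero variance in obs or pred")
    u = (obs.mean() - pred.mean()) / np.sqrt(so * sp)
    v = so / sp
    cb = 2.0 / (v + 1.0 / v + u**2)
    return float(r * cb), float(r), float(cb)


def r2_score(obs, pred, method: str = "pearson"):
    """Test-set coefficient of determination.

    ``"pearson"`` (default): squared Pearson correlation between observed and
    predicted.  ``"sse"``: 1 − SSE/SST (can be negative for poor models).
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if method == "pearson":
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)
    if method == "sse":
        sst = float(np.sum((obs - obs.mean()) ** 2))
        return float(1.0 - np.sum((obs - pred) ** 2) / sst)
    raise ValueError("method must be 'pearson' or 'sse'")


def cross_validate(
    data: pd.DataFrame,
    response: str = "response",
    candidate_terms=DEFAULT_CANDIDATE_TERMS,
    n_sim: int = 1000,
    split: float = 0.5,
    alpha: float = 0.05,
    seed: int | None = None,
    reselect_terms: bool = True,
    fixed_terms=None,
    r2_method: str = "pearson",
    cycle: str = "cycle",
    temperature: str = "temperature",
) -> AdequacyReport:
    """Repeated random-split cross-validation of the backward-eliminated model.

    For each of ``n_sim`` simulations the rows are randomly partitioned into
    a generation subset (fraction ``split``, floored) and a test subset.  The
    polynomial model is selected and fitted on the generation subset — by
    backward elimination when ``reselect_terms`` (the default), or by
    refitting the frozen ``fixed_terms`` — and evaluated on the test subset
    via the QMEP partition, Lin's CCC and R².  The report carries the
    across-simulation means, with the partition expressed as percentages of
    QMEP.

    Splits on which fitting fails are skipped and counted; more than 10%
    failures aborts.  Splits with a degenerate partition (zero test-set
    variance) are excluded from the correlation-based averages and counted in
    ``n_degenerate``.
    """
    n = len(data)
    candidates = list(candidate_terms)
    if n < 2 * (len(candidates) + 2):
        raise ValueError(
            f"need at least {2 * (len(candidates) + 2)} rows for a "
            f"{len(candidates)}-term candidate pool; got {n}"
        )
    if not 0 < split < 1:
        raise ValueError("split must lie in (0, 1)")
    if reselect_terms is False and fixed_terms is None:
        raise ValueError("fixed_terms is required when reselect_terms=False")
    rng = np.random.default_rng(seed)
    n_gen = int(np.floor(n * split))

    stats: list[dict] = []
    n_failed = 0
    failures: list[str] = []
    for _ in range(n_sim):
        perm = rng.permutation(n)
        gen = data.iloc[perm[:n_gen]]
        test = data.iloc[perm[n_gen:]]
        try:
            if reselect_terms:
                model = fit_polynomial_backward(
                    gen, response=response, candidate_terms=candidates,
                    alpha=alpha, cycle=cycle, temperature=temperature,
                )
            else:
                model = fit_polynomial_backward(
                    gen, response=response, candidate_terms=fixed_terms,
                    alpha=2.0, cycle=cycle, temperature=temperature,
                )  # alpha > 1 keeps every frozen term
            pred = model.predict(test[temperature], test[cycle])
        except Exception as exc:  # noqa: BLE001 — logged, counted, re-raised in bulk
            n_failed += 1
            failures.append(str(exc))
            continue
        obs = np.asarray(test[response], dtype=float)
        qmep, mdev, sdev, rerr = qmep_partition(obs, pred)
        rec = {"qmep": qmep}
        if qmep > 0 and not np.isnan(sdev):
            rec["pct_mean"] = 100.0 * mdev / qmep
            rec["pct_sys"] = 100.0 * sdev / qmep
            rec["pct_rand"] = 100.0 * rerr / qmep
        so, sp, _ = _moments(obs, pred)
        if so > 0 and sp > 0:
            ccc, rho, cb = lin_ccc(obs, pred)
            rec.update(ccc=ccc, rho=rho, cb=cb, r2=r2_score(obs, pred, r2_method))
        stats.append(rec)

    if n_failed > 0.10 * n_sim:
        raise RuntimeError(
            f"cross-validation aborted: {n_failed}/{n_sim} splits failed to "
            f"fit; first failures: {failures[:3]}"
        )

    frame = pd.DataFrame(stats)

    def _mean(col):
        if col not in frame or frame[col].dropna().empty:
            return float("nan")
        return float(frame[col].mean())

    n_eff = len(frame)
    n_degenerate = int(n_eff - frame["ccc"].notna().sum()) if "ccc" in frame else n_eff
    return AdequacyReport(
        n_sim=n_sim,
        qmep=_mean("qmep"),
        pct_mean_deviation=_mean("pct_mean"),
        pct_systematic_deviation=_mean("pct_sys"),
        pct_random_error=_mean("pct_rand"),
        ccc=_mean("ccc"),
        rho=_mean("rho"),
        cb=_mean("cb"),
        r2=_mean("r2"),
        seed=seed,
        n_failed=n_failed,
        n_degenerate=n_degenerate,
        response_name=response,
    )
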