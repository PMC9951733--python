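"""Synthetic climatic-chamber data generator.

Real chamber data for the broiler-litter ammonia study are not publicly
deposited, so every downstream stage (speciation chemistry, model fitting,
adequacy analysis) is exercised on synthetic tables whose mean structure is
the set of published per-cycle equations for litter moisture, pH, total
nitrogen and ammoniacal nitrogen, and whose noise is Gaussian at the scale of
each equation's standard error of the estimate (SEE).

Response variables (ammonia generation potential in g·kg⁻¹ and SMDAE emission
flux) are generated from the published multiple-regression models in
temperature and reuse cycle, with user-set Gaussian noise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .design import CONDITIONS, SAMPLE_COLUMNS, DesignGrid, MAX_CYCLES, TEMPERATURE_RANGE
from .terms import evaluate_terms

#: The published generation (g·kg⁻¹) and emission (flux units as printed)
#: models, used as generating truth for parameter-recovery studies.
#: Keys are (response, bed_type); coefficients are on the shared term pool.
PUBLISHED_RESPONSE_MODELS: dict[tuple[str, str], dict[str, float]] = {
    ("generation", "wood_shavings"): {"T": 0.028, "C": 6.301, "C2": -1.059},
    ("generation", "coffee_husks"): {"T": 0.046, "C": 4.247, "C2": -0.512},
    ("emission", "wood_shavings"): {"T": 0.00031, "C": -0.00280, "C2": 0.00086},
    ("emission", "coffee_husks"): {"T": 0.00024, "C": -0.00014, "C2": 0.00023},
}

VARIABLES = ("moisture", "ph", "total_n", "ammoniacal_n")

# Physical clamps applied after noise; clip events are counted, not silent.
_CLIP_BOUNDS = {
    "moisture": (0.0, 100.0),
    "ph": (0.0, 14.0),
    "total_n": (0.0, np.inf),
}


@dataclass(frozen=True)
class MeanEquation:
    """Polynomial mean in the reuse cycle C plus its residual scale."""

    coef: tuple  # (c0, c1[, c2]) -> c0 + c1*C + c2*C²
    see: float

    def __post_init__(self):
        if len(self.coef) > 3:
            raise ValueError("mean equations are at most quadratic in C")
        if self.see < 0:
            raise ValueError("SEE must be >= 0")

    def __call__(self, cycle) -> np.ndarray:
        c = np.asarray(cycle, dtype=float)
        return sum(b * c**k for k, b in enumerate(self.coef))


class MeanStructure:
    """Lookup of mean equations per (bed type, variable, condition).

    ``condition`` is the string ``"initial"`` or a chamber temperature.  The
    packaged default carries the published equation tables; users may load a
    modified YAML with the same key tree.
    """

    def __init__(self, tree: Mapping):
        self._eqs: dict[tuple[str, str, str], MeanEquation] = {}
        for bed_type, bed_block in tree.items():
            for variable, var_block in bed_block.items():
                if variable == "max_cycle":
                    continue
                for cond, eq in var_block.items():
                    key = (bed_type, variable, str(cond))
                    self._eqs[key] = MeanEquation(tuple(eq["coef"]), float(eq["see"]))

    @classmethod
    def default(cls) -> "MeanStructure":
        ref = importlib.resources.files("litternh3").joinpath("data/mean_structure.yaml")
        return cls(yaml.safe_load(ref.read_text()))

    @classmethod
    def from_yaml(cls, path) -> "MeanStructure":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def equation(self, bed_type: str, variable: str, condition) -> MeanEquation:
        key = (bed_type, variable, _condition_key(condition))
        try:
            return self._eqs[key]
        except KeyError:
            raise KeyError(
                f"uncovered design cell: no mean equation for bed_type={bed_type!r}, "
                f"variable={variable!r}, condition={condition!r}"
            ) from None

    def mean(self, bed_type: str, variable: str, condition, cycle) -> np.ndarray:
        return self.equation(bed_type, variable, condition)(cycle)


def _condition_key(condition) -> str:
    if condition == "initial":
        return "initial"
    t = float(condition)
    return str(int(t)) if t == int(t) else str(t)


def simulate_bed_properties(
    grid: DesignGrid,
    means: MeanStructure | None = None,
    noise_scale: float = 1.0,
    seed: int | None = None,
    conditions=CONDITIONS,
) -> pd.DataFrame:
    """Simulate litter physico-chemical properties on a factorial grid.

    Each variable is drawn as (published-equation mean) + N(0, noise_scale·SEE).
    ``noise_scale`` rescales every equation's SEE jointly; 0 reproduces the
    mean structure exactly.  Initial-condition rows are temperature-free (the
    samples predate the thermal treatment) and appear once per cycle ×
    replicate with an empty temperature field.

    After noise, moisture is clipped to [0, 100], pH to [0, 14] and
    ammoniacal N to [0, total N]; the number of clipped values is recorded in
    ``df.attrs["n_clipped"]``.

    Returns a DataFrame with columns ``bed_type, cycle, temperature,
    condition, replicate, moisture, ph, total_n, ammoniacal_n``.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    means = means or MeanStructure.default()
    rng = np.random.default_rng(seed)

    cells: list[tuple] = []  # (cycle, temperature-or-nan, condition, replicate)
    for cycle in grid.cycles:
        for rep in range(1, grid.n_replicates + 1):
            if "initial" in conditions:
                cells.append((cycle, np.nan, "initial", rep))
            if "treated" in conditions:
                for temp in grid.temperatures:
                    cells.append((cycle, temp, "treated", rep))

    df = pd.DataFrame(cells, columns=["cycle", "temperature", "condition", "replicate"])
    df.insert(0, "bed_type", grid.bed_type)

    n_clipped = 0
    for variable in VARIABLES:
        values = np.empty(len(df))
        for i, row in enumerate(df.itertuples(index=False)):
            cond = "initial" if row.condition == "initial" else row.temperature
            eq = means.equation(grid.bed_type, variable, cond)
            values[i] = eq(row.cycle) + rng.normal(0.0, noise_scale * eq.see)
        if variable in _CLIP_BOUNDS:
            lo, hi = _CLIP_BOUNDS[variable]
            clipped = np.clip(values, lo, hi)
            n_clipped += int(np.sum(clipped != values))
            values = clipped
        df[variable] = values

    # ammoniacal N cannot exceed total N nor be negative
    clipped_na = df["ammoniacal_n"].clip(lower=0.0, upper=df["total_n"])
    n_clipped += int((clipped_na != df["ammoniacal_n"]).sum())
    df["ammoniacal_n"] = clipped_na

    df = df[list(SAMPLE_COLUMNS)]
    df.attrs["n_clipped"] = n_clipped
    df.attrs["seed"] = seed
    return df


def simulate_responses(
    model: Mapping[str, float],
    grid: DesignGrid,
    noise_sd: float = 0.0,
    noise_frac_of_mean: float | None = None,
    seed: int | None = None,
    response_name: str = "response",
) -> pd.DataFrame:
    """Simulate a response surface (generation or emission) on a factorial grid.

    ``model`` maps term names ("1", "T", "T2", ..., "C3") to coefficients;
    the published models are available in :data:`PUBLISHED_RESPONSE_MODELS`.
    Noise is Gaussian with constant sd ``noise_sd``, or — if
    ``noise_frac_of_mean`` is given — heteroscedastic with sd equal to that
    fraction of the absolute cell mean.

    Cells outside the models' experimental validity range (T outside
    [25, 40] °C or C beyond the substrate's maximum cycle) are generated
    anyway but flagged in ``df.attrs["warnings"]``.
    """
    coefficients = getattr(model, "coefficients", model)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_frac_of_mean is not None and noise_sd:
        raise ValueError("give either noise_sd or noise_frac_of_mean, not both")
    rng = np.random.default_rng(seed)

    rows = [
        (temp, cycle, rep)
        for cycle in grid.cycles
        for temp in grid.temperatures
        for rep in range(1, grid.n_replicates + 1)
    ]
    df = pd.DataFrame(rows, columns=["temperature", "cycle", "replicate"])
    mean = evaluate_terms(coefficients, df["temperature"], df["cycle"])
    if noise_frac_of_mean is not None:
        sd = np.abs(mean) * noise_frac_of_mean
    else:
        sd = np.full(len(df), float(noise_sd))
    df[response_name] = mean + rng.normal(0.0, 1.0, len(df)) * sd

    warnings: list[str] = []
    lo, hi = TEMPERATURE_RANGE
    if any(t < lo or t > hi for t in grid.temperatures):
        warnings.append(f"temperatures outside the validity range [{lo}, {hi}] °C")
    if max(grid.cycles) > MAX_CYCLES[grid.bed_type]:
        warnings.append(f"cycles beyond the observed maximum for {grid.bed_type}")
    df.attrs["warnings"] = warnings
    df.attrs["seed"] = seed
    return df
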