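"""Factorial design description and litter-sample table schema.

The climatic-chamber experiment crosses litter reuse cycle with chamber air
temperature, separately per bedding substrate: wood shavings support up to 4
reuse cycles and coffee husks up to 6, each tested at 25, 30, 35 and 40 °C
with 3 replicate facilities per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

BED_TYPES = ("wood_shavings", "coffee_husks")
MAX_CYCLES = {"wood_shavings": 4, "coffee_husks": 6}
STANDARD_TEMPERATURES = (25.0, 30.0, 35.0, 40.0)
TEMPERATURE_RANGE = (25.0, 40.0)
CONDITIONS = ("initial", "treated")

#: Column order of a litter-sample table (one row per design cell × replicate).
SAMPLE_COLUMNS = (
    "bed_type", "cycle", "temperature", "condition", "replicate",
    "moisture", "ph", "total_n", "ammoniacal_n",
)


@dataclass(frozen=True)
class DesignGrid:
    """Factorial layout: bed type × reuse cycles × air temperatures × replicates.

    Parameters
    ----------
    bed_type : {"wood_shavings", "coffee_husks"}
    cycles : tuple of int
        Reuse cycles to include; must stay within the substrate's observed
        range (1–4 for wood shavings, 1–6 for coffee husks).
    temperatures : tuple of float
        Chamber air temperatures in °C, within [25, 40].
    n_replicates : int
        Replicate facilities per design cell (the study used 3).
    """

    bed_type: str
    cycles: tuple = ()
    temperatures: tuple = STANDARD_TEMPERATURES
    n_replicates: int = 3

    def __post_init__(self):
        if self.bed_type not in BED_TYPES:
            raise ValueError(f"bed_type must be one of {BED_TYPES}, got {self.bed_type!r}")
        cycles = tuple(self.cycles) or tuple(range(1, MAX_CYCLES[self.bed_type] + 1))
        object.__setattr__(self, "cycles", cycles)
        object.__setattr__(self, "temperatures", tuple(float(t) for t in self.temperatures))
        lo, hi = 1, MAX_CYCLES[self.bed_type]
        if not all(lo <= c <= hi for c in self.cycles):
            raise ValueError(f"cycles for {self.bed_type} must lie in [{lo}, {hi}]")
        if not all(TEMPERATURE_RANGE[0] <= t <= TEMPERATURE_RANGE[1] for t in self.temperatures):
            raise ValueError(f"temperatures must lie in {TEMPERATURE_RANGE}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    @property
    def n_cells(self) -> int:
        return len(self.cycles) * len(self.temperatures)


def validate_samples(df: pd.DataFrame, strict: bool = True) -> list[str]:
    """Check a litter-sample table against its physical invariants.

    Returns a list of human-readable problems (row-indexed).  With
    ``strict=True`` a non-empty list raises ``ValueError`` instead.
    Initial-condition rows may carry an empty temperature.
    """
    problems: list[str] = []
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
    else:
        for idx, row in df.iterrows():
            if row["bed_type"] not in BED_TYPES:
                problems.append(f"row {idx}: unknown bed_type {row['bed_type']!r}")
            if not (0 <= row["moisture"] <= 100):
                problems.append(f"row {idx}: moisture {row['moisture']} outside [0, 100]")
            if not (0 <= row["ph"] <= 14):
                problems.append(f"row {idx}: ph {row['ph']} outside [0, 14]")
            if row["ammoniacal_n"] < 0 or row["ammoniacal_n"] > row["total_n"]:
                problems.append(
                    f"row {idx}: ammoniacal_n {row['ammoniacal_n']} outside "
                    f"[0, total_n={row['total_n']}]"
                )
    if strict and problems:
        raise ValueError("invalid litter-sample table: " + "; ".join(problems))
    return problems
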