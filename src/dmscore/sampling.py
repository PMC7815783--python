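"""Individual-level Monte Carlo samples from a compartmental population state.

The sampling frame is the simulated population restricted to an age range
(15-79 years by default). Individuals are drawn with replacement from a
multinomial over strata with probabilities proportional to compartment
occupancy — the compartment masses are continuous, so finite-population
draws without replacement would not be meaningful. Individuals carry their
five-year age band rather than an exact age, since the score's age
categories are the bands themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    N_PROFILES,
    CompartmentState,
    bands_in_range,
)

#: canonical column order of the individual-level table
COLUMNS = ["id", "sex", "age_band", "obese", "smoker", "inactive", "diabetic"]

DEFAULT_AGE_RANGE = (15.0, 79.0)


@dataclass
class IndividualTable:
    """Sampled or synthetic persons with binary covariates and disease flag.

    ``data`` holds one row per person with the columns in :data:`COLUMNS`
    (sex 0 = female, 1 = male; flags 0/1); ``provenance`` records how the
    table was produced (source state time, seed, n, generator).
    """

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"table missing columns {missing}")
        self.data = self.data.loc[:, COLUMNS].reset_index(drop=True)
        if self.data["id"].duplicated().any():
            raise ValueError("individual ids must be unique")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV plus a JSON provenance sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        path.with_suffix(path.suffix + ".provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "IndividualTable":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".provenance.json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(data, prov)


def sample_individuals(
    state: CompartmentState,
    n: int,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
    seed: int | None = None,
) -> IndividualTable:
    """Draw ``n`` individuals from the state's occupancy within ``age_range``.

    Multinomial over the in-frame strata with probabilities proportional to
    occupancy; deterministic given ``seed``. ``n = 0`` yields an empty table.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    bands = bands_in_range(*age_range)
    frame = state.occupancy[:, bands]  # (2, n_bands, 8, 2)
    total = frame.sum()
    if total <= 0:
        raise ValueError(f"empty sampling frame in age range {age_range}")

    probs = frame.ravel() / total
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)

    sex_i, band_i, prof_i, dia_i = np.indices(frame.shape).reshape(4, -1)
    reps = np.repeat(np.arange(counts.size), counts)
    rng.shuffle(reps)  # row order carries no stratum structure
    prof = prof_i[reps]
    data = pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": sex_i[reps],
            "age_band": np.asarray(bands)[band_i[reps]],
            "obese": prof & 1,
            "smoker": prof >> 1 & 1,
            "inactive": prof >> 2 & 1,
            "diabetic": dia_i[reps],
        }
    )
    return IndividualTable(
        data,
        provenance={
            "generator": "sample_individuals",
            "source_time": state.time,
            "age_range": list(age_range),
            "n": n,
            "seed": seed,
            "rng": "numpy.random.default_rng PCG64, multinomial",
        },
    )


def describe(table: IndividualTable | pd.DataFrame) -> dict:
    """Marginal prevalences of diabetes and each risk factor.

    Returns overall proportions plus breakdowns by sex and by age band,
    each as a mapping quantity -> proportion in [0, 1].
    """
    df = table.data if isinstance(table, IndividualTable) else table
    if len(df) == 0:
        raise ValueError("cannot describe an empty table")
    quantities = {
        "diabetes": "diabetic",
        "obesity": "obese",
        "smoking": "smoker",
        "inactivity": "inactive",
    }
    overall = {q: float(df[c].mean()) for q, c in quantities.items()}
    by_sex = {
        ("female", "male")[int(s)]: {q: float(g[c].mean())
                                     for q, c in quantities.items()}
        for s, g in df.groupby("sex")
    }
    by_band = {
        int(b): {q: float(g[c].mean()) for q, c in quantities.items()}
        for b, g in df.groupby("age_band")
    }
    return {"n": len(df), "overall": overall, "by_sex": by_sex,
            "by_age_band": by_band}
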