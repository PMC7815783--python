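"""Synthetic individual-level tables with known ground truth.

A :class:`GeneratorSpec` fixes the covariate marginals (sex split, age-band
distribution over the 15-79 frame, risk-factor prevalences) and a logistic
disease model (intercept plus per-category betas). :func:`generate` draws
covariates independently per the marginals (optionally from a joint
risk-factor table) and assigns diabetes Bernoulli(expit(linear predictor)).
Because the generating coefficients are known exactly, every downstream
stage — fitting, points conversion, cut-off selection — can be tested by
parameter recovery without any external dataset.

:func:`builtin_fixture` packages published multivariable models for a
Middle-Eastern national population at three time points (2020, 2030, 2050),
together with the corresponding reported risk-factor marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import band_label, bands_in_range
from .sampling import DEFAULT_AGE_RANGE, IndividualTable

#: age bands of the default sampling frame: 15-19 ... 75-79
FRAME_BANDS = tuple(bands_in_range(*DEFAULT_AGE_RANGE))

FACTOR_COLUMNS = ("obese", "smoker", "inactive")


@dataclass
class GeneratorSpec:
    """Ground-truth recipe for a synthetic individual table.

    ``factor_marginals`` maps factor column -> prevalence, either a scalar or
    an array of shape (2, len(bands)) for sex- and age-specific values.
    ``disease_model`` is {"intercept": b0, "<covariable>": {category: beta}};
    covariables follow the scorekit category labels ("male", "15-19",
    "obese", ...). ``factor_joint``, if given, is a length-8 probability
    vector over the 3-bit factor profiles and overrides the marginals.
    """

    n: int
    male_fraction: float = 0.5
    bands: tuple[int, ...] = FRAME_BANDS
    age_distribution: np.ndarray | None = None  # default uniform over bands
    factor_marginals: dict = field(default_factory=dict)
    disease_model: dict = field(default_factory=dict)
    factor_joint: np.ndarray | None = None
    seed: int | None = None
    name: str = "synthetic"

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be nonnegative")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction outside [0, 1]")
        if self.age_distribution is None:
            self.age_distribution = np.full(len(self.bands),
                                            1.0 / len(self.bands))
        self.age_distribution = np.asarray(self.age_distribution, float)
        if len(self.age_distribution) != len(self.bands):
            raise ValueError("age distribution length != number of bands")
        if (self.age_distribution < 0).any() or not np.isclose(
            self.age_distribution.sum(), 1.0
        ):
            raise ValueError("age distribution must be a probability vector")
        for f, p in self.factor_marginals.items():
            arr = np.asarray(p, float)
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"marginal prevalence of {f!r} outside [0, 1]")
        if self.factor_joint is not None:
            self.factor_joint = np.asarray(self.factor_joint, float)
            if self.factor_joint.shape != (8,) or (
                self.factor_joint < 0
            ).any() or not np.isclose(self.factor_joint.sum(), 1.0):
                raise ValueError("factor_joint must be 8 probabilities summing to 1")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n": self.n,
            "male_fraction": self.male_fraction,
            "bands": list(self.bands),
            "age_distribution": self.age_distribution.tolist(),
            "factor_marginals": {
                k: (np.asarray(v).tolist() if np.ndim(v) else float(v))
                for k, v in self.factor_marginals.items()
            },
            "disease_model": self.disease_model,
            "factor_joint": (
                None if self.factor_joint is None else self.factor_joint.tolist()
            ),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorSpec":
        return cls(
            n=d["n"],
            male_fraction=d.get("male_fraction", 0.5),
            bands=tuple(d.get("bands", FRAME_BANDS)),
            age_distribution=d.get("age_distribution"),
            factor_marginals={
                k: np.asarray(v) if isinstance(v, list) else v
                for k, v in d.get("factor_marginals", {}).items()
            },
            disease_model=d.get("disease_model", {}),
            factor_joint=d.get("factor_joint"),
            seed=d.get("seed"),
            name=d.get("name", "synthetic"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GeneratorSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _marginal_for(spec: GeneratorSpec, factor: str, sex: np.ndarray,
                  band_idx: np.ndarray) -> np.ndarray:
    p = spec.factor_marginals.get(factor, 0.0)
    arr = np.asarray(p, float)
    if arr.ndim == 0:
        return np.full(len(sex), float(arr))
    if arr.shape != (2, len(spec.bands)):
        raise ValueError(
            f"marginal for {factor!r} must be scalar or (2, {len(spec.bands)})"
        )
    return arr[sex, band_idx]


def linear_predictor(spec: GeneratorSpec, df: pd.DataFrame) -> np.ndarray:
    """Generating log-odds of disease for each row of a covariate table."""
    model = spec.disease_model
    lp = np.full(len(df), float(model.get("intercept", 0.0)))
    sex_beta = model.get("sex", {})
    lp += df["sex"].to_numpy() * float(sex_beta.get("male", 0.0))
    age_betas = model.get("age_band", {})
    lp += df["age_band"].map(
        lambda b: float(age_betas.get(band_label(b), 0.0))
    ).to_numpy()
    for f in FACTOR_COLUMNS:
        cats = model.get(f, {})
        # indicator category carries the beta; reference is 0
        beta = float(next(iter(cats.values()))) if cats else 0.0
        lp += df[f].to_numpy() * beta
    return lp


def generate(spec: GeneratorSpec) -> IndividualTable:
    """Draw a synthetic table: covariates per the marginals, then disease."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    sex = (rng.random(n) < spec.male_fraction).astype(int)
    band_idx = rng.choice(len(spec.bands), size=n, p=spec.age_distribution)
    bands = np.asarray(spec.bands)[band_idx]

    if spec.factor_joint is not None:
        codes = rng.choice(8, size=n, p=spec.factor_joint)
        factors = {
            "obese": codes & 1,
            "smoker": codes >> 1 & 1,
            "inactive": codes >> 2 & 1,
        }
    else:
        factors = {
            f: (rng.random(n) < _marginal_for(spec, f, sex, band_idx)).astype(int)
            for f in FACTOR_COLUMNS
        }

    df = pd.DataFrame({"id": np.arange(n), "sex": sex, "age_band": bands,
                       **factors})
    prob = expit(linear_predictor(spec, df))
    df["diabetic"] = (rng.random(n) < prob).astype(int)
    return IndividualTable(
        df,
        provenance={
            "generator": "synthdata.generate",
            "spec": spec.name,
            "n": n,
            "seed": spec.seed,
            "rng": "numpy.random.default_rng PCG64",
        },
    )


# ---------------------------------------------------------------------------
# Packaged yearly fixtures
# ---------------------------------------------------------------------------

_AGE_LABELS = [band_label(b) for b in FRAME_BANDS]  # 15-19 ... 75-79

# published multivariable betas (intercept; age bands above reference 15-19;
# male; obese; smoker; inactive) and reported risk-factor marginals per year
_FIXTURES: dict[int, dict] = {
    2020: {
        "intercept": -4.10,
        "age": [0.59, 1.02, 0.97, 1.42, 1.54, 1.79,
                2.02, 2.46, 2.46, 2.39, 2.62, 2.45],
        "male": 0.20, "obese": 1.40, "smoker": 0.31, "inactive": 0.53,
        "marginals": {"obese": 0.407, "smoker": 0.164, "inactive": 0.493},
    },
    2030: {
        "intercept": -3.95,
        "age": [0.42, 0.79, 0.88, 1.05, 1.33, 1.75,
                1.96, 2.00, 2.37, 2.28, 2.36, 2.02],
        "male": 0.06, "obese": 1.39, "smoker": 0.36, "inactive": 0.42,
        "marginals": {"obese": 0.438, "smoker": 0.166, "inactive": 0.512},
    },
    2050: {
        "intercept": -3.67,
        "age": [0.05, 0.31, 0.70, 0.79, 1.25, 1.48,
                1.72, 1.91, 1.88, 1.99, 1.77, 2.18],
        "male": 0.29, "obese": 1.48, "smoker": 0.22, "inactive": 0.37,
        "marginals": {"obese": 0.484, "smoker": 0.183, "inactive": 0.570},
    },
}


def builtin_fixture(year: int, n: int = 5000,
                    seed: int | None = None) -> GeneratorSpec:
    """Packaged generating spec for one of the supported years.

    Encodes the published multivariable disease model (intercept and
    per-category betas) and the reported risk-factor marginal prevalences
    for that year. The sex split (0.5) and the uniform age-band distribution
    over the 15-79 frame are this package's declared defaults, since the
    source tables do not print the sample's demographic composition.
    """
    if year not in _FIXTURES:
        raise ValueError(f"unsupported year {year}; choose from "
                         f"{sorted(_FIXTURES)}")
    fx = _FIXTURES[year]
    disease_model = {
        "intercept": fx["intercept"],
        "sex": {"male": fx["male"]},
        "age_band": dict(zip(_AGE_LABELS[1:], fx["age"])),
        "obese": {"obese": fx["obese"]},
        "smoker": {"smoker": fx["smoker"]},
        "inactive": {"inactive": fx["inactive"]},
    }
    return GeneratorSpec(
        n=n,
        male_fraction=0.5,
        factor_marginals=dict(fx["marginals"]),
        disease_model=disease_model,
        seed=seed,
        name=f"builtin-{year}",
    )
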