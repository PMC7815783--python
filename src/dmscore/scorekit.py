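"""Logistic-regression fitting and points-type score construction.

A points-type risk score is built the conventional way: fit a multivariable
logistic regression of disease on categorical covariables, multiply each
category's log-odds-ratio (beta) by 10, and round to the nearest integer.
Rounding is applied to the full-precision fitted beta, halves away from
zero. Reference categories (female, youngest age band, factor absent) carry
zero points by construction. No interaction terms are ever included, keeping
the score a simple sum over the individual's categories.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .model import band_label
from .sampling import IndividualTable

#: default covariables, in reporting order
DEFAULT_COVARIABLES = ("age_band", "sex", "obese", "smoker", "inactive")

#: category labels per binary covariable: (reference, indicator)
BINARY_LEVELS = {
    "sex": ("female", "male"),
    "obese": ("non-obese", "obese"),
    "smoker": ("non-smoker", "smoker"),
    "inactive": ("active", "inactive"),
}

NEWTON_TOL = 1e-8


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


class ConvergenceError(RuntimeError):
    """The iteratively reweighted fit did not converge."""


def _as_frame(table: IndividualTable | pd.DataFrame) -> pd.DataFrame:
    return table.data if isinstance(table, IndividualTable) else table


def categorize(df: pd.DataFrame, covariable: str) -> pd.Series:
    """Map a coded column to its category labels (age bands to '15-19' etc.)."""
    if covariable == "age_band":
        return df["age_band"].map(band_label)
    ref, ind = BINARY_LEVELS[covariable]
    return df[covariable].map({0: ref, 1: ind})


@dataclass
class LogisticFit:
    """Intercept and per-category coefficients of a fitted logistic model.

    ``coef`` maps covariable -> ordered {category: (beta, se)}; reference
    categories are present with beta 0 and se None. Odds ratios and Wald
    confidence intervals are derived views of the betas.
    """

    intercept: float
    intercept_se: float
    coef: dict[str, dict[str, tuple[float, float | None]]]
    n: int
    converged: bool
    llf: float
    mode: str = "multivariable"

    def beta(self, covariable: str, category: str) -> float:
        return self.coef[covariable][category][0]

    def odds_ratio(
        self, covariable: str, category: str, alpha: float = 0.05
    ) -> tuple[float, tuple[float, float]]:
        """OR = exp(beta) with a Wald CI exponentiated from the beta scale."""
        b, se = self.coef[covariable][category]
        if se is None:
            return 1.0, (1.0, 1.0)
        z = norm.ppf(1 - alpha / 2)
        return math.exp(b), (math.exp(b - z * se), math.exp(b + z * se))

    def to_frame(self) -> pd.DataFrame:
        """Per-category coefficient table: beta, SE, OR with 95% CI."""
        rows = []
        for cov, cats in self.coef.items():
            for cat, (b, se) in cats.items():
                orr, (lo, hi) = self.odds_ratio(cov, cat)
                rows.append(
                    {
                        "covariable": cov,
                        "category": cat,
                        "beta": b,
                        "se": se,
                        "OR": orr if se is not None else np.nan,
                        "OR_ci_low": lo if se is not None else np.nan,
                        "OR_ci_high": hi if se is not None else np.nan,
                        "reference": se is None,
                    }
                )
        return pd.DataFrame(rows)


def _dummy_design(
    df: pd.DataFrame, covariables: tuple[str, ...] | list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Intercept + one dummy per non-reference category, columns 'cov:cat'."""
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    levels: dict[str, list[str]] = {}
    for cov in covariables:
        cats = categorize(df, cov)
        if cov == "age_band":
            present = sorted(df["age_band"].unique())
            labels = [band_label(b) for b in present]
        else:
            ref, ind = BINARY_LEVELS[cov]
            labels = [lvl for lvl in (ref, ind) if (cats == lvl).any()]
        levels[cov] = labels
        for lab in labels[1:]:  # first present level is the reference
            X[f"{cov}:{lab}"] = (cats == lab).astype(float)
    return X, levels


def _separation_suspects(y: np.ndarray, X: pd.DataFrame) -> list[str]:
    out = []
    for col in X.columns:
        if col == "const":
            continue
        x = X[col].to_numpy()
        for v in (0.0, 1.0):
            sub = y[x == v]
            if len(sub) and (sub.min() == sub.max()):
                out.append(col)
                break
    return out


def fit_logistic(
    table: IndividualTable | pd.DataFrame,
    covariables: tuple[str, ...] | list[str] = DEFAULT_COVARIABLES,
    mode: str = "multivariable",
    outcome: str = "diabetic",
) -> LogisticFit | dict[str, LogisticFit]:
    """Maximum-likelihood logistic regression of the outcome on covariables.

    ``mode='multivariable'`` fits all covariables jointly and returns one
    :class:`LogisticFit`; ``mode='univariable'`` fits each covariable in a
    separate intercept-plus-covariable model and returns a dict keyed by
    covariable. Newton-Raphson to gradient tolerance 1e-8; no interactions.
    """
    df = _as_frame(table)
    if len(df) == 0:
        raise ValueError("cannot fit on an empty table")
    y = df[outcome].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("outcome must include both classes")
    if mode == "univariable":
        return {
            cov: fit_logistic(df, (cov,), "multivariable", outcome)
            for cov in covariables
        }
    if mode != "multivariable":
        raise ValueError(f"unknown mode {mode!r}")

    X, levels = _dummy_design(df, covariables)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(
                method="newton", tol=NEWTON_TOL, maxiter=200, disp=0
            )
    except Exception as exc:
        if type(exc).__name__.startswith("PerfectSeparation") or isinstance(
            exc, (np.linalg.LinAlgError, RuntimeWarning)
        ):
            bad = _separation_suspects(y, X) or ["<unidentified>"]
            raise SeparationError(
                f"complete or quasi-complete separation involving {bad}"
            ) from exc
        raise
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"Newton iterations did not converge: {res.mle_retvals}"
        )
    if np.abs(res.params.drop("const")).max() > 30:
        bad = _separation_suspects(y, X) or ["<unidentified>"]
        raise SeparationError(
            f"coefficients diverged, separation involving {bad}"
        )

    coef: dict[str, dict[str, tuple[float, float | None]]] = {}
    for cov in covariables:
        cats: dict[str, tuple[float, float | None]] = {}
        for i, lab in enumerate(levels[cov]):
            if i == 0:
                cats[lab] = (0.0, None)
            else:
                col = f"{cov}:{lab}"
                cats[lab] = (float(res.params[col]), float(res.bse[col]))
        coef[cov] = cats
    return LogisticFit(
        intercept=float(res.params["const"]),
        intercept_se=float(res.bse["const"]),
        coef=coef,
        n=len(df),
        converged=True,
        llf=float(res.llf),
        mode=mode,
    )


def beta_to_points(beta: float) -> int:
    """Integer points for a coefficient: round(10 * beta), halves away from zero."""
    if not math.isfinite(beta):
        raise ValueError("beta must be finite")
    x = 10.0 * beta
    pts = int(math.copysign(math.floor(abs(x) + 0.5), x))
    if pts < 0:
        warnings.warn(
            f"beta {beta:.4g} yields negative points ({pts}); kept as-is",
            stacklevel=2,
        )
    return pts


@dataclass
class ScoreDefinition:
    """A points-type score: covariable -> category -> integer points.

    Every covariable has a zero-point reference category; an individual's
    score is the sum of the points of their categories. ``cutoff`` (optional,
    half-integers allowed) marks the flagged-for-testing threshold.
    """

    name: str
    points: dict[str, dict[str, int]]
    year: int | str | None = None
    cutoff: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for cov, cats in self.points.items():
            if 0 not in cats.values():
                raise ValueError(f"covariable {cov!r} has no 0-point reference")

    @property
    def max_score(self) -> int:
        """Sum of per-covariable maxima."""
        return sum(max(c.values()) for c in self.points.values())

    @property
    def covariables(self) -> list[str]:
        return list(self.points)

    def restricted(self, covariables: list[str]) -> "ScoreDefinition":
        """Copy keeping only the named covariables (for cross-score comparison)."""
        keep = {c: dict(v) for c, v in self.points.items() if c in covariables}
        if not keep:
            raise ValueError(
                f"score {self.name!r} shares no covariables with {covariables}"
            )
        return ScoreDefinition(
            self.name, keep, self.year, self.cutoff,
            {**self.provenance, "restricted_to": list(keep)},
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "year": self.year,
            "covariables": {c: dict(v) for c, v in self.points.items()},
            "cutoff": self.cutoff,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScoreDefinition":
        return cls(
            name=d["name"],
            points={c: {k: int(v) for k, v in cats.items()}
                    for c, cats in d["covariables"].items()},
            year=d.get("year"),
            cutoff=d.get("cutoff"),
            provenance=d.get("provenance", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ScoreDefinition":
        return cls.from_dict(json.loads(Path(path).read_text()))


def derive_score(
    table: IndividualTable | pd.DataFrame,
    covariables: tuple[str, ...] | list[str] = DEFAULT_COVARIABLES,
    name: str = "derived",
    year: int | str | None = None,
) -> tuple[ScoreDefinition, LogisticFit]:
    """Fit the multivariable model and convert its betas to integer points."""
    fit = fit_logistic(table, covariables, "multivariable")
    points = {
        cov: {cat: beta_to_points(b) for cat, (b, _) in cats.items()}
        for cov, cats in fit.coef.items()
    }
    definition = ScoreDefinition(
        name,
        points,
        year=year,
        provenance={"derived_from": "fit_logistic", "n": fit.n},
    )
    return definition, fit


def apply_score(
    table: IndividualTable | pd.DataFrame, definition: ScoreDefinition
) -> np.ndarray:
    """Per-individual integer score: sum of points over the row's categories."""
    df = _as_frame(table)
    total = np.zeros(len(df), dtype=int)
    for cov, cats in definition.points.items():
        if cov not in df.columns:
            raise KeyError(f"covariable {cov!r} missing from table")
        labels = categorize(df, cov)
        unknown = set(labels.unique()) - set(cats)
        if unknown:
            raise KeyError(
                f"categories {sorted(unknown)} of {cov!r} missing from "
                f"score {definition.name!r}"
            )
        total += labels.map(cats).to_numpy(int)
    return total


def score_table_to_frame(
    definition: ScoreDefinition, fit: LogisticFit | None = None
) -> pd.DataFrame:
    """Reporting view: per category OR, adjusted beta, and points."""
    rows = []
    for cov, cats in definition.points.items():
        for cat, pts in cats.items():
            row = {"covariable": cov, "category": cat, "points": pts}
            if fit is not None and cat in fit.coef.get(cov, {}):
                b, se = fit.coef[cov][cat]
                row["beta"] = b
                if se is not None:
                    orr, (lo, hi) = fit.odds_ratio(cov, cat)
                    row["aOR"] = orr
                    row["aOR_ci_low"] = lo
                    row["aOR_ci_high"] = hi
            rows.append(row)
    return pd.DataFrame(rows)
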