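"""Diagnostic performance of a scored population.

Provides ROC/AUC (Mann-Whitney statistic with tie correction, stratified
bootstrap CI), cut-off selection — Youden-style maximisation of
sensitivity + specificity, or constrained to a minimum specificity or
sensitivity — confusion-matrix summaries with Wilson confidence intervals,
the analytic prevalence identities linking sensitivity, specificity, PPV,
NPV and the flagged proportion, per-stratum testing yields (persons tested
per case found = inverse prevalence), and a multi-score comparison harness.

The flagging rule throughout is: score >= cut-off means flagged for testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint

from .model import CompartmentState, bands_in_range
from .sampling import DEFAULT_AGE_RANGE, IndividualTable
from .scorekit import ScoreDefinition, apply_score

DEFAULT_BOOTSTRAP = 2000


class OneClassError(ValueError):
    """Scores must include both diseased and non-diseased individuals."""


class UnattainableConstraint(ValueError):
    """No cut-off satisfies the requested sensitivity/specificity bound."""


def _wilson(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (np.nan, np.nan)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


@dataclass
class ConfusionAtCutoff:
    """Counts and proportions of the score >= cutoff classification rule."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    se: float
    sp: float
    ppv: float
    npv: float
    flagged: float  # proportion of the sample at or above the cutoff
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n

    @property
    def missed(self) -> float:
        """Fraction of true cases not flagged (1 - sensitivity)."""
        return 1.0 - self.se

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff, "tp": self.tp, "fp": self.fp,
            "tn": self.tn, "fn": self.fn, "sensitivity": self.se,
            "specificity": self.sp, "ppv": self.ppv, "npv": self.npv,
            "proportion_flagged": self.flagged,
        }


def _check_two_class(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise OneClassError("labels contain a single class")


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionAtCutoff:
    """Confusion counts and Wilson-CI proportions at one cut-off."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    flag = s >= cutoff
    tp = int(np.sum(flag & (y == 1)))
    fp = int(np.sum(flag & (y == 0)))
    fn = int(np.sum(~flag & (y == 1)))
    tn = int(np.sum(~flag & (y == 0)))
    n = len(y)
    se = tp / (tp + fn) if tp + fn else np.nan
    sp = tn / (tn + fp) if tn + fp else np.nan
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    return ConfusionAtCutoff(
        cutoff=float(cutoff), tp=tp, fp=fp, tn=tn, fn=fn,
        se=se, sp=sp, ppv=ppv, npv=npv, flagged=(tp + fp) / n,
        ci={
            "sensitivity": _wilson(tp, tp + fn),
            "specificity": _wilson(tn, tn + fp),
            "ppv": _wilson(tp, tp + fp),
            "npv": _wilson(tn, tn + fn),
            "proportion_flagged": _wilson(tp + fp, n),
        },
    )


def _auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC = P(case > control) + P(tie)/2."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores)  # midranks handle ties
    r1 = ranks[labels == 1].sum()
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n0)


@dataclass
class PerformanceReport:
    """ROC curve, AUC with bootstrap CI, and (optionally) a chosen cut-off."""

    roc: pd.DataFrame  # columns fpr, tpr, threshold; step curve (0,0)->(1,1)
    auc: float
    auc_ci: tuple[float, float]
    confusion: ConfusionAtCutoff | None = None
    cutoff_policy: str | None = None
    n_bootstrap: int = DEFAULT_BOOTSTRAP
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        """One-row summary in the conventional reporting layout."""
        row = {
            "AUC": self.auc,
            "AUC_ci_low": self.auc_ci[0],
            "AUC_ci_high": self.auc_ci[1],
            "cutoff_policy": self.cutoff_policy,
        }
        if self.confusion is not None:
            c = self.confusion
            row.update(
                cutoff=c.cutoff, sensitivity=c.se, specificity=c.sp,
                ppv=c.ppv, npv=c.npv, proportion_flagged=c.flagged,
            )
            for key, (lo, hi) in c.ci.items():
                row[f"{key}_ci_low"] = lo
                row[f"{key}_ci_high"] = hi
        return pd.DataFrame([row])


def roc_and_auc(
    scores,
    labels,
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int | None = 0,
) -> PerformanceReport:
    """Empirical ROC and AUC with a stratified-bootstrap confidence interval.

    The AUC is the tie-corrected Mann-Whitney statistic, identical to the
    trapezoidal area under the empirical ROC. Bootstrap resamples cases and
    controls separately (stratified), seeded for determinism.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    _check_two_class(y)
    fpr, tpr, thr = roc_curve(y, s)
    auc = _auc_mann_whitney(s, y)

    cases = s[y == 1]
    controls = s[y == 0]
    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    yb = np.concatenate([np.ones(len(cases), int), np.zeros(len(controls), int)])
    for i in range(n_bootstrap):
        sb = np.concatenate(
            [rng.choice(cases, len(cases)), rng.choice(controls, len(controls))]
        )
        boot[i] = _auc_mann_whitney(sb, yb)
    ci = tuple(np.percentile(boot, [2.5, 97.5]))
    return PerformanceReport(
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        auc=float(auc),
        auc_ci=(float(ci[0]), float(ci[1])),
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def candidate_cutoffs(scores) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus one beyond each extreme."""
    u = np.unique(np.asarray(scores, float))
    return np.concatenate([[u[0] - 0.5], (u[:-1] + u[1:]) / 2, [u[-1] + 0.5]])


def optimal_cutoff(scores, labels) -> ConfusionAtCutoff:
    """Cut-off maximising sensitivity + specificity (Youden's J + 1).

    Ties on the objective break toward the smallest cut-off, which favours
    sensitivity — the natural choice in a screening context.
    """
    y = np.asarray(labels, int)
    _check_two_class(y)
    best = None
    for c in candidate_cutoffs(scores):
        conf = confusion_at_cutoff(scores, y, c)
        if best is None or conf.se + conf.sp > best.se + best.sp + 1e-12:
            best = conf
    return best


def constrained_cutoff(
    scores, labels, min_specificity: float | None = None,
    min_sensitivity: float | None = None,
) -> ConfusionAtCutoff:
    """Cut-off under a minimum-specificity or minimum-sensitivity constraint.

    With ``min_specificity``: the smallest cut-off whose specificity meets the
    bound (specificity is non-decreasing in the cut-off, so this maximises
    sensitivity subject to it). With ``min_sensitivity``: the largest cut-off
    whose sensitivity meets the bound (maximises specificity subject to it).
    """
    if (min_specificity is None) == (min_sensitivity is None):
        raise ValueError("specify exactly one of min_specificity/min_sensitivity")
    y = np.asarray(labels, int)
    _check_two_class(y)
    cands = candidate_cutoffs(scores)
    confs = [confusion_at_cutoff(scores, y, c) for c in cands]
    if min_specificity is not None:
        ok = [c for c in confs if c.sp >= min_specificity]
        if not ok:
            raise UnattainableConstraint(
                f"specificity >= {min_specificity} unattainable; best "
                f"achievable is {max(c.sp for c in confs):.4f}"
            )
        return min(ok, key=lambda c: c.cutoff)
    ok = [c for c in confs if c.se >= min_sensitivity]
    if not ok:
        raise UnattainableConstraint(
            f"sensitivity >= {min_sensitivity} unattainable; best "
            f"achievable is {max(c.se for c in confs):.4f}"
        )
    return max(ok, key=lambda c: c.cutoff)


def predictive_values(se: float, sp: float, p: float) -> dict[str, float]:
    """PPV, NPV and flagged proportion from sensitivity, specificity, prevalence.

    PPV = se*p / (se*p + (1-sp)(1-p));
    NPV = sp(1-p) / (sp(1-p) + (1-se)p);
    proportion flagged pi = se*p + (1-sp)(1-p).
    0/0 cases are reported as NaN (not estimable).
    """
    for name, v in (("se", se), ("sp", sp), ("p", p)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    pos = se * p + (1 - sp) * (1 - p)
    neg = sp * (1 - p) + (1 - se) * p
    ppv = se * p / pos if pos > 0 else np.nan
    npv = sp * (1 - p) / neg if neg > 0 else np.nan
    return {"ppv": ppv, "npv": npv, "proportion_flagged": pos}


# -- testing yields ----------------------------------------------------------

def _yield_rows(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["yield"] = np.where(df["prevalence"] > 0, 1.0 / df["prevalence"], np.nan)
    df["estimable"] = df["prevalence"] > 0
    return df


def yields(
    source: CompartmentState | IndividualTable | pd.DataFrame,
    by: list[str] | None = None,
    age_range: tuple[float, float] = DEFAULT_AGE_RANGE,
) -> pd.DataFrame:
    """Testing yield per stratum: persons to test to find one diabetes case.

    For an individual table, strata are the cross-classification of the
    ``by`` columns (default sex and age band). For a compartment state,
    strata follow the single-factor grouping conventional for screening-yield
    charts: per sex and age band, the sub-populations with each risk factor
    and the factor-free sub-population. Yield = 1 / stratum prevalence;
    zero-prevalence strata are flagged not-estimable, empty strata skipped.
    """
    if isinstance(source, CompartmentState):
        return _yields_from_state(source, age_range)
    df = source.data if isinstance(source, IndividualTable) else source
    by = by or ["sex", "age_band"]
    rows = []
    for key, g in df.groupby(by):
        key = key if isinstance(key, tuple) else (key,)
        if len(g) == 0:
            continue
        rows.append(
            dict(zip(by, key), n=len(g), prevalence=float(g["diabetic"].mean()))
        )
    if not rows:
        warnings.warn("no nonempty strata", stacklevel=2)
        return pd.DataFrame(
            columns=[*by, "n", "prevalence", "yield", "estimable"]
        )
    return _yield_rows(rows)


_STATE_GROUPS = {
    "obese": lambda c: bool(c & 1),
    "smoker": lambda c: bool(c & 2),
    "inactive": lambda c: bool(c & 4),
    "no-factor": lambda c: c == 0,
}


def _yields_from_state(
    state: CompartmentState, age_range: tuple[float, float]
) -> pd.DataFrame:
    rows = []
    for sex in (0, 1):
        for band in bands_in_range(*age_range):
            for group, pred in _STATE_GROUPS.items():
                codes = [c for c in range(8) if pred(c)]
                occ = state.occupancy[sex, band, codes, :]
                total = occ.sum()
                if total <= 0:
                    warnings.warn(
                        f"empty stratum sex={sex} band={band} group={group}",
                        stacklevel=3,
                    )
                    continue
                rows.append(
                    {
                        "sex": sex,
                        "age_band": band,
                        "group": group,
                        "n": float(total),
                        "prevalence": float(occ[:, 1].sum() / total),
                    }
                )
    return _yield_rows(rows)


def compare_scores(
    table: IndividualTable | pd.DataFrame,
    definitions: list[ScoreDefinition],
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Apply several score definitions to one table and re-optimise cut-offs.

    Each definition is restricted to the covariables present in the table
    (a definition sharing none raises); the cut-off is re-chosen per score
    by maximising sensitivity + specificity. One row per score: AUC with CI,
    cut-off, sensitivity, specificity.
    """
    df = table.data if isinstance(table, IndividualTable) else table
    labels = df["diabetic"].to_numpy(int)
    available = [c for c in df.columns if c not in ("id", "diabetic")]
    rows = []
    for d in definitions:
        shared = [c for c in d.covariables if c in available]
        restricted = d.restricted(shared)  # raises if no overlap
        scores = apply_score(df, restricted)
        rep = roc_and_auc(scores, labels, n_bootstrap=n_bootstrap, seed=seed)
        conf = optimal_cutoff(scores, labels)
        rows.append(
            {
                "score": d.name,
                "covariables_used": ",".join(shared),
                "AUC": rep.auc,
                "AUC_ci_low": rep.auc_ci[0],
                "AUC_ci_high": rep.auc_ci[1],
                "cutoff": conf.cutoff,
                "sensitivity": conf.se,
                "specificity": conf.sp,
            }
        )
    return pd.DataFrame(rows)


def evaluate_scores(
    scores,
    labels,
    policy: str = "max-se-sp",
    n_bootstrap: int = DEFAULT_BOOTSTRAP,
    seed: int | None = 0,
) -> PerformanceReport:
    """Full report for one score vector under a cut-off policy.

    ``policy`` is ``"max-se-sp"`` (Youden-style), ``"sp-ge:<v>"`` or
    ``"se-ge:<v>"`` for the constrained variants.
    """
    rep = roc_and_auc(scores, labels, n_bootstrap=n_bootstrap, seed=seed)
    if policy == "max-se-sp":
        conf = optimal_cutoff(scores, labels)
    elif policy.startswith("sp-ge:"):
        conf = constrained_cutoff(scores, labels,
                                  min_specificity=float(policy[6:]))
    elif policy.startswith("se-ge:"):
        conf = constrained_cutoff(scores, labels,
                                  min_sensitivity=float(policy[6:]))
    else:
        raise ValueError(f"unknown cutoff policy {policy!r}")
    rep.confusion = conf
    rep.cutoff_policy = policy
    return rep
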