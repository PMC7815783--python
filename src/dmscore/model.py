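"""Age-structured compartmental model of type 2 diabetes and its risk factors.

The population is stratified by sex, twenty five-year age bands, the eight
combinations of three binary risk factors (obesity, daily smoking, physical
inactivity), and diabetes status — 2 x 20 x 8 x 2 = 640 compartments.
Dynamics are deterministic first-order flows (forward Euler): entry into the
youngest band, exponential aging between bands, per-stratum mortality,
one-factor-at-a-time risk-factor onset and reversal, and diabetes incidence
at a baseline hazard multiplied by the relative risk of each factor present.
Diabetes is absorbing.

A light calibration routine adjusts a named subset of the parameters so that
simulated prevalences match user-supplied targets, by bounded least squares.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

N_SEX = 2
N_BANDS = 20
N_PROFILES = 8
FACTORS = ("obese", "smoker", "inactive")
SEX_LABELS = ("female", "male")
QUANTITIES = ("diabetes", "obesity", "smoking", "inactivity")

#: quantity name -> factor index (diabetes handled separately)
_QUANTITY_FACTOR = {"obesity": 0, "smoking": 1, "inactivity": 2}


def band_label(band: int) -> str:
    """Label of a five-year age band, e.g. band 3 -> '15-19'."""
    if not 0 <= band < N_BANDS:
        raise IndexError(f"age band {band} outside 0..{N_BANDS - 1}")
    return f"{5 * band}-{5 * band + 4}"


def bands_in_range(lo: float, hi: float) -> list[int]:
    """Age bands wholly contained in the closed age range [lo, hi]."""
    return [k for k in range(N_BANDS) if 5 * k >= lo and 5 * k + 4 <= hi]


class InvariantViolation(RuntimeError):
    """A model invariant (nonnegativity, step-size bound) was violated."""


class UndefinedPrevalence(ValueError):
    """Prevalence requested over an empty population filter."""


@dataclass(frozen=True)
class RiskProfile:
    """Combination of the three binary risk-factor statuses."""

    obese: bool = False
    smoker: bool = False
    inactive: bool = False

    @property
    def code(self) -> int:
        """3-bit code: bit 0 obesity, bit 1 smoking, bit 2 inactivity."""
        return int(self.obese) | int(self.smoker) << 1 | int(self.inactive) << 2

    @classmethod
    def from_code(cls, code: int) -> "RiskProfile":
        if not 0 <= code < N_PROFILES:
            raise IndexError(f"profile code {code} outside 0..7")
        return cls(bool(code & 1), bool(code & 2), bool(code & 4))

    def has(self, factor: int) -> bool:
        return bool(self.code >> factor & 1)

    def __iter__(self):
        yield from (self.obese, self.smoker, self.inactive)


ALL_PROFILES = tuple(RiskProfile.from_code(c) for c in range(N_PROFILES))
# has-factor masks per factor, indexed by profile code
_PROFILE_HAS = np.array(
    [[bool(c >> f & 1) for c in range(N_PROFILES)] for f in range(3)]
)


@dataclass(frozen=True)
class Stratum:
    """One of the 640 compartments."""

    sex: int  # 0 female, 1 male
    age_band: int
    profile: RiskProfile
    diabetic: bool

    def __post_init__(self):
        if self.sex not in (0, 1):
            raise IndexError(f"sex index {self.sex} not in (0, 1)")
        if not 0 <= self.age_band < N_BANDS:
            raise IndexError(f"age band {self.age_band} outside 0..{N_BANDS - 1}")


@dataclass
class ModelParams:
    """All rates of the compartmental model, in events per person-year.

    Arrays are indexed (sex,), (sex, band[, diabetic]) or (factor, sex, band);
    scalars broadcast on construction via :meth:`from_scalars`.
    """

    entry_rate: np.ndarray  # (2,) persons/year into band 0
    mortality: np.ndarray  # (2, 20, 2) per-capita, diabetes-specific
    onset: np.ndarray  # (3, 2, 20) factor acquisition
    reversal: np.ndarray  # (3, 2, 20) factor loss
    baseline_incidence: np.ndarray  # (2, 20) diabetes hazard, no factors
    rr: np.ndarray  # (3,) relative risk per factor
    aging_rate: float = 0.2  # 1 / five-year band residence

    def __post_init__(self):
        self.entry_rate = np.broadcast_to(
            np.asarray(self.entry_rate, float), (N_SEX,)
        ).copy()
        self.mortality = np.broadcast_to(
            np.asarray(self.mortality, float), (N_SEX, N_BANDS, 2)
        ).copy()
        self.onset = np.broadcast_to(
            np.asarray(self.onset, float), (3, N_SEX, N_BANDS)
        ).copy()
        self.reversal = np.broadcast_to(
            np.asarray(self.reversal, float), (3, N_SEX, N_BANDS)
        ).copy()
        self.baseline_incidence = np.broadcast_to(
            np.asarray(self.baseline_incidence, float), (N_SEX, N_BANDS)
        ).copy()
        self.rr = np.broadcast_to(np.asarray(self.rr, float), (3,)).copy()
        self.validate()

    def validate(self) -> None:
        for name in ("entry_rate", "mortality", "onset", "reversal",
                     "baseline_incidence"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"{name} must be nonnegative")
        if (self.rr <= 0).any():
            raise ValueError("relative risks must be strictly positive")
        if self.aging_rate < 0:
            raise ValueError("aging_rate must be nonnegative")

    @classmethod
    def from_scalars(
        cls,
        entry_rate: float = 0.0,
        mortality: float = 0.0,
        onset: float = 0.0,
        reversal: float = 0.0,
        baseline_incidence: float = 0.0,
        rr: Sequence[float] | float = 1.0,
        aging_rate: float = 0.2,
    ) -> "ModelParams":
        return cls(
            entry_rate=np.asarray(entry_rate, float),
            mortality=np.asarray(mortality, float),
            onset=np.asarray(onset, float),
            reversal=np.asarray(reversal, float),
            baseline_incidence=np.asarray(baseline_incidence, float),
            rr=np.asarray(rr, float),
            aging_rate=aging_rate,
        )

    @classmethod
    def from_dict(cls, cfg: dict) -> "ModelParams":
        """Build from a plain (YAML/JSON-loaded) mapping; scalars broadcast."""
        kwargs = {}
        for key in ("entry_rate", "mortality", "onset", "reversal",
                    "baseline_incidence", "rr"):
            if key in cfg:
                kwargs[key] = np.asarray(cfg[key], float)
        params = cls.from_scalars(aging_rate=float(cfg.get("aging_rate", 0.2)))
        for key, value in kwargs.items():
            setattr(params, key, value)
        params.__post_init__()
        return params

    def copy(self) -> "ModelParams":
        return ModelParams(
            entry_rate=self.entry_rate.copy(),
            mortality=self.mortality.copy(),
            onset=self.onset.copy(),
            reversal=self.reversal.copy(),
            baseline_incidence=self.baseline_incidence.copy(),
            rr=self.rr.copy(),
            aging_rate=self.aging_rate,
        )


@dataclass
class CompartmentState:
    """Occupancy of every compartment at one time point.

    ``occupancy`` has shape (sex, age band, profile code, diabetic) =
    (2, 20, 8, 2); entries are person counts (continuous masses).
    """

    time: float
    occupancy: np.ndarray

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, float)
        if self.occupancy.shape != (N_SEX, N_BANDS, N_PROFILES, 2):
            raise ValueError(
                f"occupancy shape {self.occupancy.shape} != "
                f"{(N_SEX, N_BANDS, N_PROFILES, 2)}"
            )
        if (self.occupancy < 0).any():
            raise InvariantViolation("negative occupancy")

    @classmethod
    def zeros(cls, time: float = 0.0) -> "CompartmentState":
        return cls(time, np.zeros((N_SEX, N_BANDS, N_PROFILES, 2)))

    @property
    def total(self) -> float:
        return float(self.occupancy.sum())

    def get(self, stratum: Stratum) -> float:
        return float(
            self.occupancy[
                stratum.sex, stratum.age_band, stratum.profile.code,
                int(stratum.diabetic),
            ]
        )

    def set(self, stratum: Stratum, count: float) -> None:
        if count < 0:
            raise InvariantViolation("negative occupancy")
        self.occupancy[
            stratum.sex, stratum.age_band, stratum.profile.code,
            int(stratum.diabetic),
        ] = count

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time, sex, age_band, factor flags, diabetic, count."""
        idx = np.indices(self.occupancy.shape).reshape(4, -1)
        sex, band, prof, dia = idx
        return pd.DataFrame(
            {
                "time": self.time,
                "sex": sex,
                "age_band": band,
                "obese": prof & 1,
                "smoker": prof >> 1 & 1,
                "inactive": prof >> 2 & 1,
                "diabetic": dia,
                "count": self.occupancy.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CompartmentState":
        times = frame["time"].unique()
        if len(times) != 1:
            raise ValueError("frame holds more than one time point")
        occ = np.zeros((N_SEX, N_BANDS, N_PROFILES, 2))
        prof = (
            frame["obese"].to_numpy()
            | frame["smoker"].to_numpy() << 1
            | frame["inactive"].to_numpy() << 2
        )
        occ[
            frame["sex"].to_numpy(),
            frame["age_band"].to_numpy(),
            prof,
            frame["diabetic"].to_numpy(),
        ] = frame["count"].to_numpy(float)
        return cls(float(times[0]), occ)


@dataclass(frozen=True)
class PrevalenceTarget:
    """A prevalence the calibrated model should match at a given year."""

    year: float
    quantity: str  # diabetes | obesity | smoking | inactivity
    value: float
    sex: str | None = None
    age_range: tuple[float, float] | None = None
    weight: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("target value must lie in [0, 1]")
        if self.weight < 0:
            raise ValueError("target weight must be nonnegative")
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def incidence_hazard(
    params: ModelParams, sex: int, age_band: int, profile: RiskProfile
) -> float:
    """Diabetes hazard for one stratum: baseline times the product of the
    relative risks of the factors present (multiplicative composition)."""
    if sex not in (0, 1):
        raise IndexError(f"sex index {sex} not in (0, 1)")
    if not 0 <= age_band < N_BANDS:
        raise IndexError(f"age band {age_band} outside 0..{N_BANDS - 1}")
    lam0 = params.baseline_incidence[sex, age_band]
    mult = np.prod([params.rr[f] for f in range(3) if profile.has(f)])
    return float(lam0 * mult)


def _hazard_array(params: ModelParams) -> np.ndarray:
    """Incidence hazard for every (sex, band, profile), shape (2, 20, 8)."""
    rr_prod = np.prod(
        np.where(_PROFILE_HAS, params.rr[:, None], 1.0), axis=0
    )  # (8,)
    return params.baseline_incidence[:, :, None] * rr_prod[None, None, :]


# profile index pairs for one-factor transitions, per factor
_WITHOUT = [np.array([c for c in range(N_PROFILES) if not c >> f & 1])
            for f in range(3)]
_WITH = [_WITHOUT[f] | (1 << f) for f in range(3)]


def _total_outflow_rate(params: ModelParams) -> np.ndarray:
    """Per-capita total outflow rate per compartment, shape (2, 20, 8, 2)."""
    rate = np.zeros((N_SEX, N_BANDS, N_PROFILES, 2))
    rate += params.mortality[:, :, None, :]
    rate[:, : N_BANDS - 1] += params.aging_rate
    for f in range(3):
        rate[:, :, _WITHOUT[f], :] += params.onset[f][:, :, None, None]
        rate[:, :, _WITH[f], :] += params.reversal[f][:, :, None, None]
    rate[:, :, :, 0] += _hazard_array(params)
    return rate


def step(state: CompartmentState, params: ModelParams, dt: float) -> CompartmentState:
    """Advance the state by one forward-Euler step of length ``dt`` years.

    ``dt`` must keep every per-step transition probability at or below one
    (total per-capita outflow rate x dt <= 1), which also guarantees
    nonnegative occupancies.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rate = _total_outflow_rate(params)
    if (rate * dt > 1.0 + 1e-12).any():
        raise InvariantViolation(
            f"dt={dt} makes a per-step transition probability exceed 1 "
            f"(max total rate {rate.max():.3g}/yr); reduce dt"
        )

    N = state.occupancy
    inflow = np.zeros_like(N)
    outflow = N * rate

    # aging k -> k+1 (terminal band retains its members)
    inflow[:, 1:] += N[:, : N_BANDS - 1] * params.aging_rate
    # one-factor onset and reversal
    for f in range(3):
        inflow[:, :, _WITH[f], :] += (
            N[:, :, _WITHOUT[f], :] * params.onset[f][:, :, None, None]
        )
        inflow[:, :, _WITHOUT[f], :] += (
            N[:, :, _WITH[f], :] * params.reversal[f][:, :, None, None]
        )
    # diabetes incidence (absorbing)
    inflow[:, :, :, 1] += N[:, :, :, 0] * _hazard_array(params)

    new = N + dt * (inflow - outflow)
    new[:, 0, 0, 0] += dt * params.entry_rate  # births/entries, factor-free
    if (new < -1e-9 * max(1.0, N.max())).any():
        raise InvariantViolation("negative occupancy after step")
    np.clip(new, 0.0, None, out=new)
    return CompartmentState(state.time + dt, new)


def simulate(
    initial: CompartmentState, params: ModelParams, t_end: float, dt: float = 0.1
) -> list[CompartmentState]:
    """States at initial.time, +dt, ..., t_end (last step shortened if needed)."""
    if t_end <= initial.time:
        raise ValueError("t_end must exceed the initial time")
    states = [initial]
    t = initial.time
    while t < t_end - 1e-12:
        h = min(dt, t_end - t)
        states.append(step(states[-1], params, h))
        t = states[-1].time
    return states


def prevalence(
    state: CompartmentState,
    quantity: str,
    sex: str | int | None = None,
    age_range: tuple[float, float] | None = None,
    profile_filter: Callable[[RiskProfile], bool] | None = None,
) -> float:
    """Proportion of the filtered occupancy with the given quantity."""
    if quantity not in QUANTITIES:
        raise ValueError(f"unknown quantity {quantity!r}")
    occ = state.occupancy
    codes = list(range(N_PROFILES))
    if sex is not None:
        s = SEX_LABELS.index(sex) if isinstance(sex, str) else int(sex)
        occ = occ[s : s + 1]
    if age_range is not None:
        bands = bands_in_range(*age_range)
        if not bands:
            raise UndefinedPrevalence(f"no age band inside {age_range}")
        occ = occ[:, bands]
    if profile_filter is not None:
        codes = [c for c in codes if profile_filter(RiskProfile.from_code(c))]
        occ = occ[:, :, codes]
    total = occ.sum()
    if total <= 0:
        raise UndefinedPrevalence("filtered occupancy is zero")
    if quantity == "diabetes":
        hit = occ[..., 1].sum()
    else:
        f = _QUANTITY_FACTOR[quantity]
        hit = occ[:, :, [i for i, c in enumerate(codes) if c >> f & 1]].sum()
    return float(hit / total)


# -- calibration -------------------------------------------------------------

_KEY_RE = re.compile(r"^(\w+)(?:\[([\d,\s]+)\])?$")

_SCALAR_FIELDS = {"aging_rate"}
_ARRAY_FIELDS = {"entry_rate", "mortality", "onset", "reversal",
                 "baseline_incidence", "rr"}


def _parse_key(key: str) -> tuple[str, tuple[int, ...] | None]:
    m = _KEY_RE.match(key)
    if not m:
        raise KeyError(f"cannot parse free-parameter key {key!r}")
    name, idx = m.group(1), m.group(2)
    if name not in _SCALAR_FIELDS | _ARRAY_FIELDS:
        raise KeyError(f"unknown ModelParams field {name!r}")
    return name, tuple(int(i) for i in idx.split(",")) if idx else None


def _get_param(params: ModelParams, key: str) -> float:
    name, idx = _parse_key(key)
    value = getattr(params, name)
    if idx is None:
        if name in _SCALAR_FIELDS:
            return float(value)
        return float(np.asarray(value).flat[0])  # uniform-array shorthand
    # partial indices address a slice; a uniform slice reads as its first entry
    return float(np.asarray(value[idx]).flat[0])


def _set_param(params: ModelParams, key: str, x: float) -> None:
    name, idx = _parse_key(key)
    if name in _SCALAR_FIELDS:
        setattr(params, name, float(x))
    elif idx is None:
        getattr(params, name)[...] = x  # set the whole array uniformly
    else:
        getattr(params, name)[idx] = x


@dataclass
class CalibrationResult:
    params: ModelParams
    loss: float
    free: dict[str, float] = field(default_factory=dict)
    success: bool = True
    message: str = ""


def _target_residuals(
    initial: CompartmentState,
    params: ModelParams,
    targets: Sequence[PrevalenceTarget],
    dt: float,
) -> np.ndarray:
    t_max = max(t.year for t in targets)
    if t_max > initial.time:
        states = simulate(initial, params, t_max, dt)
    else:
        states = [initial]
    times = np.array([s.time for s in states])
    res = []
    for tg in targets:
        s = states[int(np.argmin(np.abs(times - tg.year)))]
        p = prevalence(s, tg.quantity, sex=tg.sex, age_range=tg.age_range)
        res.append(np.sqrt(tg.weight) * (p - tg.value))
    return np.array(res)


def calibrate(
    initial: CompartmentState,
    params0: ModelParams,
    targets: Sequence[PrevalenceTarget],
    free: dict[str, tuple[float, float]],
    dt: float = 0.1,
) -> CalibrationResult:
    """Fit the named free parameters to the prevalence targets.

    ``free`` maps parameter keys — a field name (uniform fill), or an indexed
    entry like ``"rr[0]"`` or ``"baseline_incidence[1, 10]"`` — to (lo, hi)
    bounds. Minimises the weighted sum of squared prevalence errors with
    bounded least squares from the params0 start; deterministic.
    """
    if not targets:
        raise ValueError("at least one target is required")
    loss0 = float(np.sum(_target_residuals(initial, params0, targets, dt) ** 2))
    if not free:
        return CalibrationResult(params0.copy(), loss0)
    if len(free) > len(targets):
        warnings.warn(
            f"{len(free)} free parameters but only {len(targets)} targets; "
            "the fit may be unidentifiable",
            stacklevel=2,
        )

    keys = list(free)
    lo = np.array([free[k][0] for k in keys])
    hi = np.array([free[k][1] for k in keys])
    x0 = np.clip([_get_param(params0, k) for k in keys], lo, hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        p = params0.copy()
        for k, v in zip(keys, x):
            _set_param(p, k, v)
        return _target_residuals(initial, p, targets, dt)

    sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
    if not sol.success:
        raise RuntimeError(f"calibration failed: {sol.message}")
    fitted = params0.copy()
    for k, v in zip(keys, sol.x):
        _set_param(fitted, k, v)
    loss = float(np.sum(sol.fun**2))
    if loss > loss0 + 1e-15:  # least_squares never worsens its own start
        fitted, loss = params0.copy(), loss0
    return CalibrationResult(
        fitted, loss, dict(zip(keys, map(float, sol.x))), sol.success, sol.message
    )
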