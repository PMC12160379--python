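"""Synthetic lifespan gait dataset with known ground truth.

Emulates the statistical structure of a pooled multi-study joint-power
cohort: participants aged across the lifespan (decade-stratified so the young
and the old are not underrepresented), anthropometry following an age-growth
curve, self-selected walking speed near 1.2 m/s, and per-joint 101-point
power waveforms built as

    template(t) + f_age(age, t) + f_speed(speed, t) + f_strlen(l, t)
    + f_ht(h, t) + f_age,speed(age, speed, t) + b_study(t)
    + sex * beta_sex + iid Gaussian noise,

which is exactly the additive mean structure the function-on-scalar
regression assumes.  Every component is recorded in a :class:`GroundTruth`
object so that estimators can be tested for recovery of known effects.

Templates are sums of Gaussian bumps whose centres, widths and amplitudes are
chosen so each canonical discrete power index region carries its textbook
sign (e.g. a positive ankle push-off burst in pre-swing, a negative knee
extensor burst during loading response).  Covariate effects are smooth
rank-one surfaces: a smooth amplitude profile in the covariate times the
joint's propulsion-burst shape in cycle time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import BSpline
from scipy.stats import truncnorm

from .preprocess import (
    FULL_GRID,
    JOINTS,
    PowerWaveform,
    read_covariates_csv,
    read_waveforms_csv,
    write_covariates_csv,
    write_waveforms_csv,
)

EFFECT_NAMES = ("age", "speed", "stride_length", "height", "age_speed")

#: Lifespan reference grid: one row per decade of life with the representative
#: age and the cohort-mean height and stride length used both to anchor the
#: synthetic growth curves and as the default prediction grid.
DECADE_REFERENCE = pd.DataFrame(
    {
        "decade": np.arange(1, 10),
        "age": [5.0, 15.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 85.0],
        "height_m": [1.04, 1.64, 1.75, 1.73, 1.74, 1.72, 1.70, 1.69, 1.64],
        "stride_length_m": [0.88, 1.34, 1.47, 1.36, 1.30, 1.35, 1.39, 1.29, 1.26],
    }
)

SPEED_MEAN, SPEED_SD = 1.2, 0.2
SPEED_RANGE = (0.5, 2.0)
HEIGHT_JITTER_SD = 0.05
STRIDE_JITTER_SD = 0.08

#: Default constant sex offsets (male minus female), W/kg, per joint.
DEFAULT_BETA_SEX = {"ankle": -0.026, "hip": -0.019, "knee": 0.012}

_COVARIATE_COLUMNS = (
    "participant_id",
    "sex",
    "age",
    "speed",
    "stride_length",
    "height",
    "mass",
    "study_id",
)


def decade_of(age: float) -> int:
    """Decade of life (1-based): 1st is <10 years, 9th is 80+."""
    return int(min(9, age // 10 + 1))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    ``noise_sd`` is the residual standard deviation in W/kg per cycle point
    (the model equation's iid Gaussian error); ``study_sd`` scales the random
    study-intercept curves; ``effect_scale`` multiplies each true covariate
    effect (1.0 keeps the defaults, 0.0 switches an effect off).
    """

    n_participants: int = 200
    age_range: tuple[float, float] = (3.0, 91.0)
    n_studies: int = 6
    seed: int = 0
    noise_sd: float = 0.15
    study_sd: float = 0.10
    effect_scale: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.noise_sd < 0 or self.study_sd < 0:
            raise ValueError("noise_sd and study_sd must be non-negative")
        lo, hi = self.age_range
        if not (3.0 <= lo < hi <= 91.0):
            raise ValueError(f"age_range must satisfy 3 <= lo < hi <= 91, got {self.age_range}")
        unknown = set(self.effect_scale) - set(EFFECT_NAMES)
        if unknown:
            raise ValueError(f"unknown effect_scale keys: {sorted(unknown)}")
        scales = {name: 1.0 for name in EFFECT_NAMES}
        scales.update({k: float(v) for k, v in self.effect_scale.items()})
        object.__setattr__(self, "effect_scale", scales)


@dataclass(frozen=True)
class GaussianBump:
    """A Gaussian bump amplitude * exp(-((t - center)/width)^2 / 2)."""

    center: float
    width: float
    amplitude: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((t - self.center) / self.width) ** 2)


#: Template bumps per joint (percent-of-cycle centre, width, amplitude W/kg).
#: Signs follow the canonical power-index regions: negative ankle absorption in
#: mid/terminal stance then the positive push-off burst; negative knee bursts at
#: loading response, pre-swing and terminal swing around a small positive
#: mid-stance burst; positive hip bursts in early stance and pull-off around a
#: negative mid-stance burst.
TEMPLATE_BUMPS: dict[str, tuple[GaussianBump, ...]] = {
    "ankle": (GaussianBump(35.0, 9.0, -0.7), GaussianBump(55.0, 6.0, 2.3)),
    "knee": (
        GaussianBump(8.0, 4.0, -0.8),
        GaussianBump(20.0, 5.0, 0.5),
        GaussianBump(58.0, 5.0, -1.0),
        GaussianBump(92.0, 4.0, -0.9),
    ),
    "hip": (
        GaussianBump(8.0, 5.0, 0.6),
        GaussianBump(35.0, 8.0, -0.6),
        GaussianBump(62.0, 6.0, 0.8),
    ),
}

#: Unit-height cycle-time shape through which covariate effects act
#: (the joint's main propulsion burst).
EFFECT_TIME_SHAPE: dict[str, GaussianBump] = {
    "ankle": GaussianBump(55.0, 6.0, 1.0),
    "hip": GaussianBump(62.0, 6.0, 1.0),
    "knee": GaussianBump(20.0, 5.0, 1.0),
}

#: Default age-amplitude profiles per joint: ("gauss", centre, scale) gives
#: exp(-((a-centre)/scale)^2); ("tanh", centre, scale) gives tanh((a-centre)/scale).
DEFAULT_AGE_PROFILE: dict[str, tuple[str, float, float]] = {
    "ankle": ("gauss", 25.0, 22.0),
    "hip": ("tanh", 30.0, 20.0),
    "knee": ("gauss", 30.0, 30.0),
}

#: Default effect amplitudes (W/kg at the burst peak per unit profile).
DEFAULT_EFFECT_AMP: dict[str, dict[str, float]] = {
    "age": {"ankle": 0.20, "hip": 0.12, "knee": 0.08},
    "speed": {"ankle": 0.80, "hip": 0.35, "knee": 0.30},
    "stride_length": {"ankle": 0.15, "hip": 0.10, "knee": 0.10},
    "height": {"ankle": 0.10, "hip": 0.10, "knee": 0.10},
    "age_speed": {"ankle": 0.15, "hip": 0.08, "knee": 0.05},
}

STUDY_BASIS_DIM = 8

_COVARIATE_DOMAINS = {
    "speed": SPEED_RANGE,
    "stride_length": (0.3, 2.5),
    "height": (0.6, 2.2),
}


def _age_profile_value(profile: tuple[str, float, float], age: np.ndarray) -> np.ndarray:
    kind, centre, scale = profile
    age = np.asarray(age, dtype=float)
    if kind == "gauss":
        return np.exp(-(((age - centre) / scale) ** 2))
    if kind == "tanh":
        return np.tanh((age - centre) / scale)
    raise ValueError(f"unknown age profile kind {kind!r}")


def _speed_profile(speed: np.ndarray) -> np.ndarray:
    s = np.asarray(speed, dtype=float) - SPEED_MEAN
    return s + 0.15 * s**2


def _study_basis(t: np.ndarray) -> np.ndarray:
    lo, hi = float(FULL_GRID[0]), float(FULL_GRID[-1])
    interior = np.linspace(lo, hi, STUDY_BASIS_DIM - 2)
    knots = np.r_[[lo] * 3, interior, [hi] * 3]
    return BSpline.design_matrix(np.asarray(t, dtype=float), knots, 3).toarray()


def _decade_windows(age_range: tuple[float, float]) -> list[tuple[int, float, float]]:
    lo, hi = age_range
    windows = []
    for d in range(1, 10):
        d_lo = 0.0 if d == 1 else 10.0 * (d - 1)
        d_hi = hi if d == 9 else 10.0 * d
        w_lo, w_hi = max(d_lo, lo), min(d_hi, hi)
        if w_lo < w_hi:
            windows.append((d, w_lo, w_hi))
    return windows


def _growth_curve(age: np.ndarray, decade_means: np.ndarray) -> np.ndarray:
    """Piecewise-linear age curve: plateaus at the decade mean inside each
    decade with 1-year ramps across decade boundaries, so the average over a
    decade matches the anchor value."""
    xs, ys = [3.0], [decade_means[0]]
    for d in range(1, 9):  # boundaries at ages 10, 20, ..., 80
        b = 10.0 * d
        xs += [b - 0.5, b + 0.5]
        ys += [decade_means[d - 1], decade_means[d]]
    xs.append(91.0)
    ys.append(decade_means[-1])
    return np.interp(np.asarray(age, dtype=float), xs, ys)


@dataclass
class GroundTruth:
    """The exact data-generating components of the synthetic cohort.

    All effect surfaces are rank-one: ``amp * (profile(x) - centre) * shape(t)``
    with the centring constant chosen so the effect is approximately mean-zero
    over the covariate sampling distribution, mirroring the sum-to-zero
    identifiability constraints of the fitted model.
    """

    template_bumps: dict[str, tuple[GaussianBump, ...]]
    effect_shape: dict[str, GaussianBump]
    effect_amp: dict[str, dict[str, float]]
    age_profile: dict[str, tuple[str, float, float]]
    center_const: dict[str, float]
    beta_sex: dict[str, float]
    study_coefs: dict[str, np.ndarray]  # joint -> (n_studies, STUDY_BASIS_DIM)
    age_domain: tuple[float, float]

    # -- evaluation ---------------------------------------------------------

    def template(self, joint: str, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return sum(b(t) for b in self.template_bumps[joint])

    def _profile(self, effect: str, joint: str, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if effect == "age":
            g = _age_profile_value(self.age_profile[joint], x)
        elif effect == "speed":
            g = _speed_profile(x)
        elif effect == "stride_length":
            g = x - 1.3
        elif effect == "height":
            g = x - 1.6
        else:
            raise ValueError(f"unknown effect {effect!r}")
        return g - self.center_const[effect if effect != "age" else f"age_{joint}"]

    def effect_surface(self, effect: str, joint: str, x, t) -> np.ndarray:
        """Bivariate effect f_effect(x, t) on the grid outer(x, t)."""
        prof = np.atleast_1d(self._profile(effect, joint, x))
        shape = self.effect_shape[joint](t)
        return self.effect_amp[effect][joint] * np.multiply.outer(prof, shape)

    def interaction_surface(self, joint: str, age, speed, t) -> np.ndarray:
        a = np.atleast_1d(self._profile("age", joint, age))
        s = np.atleast_1d(np.asarray(speed, dtype=float) - SPEED_MEAN)
        shape = self.effect_shape[joint](t)
        return self.effect_amp["age_speed"][joint] * np.multiply.outer(a * s, shape)

    def study_curve(self, joint: str, study_index: int, t: np.ndarray) -> np.ndarray:
        coefs = self.study_coefs[joint]
        if not 0 <= study_index < coefs.shape[0]:
            raise ValueError(f"unknown study index {study_index}")
        return _study_basis(t) @ coefs[study_index]

    def total_effect(self, record: Mapping, joint: str, t: np.ndarray) -> np.ndarray:
        """Sum of all covariate effect terms at one participant's covariates."""
        out = np.zeros(np.asarray(t).shape, dtype=float)
        for effect in ("age", "speed", "stride_length", "height"):
            key = {"stride_length": "stride_length", "height": "height"}.get(effect, effect)
            out += self.effect_surface(effect, joint, record[key], t)[0]
        out += self.interaction_surface(joint, record["age"], record["speed"], t)[0]
        return out

    def mean_waveform(self, record: Mapping, joint: str, t: np.ndarray) -> np.ndarray:
        study_index = int(str(record["study_id"]).removeprefix("study")) - 1
        sex_num = 1.0 if record["sex"] == "male" else 0.0
        return (
            self.template(joint, t)
            + self.total_effect(record, joint, t)
            + self.study_curve(joint, study_index, t)
            + sex_num * self.beta_sex[joint]
        )

    def true_curve(self, joint: str, *, age, speed, stride_length, height, sex, t) -> np.ndarray:
        """Population-level mean curve (no study term) at given covariates."""
        record = {
            "age": age,
            "speed": speed,
            "stride_length": stride_length,
            "height": height,
        }
        sex_num = 1.0 if sex == "male" else 0.0
        return (
            self.template(joint, t)
            + self.total_effect(record, joint, t)
            + sex_num * self.beta_sex[joint]
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "template_bumps": {
                j: [[b.center, b.width, b.amplitude] for b in bumps]
                for j, bumps in self.template_bumps.items()
            },
            "effect_shape": {
                j: [b.center, b.width, b.amplitude] for j, b in self.effect_shape.items()
            },
            "effect_amp": {e: dict(v) for e, v in self.effect_amp.items()},
            "age_profile": {j: list(v) for j, v in self.age_profile.items()},
            "center_const": dict(self.center_const),
            "beta_sex": dict(self.beta_sex),
            "study_coefs": {j: c.tolist() for j, c in self.study_coefs.items()},
            "age_domain": list(self.age_domain),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        return cls(
            template_bumps={
                j: tuple(GaussianBump(*b) for b in bumps)
                for j, bumps in d["template_bumps"].items()
            },
            effect_shape={j: GaussianBump(*b) for j, b in d["effect_shape"].items()},
            effect_amp={e: dict(v) for e, v in d["effect_amp"].items()},
            age_profile={j: (v[0], float(v[1]), float(v[2])) for j, v in d["age_profile"].items()},
            center_const={k: float(v) for k, v in d["center_const"].items()},
            beta_sex={j: float(v) for j, v in d["beta_sex"].items()},
            study_coefs={j: np.asarray(c, dtype=float) for j, c in d["study_coefs"].items()},
            age_domain=tuple(d["age_domain"]),
        )


def _centering_constants(
    config: GeneratorConfig, age_profile: Mapping[str, tuple[str, float, float]]
) -> dict[str, float]:
    """Approximate population means of each amplitude profile under the
    decade-stratified covariate distribution, used to centre the true effects."""
    windows = _decade_windows(config.age_range)
    ages = np.concatenate([np.linspace(lo, hi, 200) for _, lo, hi in windows])
    consts: dict[str, float] = {}
    for joint in JOINTS:
        consts[f"age_{joint}"] = float(np.mean(_age_profile_value(age_profile[joint], ages)))
    a, b = (np.array(SPEED_RANGE) - SPEED_MEAN) / SPEED_SD
    sgrid = np.linspace(*SPEED_RANGE, 400)
    w = truncnorm.pdf(sgrid, a, b, loc=SPEED_MEAN, scale=SPEED_SD)
    consts["speed"] = float(np.trapezoid(_speed_profile(sgrid) * w, sgrid))
    heights = _growth_curve(ages, DECADE_REFERENCE["height_m"].to_numpy())
    strides = _growth_curve(ages, DECADE_REFERENCE["stride_length_m"].to_numpy())
    consts["stride_length"] = float(np.mean(strides) - 1.3)
    consts["height"] = float(np.mean(heights) - 1.6)
    return consts


def make_ground_truth(
    config: GeneratorConfig,
    *,
    beta_sex: Mapping[str, float] | None = None,
    template_bumps: Mapping[str, Sequence[GaussianBump]] | None = None,
    effect_amp: Mapping[str, Mapping[str, float]] | None = None,
    age_profile: Mapping[str, tuple[str, float, float]] | None = None,
) -> GroundTruth:
    """Construct the ground truth for a configuration.

    Study-intercept spline coefficients are drawn (zero-mean Gaussian, scale
    ``config.study_sd``) from a stream derived from ``config.seed``; all other
    components are deterministic.  Keyword overrides replace the defaults for
    recovery experiments with bespoke truths.
    """
    rng = np.random.default_rng([config.seed, 17])
    study_coefs = {
        j: config.study_sd * rng.standard_normal((config.n_studies, STUDY_BASIS_DIM))
        for j in JOINTS
    }
    profiles = dict(DEFAULT_AGE_PROFILE)
    if age_profile:
        profiles.update(age_profile)
    amps = {e: dict(v) for e, v in DEFAULT_EFFECT_AMP.items()}
    if effect_amp:
        for e, v in effect_amp.items():
            amps[e].update(v)
    for e in EFFECT_NAMES:
        amps[e] = {j: a * config.effect_scale[e] for j, a in amps[e].items()}
    betas = dict(DEFAULT_BETA_SEX)
    if beta_sex:
        betas.update(beta_sex)
    bumps = {j: tuple(b) for j, b in TEMPLATE_BUMPS.items()}
    if template_bumps:
        bumps.update({j: tuple(b) for j, b in template_bumps.items()})
    return GroundTruth(
        template_bumps=bumps,
        effect_shape=dict(EFFECT_TIME_SHAPE),
        effect_amp=amps,
        age_profile=profiles,
        center_const=_centering_constants(config, profiles),
        beta_sex=betas,
        study_coefs=study_coefs,
        age_domain=config.age_range,
    )


def simulate_covariates(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the participant covariate table.

    Ages are decade-stratified (round-robin over the decades intersecting the
    configured range); height and stride length follow the piecewise-linear
    growth curves anchored at the decade means, plus Gaussian jitter; walking
    speed is truncated-normal around 1.2 m/s on [0.5, 2.0]; body mass comes
    from height via a truncated-normal body-mass index; studies are assigned
    in balanced random order.
    """
    if config.n_participants < config.n_studies:
        raise ValueError(
            f"n_participants ({config.n_participants}) must be >= n_studies "
            f"({config.n_studies}) so every study is populated"
        )
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_participants
    windows = _decade_windows(config.age_range)
    ages = np.empty(n)
    for i in range(n):
        _, lo, hi = windows[i % len(windows)]
        ages[i] = rng.uniform(lo, hi)
    heights = _growth_curve(ages, DECADE_REFERENCE["height_m"].to_numpy())
    heights = heights + rng.normal(0.0, HEIGHT_JITTER_SD, n)
    strides = _growth_curve(ages, DECADE_REFERENCE["stride_length_m"].to_numpy())
    strides = strides + rng.normal(0.0, STRIDE_JITTER_SD, n)
    a, b = (np.array(SPEED_RANGE) - SPEED_MEAN) / SPEED_SD
    speeds = truncnorm.rvs(a, b, loc=SPEED_MEAN, scale=SPEED_SD, size=n, random_state=rng)
    sex = rng.choice(["male", "female"], size=n)
    bmi = np.clip(rng.normal(21.0, 2.5, n), 13.0, 35.0)
    mass = bmi * heights**2
    study_index = rng.permutation(n) % config.n_studies
    return pd.DataFrame(
        {
            "participant_id": [f"P{i + 1:04d}" for i in range(n)],
            "sex": sex,
            "age": ages,
            "speed": speeds,
            "stride_length": np.clip(strides, *_COVARIATE_DOMAINS["stride_length"]),
            "height": np.clip(heights, *_COVARIATE_DOMAINS["height"]),
            "mass": mass,
            "study_id": [f"study{j + 1}" for j in study_index],
        }
    )


def simulate_waveforms(
    covariates: pd.DataFrame,
    truth: GroundTruth,
    config: GeneratorConfig,
    joints: Sequence[str] = JOINTS,
) -> list[PowerWaveform]:
    """Generate one full-cycle waveform per participant and joint.

    The waveform is the exact ground-truth mean at the participant's
    covariates plus iid Gaussian noise of scale ``config.noise_sd``.  Ankle
    waveforms are produced on the full 101-point grid; subsetting to 25–75 is
    a preprocessing step, matching the analysis order of operations.
    """
    rng = np.random.default_rng([config.seed, 2])
    lo, hi = truth.age_domain
    t = FULL_GRID
    out: list[PowerWaveform] = []
    for record in covariates.to_dict("records"):
        study_index = int(str(record["study_id"]).removeprefix("study")) - 1
        if not 0 <= study_index < config.n_studies:
            raise ValueError(f"unknown study_id {record['study_id']!r}")
        if not lo <= record["age"] <= hi:
            raise ValueError(f"age {record['age']} outside truth domain [{lo}, {hi}]")
        for name, dom in _COVARIATE_DOMAINS.items():
            if not dom[0] <= record[name] <= dom[1]:
                raise ValueError(f"{name} {record[name]} outside truth domain {dom}")
        for joint in joints:
            values = truth.mean_waveform(record, joint, t)
            if config.noise_sd > 0:
                values = values + rng.normal(0.0, config.noise_sd, t.size)
            out.append(
                PowerWaveform(
                    participant_id=str(record["participant_id"]),
                    study_id=str(record["study_id"]),
                    joint=joint,
                    grid=t.copy(),
                    values=values,
                )
            )
    return out


def simulate_dataset(
    config: GeneratorConfig,
    *,
    joints: Sequence[str] = JOINTS,
    **truth_overrides,
) -> tuple[pd.DataFrame, list[PowerWaveform], GroundTruth]:
    """Convenience wrapper: covariates, waveforms and the truth in one call."""
    truth = make_ground_truth(config, **truth_overrides)
    covs = simulate_covariates(config)
    waveforms = simulate_waveforms(covs, truth, config, joints=joints)
    return covs, waveforms, truth


def export_dataset(
    waveforms: Sequence[PowerWaveform],
    covariates: pd.DataFrame,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write waveforms.csv, covariates.csv and truth.yaml into ``out_dir``."""
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {out_dir}")
    known = set(covariates["participant_id"].astype(str))
    orphans = sorted({w.participant_id for w in waveforms} - known)
    if orphans:
        raise ValueError(f"waveforms reference unknown participants: {orphans[:5]}")
    paths = {
        "waveforms": out_dir / "waveforms.csv",
        "covariates": out_dir / "covariates.csv",
        "truth": out_dir / "truth.yaml",
    }
    write_waveforms_csv(waveforms, paths["waveforms"])
    write_covariates_csv(covariates, paths["covariates"])
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth.to_dict(), fh)
    return paths


def load_dataset(
    data_dir: str | Path,
) -> tuple[list[PowerWaveform], pd.DataFrame, GroundTruth | None]:
    """Read back a dataset written by :func:`export_dataset`."""
    data_dir = Path(data_dir)
    waveforms = read_waveforms_csv(data_dir / "waveforms.csv")
    covariates = read_covariates_csv(data_dir / "covariates.csv")
    truth = None
    truth_path = data_dir / "truth.yaml"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = GroundTruth.from_dict(yaml.safe_load(fh))
    return waveforms, covariates, truth
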