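"""Preprocessing of gait joint-power signals.

Turns per-stride joint moment / angular-velocity recordings into the
analysis-ready set of mass-normalised power waveforms the regression model
consumes.  The steps, in pipeline order:

1. :func:`compute_power` — scalar joint power as the dot product of the net
   joint moment and the joint angular velocity, sample by sample (W).
2. :func:`time_normalize` — resample one stride (between two consecutive
   initial contacts of the same limb) onto 101 equally spaced cycle points.
3. :func:`mass_normalize` — divide by body mass (W/kg).
4. :func:`average_strides_limbs` — pointwise mean over all strides of both
   limbs for one participant and joint.
5. :func:`subset_ankle` — restrict ankle waveforms to cycle points 25–75
   (51 points); ankle power outside that range is essentially zero, so the
   model for the ankle is fitted on the subset only.

Cycle-point indexing is 0-based over 0..100, i.e. percent of the gait cycle;
"points 25 to 75" are the percent labels 25–75 inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

JOINTS = ("hip", "knee", "ankle")

#: Full gait-cycle grid: 0..100 percent in steps of 1.
FULL_GRID = np.arange(101.0)

#: Ankle analysis window (inclusive percent-of-cycle labels).
ANKLE_WINDOW = (25, 75)

#: Minimum samples per stride for cubic interpolation; below this a linear
#: interpolant is used instead.
CUBIC_MIN_SAMPLES = 10


@dataclass
class PowerWaveform:
    """One joint's power curve for one participant, in W/kg.

    ``grid`` holds percent-of-cycle labels: 0..100 for hip/knee (101 points)
    or 25..75 for the ankle after subsetting (51 points).
    """

    participant_id: str
    study_id: str
    joint: str
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}; expected one of {JOINTS}")
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(
                f"non-finite power values for participant {self.participant_id}, joint {self.joint}"
            )


@dataclass
class RawStride:
    """Raw per-stride recording of one joint on one limb.

    ``joint_moment`` (N·m) and ``joint_angular_velocity`` (rad/s) are
    (n_samples, n_axes) arrays sharing shape; ``event_indices`` are sample
    indices of initial contacts, consecutive pairs delimiting strides.
    """

    participant_id: str
    limb: str
    joint: str
    sample_times: np.ndarray
    joint_moment: np.ndarray
    joint_angular_velocity: np.ndarray
    event_indices: Sequence[int] = field(default_factory=tuple)
    body_mass: float = 1.0

    def __post_init__(self) -> None:
        if self.limb not in ("left", "right"):
            raise ValueError(f"limb must be 'left' or 'right', got {self.limb!r}")
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}")
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.joint_moment = np.atleast_2d(np.asarray(self.joint_moment, dtype=float))
        self.joint_angular_velocity = np.atleast_2d(
            np.asarray(self.joint_angular_velocity, dtype=float)
        )
        if self.joint_moment.shape[0] == 1 and self.sample_times.size == 1:
            # single-sample input supplied as a flat axis vector
            pass
        elif self.joint_moment.shape[0] != self.sample_times.size:
            # accept (n_axes, n_samples) written transposed only when unambiguous
            raise ValueError("joint_moment must have one row per sample")
        if self.joint_moment.shape != self.joint_angular_velocity.shape:
            raise ValueError("moment and angular-velocity series must share shape")
        if self.sample_times.size > 1 and not np.all(np.diff(self.sample_times) > 0):
            raise ValueError("sample_times must be strictly increasing")
        self.event_indices = tuple(int(i) for i in self.event_indices)
        for i in self.event_indices:
            if not 0 <= i < self.sample_times.size:
                raise ValueError(f"event index {i} outside the sampled series")
        if self.body_mass <= 0:
            raise ValueError(f"body_mass must be positive, got {self.body_mass}")


def compute_power(stride: RawStride) -> np.ndarray:
    """Scalar joint power (W): per-sample dot product of moment and angular velocity."""
    return np.einsum("ij,ij->i", stride.joint_moment, stride.joint_angular_velocity)


def time_normalize(
    series: np.ndarray,
    event_pair: tuple[int, int],
    sample_times: np.ndarray | None = None,
) -> np.ndarray:
    """Resample one stride onto 101 equally spaced cycle points.

    The stride spans ``series[i0 .. i1]`` where ``event_pair = (i0, i1)`` are
    the sample indices of two consecutive initial contacts.  Interpolation is
    cubic, falling back to linear when the stride holds fewer than
    ``CUBIC_MIN_SAMPLES`` samples.  The first and last output points equal the
    samples at the contacts exactly.
    """
    series = np.asarray(series, dtype=float)
    i0, i1 = (int(e) for e in event_pair)
    if not 0 <= i0 < series.size and 0 <= i1 < series.size:
        raise ValueError(f"event pair {event_pair} outside series of length {series.size}")
    if i1 <= i0:
        raise ValueError(f"events out of order: {event_pair}")
    if i1 >= series.size:
        raise ValueError(f"event index {i1} outside series of length {series.size}")
    n_seg = i1 - i0 + 1
    if n_seg < 4:
        raise ValueError(f"too few samples between events ({n_seg}); need at least 4")
    if sample_times is None:
        t_seg = np.arange(i0, i1 + 1, dtype=float)
    else:
        sample_times = np.asarray(sample_times, dtype=float)
        t_seg = sample_times[i0 : i1 + 1]
    y_seg = series[i0 : i1 + 1]
    t_out = np.linspace(t_seg[0], t_seg[-1], 101)
    if n_seg >= CUBIC_MIN_SAMPLES:
        out = CubicSpline(t_seg, y_seg)(t_out)
    else:
        out = np.interp(t_out, t_seg, y_seg)
    # guard the endpoint contract against interpolation round-off
    out[0], out[-1] = y_seg[0], y_seg[-1]
    return out


def mass_normalize(curve: np.ndarray, mass: float) -> np.ndarray:
    """Convert W to W/kg by pointwise division by body mass."""
    if mass <= 0:
        raise ValueError(f"body mass must be positive, got {mass}")
    return np.asarray(curve, dtype=float) / mass


def average_strides_limbs(curves: Sequence[np.ndarray]) -> np.ndarray:
    """Pointwise mean over all strides of both limbs (any number >= 1)."""
    if len(curves) == 0:
        raise ValueError("cannot average an empty group of strides")
    arrs = [np.asarray(c, dtype=float) for c in curves]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("all strides must share the same cycle grid")
    return np.mean(arrs, axis=0)


def subset_ankle(waveform: PowerWaveform) -> PowerWaveform:
    """Restrict a full-cycle ankle waveform to cycle points 25–75 (51 points)."""
    if waveform.joint != "ankle":
        raise ValueError(
            f"ankle subsetting applies only to the ankle, got joint {waveform.joint!r}"
        )
    if waveform.grid.size != FULL_GRID.size or not np.array_equal(waveform.grid, FULL_GRID):
        raise ValueError("ankle subsetting expects the full 101-point cycle grid")
    lo, hi = ANKLE_WINDOW
    mask = (waveform.grid >= lo) & (waveform.grid <= hi)
    return PowerWaveform(
        participant_id=waveform.participant_id,
        study_id=waveform.study_id,
        joint=waveform.joint,
        grid=waveform.grid[mask],
        values=waveform.values[mask],
    )


def prepare_waveforms(waveforms: Iterable[PowerWaveform]) -> list[PowerWaveform]:
    """Analysis-ready waveform set: ankle subset to 25–75, hip/knee untouched."""
    out = []
    for w in waveforms:
        if w.joint == "ankle" and w.grid.size == FULL_GRID.size:
            out.append(subset_ankle(w))
        else:
            out.append(w)
    return out


def strides_to_waveforms(
    strides: Sequence[RawStride], study_id: str
) -> list[PowerWaveform]:
    """Full per-stride pipeline, grouped by participant and joint.

    For every stride delimited by consecutive initial contacts: power, time
    normalisation, mass normalisation; then the mean over all strides of both
    limbs per participant/joint.
    """
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    for s in strides:
        power = compute_power(s)
        for i0, i1 in zip(s.event_indices[:-1], s.event_indices[1:]):
            curve = time_normalize(power, (i0, i1), s.sample_times)
            curve = mass_normalize(curve, s.body_mass)
            groups.setdefault((s.participant_id, s.joint), []).append(curve)
    out = []
    for (pid, joint), curves in sorted(groups.items()):
        out.append(
            PowerWaveform(
                participant_id=pid,
                study_id=study_id,
                joint=joint,
                grid=FULL_GRID.copy(),
                values=average_strides_limbs(curves),
            )
        )
    return out


# ---------------------------------------------------------------------------
# dataset I/O (long-format waveform CSV, covariate CSV, raw stride CSV)
# ---------------------------------------------------------------------------

WAVEFORM_COLUMNS = ("participant_id", "study_id", "joint", "cycle_point", "power_wkg")


def waveforms_to_frame(waveforms: Iterable[PowerWaveform]) -> pd.DataFrame:
    rows = []
    for w in waveforms:
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": w.participant_id,
                    "study_id": w.study_id,
                    "joint": w.joint,
                    "cycle_point": w.grid.astype(int),
                    "power_wkg": w.values,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=list(WAVEFORM_COLUMNS))
    return pd.concat(rows, ignore_index=True)


def frame_to_waveforms(df: pd.DataFrame) -> list[PowerWaveform]:
    missing = set(WAVEFORM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"waveform table is missing columns: {sorted(missing)}")
    out = []
    for (pid, sid, joint), g in df.groupby(
        ["participant_id", "study_id", "joint"], sort=True
    ):
        g = g.sort_values("cycle_point")
        out.append(
            PowerWaveform(
                participant_id=str(pid),
                study_id=str(sid),
                joint=str(joint),
                grid=g["cycle_point"].to_numpy(dtype=float),
                values=g["power_wkg"].to_numpy(dtype=float),
            )
        )
    return out


def write_waveforms_csv(waveforms: Iterable[PowerWaveform], path: str | Path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    waveforms_to_frame(waveforms).to_csv(path, index=False, float_format="%.17g")


def read_waveforms_csv(path: str | Path) -> list[PowerWaveform]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"waveform file does not exist: {path}")
    return frame_to_waveforms(pd.read_csv(path, float_precision="round_trip"))


def write_covariates_csv(covariates: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory does not exist: {path.parent}")
    covariates.to_csv(path, index=False, float_format="%.17g")


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"covariate file does not exist: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def read_raw_strides_csv(path: str | Path) -> list[RawStride]:
    """Read a wide per-axis raw stride table.

    Expected columns: participant_id, limb, joint, body_mass_kg, time_s,
    moment_x/y/z (N·m), angvel_x/y/z (rad/s), initial_contact (0/1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raw stride file does not exist: {path}")
    df = pd.read_csv(path)
    required = {"participant_id", "limb", "joint", "body_mass_kg", "time_s", "initial_contact"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"raw stride table is missing columns: {sorted(missing)}")
    axes = sorted(c.removeprefix("moment_") for c in df.columns if c.startswith("moment_"))
    if not axes:
        raise ValueError("raw stride table has no moment_<axis> columns")
    strides = []
    for (pid, limb, joint), g in df.groupby(["participant_id", "limb", "joint"], sort=True):
        g = g.sort_values("time_s")
        strides.append(
            RawStride(
                participant_id=str(pid),
                limb=str(limb),
                joint=str(joint),
                sample_times=g["time_s"].to_numpy(),
                joint_moment=np.column_stack([g[f"moment_{a}"] for a in axes]),
                joint_angular_velocity=np.column_stack([g[f"angvel_{a}"] for a in axes]),
                event_indices=np.flatnonzero(g["initial_contact"].to_numpy() > 0),
                body_mass=float(g["body_mass_kg"].iloc[0]),
            )
        )
    return strides
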