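"""Discrete joint-power indices of the gait cycle (Winter's A1–H3).

The nine canonical peaks of the sagittal lower-limb power curves during
walking: two at the ankle (A1 eccentric plantar-flexor absorption in mid/
terminal stance, A2 the concentric push-off burst in pre-swing), four at the
knee (K1 loading-response absorption, K2 mid-stance generation, K3 pre-swing
absorption by rectus femoris, K4 terminal-swing hamstring absorption) and
three at the hip (H1 early-stance extensor generation — not always present —
H2 mid-stance absorption, H3 pre/initial-swing flexor "pull-off" generation).

The numeric cycle windows encode standard gait-phase boundaries; the
literature names only the phases, so the windows are a design choice and are
overridable (see :func:`default_definitions`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import PowerWaveform

POSITIVE_MAX = "positive_max"
NEGATIVE_MIN = "negative_min"

#: Default windows (percent-of-cycle, inclusive) and polarities per label.
DEFAULT_WINDOWS: dict[str, tuple[str, tuple[int, int], str]] = {
    "A1": ("ankle", (10, 45), NEGATIVE_MIN),
    "A2": ("ankle", (40, 65), POSITIVE_MAX),
    "K1": ("knee", (0, 15), NEGATIVE_MIN),
    "K2": ("knee", (10, 40), POSITIVE_MAX),
    "K3": ("knee", (45, 70), NEGATIVE_MIN),
    "K4": ("knee", (85, 100), NEGATIVE_MIN),
    "H1": ("hip", (0, 20), POSITIVE_MAX),
    "H2": ("hip", (20, 50), NEGATIVE_MIN),
    "H3": ("hip", (50, 75), POSITIVE_MAX),
}

#: Below this magnitude (W/kg) a peak is flagged absent (H1 in particular is
#: not always present).
DEFAULT_ABSENCE_EPSILON = 0.01

QC_OK = "ok"
QC_WRONG_SIGN = "wrong_sign"
QC_ABSENT = "absent"


@dataclass(frozen=True)
class DiscreteIndexDefinition:
    label: str
    joint: str
    window: tuple[int, int]
    polarity: str

    def __post_init__(self) -> None:
        lo, hi = self.window
        if lo > hi:
            raise ValueError(f"window out of order for {self.label}: {self.window}")
        if self.polarity not in (POSITIVE_MAX, NEGATIVE_MIN):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass(frozen=True)
class DiscreteIndexValue:
    label: str
    value: float
    cycle_location: int
    qc_flag: str


def default_definitions(
    window_overrides: Mapping[str, Sequence[int]] | None = None,
) -> tuple[DiscreteIndexDefinition, ...]:
    """The nine index definitions, optionally with per-label window overrides."""
    overrides = {k: tuple(int(x) for x in v) for k, v in (window_overrides or {}).items()}
    unknown = set(overrides) - set(DEFAULT_WINDOWS)
    if unknown:
        raise ValueError(f"unknown index labels in window overrides: {sorted(unknown)}")
    defs = []
    for label, (joint, window, polarity) in DEFAULT_WINDOWS.items():
        defs.append(
            DiscreteIndexDefinition(
                label=label,
                joint=joint,
                window=overrides.get(label, window),
                polarity=polarity,
            )
        )
    return tuple(defs)


def extract(
    waveform: PowerWaveform,
    defn: DiscreteIndexDefinition,
    absence_epsilon: float = DEFAULT_ABSENCE_EPSILON,
) -> DiscreteIndexValue:
    """Extremum of the waveform over the index window.

    The value is the max (``positive_max``) or min (``negative_min``) over the
    cycle points falling inside the window; ties break to the earliest point.
    QC: ``wrong_sign`` when the extremum's sign contradicts the polarity,
    ``absent`` when its magnitude is below ``absence_epsilon``.
    """
    if waveform.joint != defn.joint:
        raise ValueError(
            f"index {defn.label} is defined for the {defn.joint}, got a "
            f"{waveform.joint} waveform"
        )
    lo, hi = defn.window
    mask = (waveform.grid >= lo) & (waveform.grid <= hi)
    if not mask.any():
        raise ValueError(
            f"window {defn.window} of {defn.label} does not intersect the "
            f"waveform grid [{waveform.grid[0]:g}, {waveform.grid[-1]:g}]"
        )
    vals = waveform.values[mask]
    pts = waveform.grid[mask]
    # argmax/argmin return the first occurrence: earliest-point tie-break
    i = int(np.argmax(vals)) if defn.polarity == POSITIVE_MAX else int(np.argmin(vals))
    value = float(vals[i])
    if abs(value) < absence_epsilon:
        qc = QC_ABSENT
    elif (defn.polarity == POSITIVE_MAX) != (value > 0):
        qc = QC_WRONG_SIGN
    else:
        qc = QC_OK
    return DiscreteIndexValue(
        label=defn.label, value=value, cycle_location=int(pts[i]), qc_flag=qc
    )


def extract_all(
    waveforms: Iterable[PowerWaveform],
    definitions: Sequence[DiscreteIndexDefinition] | None = None,
    absence_epsilon: float = DEFAULT_ABSENCE_EPSILON,
) -> pd.DataFrame:
    """Index table: one row per waveform x applicable label, deterministic order."""
    defs = definitions if definitions is not None else default_definitions()
    rows = []
    for w in sorted(waveforms, key=lambda w: (w.participant_id, w.joint)):
        for d in defs:
            if d.joint != w.joint:
                continue
            v = extract(w, d, absence_epsilon)
            rows.append(
                {
                    "participant_id": w.participant_id,
                    "joint": w.joint,
                    "label": v.label,
                    "value_wkg": v.value,
                    "cycle_location": v.cycle_location,
                    "qc_flag": v.qc_flag,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "joint", "label", "value_wkg", "cycle_location", "qc_flag"],
    )


def extract_from_matrix(
    curves: np.ndarray, grid: np.ndarray, defn: DiscreteIndexDefinition
) -> np.ndarray:
    """Vectorised index values for a stack of curves (n_curves, n_points).

    Used for posterior-draw confidence intervals where one index is read off
    thousands of simulated curves at once.  Matches :func:`extract` values.
    """
    lo, hi = defn.window
    mask = (np.asarray(grid) >= lo) & (np.asarray(grid) <= hi)
    if not mask.any():
        raise ValueError(f"window {defn.window} does not intersect the grid")
    sub = np.asarray(curves)[:, mask]
    return sub.max(axis=1) if defn.polarity == POSITIVE_MAX else sub.min(axis=1)
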