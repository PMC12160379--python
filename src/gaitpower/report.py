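"""Reporting layer: lifespan prediction grid, peak trajectories, run bundle.

Because the coefficient surfaces of a functional additive model are hard to
read directly, results are reported as predicted mean waveforms on a fixed
covariate grid — nine decades of life (represented by their midpoint age and
the cohort-mean height and stride length for that decade) crossed with three
walking speeds (0.8, 1.2, 1.4 m/s), sex fixed to male — and as the discrete
power-index peaks of those predicted curves, with 95% confidence intervals
obtained by posterior simulation of whole curves and re-extraction of each
index from every simulated curve (the delta method is unreliable at a
non-smooth argmax, so simulation is used).
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fosr import FittedFoSR
from .synthetic import DECADE_REFERENCE
from .winter import (
    DiscreteIndexDefinition,
    default_definitions,
    extract,
    extract_from_matrix,
)
from .preprocess import PowerWaveform

log = logging.getLogger(__name__)

PREDICTION_SPEEDS = (0.8, 1.2, 1.4)


def default_grid(speeds: Sequence[float] = PREDICTION_SPEEDS) -> pd.DataFrame:
    """The lifespan prediction grid: 9 decades x len(speeds) rows per joint.

    Heights and stride lengths are the decade-mean reference values; the
    representative age is the decade midpoint; sex is fixed to male.
    """
    rows = []
    for _, ref in DECADE_REFERENCE.iterrows():
        for speed in speeds:
            rows.append(
                {
                    "decade": int(ref["decade"]),
                    "age": float(ref["age"]),
                    "height": float(ref["height_m"]),
                    "stride_length": float(ref["stride_length_m"]),
                    "sex": "male",
                    "speed": float(speed),
                }
            )
    return pd.DataFrame(rows)


def peak_trajectories(
    fit: FittedFoSR,
    grid: pd.DataFrame | None = None,
    definitions: Sequence[DiscreteIndexDefinition] | None = None,
    n_draws: int = 4000,
    seed: int = 0,
    smoothing_uncertainty: bool = True,
) -> pd.DataFrame:
    """Index peaks of population-level predicted curves across the grid.

    For every grid row the population mean curve (study curves excluded) is
    predicted; each index defined for the fitted joint is extracted from it,
    and its 95% CI is the 2.5/97.5 percentile of the index re-extracted from
    ``n_draws`` posterior curve draws.  QC flags from the mean-curve
    extraction are recorded, never dropped.
    """
    if grid is None:
        grid = default_grid()
    defs = [
        d
        for d in (definitions if definitions is not None else default_definitions())
        if d.joint == fit.joint
    ]
    if not defs:
        raise ValueError(f"no index definitions for joint {fit.joint!r}")
    pred = fit.predict(grid, include_study=False, with_se=False)
    mean_curves = pred["mean"]
    X = fit.design.row_design(grid, include_study=False)
    draws = fit.posterior_draws(n_draws, seed, smoothing_uncertainty=smoothing_uncertainty)
    curves = (X @ draws.T).T.reshape(n_draws, len(grid), fit.design.n_points)

    rows = []
    for i, grow in grid.reset_index(drop=True).iterrows():
        wave = PowerWaveform(
            participant_id="grid",
            study_id="population",
            joint=fit.joint,
            grid=fit.design.grid,
            values=mean_curves[i],
        )
        for d in defs:
            val = extract(wave, d)
            sims = extract_from_matrix(curves[:, i, :], fit.design.grid, d)
            lo, hi = (
                np.percentile(sims, [2.5, 97.5]) if n_draws > 0 else (np.nan, np.nan)
            )
            rows.append(
                {
                    "joint": fit.joint,
                    "label": d.label,
                    "decade": int(grow["decade"]) if "decade" in grow else i,
                    "age": float(grow["age"]),
                    "speed": float(grow["speed"]),
                    "mean_wkg": val.value,
                    "lower_wkg": float(lo),
                    "upper_wkg": float(hi),
                    "cycle_location": val.cycle_location,
                    "qc_flag": val.qc_flag,
                    "extrapolated": bool(pred["extrapolated"][i]),
                }
            )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _plot_predictions(fit: FittedFoSR, grid: pd.DataFrame, path: Path) -> None:
    speeds = sorted(grid["speed"].unique())
    fig, axes = plt.subplots(1, len(speeds), figsize=(4 * len(speeds), 3.2), sharey=True)
    axes = np.atleast_1d(axes)
    cmap = plt.get_cmap("viridis")
    for ax, speed in zip(axes, speeds):
        sub = grid[grid["speed"] == speed].reset_index(drop=True)
        pred = fit.predict(sub, include_study=False, with_se=False)
        for i, row in sub.iterrows():
            ax.plot(
                fit.design.grid,
                pred["mean"][i],
                color=cmap((row["decade"] - 1) / 8.0),
                label=f"{int(row['decade'])}",
            )
        ax.set_title(f"{fit.joint}, {speed} m/s")
        ax.set_xlabel("gait cycle (%)")
    axes[0].set_ylabel("power (W/kg)")
    axes[-1].legend(title="decade", fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report(
    fits: Mapping[str, FittedFoSR],
    trajectories: pd.DataFrame,
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    grid: pd.DataFrame | None = None,
    model_paths: Mapping[str, str | Path] | None = None,
) -> dict:
    """Write the report bundle; returns the manifest dictionary.

    Contents: per-joint trajectory CSVs, the pooled trajectories.csv, a
    sex-effect table (estimate, t, p per joint), predicted-curve plots per
    decade and speed, and a manifest (config echo, seed, library versions,
    output hashes) sufficient to reproduce the run.
    """
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {out_dir}")
    if grid is None:
        grid = default_grid()

    manifest: dict = {
        "gaitpower_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": seed,
        "config": dict(config) if config else None,
        "outputs": {},
        "no_results": trajectories.empty,
    }

    traj_path = out_dir / "trajectories.csv"
    trajectories.to_csv(traj_path, index=False)
    manifest["outputs"]["trajectories.csv"] = _sha256(traj_path)
    if trajectories.empty:
        log.warning("no trajectory results to report; writing empty bundle")

    sex_rows = []
    for joint, fit in sorted(fits.items()):
        test = fit.sex_effect_test()
        sex_rows.append(
            {
                "joint": joint,
                "estimate_wkg": test.estimate,
                "se_wkg": test.se,
                "t": test.tstat,
                "p": test.pvalue,
                "df": test.df,
            }
        )
        if not trajectories.empty:
            jt = trajectories[trajectories["joint"] == joint]
            jt.to_csv(out_dir / f"trajectories_{joint}.csv", index=False)
            manifest["outputs"][f"trajectories_{joint}.csv"] = _sha256(
                out_dir / f"trajectories_{joint}.csv"
            )
        plot_path = out_dir / f"predicted_{joint}.png"
        _plot_predictions(fit, grid, plot_path)
        manifest["outputs"][f"predicted_{joint}.png"] = _sha256(plot_path)
    sex_path = out_dir / "sex_effects.csv"
    pd.DataFrame(
        sex_rows, columns=["joint", "estimate_wkg", "se_wkg", "t", "p", "df"]
    ).to_csv(sex_path, index=False)
    manifest["outputs"]["sex_effects.csv"] = _sha256(sex_path)

    if model_paths:
        manifest["model_bundles"] = {
            joint: {"path": str(p), "sha256": _sha256(Path(p))}
            for joint, p in sorted(model_paths.items())
        }

    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
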