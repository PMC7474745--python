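"""Train/test protocol, accuracy metrics, and the end-to-end pipeline.

The assessment protocol mirrors the measurement study: pool the
angle-torque samples of all runs, draw a random 500-sample training
subset, fit the network, and score the held-out remainder per world-axis
component with

* MAV — mean absolute value of the true torque component (N·m),
* MSE — mean squared prediction error,
* RE  — the ratio MSE / MAV.

MSE is reported on the N·m scale as the protocol prints it; note RE is
then not dimensionless — it is kept as defined rather than silently
converted to an RMSE ratio, and the MAV in the denominator is that of the
true torques.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .bpann import LMMLPRegressor
from .robot_model import RobotParams, external_wrench, forward_kinematics
from .shoulder_kinematics import SphereFit, fit_sphere, globographic_angles
from .statics import (OrthosisParams, compensate_orthosis, flange_speeds,
                      moving_average, passive_torque, repeatability_check)

__all__ = [
    "SplitSpec",
    "MetricReport",
    "PipelineConfig",
    "PipelineError",
    "split",
    "metrics",
    "process_log",
    "run_pipeline",
]

logger = logging.getLogger("shoulder_torque")

_AXES = ("x", "y", "z")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test split: ``n_train`` samples drawn uniformly
    without replacement, seeded."""

    n_train: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train <= 0:
            raise ValueError("n_train must be positive")


def split(samples: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition ``samples`` into a seeded uniform random training subset
    of size ``spec.n_train`` and its complement (the test set).  The two
    parts are disjoint and exhaustive."""
    n = len(samples)
    if spec.n_train >= n:
        raise ValueError(f"n_train={spec.n_train} must be smaller than the sample count {n}")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[: spec.n_train])
    test_idx = np.sort(perm[spec.n_train:])
    return samples.iloc[train_idx].reset_index(drop=True), samples.iloc[test_idx].reset_index(drop=True)


@dataclass(frozen=True)
class MetricReport:
    """Per-component MAV / MSE / RE.  ``re_undefined`` flags components
    whose MAV is zero (RE reported as NaN)."""

    mav: np.ndarray
    mse: np.ndarray
    re: np.ndarray
    re_undefined: np.ndarray
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "n_samples": int(self.n_samples),
            "per_axis": {
                axis: {
                    "mav": float(self.mav[k]),
                    "mse": float(self.mse[k]),
                    "re": None if self.re_undefined[k] else float(self.re[k]),
                }
                for k, axis in enumerate(_AXES)
            },
        }

    def to_text(self) -> str:
        """Table rounded to 3 decimals, matching the usual presentation."""
        lines = ["axis     MAV      MSE       RE"]
        for k, axis in enumerate(_AXES):
            re = "nan" if self.re_undefined[k] else f"{self.re[k]:.4f}"
            lines.append(f"{axis}    {self.mav[k]:8.3f} {self.mse[k]:8.3f}   {re}")
        return "\n".join(lines)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def metrics(y_true, y_pred) -> MetricReport:
    """Per-component MAV of the true torques, MSE of the prediction, and
    RE = MSE / MAV (NaN-flagged where MAV is zero)."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yt.ndim == 1:
        yt, yp = yt[:, None], yp[:, None]
    if yt.shape != yp.shape or yt.shape[0] < 1:
        raise ValueError("y_true and y_pred must be nonempty and of equal shape")
    mav = np.mean(np.abs(yt), axis=0)
    mse = np.mean((yp - yt) ** 2, axis=0)
    undefined = mav == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        re = np.where(undefined, np.nan, mse / np.where(undefined, 1.0, mav))
    return MetricReport(mav=mav, mse=mse, re=re, re_undefined=undefined, n_samples=yt.shape[0])


# ------------------------------------------------------------------ pipeline

@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the logs themselves."""

    robot: RobotParams
    reference_axes: np.ndarray
    radius: float
    elbow_in_flange: np.ndarray
    orthosis: OrthosisParams
    window: int = 25                  # moving-average, samples (0.5 s at 50 Hz)
    fit_fraction: float = 0.7         # former part of each run used for sphere fitting
    speed_threshold: float = 0.1      # quasi-static gate, m/s
    repeatability_tol: float = 0.1
    n_train: int = 500
    n_hidden: int = 9
    seed: int = 0
    training: dict = dc_field(default_factory=dict)   # extra LMMLPRegressor kwargs


@dataclass
class RunResult:
    """One processed run: posture + torque samples and the sphere fit."""

    frame: pd.DataFrame               # t, plane, elevation, mx, my, mz, speed, quasi_static
    sphere: SphereFit


def process_log(log: pd.DataFrame, config: PipelineConfig) -> RunResult:
    """Kinematics + statics for one robot log.

    Order fixed: the external joint torques are smoothed first, then the
    wrench is recovered sample by sample, orthosis gravity removed, and
    the passive torque taken about the sphere-fit center.  The sphere is
    fitted on the former ``fit_fraction`` of the elbow trajectory, where
    the fixed-center assumption holds best.
    """
    try:
        q = log[[f"q{j + 1}" for j in range(7)]].to_numpy(dtype=float)
        tau = log[[f"tau_e{j + 1}" for j in range(7)]].to_numpy(dtype=float)
        t = log["t"].to_numpy(dtype=float)
    except KeyError as exc:
        raise PipelineError("parse", f"log is missing column {exc}") from exc

    tau_s = moving_average(tau, config.window)
    n = len(t)
    poses = [forward_kinematics(q[i], config.robot) for i in range(n)]
    elbow_world = np.array([p.apply(config.elbow_in_flange) for p in poses])

    n_fit = max(4, int(np.ceil(config.fit_fraction * n)))
    try:
        sphere = fit_sphere(elbow_world[:n_fit])
    except Exception as exc:
        raise PipelineError("sphere_fit", str(exc)) from exc

    torque = np.empty((n, 3))
    plane = np.empty(n)
    elevation = np.empty(n)
    degenerate = np.zeros(n, dtype=bool)
    for i in range(n):
        w = external_wrench(q[i], tau_s[i], config.robot)
        w = compensate_orthosis(w, poses[i], config.orthosis)
        torque[i] = passive_torque(w, poses[i], sphere.center)
        posture = globographic_angles(elbow_world[i], sphere, timestamp=t[i])
        plane[i], elevation[i] = posture.plane_of_elevation, posture.elevation
        degenerate[i] = posture.degenerate

    speeds = flange_speeds(t, np.array([p.translation for p in poses]))
    frame = pd.DataFrame({
        "t": t, "plane": plane, "elevation": elevation,
        "mx": torque[:, 0], "my": torque[:, 1], "mz": torque[:, 2],
        "speed": speeds,
        "quasi_static": speeds <= config.speed_threshold,
        "degenerate": degenerate,
    })
    return RunResult(frame=frame, sphere=sphere)


@dataclass
class PipelineResult:
    samples: pd.DataFrame
    train: pd.DataFrame
    test: pd.DataFrame
    model: LMMLPRegressor
    report: MetricReport
    runs: list


def run_pipeline(trajectories, config: PipelineConfig, out_dir=None) -> PipelineResult:
    """Chain every stage on one or more trajectories.

    ``trajectories`` is a list whose items are either a single robot-log
    DataFrame or a ``(repeat1, repeat2)`` pair; pairs are subjected to the
    repeatability check (the pipeline aborts on failure, repeat 1 then
    supplies the data).  Artifacts (posture CSV, torque CSV, model JSON,
    history CSV, metric report JSON) are written to ``out_dir`` when
    given.  The result is fully determined by (logs, config).
    """
    runs: list[RunResult] = []
    for k, item in enumerate(trajectories):
        if isinstance(item, (tuple, list)):
            rep1, rep2 = item
            r1 = process_log(rep1, config)
            r2 = process_log(rep2, config)
            check = repeatability_check(r1.frame, r2.frame, tol=config.repeatability_tol)
            logger.info("[repeatability] trajectory %d rms fraction %.4f (tol %.2f)",
                        k, check.rms_fraction, check.tol)
            if not check.passed:
                raise PipelineError(
                    "repeatability",
                    f"trajectory {k}: rms fraction {check.rms_fraction:.4f} exceeds "
                    f"tolerance {check.tol}; data invalid",
                )
            runs.append(r1)
        else:
            runs.append(process_log(item, config))
        logger.info("[statics] trajectory %d: %d samples, sphere rms %.2e m",
                    k, len(runs[-1].frame), runs[-1].sphere.rms_residual)

    samples = pd.concat([r.frame for r in runs], ignore_index=True)
    train, test = split(samples, SplitSpec(n_train=config.n_train, seed=config.seed))
    X_cols, Y_cols = ["plane", "elevation"], ["mx", "my", "mz"]
    model = LMMLPRegressor(n_hidden=config.n_hidden, random_state=config.seed,
                           **config.training)
    model.fit(train[X_cols].to_numpy(), train[Y_cols].to_numpy())
    logger.info("[train] H=%d epochs=%d goal_met=%s final_mse=%.2e",
                config.n_hidden, model.n_iter_, model.goal_met_, model.final_mse_)
    y_pred = model.predict(test[X_cols].to_numpy())
    report = metrics(test[Y_cols].to_numpy(), y_pred)
    logger.info("[evaluate]\n%s", report.to_text())

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        posture = pd.DataFrame({
            "timestamp": samples["t"],
            "plane_of_elevation_deg": np.rad2deg(samples["plane"]),
            "elevation_deg": np.rad2deg(samples["elevation"]),
        })
        posture.to_csv(out / "postures.csv", index=False)
        torque = pd.DataFrame({
            "timestamp": samples["t"],
            "plane_deg": np.rad2deg(samples["plane"]),
            "elevation_deg": np.rad2deg(samples["elevation"]),
            "MPx": samples["mx"], "MPy": samples["my"], "MPz": samples["mz"],
        })
        torque.to_csv(out / "passive_torque.csv", index=False)
        model.save(out / "model.json")
        model.history_.to_frame().to_csv(out / "training_history.csv", index=False)
        report.save(out / "metrics.json")

    return PipelineResult(samples=samples, train=train, test=test, model=model,
                          report=report, runs=runs)
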