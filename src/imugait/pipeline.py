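"""End-to-end processing: simulate/load -> calibrate -> fuse -> joints ->
(optional) correction -> agreement report.

Mirrors the on-device processing order: the first ``calibration_window``
seconds of every trial calibrate each IMU, the fused sagittal inclinations
feed the trigonometric joint equations, and the optional regression stage
corrects each joint using [angle, angular velocity] inputs.  Everything is
deterministic for a fixed config (one seed drives simulation noise,
regression initialization and fold shuffling), so two runs of the same
config produce byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as gio
from .calibration import calibrate_trial
from .correction import DriftCorrector, apply_correction
from .kinematics import JointAngleSeries, SegmentOrientationSeries, joint_angles
from .metrics import agreement_report
from .orientation import estimate_segment_angles
from .synthetic import SensorParams, default_profile, inject_turn, simulate_trial

log = logging.getLogger("imugait")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``trial_path`` points at an existing trial CSV, or a synthetic
    trial is generated from the terrain/speed/noise settings.
    """

    out_dir: str = "pipeline_out"
    trial_path: str | None = None
    # simulation settings (used when trial_path is None)
    fs: float = 100.0
    terrain: str = "flat"
    speed: str = "normal"
    n_cycles: int = 10
    gyro_noise_sd: float = 0.2      # deg/s
    acc_noise_sd: float = 0.01      # g
    gyro_bias: tuple = (0.5, 1.0, -0.5)  # deg/s
    drift_slope: float = 0.0        # deg/s
    turn_at: float | None = None    # s
    turn_multiplier: float = 2.0
    # processing settings
    method: str = "complementary"
    filter_params: dict = field(default_factory=dict)
    correction: dict | None = None  # DriftCorrector kwargs, e.g. {"kind": "nn"}
    xapen_m: int = 2
    xapen_r: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs > 200:
            raise ValueError("fs must be <= 200 Hz")


def _side_joints(seg_est, fs, side, motion) -> JointAngleSeries:
    needed = [("trunk", "center"), ("thigh", side), ("shank", side), ("foot", side)]
    missing = [k for k in needed if k not in seg_est]
    if missing:
        raise ValueError(f"cannot compute {side} joint angles: "
                         f"missing sensors {missing}")
    seg = SegmentOrientationSeries(
        trunk=seg_est[("trunk", "center")][motion],
        thigh=seg_est[("thigh", side)][motion],
        shank=seg_est[("shank", side)][motion],
        foot=seg_est[("foot", side)][motion],
        fs=fs, side=side)
    return joint_angles(seg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the report plus output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- acquire ---------------------------------------------------------
    if config.trial_path is not None:
        trial = gio.read_trial(config.trial_path)
        log.info("loaded trial %s (%d samples)", config.trial_path, len(trial))
    else:
        profile = default_profile(config.terrain, config.speed, config.n_cycles)
        sensor = SensorParams(
            fs=config.fs, gyro_noise_sd=config.gyro_noise_sd,
            acc_noise_sd=config.acc_noise_sd, gyro_bias=config.gyro_bias,
            drift_slope=config.drift_slope, seed=config.seed)
        trial = simulate_trial(profile, sensor)
        if config.turn_at is not None:
            trial = inject_turn(trial, config.turn_at, config.turn_multiplier)
        log.info("simulated %s/%s trial: %d samples at %g Hz",
                 config.terrain, config.speed, len(trial), trial.fs)
    trial_csv = gio.write_trial(trial, out / "trial.csv")

    # --- calibrate (first window is the static prelude) ------------------
    states = calibrate_trial(trial)
    calib_path = gio.write_calibration(states, out / "calib.yaml")
    log.info("calibration done for %d sensors", len(states))

    # --- fuse -------------------------------------------------------------
    seg_est = estimate_segment_angles(trial, states, method=config.method,
                                      filter_params=config.filter_params)
    seg_path = gio.write_segments(seg_est, trial.t, out / "segments.csv")

    # --- joint angles (motion phase) --------------------------------------
    motion = trial.motion_slice()
    sides = sorted({side for seg, side in trial.sensors if seg == "thigh"})
    joints = {side: _side_joints(seg_est, trial.fs, side, motion)
              for side in sides}
    joints_path = gio.write_joints(joints, out / "joints.csv")

    paths = {"trial": str(trial_csv), "calibration": str(calib_path),
             "segments": str(seg_path), "joints": str(joints_path)}

    # --- reference (simulation ground truth) -------------------------------
    truth = trial.meta.get("truth_joints")
    report: dict = {"method": config.method, "seed": config.seed}
    corrected = None
    if truth is not None:
        gio.write_joints(truth, out / "ref.csv")
        paths["reference"] = str(out / "ref.csv")

        # --- optional regression correction --------------------------------
        if config.correction is not None:
            kwargs = dict(config.correction)
            kwargs.setdefault("seed", config.seed)
            models = {}
            for joint in ("hip", "knee", "ankle"):
                X = np.vstack([
                    np.column_stack([getattr(joints[s], joint),
                                     joints[s].angular_velocity(joint)])
                    for s in sides])
                y = np.concatenate([getattr(truth[s], joint) for s in sides])
                models[joint] = DriftCorrector(**kwargs).fit(X, y)
            corrected = {s: apply_correction(models, joints[s]) for s in sides}
            paths["corrected"] = str(
                gio.write_joints(corrected, out / "corrected.csv"))

        # --- agreement metrics --------------------------------------------
        t = joints[sides[0]].t
        for side in sides:
            for joint in ("hip", "knee", "ankle"):
                test = getattr(joints[side], joint)
                ref = getattr(truth[side], joint)
                rep = agreement_report(test, ref, t, config.xapen_m,
                                       config.xapen_r)
                report[f"{side}_{joint}"] = rep.as_dict()
                if corrected is not None:
                    rep_c = agreement_report(
                        getattr(corrected[side], joint), ref, t,
                        config.xapen_m, config.xapen_r)
                    report[f"{side}_{joint}_corrected"] = rep_c.as_dict()

    paths["report"] = str(gio.write_report(report, out / "report.yaml"))
    return {"report": report, "paths": paths}
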