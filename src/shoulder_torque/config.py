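"""YAML configuration for the pipeline (robot geometry, calibration pose,
orthosis model, filtering, split and training settings)."""

from __future__ import annotations

import numpy as np
import yaml

from .evaluation import PipelineConfig
from .robot_model import RobotParams
from .statics import OrthosisParams
from .synthetic_data import default_scene, default_orthosis

__all__ = ["default_config", "load_config", "save_config"]


def default_config(seed: int = 0) -> PipelineConfig:
    """Pipeline configuration matching the standard synthetic scene."""
    scene = default_scene()
    return PipelineConfig(
        robot=scene.robot,
        reference_axes=scene.reference_axes,
        radius=scene.radius,
        elbow_in_flange=scene.elbow_in_flange,
        orthosis=default_orthosis(),
        seed=seed,
    )


def save_config(config: PipelineConfig, path) -> None:
    doc = {
        "robot": config.robot.to_dict(),
        "calibration": {
            "reference_axes": np.asarray(config.reference_axes, float).tolist(),
            "radius": float(config.radius),
            "elbow_in_flange": np.asarray(config.elbow_in_flange, float).tolist(),
        },
        "orthosis": {
            "mass": float(config.orthosis.mass),
            "com_in_flange": config.orthosis.com_in_flange.tolist(),
        },
        "filter": {"window": config.window},
        "sphere": {"fit_fraction": config.fit_fraction},
        "quasi_static": {"speed_threshold": config.speed_threshold},
        "repeatability": {"tol": config.repeatability_tol},
        "split": {"n_train": config.n_train, "seed": config.seed},
        "network": {"n_hidden": config.n_hidden, **config.training},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    net = dict(doc.get("network", {}))
    n_hidden = int(net.pop("n_hidden", 9))
    return PipelineConfig(
        robot=RobotParams.from_dict(doc["robot"]),
        reference_axes=np.asarray(doc["calibration"]["reference_axes"], float),
        radius=float(doc["calibration"]["radius"]),
        elbow_in_flange=np.asarray(doc["calibration"]["elbow_in_flange"], float),
        orthosis=OrthosisParams(
            mass=float(doc["orthosis"]["mass"]),
            com_in_flange=np.asarray(doc["orthosis"]["com_in_flange"], float),
        ),
        window=int(doc.get("filter", {}).get("window", 25)),
        fit_fraction=float(doc.get("sphere", {}).get("fit_fraction", 0.7)),
        speed_threshold=float(doc.get("quasi_static", {}).get("speed_threshold", 0.1)),
        repeatability_tol=float(doc.get("repeatability", {}).get("tol", 0.1)),
        n_train=int(doc.get("split", {}).get("n_train", 500)),
        seed=int(doc.get("split", {}).get("seed", 0)),
        n_hidden=n_hidden,
        training=net,
    )
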