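"""On-disk formats: transforms and lines as JSON, datasets as PNG+CSV+JSON.

A dataset directory holds::

    frames/00000.png ...   8-bit grayscale frames
    labels.csv             frame_id,u,v (ground-truth centroids)
    poses.json             per-frame noiseless and noisy needle lines
    calibration_gt.json    ground-truth transform (16-element row-major)
    config.yaml            echo of the generating PhantomConfig

Transforms serialise as ``{"matrix": [...16 floats...]}`` plus a named
decomposition; lines as ``{"tip": [x,y,z], "direction": [x,y,z]}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .geometry import NeedleLine, PixelPoint, RigidScaledTransform
from .phantom import AnnotatedFrame, PhantomConfig

__all__ = [
    "transform_to_dict", "transform_from_dict",
    "save_transform", "load_transform",
    "line_to_dict", "line_from_dict",
    "write_dataset", "read_dataset",
    "write_pairs", "read_pairs",
]


# -- transforms -------------------------------------------------------------

def transform_to_dict(T: RigidScaledTransform) -> dict:
    return {
        "matrix": [float(x) for x in T.matrix.ravel()],  # row-major
        "decomposition": {
            "rotation": T.rotation.tolist(),
            "scales": T.scales.tolist(),
            "translation": T.translation.tolist(),
        },
    }


def transform_from_dict(d: dict) -> RigidScaledTransform:
    return RigidScaledTransform(np.array(d["matrix"], dtype=float).reshape(4, 4))


def save_transform(T: RigidScaledTransform, path) -> None:
    Path(path).write_text(json.dumps(transform_to_dict(T), indent=2))


def load_transform(path) -> RigidScaledTransform:
    return transform_from_dict(json.loads(Path(path).read_text()))


# -- lines ------------------------------------------------------------------

def line_to_dict(line: NeedleLine) -> dict:
    return {"tip": line.tip.tolist(), "direction": line.direction.tolist()}


def line_from_dict(d: dict) -> NeedleLine:
    return NeedleLine(d["tip"], d["direction"])


# -- point-line pairs -------------------------------------------------------

def write_pairs(pairs, path) -> None:
    """pairs.json: list of {point: [u, v], line: {tip, direction}}."""
    payload = [
        {"point": [p.point.u, p.point.v], "line": line_to_dict(p.line)}
        for p in pairs
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_pairs(path):
    from .calibration import PointLinePair

    payload = json.loads(Path(path).read_text())
    return [
        PointLinePair(
            PixelPoint(float(d["point"][0]), float(d["point"][1])),
            line_from_dict(d["line"]),
        )
        for d in payload
    ]


# -- datasets ---------------------------------------------------------------

def write_dataset(
    directory,
    frames: Sequence[AnnotatedFrame],
    T_gt: RigidScaledTransform,
    config: PhantomConfig,
) -> Path:
    directory = Path(directory)
    (directory / "frames").mkdir(parents=True, exist_ok=True)
    rows = []
    poses = []
    for f in frames:
        Image.fromarray(f.image, mode="L").save(
            directory / "frames" / f"{f.frame_id:05d}.png"
        )
        rows.append({"frame_id": f.frame_id, "u": f.label.u, "v": f.label.v})
        poses.append(
            {
                "frame_id": f.frame_id,
                "pose": line_to_dict(f.pose),
                "noisy_pose": line_to_dict(f.noisy_pose),
                "insertion_angle": f.insertion_angle,
                "heading": f.heading,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "labels.csv", index=False)
    (directory / "poses.json").write_text(json.dumps(poses, indent=2))
    save_transform(T_gt, directory / "calibration_gt.json")
    (directory / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    return directory


def read_dataset(directory) -> Tuple[List[AnnotatedFrame], RigidScaledTransform, PhantomConfig]:
    directory = Path(directory)
    config = PhantomConfig(**yaml.safe_load((directory / "config.yaml").read_text()))
    # YAML round-trips tuples as lists
    config = PhantomConfig(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in config.to_dict().items()
        }
    )
    T_gt = load_transform(directory / "calibration_gt.json")
    labels = pd.read_csv(directory / "labels.csv").set_index("frame_id")
    poses = {p["frame_id"]: p for p in json.loads((directory / "poses.json").read_text())}
    frames = []
    for png in sorted((directory / "frames").glob("*.png")):
        fid = int(png.stem)
        image = np.asarray(Image.open(png).convert("L"))
        p = poses[fid]
        frames.append(
            AnnotatedFrame(
                image=image,
                label=PixelPoint(float(labels.loc[fid, "u"]), float(labels.loc[fid, "v"])),
                pose=line_from_dict(p["pose"]),
                noisy_pose=line_from_dict(p["noisy_pose"]),
                insertion_angle=float(p["insertion_angle"]),
                heading=float(p["heading"]),
                frame_id=fid,
            )
        )
    return frames, T_gt, config
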