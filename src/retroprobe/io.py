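"""File formats: TIFF stacks with sidecar calibration, recordings, ROIs.

Stacks travel as multi-page TIFF arranged ``(z, channel, y, x)`` with a
JSON sidecar (``<name>.json``) holding ``pixel_size_um`` and
``z_step_um`` so the physical calibration round-trips bit-exactly.
Recordings are NumPy ``.npz`` containers with an embedded JSON header
(sampling rate, channel map, step annotations, stimulus events).  ROI
polygons import/export as two-column CSV (``x_px,y_px``) or as the plain
whitespace-separated XY coordinate lists ImageJ writes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ephys import DepthStep, ElectrodeInfo, RecordingBlock, StimulusEvent
from .trauma import FluorescenceStack, ROIPolygon

__all__ = [
    "write_stack",
    "read_stack",
    "write_recording",
    "read_recording",
    "write_roi_csv",
    "read_roi_csv",
    "write_roi_imagej",
    "read_roi_imagej",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: FluorescenceStack, path: str | Path) -> Path:
    """Write a two-channel stack as multi-page TIFF + JSON calibration sidecar."""
    path = Path(path)
    data = np.stack([stack.green, stack.red], axis=1).astype(np.float32)  # (z, c, y, x)
    tifffile.imwrite(path, data, metadata={"axes": "ZCYX"})
    _sidecar(path).write_text(
        json.dumps(
            {
                "pixel_size_um": stack.pixel_size_um,
                "z_step_um": stack.z_step_um,
                "channels": ["green", "red"],
            },
            indent=1,
        )
    )
    return path


def read_stack(path: str | Path) -> FluorescenceStack:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 3:  # single z-plane collapses the leading axis
        data = data[None]
    meta = json.loads(_sidecar(path).read_text())
    return FluorescenceStack(
        green=data[:, 0].astype(float),
        red=data[:, 1].astype(float),
        pixel_size_um=meta["pixel_size_um"],
        z_step_um=meta["z_step_um"],
    )


def write_recording(block: RecordingBlock, path: str | Path) -> Path:
    """Write a recording as .npz with an embedded JSON header."""
    path = Path(path)
    header = {
        "fs_hz": block.fs_hz,
        "electrodes": [
            {
                "shank": e.shank,
                "index": e.index,
                "role": e.role,
                "diameter_um": e.diameter_um,
            }
            for e in block.electrodes
        ],
        "steps": [
            {"index": s.index, "t_start_s": s.t_start_s, "t_stop_s": s.t_stop_s}
            for s in block.steps
        ],
        "stimuli": [
            {
                "onset_s": ev.onset_s,
                "duration_s": ev.duration_s,
                "irradiance_uw_mm2": ev.irradiance_uw_mm2,
            }
            for ev in block.stimuli
        ],
    }
    np.savez_compressed(
        path, traces_uv=block.traces_uv, header=np.str_(json.dumps(header))
    )
    return path


def read_recording(path: str | Path) -> RecordingBlock:
    with np.load(path, allow_pickle=False) as z:
        traces = z["traces_uv"]
        header = json.loads(str(z["header"]))
    return RecordingBlock(
        traces_uv=traces,
        fs_hz=header["fs_hz"],
        electrodes=[ElectrodeInfo(**e) for e in header["electrodes"]],
        steps=[DepthStep(**s) for s in header["steps"]],
        stimuli=[StimulusEvent(**s) for s in header["stimuli"]],
    )


def write_roi_csv(roi: ROIPolygon, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(roi.vertices, columns=["x_px", "y_px"]).to_csv(path, index=False)
    return path


def read_roi_csv(path: str | Path, provenance: str = "manual-import") -> ROIPolygon:
    df = pd.read_csv(path)
    return ROIPolygon(df[["x_px", "y_px"]].to_numpy(float), provenance=provenance)


def write_roi_imagej(roi: ROIPolygon, path: str | Path) -> Path:
    """Plain-text XY coordinate list, one ``x<TAB>y`` pair per line."""
    path = Path(path)
    lines = [f"{x:.4f}\t{y:.4f}" for x, y in roi.vertices]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_roi_imagej(path: str | Path, provenance: str = "manual-import") -> ROIPolygon:
    rows = [
        [float(v) for v in line.split()]
        for line in Path(path).read_text().strip().splitlines()
        if line.strip()
    ]
    return ROIPolygon(np.asarray(rows, dtype=float), provenance=provenance)
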