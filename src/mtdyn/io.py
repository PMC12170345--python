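"""Readers and writers for the package's on-disk formats.

Trajectories, spots and FRAP traces travel as CSV (pandas); kymographs
and spot fields as 16-bit TIFF (tifffile); protofilament models as the
plain-text contour format implemented in :mod:`mtdyn.flare`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .mtsim import DEFAULT_FRAME_INTERVAL, DEFAULT_PIXEL_SIZE, KymographImage, Trajectory
from .photometry import FRAPTrace, SpotRecord


def write_trajectory_csv(path, traj: Trajectory) -> None:
    df = pd.DataFrame({"time_s": traj.times, "position_um": traj.positions})
    if traj.true_states is not None:
        df["true_state"] = traj.true_states
    df.to_csv(path, index=False)


def read_trajectory_csv(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(
        times=df["time_s"].to_numpy(),
        positions=df["position_um"].to_numpy(),
        true_states=df["true_state"].tolist() if "true_state" in df else None,
    )


def write_kymograph_tiff(path, kymo: KymographImage) -> None:
    tifffile.imwrite(path, np.clip(kymo.pixel_values, 0, 65535).astype(np.uint16))


def read_kymograph_tiff(
    path,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> KymographImage:
    img = tifffile.imread(path).astype(float)
    return KymographImage(pixel_values=img, pixel_size=pixel_size, frame_interval=frame_interval)


def write_image_tiff(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.clip(image, 0, 65535).astype(np.uint16))


def write_spots_csv(path, records: list[SpotRecord]) -> None:
    pd.DataFrame(
        {
            "x_px": [r.x for r in records],
            "y_px": [r.y for r in records],
            "amplitude": [r.amplitude for r in records],
            "sigma_px": [r.sigma for r in records],
            "integrated_intensity": [r.integrated_intensity for r in records],
            "fit_residual": [r.fit_residual for r in records],
            "truth_n": [r.truth_n if r.truth_n is not None else -1 for r in records],
            "converged": [r.converged for r in records],
        }
    ).to_csv(path, index=False)


def read_spots_csv(path) -> list[SpotRecord]:
    df = pd.read_csv(path)
    return [
        SpotRecord(
            x=row.x_px, y=row.y_px, amplitude=row.amplitude, sigma=row.sigma_px,
            integrated_intensity=row.integrated_intensity,
            fit_residual=row.fit_residual,
            truth_n=None if row.truth_n < 0 else int(row.truth_n),
            converged=bool(row.converged),
        )
        for row in df.itertuples()
    ]


def write_frap_csv(path, trace: FRAPTrace) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bleach_index={trace.bleach_index}\n")
        pd.DataFrame({"time_s": trace.times, "intensity": trace.intensities}).to_csv(
            fh, index=False
        )


def read_frap_csv(path) -> FRAPTrace:
    bleach_index = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "bleach_index=" in first:
            bleach_index = int(first.split("bleach_index=")[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    if bleach_index is None:
        raise ValueError(f"{path}: missing '# bleach_index=' header (bleach frame is tagged, not inferred)")
    return FRAPTrace(
        times=df["time_s"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
        bleach_index=bleach_index,
    )
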