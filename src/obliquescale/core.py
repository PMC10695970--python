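"""Core data containers shared across the pipeline.

``VolumeSeries`` holds a time-indexed 3D intensity grid together with its
geometry (voxel pitch, whether the grid is natively sheared), and
``CellTable`` holds segmented cells: positions in μm, raw fluorescence
traces, ΔF/F in percent, and per-cell quality-control results.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import zarr

from .preprocess import ShearGeometry

__all__ = ["VolumeSeries", "CellTable"]


@dataclass
class VolumeSeries:
    """Time series of 3D intensity volumes.

    Attributes
    ----------
    data : ndarray, shape (T, Nz, Ny, Nx)
        Intensity grids, x fastest in memory.
    pitch : tuple of float
        Voxel pitch (x, y, z) in μm; for sheared data the pitch of the
        native (x, y′, z′) axes.
    sheared : bool
        Whether the grid is the native sheared acquisition grid.
    geometry : ShearGeometry or None
        Shear geometry when ``sheared`` (or when it is known).
    rate : float
        Volume rate in Hz.
    motion : ndarray or None, shape (T, 3)
        Ground-truth rigid motion (μm, x/y/z) per timepoint when the series
        was synthesized with motion.
    """

    data: np.ndarray
    pitch: tuple[float, float, float]
    sheared: bool = False
    geometry: ShearGeometry | None = None
    rate: float = 1.0
    motion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (t, z, y, x)")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip")
            f.attrs["pitch"] = self.pitch
            f.attrs["sheared"] = self.sheared
            f.attrs["rate"] = self.rate
            if self.motion is not None:
                f.create_dataset("motion", data=self.motion)
            if self.geometry is not None:
                f.attrs["slope_s"] = self.geometry.slope_s
                f.attrs["native_pitch"] = self.geometry.native_pitch
                f.attrs["out_pitch"] = self.geometry.out_pitch

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "VolumeSeries":
        with h5py.File(path, "r") as f:
            geom = None
            if "slope_s" in f.attrs:
                geom = ShearGeometry(
                    slope_s=float(f.attrs["slope_s"]),
                    native_pitch=tuple(f.attrs["native_pitch"]),
                    out_pitch=tuple(f.attrs["out_pitch"]),
                )
            return cls(
                data=f["data"][...],
                pitch=tuple(f.attrs["pitch"]),
                sheared=bool(f.attrs["sheared"]),
                geometry=geom,
                rate=float(f.attrs["rate"]),
                motion=f["motion"][...] if "motion" in f else None,
            )

    def to_tiff(self, directory: str | Path, prefix: str = "vol") -> list[Path]:
        """One multi-page TIFF per timepoint."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for t in range(self.n_timepoints):
            p = directory / f"{prefix}_{t:05d}.tif"
            tifffile.imwrite(p, self.data[t].astype(np.float32), photometric="minisblack")
            paths.append(p)
        return paths

    def to_zarr(self, path: str | Path) -> None:
        root = zarr.open_group(str(path), mode="w")
        arr = root.create_array("data", shape=self.data.shape, dtype=self.data.dtype)
        arr[:] = self.data
        root.attrs["pitch"] = list(self.pitch)
        root.attrs["sheared"] = bool(self.sheared)
        root.attrs["rate"] = float(self.rate)

    @classmethod
    def from_zarr(cls, path: str | Path) -> "VolumeSeries":
        root = zarr.open_group(str(path), mode="r")
        return cls(
            data=root["data"][...],
            pitch=tuple(root.attrs["pitch"]),
            sheared=bool(root.attrs["sheared"]),
            rate=float(root.attrs["rate"]),
        )


@dataclass
class CellTable:
    """Segmented cells: μm positions, traces, ΔF/F (%), QC, display order.

    ``dff`` is percent ΔF/F (100 = a 100% fluorescence increase over
    baseline), mean-centered per cell.  ``valid_timepoints`` marks frames
    retained after motion-correction failure screening; excluded frames are
    dropped before any trace analysis.
    """

    positions: np.ndarray  # (N, 3) μm, columns x/y/z
    raw_traces: np.ndarray | None = None  # (T, N)
    dff: np.ndarray | None = None  # (T, N), percent
    qc_snr: np.ndarray | None = None  # (N,)
    qc_pass: np.ndarray | None = None  # (N,) bool
    order_1d: np.ndarray | None = None  # permutation of cell indices
    valid_timepoints: np.ndarray | None = None  # (T,) bool
    rate: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size and self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_timepoints(self) -> int:
        if self.dff is not None:
            return self.dff.shape[0]
        if self.raw_traces is not None:
            return self.raw_traces.shape[0]
        return 0

    def passing(self) -> "CellTable":
        """Sub-table restricted to QC-passing cells (all cells if QC unset)."""
        if self.qc_pass is None:
            return self
        idx = np.flatnonzero(self.qc_pass)
        return self.select(idx)

    def select(self, idx: np.ndarray) -> "CellTable":
        return CellTable(
            positions=self.positions[idx],
            raw_traces=None if self.raw_traces is None else self.raw_traces[:, idx],
            dff=None if self.dff is None else self.dff[:, idx],
            qc_snr=None if self.qc_snr is None else self.qc_snr[idx],
            qc_pass=None if self.qc_pass is None else self.qc_pass[idx],
            order_1d=None,
            valid_timepoints=self.valid_timepoints,
            rate=self.rate,
        )

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("positions", data=self.positions)
            f["positions"].attrs["units"] = "um"
            for name in ("raw_traces", "dff", "qc_snr", "qc_pass", "order_1d", "valid_timepoints"):
                val = getattr(self, name)
                if val is not None:
                    f.create_dataset(name, data=val)
            if self.dff is not None:
                f["dff"].attrs["units"] = "percent"
            f.attrs["rate"] = self.rate

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "CellTable":
        with h5py.File(path, "r") as f:
            kwargs = {"positions": f["positions"][...], "rate": float(f.attrs["rate"])}
            for name in ("raw_traces", "dff", "qc_snr", "order_1d", "valid_timepoints"):
                if name in f:
                    kwargs[name] = f[name][...]
            if "qc_pass" in f:
                kwargs["qc_pass"] = f["qc_pass"][...].astype(bool)
            if "valid_timepoints" in kwargs:
                kwargs["valid_timepoints"] = kwargs["valid_timepoints"].astype(bool)
            return cls(**kwargs)

    def summary_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.positions, columns=["x_um", "y_um", "z_um"])
        if self.qc_snr is not None:
            df["qc_snr"] = self.qc_snr
        if self.qc_pass is not None:
            df["qc_pass"] = self.qc_pass
        if self.dff is not None:
            df["dff_std_pct"] = self.dff.std(axis=0)
        df.to_csv(path, index_label="cell")
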