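"""HDF5 containers and debug exports for measurement and reconstruction
volumes. Layouts are flat: one ``data``/``albedo`` dataset plus scalar
attributes, with an optional ``optical`` group mirroring the slab
parameters, so files remain readable by any HDF5 tool.
"""

from __future__ import annotations

import csv

import h5py
import numpy as np

from .forward import MeasurementVolume, ScanGrid
from .inversion import ReconstructionVolume
from .slab import OpticalSlab


def save_measurement(path, m: MeasurementVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=m.data)
        f.attrs["dt"] = m.dt
        f.attrs["pitch"] = m.grid.pitch
        f.attrs["nx"] = m.grid.nx
        f.attrs["ny"] = m.grid.ny
        f.attrs["nt"] = m.nt
        f.attrs["gate_start"] = m.gate_start
        f.attrs["is_counts"] = m.is_counts
        slab = (m.meta or {}).get("slab")
        if isinstance(slab, OpticalSlab):
            g = f.create_group("optical")
            g.attrs["mu_a"] = slab.mu_a
            g.attrs["mu_s_prime"] = slab.mu_s_prime
            g.attrs["n_medium"] = slab.n_medium
            g.attrs["z_d"] = slab.z_d


def load_measurement(path) -> MeasurementVolume:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        a = f.attrs
        grid = ScanGrid(nx=int(a["nx"]), ny=int(a["ny"]), pitch=float(a["pitch"]))
        meta = {}
        if "optical" in f:
            g = f["optical"].attrs
            meta["slab"] = OpticalSlab(mu_a=float(g["mu_a"]),
                                       mu_s_prime=float(g["mu_s_prime"]),
                                       n_medium=float(g["n_medium"]),
                                       z_d=float(g["z_d"]))
        return MeasurementVolume(data=data, dt=float(a["dt"]), grid=grid,
                                 gate_start=float(a["gate_start"]),
                                 is_counts=bool(a["is_counts"]),
                                 meta=meta or None)


def save_reconstruction(path, v: ReconstructionVolume) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("albedo", data=v.albedo)
        f.attrs["voxel_size"] = v.voxel_size
        f.attrs["z0"] = v.z0
        method = (v.meta or {}).get("method")
        if method:
            f.attrs["method"] = method


def load_reconstruction(path) -> ReconstructionVolume:
    with h5py.File(path, "r") as f:
        albedo = f["albedo"][...]
        vs = tuple(float(x) for x in f.attrs["voxel_size"])
        z0 = float(f.attrs["z0"])
        meta = {"method": str(f.attrs["method"])} if "method" in f.attrs else None
        return ReconstructionVolume(albedo=albedo, voxel_size=vs, z0=z0, meta=meta)


def export_transient_csv(path, m: MeasurementVolume, ix: int, iy: int) -> None:
    """Write one scan point's time histogram as (time_ns, counts) CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_ns", "counts"])
        for t, c in zip(m.times, m.data[ix, iy]):
            w.writerow([f"{t:.6f}", repr(float(c))])


def load_released_measurement(path, *, dt: float, pitch: float,
                              dataset: str = "data") -> MeasurementVolume:
    """Best-effort loader for externally captured scan volumes.

    Reads an HDF5 (or MATLAB v7.3) file holding a 3D scan-by-time array
    under ``dataset`` and wraps it with user-supplied grid metadata. No
    test or pipeline stage depends on such data being present.
    """
    with h5py.File(path, "r") as f:
        if dataset not in f:
            keys = [k for k in f.keys() if isinstance(f[k], h5py.Dataset)]
            if not keys:
                raise KeyError(f"no 3D dataset found in {path}")
            dataset = keys[0]
        data = np.asarray(f[dataset][...], dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    # heuristically put the (longest) time axis last
    t_axis = int(np.argmax(data.shape))
    data = np.moveaxis(data, t_axis, 2)
    data = np.maximum(data, 0.0)
    grid = ScanGrid(nx=data.shape[0], ny=data.shape[1], pitch=pitch)
    return MeasurementVolume(data=data, dt=dt, grid=grid)
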