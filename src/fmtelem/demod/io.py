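"""HDF5 container for demodulator output."""

from __future__ import annotations

import h5py
import numpy as np

from fmtelem.demod.loop import SOURCES, DemodOutput

__all__ = ["write_demod", "read_demod"]


def write_demod(path: str, out: DemodOutput) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["log_rate_hz"] = out.log_rate_hz
        f.attrs["block_rate_hz"] = out.block_rate_hz
        f.attrs["center_hz"] = out.center_hz
        f.attrs["limit_hz"] = out.limit_hz
        f.attrs["lo_hz"] = out.lo_hz
        specs = {
            "omega": (out.omega, "tracking frequency (Hz)"),
            "theta": (out.theta, "unwrapped main-vector phase (rad)"),
            "lock": (out.lock, "tracking-lock flag from the limiting rule"),
            "u": (out.u, "compensated baseband vectors per antenna"),
            "alpha": (out.alpha, "per-antenna residual angles per block (rad)"),
            "dphi": (out.dphi, "per-antenna compensation phases per block (rad)"),
            "r_block_mean": (out.r_block_mean, "block-mean rotated vectors (A-D, M)"),
            "r_block_power": (out.r_block_power, "block-mean rotated power (A-D, M)"),
        }
        for name, (data, desc) in specs.items():
            d = f.create_dataset(name, data=data)
            d.attrs["description"] = desc
            d.attrs["rate_hz"] = out.block_rate_hz if "block" in name or name in ("alpha", "dphi") else out.log_rate_hz
        f.attrs["sources"] = ",".join(SOURCES)


def read_demod(path: str) -> DemodOutput:
    with h5py.File(path, "r") as f:
        return DemodOutput(
            omega=f["omega"][()],
            theta=f["theta"][()],
            lock=f["lock"][()].astype(bool),
            u=f["u"][()],
            alpha=f["alpha"][()],
            dphi=f["dphi"][()],
            r_block_mean=f["r_block_mean"][()],
            r_block_power=f["r_block_power"][()],
            log_rate_hz=float(f.attrs["log_rate_hz"]),
            block_rate_hz=float(f.attrs["block_rate_hz"]),
            center_hz=float(f.attrs["center_hz"]),
            limit_hz=float(f.attrs["limit_hz"]),
            lo_hz=float(f.attrs["lo_hz"]),
        )


def u_sources(out: DemodOutput) -> dict[str, np.ndarray]:
    return out.baseband_sources()
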