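"""Self-descriptive HDF5 container for simulated antenna signals.

Layout: one group per antenna with a complex dataset ``z`` (attributes
``rate_hz``, ``lo_hz``), and a ``ground_truth`` group holding the
acceleration trace, the transmitter frequency trajectories, annotations and
fade intervals.  Every dataset carries a ``description`` attribute.
"""

from __future__ import annotations

from typing import Any

import h5py
import numpy as np

from fmtelem.radio_sim.channel import FadeInterval
from fmtelem.radio_sim.render import IntermediateSignalSet
from fmtelem.radio_sim.traces import AccelerationTrace, Annotation

__all__ = ["write_signals", "read_signals"]

_ANN_DTYPE = np.dtype([("onset_s", "f8"), ("offset_s", "f8"), ("label", "S16")])
_FADE_DTYPE = np.dtype([("antenna", "S4"), ("onset_s", "f8"), ("offset_s", "f8")])


def _dset(group: h5py.Group, name: str, data, description: str, **attrs) -> h5py.Dataset:
    d = group.create_dataset(name, data=data)
    d.attrs["description"] = description
    for k, v in attrs.items():
        d.attrs[k] = v
    return d


def write_signals(
    path: str,
    signals: IntermediateSignalSet,
    ground_truth: dict[str, Any] | None = None,
) -> None:
    """Write an :class:`IntermediateSignalSet` (and optional ground truth).

    Recognized ``ground_truth`` keys: ``trace`` (:class:`AccelerationTrace`),
    ``omega_t`` (dict name -> trajectory array), ``carriers_hz`` (dict
    name -> center frequency), ``fade_intervals`` (list of
    :class:`FadeInterval`).
    """
    with h5py.File(path, "w") as f:
        f.attrs["rate_hz"] = signals.rate_hz
        f.attrs["lo_hz"] = signals.lo_hz
        f.attrs["antennas"] = ",".join(signals.antennas)
        for i, name in enumerate(signals.antennas):
            g = f.create_group(f"antenna_{name}")
            _dset(
                g,
                "z",
                signals.z[i],
                f"complex intermediate-band signal of antenna {name}",
                rate_hz=signals.rate_hz,
                lo_hz=signals.lo_hz,
            )
        if ground_truth:
            g = f.create_group("ground_truth")
            trace: AccelerationTrace | None = ground_truth.get("trace")
            if trace is not None:
                _dset(
                    g,
                    "acceleration_g",
                    trace.samples,
                    "ground-truth acceleration (g)",
                    rate_hz=trace.rate_hz,
                )
                if trace.excursions_hz is not None:
                    _dset(
                        g,
                        "excursions_hz",
                        trace.excursions_hz,
                        "movement-driven carrier excursions (Hz)",
                        rate_hz=trace.rate_hz,
                    )
                ann = np.array(
                    [(a.onset_s, a.offset_s, a.label.encode()) for a in trace.annotations],
                    dtype=_ANN_DTYPE,
                )
                _dset(g, "annotations", ann, "ground-truth behavioral events")
            omega_t = ground_truth.get("omega_t") or {}
            for name, traj in omega_t.items():
                _dset(
                    g,
                    f"omega_t_{name}",
                    np.asarray(traj),
                    f"instantaneous transmitter frequency of {name} (Hz)",
                    rate_hz=signals.rate_hz,
                )
            carriers = ground_truth.get("carriers_hz") or {}
            if carriers:
                names = sorted(carriers)
                g.attrs["transmitter_names"] = ",".join(names)
                g.attrs["carriers_hz"] = np.array([carriers[n] for n in names])
            fades = ground_truth.get("fade_intervals") or []
            if fades:
                arr = np.array(
                    [(fi.antenna.encode(), fi.onset_s, fi.offset_s) for fi in fades],
                    dtype=_FADE_DTYPE,
                )
                _dset(g, "fade_intervals", arr, "ground-truth per-antenna fade intervals")


def read_signals(path: str) -> tuple[IntermediateSignalSet, dict[str, Any]]:
    """Read signals and any stored ground truth back from HDF5."""
    with h5py.File(path, "r") as f:
        antennas = tuple(str(f.attrs["antennas"]).split(","))
        z = np.stack([f[f"antenna_{name}"]["z"][()] for name in antennas])
        signals = IntermediateSignalSet(z, float(f.attrs["rate_hz"]), float(f.attrs["lo_hz"]), antennas)
        gt: dict[str, Any] = {}
        if "ground_truth" in f:
            g = f["ground_truth"]
            if "acceleration_g" in g:
                ann = []
                if "annotations" in g:
                    for row in g["annotations"][()]:
                        ann.append(
                            Annotation(float(row["onset_s"]), float(row["offset_s"]), row["label"].decode())
                        )
                exc = g["excursions_hz"][()] if "excursions_hz" in g else None
                gt["trace"] = AccelerationTrace(
                    g["acceleration_g"][()], float(g["acceleration_g"].attrs["rate_hz"]), ann, exc
                )
            omega_t = {}
            for key in g:
                if key.startswith("omega_t_"):
                    omega_t[key[len("omega_t_"):]] = g[key][()]
            if omega_t:
                gt["omega_t"] = omega_t
            if "transmitter_names" in g.attrs:
                names = str(g.attrs["transmitter_names"]).split(",")
                gt["carriers_hz"] = dict(zip(names, np.asarray(g.attrs["carriers_hz"], dtype=float)))
            if "fade_intervals" in g:
                gt["fade_intervals"] = [
                    FadeInterval(row["antenna"].decode(), float(row["onset_s"]), float(row["offset_s"]))
                    for row in g["fade_intervals"][()]
                ]
    return signals, gt
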