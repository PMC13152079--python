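"""Serialization (traces, parameter sets, protocols, run configs) and
synthetic fixture generation for detector tests."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from ._kernel import N_OUT, OUT_NAMES, OX
from .model import Trace
from .states import N_STATES, STATE_NAMES, IX

__all__ = ["write_trace", "read_trace", "trace_to_frame", "RunConfig",
           "generate_fixture", "load_protocol_yaml", "dump_protocol_yaml"]

log = logging.getLogger("myocyte")


def trace_to_frame(trace: Trace) -> pd.DataFrame:
    """Wide DataFrame; header equals the frozen state manifest plus derived
    output names."""
    df = pd.DataFrame(trace.y, columns=STATE_NAMES)
    for i, n in enumerate(OUT_NAMES):
        df[n] = trace.out[:, i]
    df.insert(0, "t", trace.t)
    return df


def write_trace(trace: Trace, path, fmt: str | None = None,
                config: "RunConfig | None" = None) -> None:
    path = str(path)
    fmt = fmt or ("hdf5" if path.endswith((".h5", ".hdf5")) else "csv")
    if fmt == "csv":
        trace_to_frame(trace).to_csv(path, index=False)
        np.savetxt(path + ".stim", trace.stim_times)
    elif fmt == "hdf5":
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=trace.t)
            f.create_dataset("y", data=trace.y)
            f.create_dataset("out", data=trace.out)
            f.create_dataset("stim_times", data=trace.stim_times)
            f.attrs["state_names"] = ",".join(STATE_NAMES)
            f.attrs["out_names"] = ",".join(OUT_NAMES)
            if config is not None:
                f.attrs["run_config"] = json.dumps(config.to_dict())
    else:
        raise ValueError(f"unknown trace format: {fmt!r}")


def read_trace(path, fmt: str | None = None) -> Trace:
    path = str(path)
    fmt = fmt or ("hdf5" if path.endswith((".h5", ".hdf5")) else "csv")
    if fmt == "csv":
        df = pd.read_csv(path)
        t = df.pop("t").to_numpy()
        y = df[STATE_NAMES].to_numpy()
        out = df[OUT_NAMES].to_numpy()
        try:
            stim = np.atleast_1d(np.loadtxt(path + ".stim"))
        except OSError:
            stim = np.zeros(0)
        return Trace(t, y, out, stim)
    import h5py
    with h5py.File(path, "r") as f:
        return Trace(f["t"][:], f["y"][:], f["out"][:], f["stim_times"][:])


@dataclass
class RunConfig:
    """Fully serializable description of one simulation run."""

    preset: str = "male"
    multipliers: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    rtol: float = 1e-7
    atol_conc: float = 1e-9
    dt_sample: float = 0.5
    seed: int | None = None
    version: str = "1.0.0"

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig(**yaml.safe_load(fh))

    def log_banner(self) -> None:
        log.info("myocyte %s | seed=%s | rtol=%g atol=%g dt=%g | config=%s",
                 self.version, self.seed, self.rtol, self.atol_conc,
                 self.dt_sample, self.config_hash())


def load_protocol_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_protocol_yaml(protocol, path) -> None:
    d = asdict(protocol) if not isinstance(protocol, dict) else protocol
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


# ---------------------------------------------------------------------------
# synthetic fixtures: constructed traces with known biomarker values
# ---------------------------------------------------------------------------
def generate_fixture(kind: str, **params) -> Trace:
    """Construct a synthetic Trace with exactly known biomarkers.

    Kinds: ``square_ap`` (width), ``triangle_cat`` (ttp, decay),
    ``alternating_apd`` (widths, n_beats), ``dad_like_diastole``
    (bumps: list of (t, amplitude_mV)), ``triangle_tension`` (ttp, decay).
    """
    dt = params.get("dt", 0.5)
    bcl = params.get("bcl", 1000.0)
    vrest, vpeak = params.get("vrest", -88.0), params.get("vpeak", 40.0)

    def empty(nt):
        y = np.zeros((nt, N_STATES))
        out = np.zeros((nt, N_OUT))
        return y, out

    if kind == "square_ap":
        width = params.get("width", 300.0)
        t = np.arange(0.0, bcl, dt)
        y, out = empty(len(t))
        v = np.full_like(t, vrest)
        v[(t >= 1.0) & (t < 1.0 + width)] = vpeak
        # one-sample ramp so the upstroke has a defined maximum-dV/dt time
        y[:, IX["v"]] = v
        return Trace(t, y, out, np.array([0.0]))

    if kind == "triangle_cat":
        ttp = params.get("ttp", 40.0)
        decay = params.get("decay", 300.0)
        dia = params.get("dia", 1e-4)
        amp = params.get("amp", 5e-4)
        t = np.arange(0.0, bcl, dt)
        y, out = empty(len(t))
        ca = np.full_like(t, dia)
        up = (t >= 1.0) & (t < 1.0 + ttp)
        ca[up] = dia + amp * (t[up] - 1.0) / ttp
        dn = (t >= 1.0 + ttp) & (t < 1.0 + ttp + decay)
        ca[dn] = dia + amp * (1.0 - (t[dn] - 1.0 - ttp) / decay)
        y[:, IX["ca_myo"]] = ca
        v = np.full_like(t, vrest)
        v[(t >= 1.0) & (t < 300.0)] = vpeak
        y[:, IX["v"]] = v
        return Trace(t, y, out, np.array([0.0]))

    if kind == "triangle_tension":
        ttp = params.get("ttp", 150.0)
        decay = params.get("decay", 400.0)
        peak = params.get("peak", 40.0)
        t = np.arange(0.0, bcl, dt)
        y, out = empty(len(t))
        ta = np.zeros_like(t)
        up = (t >= 0.0) & (t < ttp)
        ta[up] = peak * t[up] / ttp
        dn = (t >= ttp) & (t < ttp + decay)
        ta[dn] = peak * (1.0 - (t[dn] - ttp) / decay)
        out[:, OX["tension"]] = ta
        return Trace(t, y, out, np.array([0.0]))

    if kind == "alternating_apd":
        widths = params.get("widths", (280.0, 240.0))
        n = params.get("n_beats", 10)
        t_all, v_all, stim = [], [], []
        for b in range(n):
            w = widths[b % 2]
            t = np.arange(0.0, bcl, dt) + b * bcl
            v = np.full_like(t, vrest)
            v[(t - b * bcl >= 1.0) & (t - b * bcl < 1.0 + w)] = vpeak
            t_all.append(t)
            v_all.append(v)
            stim.append(b * bcl)
        t = np.concatenate(t_all)
        y, out = empty(len(t))
        y[:, IX["v"]] = np.concatenate(v_all)
        return Trace(t, y, out, np.array(stim))

    if kind == "dad_like_diastole":
        bumps = params.get("bumps", [(500.0, 3.0)])
        length = params.get("length", 2000.0)
        t = np.arange(0.0, length, dt)
        y, out = empty(len(t))
        v = np.full_like(t, vrest)
        for tb, amp in bumps:
            v += amp * np.exp(-0.5 * ((t - tb) / 25.0) ** 2)
        y[:, IX["v"]] = v
        return Trace(t, y, out, np.array([0.0]))

    raise ValueError(f"unknown fixture kind: {kind!r}")
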