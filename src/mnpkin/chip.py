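"""Chip layout, binding traces, and trace/layout file I/O.

The sensing chip carries ``n_channels`` microfluidic channels, each running
over ``sensors_per_channel`` giant-magnetoresistance sensors.  Bait proteins
are immobilized on the sensors in duplicate, with the same immobilization
pattern in every channel; each channel receives the prey--nanoparticle
complex at a different fraction of the eluted concentration.  Sensor signals
are recorded in arbitrary units proportional to bound-particle coverage.

Traces travel between pipeline stages as a comma-delimited text file with
header columns ``time_s, channel, sensor, bait, signal``; layouts as JSON.
Channel and sensor indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ROLE_PROBE = "probe"
ROLE_NEGATIVE_CONTROL = "negative_control"
ROLE_REFERENCE = "reference"
_ROLES = (ROLE_PROBE, ROLE_NEGATIVE_CONTROL, ROLE_REFERENCE)

TRACE_COLUMNS = ("time_s", "channel", "sensor", "bait", "signal")


class LayoutError(ValueError):
    """Chip layout violates a structural invariant."""


class TraceFormatError(ValueError):
    """Trace file is malformed (missing column, bad dtype)."""


class TraceDataError(ValueError):
    """Trace content violates a data invariant (duplicate or non-monotone time)."""


@dataclass(frozen=True)
class ChipLayout:
    """Map of channels -> sensors -> baits plus acquisition parameters.

    ``bait_map`` is shared by all channels (the immobilization pattern is
    identical across channels); ``role_map`` assigns each bait name a role.
    ``dilution_fractions`` give each channel's fraction of the eluted
    complex concentration.
    """

    n_channels: int = 4
    sensors_per_channel: int = 16
    bait_map: Mapping[int, str] = field(default_factory=dict)
    role_map: Mapping[str, str] = field(default_factory=dict)
    dilution_fractions: tuple[float, ...] = (1.00, 0.75, 0.50, 0.25)
    sampling_interval: float = 5.5
    onset_time: float = 60.0

    def role_of(self, bait: str) -> str:
        try:
            return self.role_map[bait]
        except KeyError:
            raise LayoutError(f"bait {bait!r} has no role in role_map") from None

    def sensors_with_role(self, role: str) -> list[int]:
        return [s for s, b in self.bait_map.items() if self.role_map.get(b) == role]

    @property
    def baits(self) -> list[str]:
        return sorted(set(self.bait_map.values()))


@dataclass(frozen=True)
class BindingTrace:
    """One sensor's time series with its bait, channel, and role."""

    channel: int
    sensor: int
    bait: str
    times: np.ndarray
    signals: np.ndarray
    role: str = ROLE_PROBE
    reference_subtracted: bool = False
    consumed_as_reference: bool = False

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))
        if self.times.shape != self.signals.shape:
            raise TraceDataError(
                f"channel {self.channel} sensor {self.sensor}: "
                f"times and signals differ in length"
            )
        if self.role not in _ROLES:
            raise TraceDataError(f"unknown role {self.role!r}")
        dt = np.diff(self.times)
        if len(dt) and np.any(dt <= 0):
            raise TraceDataError(
                f"channel {self.channel} sensor {self.sensor}: "
                f"times not strictly increasing"
            )
        if not np.all(np.isfinite(self.signals)):
            raise TraceDataError(
                f"channel {self.channel} sensor {self.sensor}: non-finite signal"
            )

    def with_signals(self, signals: np.ndarray, **flags) -> "BindingTrace":
        return replace(self, signals=np.asarray(signals, dtype=float), **flags)

    def with_times(self, times: np.ndarray) -> "BindingTrace":
        return replace(self, times=np.asarray(times, dtype=float))

    def check_sampling(self, interval: float, rtol: float = 1e-9) -> None:
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, interval, rtol=rtol, atol=0):
            raise TraceDataError(
                f"channel {self.channel} sensor {self.sensor}: sampling interval "
                f"not constant at {interval} s"
            )


@dataclass(frozen=True)
class MNPBatch:
    """An eluted prey--nanoparticle conjugate batch and its channel dilutions."""

    prey: str
    eluted_concentration: float  # molar
    channel_concentrations: tuple[float, ...] = ()

    def __post_init__(self):
        if self.eluted_concentration < 0:
            raise ValueError("eluted_concentration must be nonnegative")
        if any(c < 0 for c in self.channel_concentrations):
            raise ValueError("channel concentrations must be nonnegative")

    @classmethod
    def from_layout(cls, prey: str, eluted: float, layout: ChipLayout) -> "MNPBatch":
        return cls(
            prey=prey,
            eluted_concentration=eluted,
            channel_concentrations=tuple(
                eluted * f for f in layout.dilution_fractions
            ),
        )


def default_layout() -> ChipLayout:
    """The standard 4-channel, 16-sensor chip.

    Six baits in duplicate per channel -- four probes (PD-1, PD-L1, PD-L2,
    B7-1) and two negative controls (murine IgG, BSA) -- plus four dedicated
    reference sensors used for channel-common background subtraction.
    """
    baits = ["PD-1", "PD-L1", "PD-L2", "B7-1", "mIgG", "BSA"]
    bait_map = {}
    for i, b in enumerate(baits):
        bait_map[2 * i] = b
        bait_map[2 * i + 1] = b
    for s in range(12, 16):
        bait_map[s] = "REF"
    role_map = {
        "PD-1": ROLE_PROBE,
        "PD-L1": ROLE_PROBE,
        "PD-L2": ROLE_PROBE,
        "B7-1": ROLE_PROBE,
        "mIgG": ROLE_NEGATIVE_CONTROL,
        "BSA": ROLE_NEGATIVE_CONTROL,
        "REF": ROLE_REFERENCE,
    }
    return validate_layout(ChipLayout(bait_map=bait_map, role_map=role_map))


def validate_layout(layout: ChipLayout) -> ChipLayout:
    """Return *layout* iff all structural invariants hold.

    Raises :class:`LayoutError` on: counts/fractions out of range, a sensor
    index outside the channel, a bait without a role, or no control or
    reference sensor (reference subtraction would be impossible).
    """
    if layout.n_channels < 1 or layout.sensors_per_channel < 1:
        raise LayoutError("n_channels and sensors_per_channel must be >= 1")
    if len(layout.dilution_fractions) != layout.n_channels:
        raise LayoutError(
            f"{len(layout.dilution_fractions)} dilution fractions for "
            f"{layout.n_channels} channels"
        )
    for f in layout.dilution_fractions:
        if not (0 < f <= 1):
            raise LayoutError(f"dilution fraction {f} outside (0, 1]")
    if layout.sampling_interval <= 0:
        raise LayoutError("sampling_interval must be positive")
    if not layout.bait_map:
        raise LayoutError("bait_map is empty")
    for s, b in layout.bait_map.items():
        if not (0 <= s < layout.sensors_per_channel):
            raise LayoutError(f"sensor index {s} outside 0..{layout.sensors_per_channel - 1}")
        if b not in layout.role_map:
            raise LayoutError(f"bait {b!r} has no role in role_map")
    for b, r in layout.role_map.items():
        if r not in _ROLES:
            raise LayoutError(f"bait {b!r} has unknown role {r!r}")
    n_ctrl = len(layout.sensors_with_role(ROLE_NEGATIVE_CONTROL)) + len(
        layout.sensors_with_role(ROLE_REFERENCE)
    )
    if n_ctrl == 0:
        raise LayoutError(
            "layout has no negative-control or reference sensors; "
            "reference subtraction impossible"
        )
    return layout


def check_bait_pattern(layout: ChipLayout, traces: Sequence[BindingTrace]) -> None:
    """Verify every channel presents the same (sensor, bait) pattern."""
    by_channel: dict[int, dict[int, str]] = {}
    for t in traces:
        by_channel.setdefault(t.channel, {})[t.sensor] = t.bait
    patterns = {ch: tuple(sorted(m.items())) for ch, m in by_channel.items()}
    distinct = set(patterns.values())
    if len(distinct) > 1:
        raise LayoutError(
            "bait pattern differs across channels: "
            + "; ".join(f"ch{ch}" for ch in sorted(patterns))
        )


# ---------------------------------------------------------------------------
# Trace file I/O (traces.csv dialect)

def write_traces(traces: Sequence[BindingTrace], path: str | Path) -> None:
    """Write traces as comma-delimited UTF-8 text with a header row.

    Signals are written with repr-exact float formatting so a read/write
    round trip is bit-exact.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for t in traces:
            for ti, si in zip(t.times.tolist(), t.signals.tolist()):
                fh.write(f"{ti!r},{t.channel},{t.sensor},{t.bait},{si!r}\n")


def read_traces(path: str | Path, layout: ChipLayout) -> list[BindingTrace]:
    """Read a traces.csv file into one :class:`BindingTrace` per (channel, sensor).

    Roles are attached from the layout's role map.  Raises
    :class:`TraceFormatError` for a missing column and
    :class:`TraceDataError` for duplicated or non-monotone time stamps,
    naming the offending sensor.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"trace file missing column(s): {', '.join(missing)}")
    traces = []
    for (ch, sens), g in df.groupby(["channel", "sensor"], sort=True):
        g = g.sort_values("time_s", kind="stable")
        times = g["time_s"].to_numpy(float)
        if len(np.unique(times)) != len(times):
            raise TraceDataError(
                f"channel {ch} sensor {sens}: duplicated time stamp"
            )
        bait = g["bait"].iloc[0]
        if g["bait"].nunique() != 1:
            raise TraceDataError(f"channel {ch} sensor {sens}: multiple baits")
        traces.append(
            BindingTrace(
                channel=int(ch),
                sensor=int(sens),
                bait=str(bait),
                times=times,
                signals=g["signal"].to_numpy(float),
                role=layout.role_of(str(bait)),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# Layout JSON I/O

def write_layout(layout: ChipLayout, path: str | Path) -> None:
    payload = {
        "n_channels": layout.n_channels,
        "sensors_per_channel": layout.sensors_per_channel,
        "bait_map": {str(k): v for k, v in layout.bait_map.items()},
        "role_map": dict(layout.role_map),
        "dilution_fractions": list(layout.dilution_fractions),
        "sampling_interval": layout.sampling_interval,
        "onset_time": layout.onset_time,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_layout(path: str | Path) -> ChipLayout:
    payload = json.loads(Path(path).read_text())
    try:
        layout = ChipLayout(
            n_channels=int(payload["n_channels"]),
            sensors_per_channel=int(payload["sensors_per_channel"]),
            bait_map={int(k): v for k, v in payload["bait_map"].items()},
            role_map=dict(payload["role_map"]),
            dilution_fractions=tuple(payload["dilution_fractions"]),
            sampling_interval=float(payload["sampling_interval"]),
            onset_time=float(payload["onset_time"]),
        )
    except KeyError as e:
        raise TraceFormatError(f"layout file missing field {e.args[0]!r}") from None
    return validate_layout(layout)
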