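"""Deterministic protocol arithmetic for the silent ZTE/RUFIS ihMT sequence.

The acquisition interleaves RUFIS readout segments (a burst of
centre-out radial spokes under a constant gradient) with off-resonance
saturation pulse trains.  These helpers reproduce the protocol's derived
quantities — segment time, preparation time, dummy-scan duration, total
scan time, and the RMS saturation amplitude over the preparation
module — from the primitive sequence parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

__all__ = [
    "ProtocolTiming",
    "PUBLISHED_PROTOCOL",
    "segment_time",
    "prep_time",
    "dummy_duration",
    "protocol_duration",
    "module_b1rms",
]


@dataclass(frozen=True)
class ProtocolTiming:
    """Sequence timing and saturation-power parameters.

    Attributes
    ----------
    tr : float
        Repetition time of one readout spoke, ms.
    spokes_per_segment : int
        Radial spokes acquired per RUFIS segment.
    segment_overhead : float
        Gradient ramps and switching time per segment, ms.
    n_sat_pulses : int
        Saturation pulses per preparation train.
    pulse_width : float
        Width of one saturation pulse, ms.
    pulse_gap : float
        Gap between consecutive saturation pulses, ms.
    prep_overhead : float
        Dead time of the preparation module beyond the pulse train, ms.
    n_dummy_segments : int
        Segments played without data acquisition after the initial
        saturation module, to let magnetization reach steady state.
    pulse_b1rms : float
        RMS B1 amplitude of a single saturation pulse, microtesla.
    per_volume_scan_time : float
        Acquisition time of one weighted volume (excluding the dummy
        preamble), seconds.
    n_volumes : int
        Number of weighted volumes in the protocol.
    """

    tr: float = 1.764
    spokes_per_segment: int = 32
    segment_overhead: float = 12.152
    n_sat_pulses: int = 10
    pulse_width: float = 0.5
    pulse_gap: float = 0.5
    prep_overhead: float = 0.8
    n_dummy_segments: int = 48
    pulse_b1rms: float = 8.75
    per_volume_scan_time: float = 65.0
    n_volumes: int = 5

    def __post_init__(self) -> None:
        for name in ("tr", "spokes_per_segment", "n_sat_pulses", "pulse_width",
                     "pulse_b1rms", "per_volume_scan_time", "n_volumes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("segment_overhead", "pulse_gap", "prep_overhead",
                     "n_dummy_segments"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_json(cls, path: str | Path) -> "ProtocolTiming":
        return cls(**json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)


#: The published silent ihMT protocol.  Overheads are back-computed so
#: that the printed totals hold exactly: the protocol quotes a 68.6 ms
#: segment (32 spokes x 1.764 ms TR -> 12.152 ms of ramps/switching) and
#: a 10.8 ms preparation module (10 x (0.5 + 0.5) ms train -> 0.8 ms of
#: dead time).
PUBLISHED_PROTOCOL = ProtocolTiming()


def segment_time(p: ProtocolTiming) -> float:
    """Duration of one RUFIS readout segment, ms (spokes x TR + overhead)."""
    return p.spokes_per_segment * p.tr + p.segment_overhead


def prep_time(p: ProtocolTiming) -> float:
    """Duration of one saturation preparation module, ms."""
    return p.n_sat_pulses * (p.pulse_width + p.pulse_gap) + p.prep_overhead


def dummy_duration(p: ProtocolTiming) -> float:
    """Duration of the dummy-segment preamble, s, reported to 0.1 s.

    Dummy segments are costed at the bare segment time (no saturation
    train between dummies).
    """
    return round(p.n_dummy_segments * segment_time(p) / 1000.0, 1)


def protocol_duration(p: ProtocolTiming) -> tuple[int, str]:
    """Total protocol time over all volumes.

    Each volume costs its acquisition time plus the dummy preamble.
    Returns the duration rounded to the nearest whole second and a
    human-readable ``"M minutes S seconds"`` string.
    """
    exact = p.n_volumes * (p.per_volume_scan_time + p.n_dummy_segments * segment_time(p) / 1000.0)
    total = round(exact)
    minutes, seconds = divmod(total, 60)
    return total, f"{minutes} minutes {seconds} seconds"


def module_b1rms(p: ProtocolTiming) -> float:
    """RMS B1 over the pulse train window, microtesla, reported to 0.1 uT.

    The train alternates pulses of RMS amplitude ``pulse_b1rms`` with
    silent gaps, so the module RMS is the pulse RMS scaled by the square
    root of the duty cycle.  The nominal window is pulses + gaps,
    excluding the module's dead time.
    """
    duty = p.pulse_width / (p.pulse_width + p.pulse_gap)
    return round(p.pulse_b1rms * math.sqrt(duty), 1)
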