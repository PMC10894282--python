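"""Recording-protocol configuration.

The default protocol mirrors a two-limb surface-EMG session: 7 bipolar
channels per limb sampled at 6000 Hz with a 20–450 Hz analog band-pass and a
±11 mV ADC range, 10 hand movements, and for each movement 2 trials of 5
alternating cycles of 4 s relaxation followed by 3 s contraction (10
repetitions of each phase per movement).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

#: Canonical movement codes: index flexion, key pinch, pulp pinch, index
#: point, cylindrical wrap, cylindrical wrap wrist-rotated, tripod pinch,
#: wrist extension, wrist flexion, wrist rotation.
DEFAULT_MOVEMENTS: tuple[str, ...] = (
    "IF", "KP", "PP", "IP", "CW", "CR", "TP", "WE", "WF", "WR",
)

LIMBS = ("unaffected", "affected")
PHASES = ("relaxation", "contraction")


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition and trial-schedule parameters for one session.

    Attributes
    ----------
    sampling_rate : float
        ADC sampling rate in Hz.
    n_channels_unaffected, n_channels_affected : int
        Electrode counts per limb (the affected limb may carry fewer
        electrodes on a short residual limb).
    movements : tuple of str
        Ordered movement codes; the order fixes RDM condition order.
    relax_duration, contract_duration : float
        Phase durations in seconds. Each cycle is one relaxation followed
        by one contraction.
    cycles_per_trial, trials : int
        ``trials * cycles_per_trial`` repetitions of each phase per movement.
    band : (float, float)
        Analog band-pass corner frequencies in Hz.
    adc_range : float
        Symmetric ADC full-scale in mV; samples are clipped to ±adc_range.
    trim_fraction : float
        Fraction of each phase discarded from both onset and recession
        before feature extraction (reaction-time guard).
    """

    sampling_rate: float = 6000.0
    n_channels_unaffected: int = 7
    n_channels_affected: int = 7
    movements: tuple[str, ...] = DEFAULT_MOVEMENTS
    relax_duration: float = 4.0
    contract_duration: float = 3.0
    cycles_per_trial: int = 5
    trials: int = 2
    band: tuple[float, float] = (20.0, 450.0)
    adc_range: float = 11.0
    trim_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.relax_duration <= 0 or self.contract_duration <= 0:
            raise ValueError("phase durations must be positive")
        if not (0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must lie in [0, 0.5)")
        if len(self.movements) == 0:
            raise ValueError("movements must be non-empty")
        if len(set(self.movements)) != len(self.movements):
            raise ValueError("movement codes must be unique")
        lo, hi = self.band
        if not (0 < lo < hi < self.sampling_rate / 2):
            raise ValueError(
                "band must satisfy 0 < low < high < sampling_rate/2"
            )
        for name in ("n_channels_unaffected", "n_channels_affected",
                     "cycles_per_trial", "trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.adc_range <= 0:
            raise ValueError("adc_range must be positive")
        object.__setattr__(self, "movements", tuple(self.movements))
        object.__setattr__(self, "band", (float(lo), float(hi)))

    # -- derived schedule arithmetic ------------------------------------

    @property
    def repetitions(self) -> int:
        """Repetitions of each phase per movement (trials × cycles)."""
        return self.trials * self.cycles_per_trial

    @property
    def cycle_duration(self) -> float:
        return self.relax_duration + self.contract_duration

    @property
    def samples_per_cycle(self) -> int:
        return round(self.cycle_duration * self.sampling_rate)

    @property
    def samples_per_trial(self) -> int:
        return self.cycles_per_trial * self.samples_per_cycle

    @property
    def total_samples(self) -> int:
        """Total samples in one limb's recording."""
        return len(self.movements) * self.trials * self.samples_per_trial

    def n_channels(self, limb: str) -> int:
        if limb == "unaffected":
            return self.n_channels_unaffected
        if limb == "affected":
            return self.n_channels_affected
        raise ValueError(f"unknown limb {limb!r}")

    def phase_samples(self, phase: str) -> int:
        dur = {"relaxation": self.relax_duration,
               "contraction": self.contract_duration}[phase]
        return round(dur * self.sampling_rate)

    def with_(self, **kwargs) -> "ProtocolConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    # -- declarative round-trip -----------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["movements"] = list(self.movements)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        d = dict(d)
        if "movements" in d:
            d["movements"] = tuple(d["movements"])
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ProtocolConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def reduced_protocol(n_movements: int = 5, n_channels: int = 4,
                     cycles_per_trial: int = 3,
                     sampling_rate: float = 500.0) -> ProtocolConfig:
    """A scaled-down protocol for simulation studies.

    Keeps the phase structure (4 s relax / 3 s contract, 2 trials) but
    shrinks the movement set, channel count, cycle count and sampling rate
    so that hundreds of synthetic sessions can be analysed quickly.  The
    band-pass is lowered to (20, 200) Hz to respect Nyquist at the reduced
    sampling rate.
    """
    return ProtocolConfig(
        sampling_rate=sampling_rate,
        n_channels_unaffected=n_channels,
        n_channels_affected=n_channels,
        movements=DEFAULT_MOVEMENTS[:n_movements],
        cycles_per_trial=cycles_per_trial,
        band=(20.0, min(200.0, 0.4 * sampling_rate)),
    )
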