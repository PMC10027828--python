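"""Pulsatile inflow waveform for the cardiac cycle.

The inlet speed over one cardiac cycle is modelled as a mean plus a small
number of cosine harmonics phased so that the global maximum (peak systole)
falls at a prescribed instant of the cycle.  With the default 0.8 s period
peak systole is at t = 0.24 s and early diastole at t = 0.54 s, the two
phases at which wall fields are reported downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Waveform", "generate_waveform"]


@dataclass(frozen=True)
class Waveform:
    """Periodic inlet-speed waveform v(t) = mean + sum_k a_k cos(2*pi*k*t/T - phi_k).

    Attributes
    ----------
    period : float
        Cardiac period T in seconds.
    mean_velocity : float
        Cycle-averaged inlet speed in m/s (the harmonics average to zero).
    harmonics : tuple of (amplitude, phase)
        Amplitude a_k (m/s) and phase phi_k (rad) of harmonic k = 1, 2, ...
    t_peak_systole, t_early_diastole : float
        Named phases of the cycle, in seconds from cycle start.
    """

    period: float
    mean_velocity: float
    harmonics: tuple = field(default_factory=tuple)
    t_peak_systole: float = 0.24
    t_early_diastole: float = 0.54

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")

    def evaluate(self, t):
        """Inlet speed at time(s) ``t`` (scalar or array), periodic in T."""
        t = np.asarray(t, dtype=float)
        v = np.full(t.shape, self.mean_velocity)
        w = 2.0 * np.pi / self.period
        for k, (amp, phase) in enumerate(self.harmonics, start=1):
            v = v + amp * np.cos(k * w * t - phase)
        return v if v.shape else float(v)

    def sample(self, n: int = 1000):
        """Return (t, v) sampled uniformly over one period (endpoint excluded)."""
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return t, self.evaluate(t)

    def to_csv(self, path, n: int = 200) -> None:
        t, v = self.sample(n)
        np.savetxt(path, np.column_stack([t, v]), delimiter=",",
                   header="t_s,velocity_m_per_s", comments="")


def generate_waveform(profile_name: str = "default_mca", period: float = 0.8,
                      mean_velocity: float = 0.25,
                      peak_velocity: float = 0.5) -> Waveform:
    """Build a named inflow profile.

    ``default_mca`` is a two-harmonic pulse: both harmonics peak together at
    peak systole (0.3 T into the cycle, i.e. 0.24 s for T = 0.8 s), with a
    second-harmonic fraction of 0.2 which keeps that instant the unique
    global maximum and the waveform strictly positive for the default
    mean/peak pair (0.25 / 0.5 m/s).
    """
    if profile_name not in ("default_mca", "steady"):
        raise ValueError(f"unknown waveform profile {profile_name!r}")
    if period <= 0:
        raise ValueError("period must be positive")
    if profile_name == "steady":
        # constant-inflow control (OSI should vanish identically)
        if mean_velocity <= 0:
            raise ValueError("mean_velocity must be positive")
        return Waveform(period=period, mean_velocity=mean_velocity,
                        harmonics=(), t_peak_systole=0.3 * period,
                        t_early_diastole=0.675 * period)
    if not peak_velocity > mean_velocity > 0:
        raise ValueError("need peak_velocity > mean_velocity > 0")
    t_peak = 0.3 * period
    t_dias = 0.675 * period
    beta = 0.2
    a1 = (peak_velocity - mean_velocity) / (1.0 + beta)
    a2 = beta * a1
    # minimum of cos(x) + beta*cos(2x) is beta - 1 at x = pi for beta <= 1/4
    if mean_velocity - a1 * (1.0 - beta) <= 0:
        raise ValueError("waveform would reverse: reduce peak_velocity or raise mean")
    w = 2.0 * np.pi / period
    harmonics = ((a1, w * t_peak), (a2, 2.0 * w * t_peak))
    return Waveform(period=period, mean_velocity=mean_velocity,
                    harmonics=harmonics, t_peak_systole=t_peak,
                    t_early_diastole=t_dias)
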