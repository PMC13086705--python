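"""Multi-shank probe geometry and acquisition-timing metadata.

A multiplexed amplifier samples its channels sequentially ("round-robin"):
one ADC running ``n_slots`` times faster than the nominal per-channel rate
visits each channel once per frame, so channel *c* is actually sampled at
``frame_time + slot(c) / adc_hz``.  Both the simulator and the velocity
estimator need this timing, along with the axial position of every site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ProbeGeometry", "RecordingConfig", "make_probe"]


@dataclass(frozen=True)
class ProbeGeometry:
    """Axial layout and ADC slot assignment of a multi-shank probe.

    Coordinates are axial positions (µm) along the nerve tract; the sign
    convention is that position increases toward the brain, so a positive
    estimated velocity means ascending propagation.
    """

    shank_positions_um: np.ndarray
    sites_per_shank: int
    site_offsets_um: np.ndarray
    channel_map: tuple  # channel -> (shank, site)
    acquisition_order: np.ndarray  # channel -> ADC slot index
    n_slots: int = 35

    def __post_init__(self):
        object.__setattr__(
            self, "shank_positions_um", np.asarray(self.shank_positions_um, float)
        )
        object.__setattr__(
            self, "site_offsets_um", np.asarray(self.site_offsets_um, float)
        )
        object.__setattr__(
            self, "acquisition_order", np.asarray(self.acquisition_order, int)
        )
        if self.shank_positions_um.size > 1:
            spacing = np.diff(np.sort(self.shank_positions_um))
            if np.any(spacing <= 0):
                raise ValueError("shank spacing must be strictly positive")
        pairs = set(self.channel_map)
        if len(pairs) != len(self.channel_map):
            raise ValueError("channel_map must be a bijection onto (shank, site)")
        slots = self.acquisition_order
        if len(np.unique(slots)) != len(slots):
            raise ValueError("acquisition_order slots must be unique")
        if slots.min() < 0 or slots.max() >= self.n_slots:
            raise ValueError("acquisition slots must lie within [0, n_slots)")

    @property
    def n_channels(self) -> int:
        return len(self.channel_map)

    @property
    def channel_positions_um(self) -> np.ndarray:
        """Axial position of every channel (µm)."""
        pos = np.empty(self.n_channels)
        for c, (shank, site) in enumerate(self.channel_map):
            pos[c] = self.shank_positions_um[shank] + self.site_offsets_um[site]
        return pos

    @property
    def max_axial_separation_um(self) -> float:
        pos = self.channel_positions_um
        return float(pos.max() - pos.min())

    def to_dict(self) -> dict:
        return {
            "shank_positions_um": self.shank_positions_um.tolist(),
            "sites_per_shank": self.sites_per_shank,
            "site_offsets_um": self.site_offsets_um.tolist(),
            "channel_map": [list(cs) for cs in self.channel_map],
            "acquisition_order": self.acquisition_order.tolist(),
            "n_slots": self.n_slots,
            "sign_convention": "positive velocity = ascending (toward brain)",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeGeometry":
        return cls(
            shank_positions_um=np.asarray(d["shank_positions_um"], float),
            sites_per_shank=int(d["sites_per_shank"]),
            site_offsets_um=np.asarray(d["site_offsets_um"], float),
            channel_map=tuple((int(s), int(t)) for s, t in d["channel_map"]),
            acquisition_order=np.asarray(d["acquisition_order"], int),
            n_slots=int(d["n_slots"]),
        )


def make_probe(
    n_shanks: int = 4,
    sites_per_shank: int = 4,
    shank_spacing_um: float = 150.0,
    site_offsets_um=None,
    n_slots: int = 35,
) -> ProbeGeometry:
    """Build a regular multi-shank probe (default: 4 shanks, 150 µm apart).

    Within-shank sites default to axially co-located (offset 0), so
    same-shank channel pairs have zero axial separation and are excluded
    from velocity estimates.
    """
    if n_shanks < 1:
        raise ValueError("n_shanks must be >= 1")
    if shank_spacing_um <= 0:
        raise ValueError("shank spacing must be strictly positive")
    if sites_per_shank < 1:
        raise ValueError("sites_per_shank must be >= 1")
    n_channels = n_shanks * sites_per_shank
    if n_channels > n_slots:
        raise ValueError("more channels than ADC slots")
    if site_offsets_um is None:
        site_offsets_um = np.zeros(sites_per_shank)
    shank_positions = np.arange(n_shanks) * float(shank_spacing_um)
    channel_map = tuple(
        (c // sites_per_shank, c % sites_per_shank) for c in range(n_channels)
    )
    acquisition_order = np.arange(n_channels)
    return ProbeGeometry(
        shank_positions_um=shank_positions,
        sites_per_shank=sites_per_shank,
        site_offsets_um=np.asarray(site_offsets_um, float),
        channel_map=channel_map,
        acquisition_order=acquisition_order,
        n_slots=n_slots,
    )


@dataclass(frozen=True)
class RecordingConfig:
    """Sampling configuration of a multiplexed extracellular recording."""

    fs_hz: float = 30_000.0
    adc_hz: float = 1_050_000.0
    n_slots: int = 35
    duration_s: float = 5.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if abs(self.adc_hz / self.n_slots - self.fs_hz) > 1e-9 * self.fs_hz:
            raise ValueError("adc_hz / n_slots must equal fs_hz")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
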