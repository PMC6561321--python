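"""Plex layout: which TMT channel carries which condition.

A six-plex experiment quantifies five samples plus a pooled reference in
one LC-MS run.  Reporter channels are named ``tmt126`` … ``tmt131``; by
default the unexposed ground control sits in 126, the four space-surviving
strains in 127–130, and channel 131 carries an equal-mass pool of all five
samples that serves as the internal reference for cross-plex scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

CHANNELS: tuple[str, ...] = (
    "tmt126",
    "tmt127",
    "tmt128",
    "tmt129",
    "tmt130",
    "tmt131",
)

#: Non-control study conditions, in channel order.
CONTROL_CONDITION = "ground_control"
STRAIN_CONDITIONS: tuple[str, ...] = (
    "uv_space",
    "uv_mars",
    "dark_space",
    "dark_mars",
)
CONDITIONS: tuple[str, ...] = (CONTROL_CONDITION,) + STRAIN_CONDITIONS

DEFAULT_CHANNEL_TO_CONDITION: dict[str, str] = {
    "tmt126": CONTROL_CONDITION,
    "tmt127": "uv_space",
    "tmt128": "uv_mars",
    "tmt129": "dark_space",
    "tmt130": "dark_mars",
}


class DesignError(ValueError):
    """Raised when a plex design violates its structural invariants."""


@dataclass(frozen=True)
class PlexDesign:
    """Maps reporter channels to experimental conditions for one plex.

    Exactly one channel is the pooled reference; it carries no condition
    label of its own and is excluded from the condition set.
    """

    plex_id: str
    channel_to_condition: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_TO_CONDITION)
    )
    reference_channel: str = "tmt131"

    def __post_init__(self) -> None:
        unknown = set(self.channel_to_condition) - set(CHANNELS)
        if unknown:
            raise DesignError(f"unknown channel labels: {sorted(unknown)}")
        if self.reference_channel not in CHANNELS:
            raise DesignError(
                f"unknown reference channel {self.reference_channel!r}"
            )
        if self.reference_channel in self.channel_to_condition:
            raise DesignError(
                "reference channel must not carry a condition label"
            )
        conditions = list(self.channel_to_condition.values())
        if len(set(conditions)) != len(conditions):
            raise DesignError("condition names must be unique across channels")

    @property
    def sample_channels(self) -> tuple[str, ...]:
        """Channels carrying samples, in canonical channel order."""
        return tuple(c for c in CHANNELS if c in self.channel_to_condition)

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.channel_to_condition[c] for c in self.sample_channels)

    def channel_for(self, condition: str) -> str:
        for channel, cond in self.channel_to_condition.items():
            if cond == condition:
                return channel
        raise KeyError(condition)


def default_design(plex_id: str) -> PlexDesign:
    """The study layout: control in 126, strains in 127-130, reference 131."""
    return PlexDesign(plex_id=plex_id)


def read_design_yaml(path) -> PlexDesign:
    """Load a plex design from a YAML mapping.

    Expected keys: ``plex_id``, ``channel_to_condition`` (mapping) and
    optionally ``reference_channel`` (default ``tmt131``).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PlexDesign(
        plex_id=str(raw["plex_id"]),
        channel_to_condition=dict(raw["channel_to_condition"]),
        reference_channel=raw.get("reference_channel", "tmt131"),
    )
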