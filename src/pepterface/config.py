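"""Geometric cutoff configuration with documented defaults.

Defaults follow the interaction criteria used to characterize the docked
complexes: close contacts and hydrophobic carbon-carbon contacts within
4.0 A (inclusive), hydrogen bonds at donor-acceptor distance <= 4.0 A with
D-H...A deviation from linearity <= 40 degrees, and inter-chain interface
residues at C-alpha distance strictly below 6.0 A.  Salt-bridge and pi-pi
cutoffs are this package's documented assumptions (see docs/methods.md).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["GeometryConfig"]


@dataclass(frozen=True)
class GeometryConfig:
    close_contact_cutoff: float = 4.0       # A, inclusive ("within")
    hydrophobic_cutoff: float = 4.0         # A, C-C pairs, inclusive
    hbond_distance_cutoff: float = 4.0      # A, donor-acceptor heavy atoms
    hbond_angle_cutoff: float = 40.0        # deg, deviation of D-H...A from 180
    hbond_distance_no_hydrogen: float = 3.5 # A, donors lacking explicit H
    salt_bridge_cutoff: float = 4.0         # A, minimal inter-group distance
    pipi_centroid_cutoff: float = 5.5       # A, ring centroid separation
    pipi_angle_cutoff: float = 30.0         # deg, inter-plane angle (parallel)
    interface_ca_cutoff: float = 6.0        # A, C-alpha pairs, strict <
    heavy_only: bool = False                # drop hydrogens in contact counts

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeometryConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
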