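"""Sensor montage: labels, unit-sphere positions, neighbourhoods and channel roles.

The analysis only ever touches the parieto-occipital sites P7/P8, the ocular
channels, and the neighbourhood graph used for bad-channel interpolation, so
the montage is deliberately lightweight: a label list, unit-sphere positions,
an undirected neighbour map restricted to scalp channels, and a role per
channel (``scalp``, ``vertical-ocular``, ``horizontal-ocular``, ``reference``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

SCALP = "scalp"
VEOG = "vertical-ocular"
HEOG = "horizontal-ocular"
REFERENCE = "reference"

# Approximate 10-20 head-surface directions (x = right, y = front, z = up).
_POSITIONS = {
    "Cz": (0.0, 0.0, 1.0),
    "Pz": (0.0, -0.71, 0.71),
    "Fz": (0.0, 0.71, 0.71),
    "P7": (-0.81, -0.59, 0.0),
    "P8": (0.81, -0.59, 0.0),
    "P3": (-0.55, -0.67, 0.5),
    "P4": (0.55, -0.67, 0.5),
    "O1": (-0.31, -0.95, 0.0),
    "O2": (0.31, -0.95, 0.0),
    "F3": (-0.55, 0.67, 0.5),
    "F4": (0.55, 0.67, 0.5),
    "C3": (-0.71, 0.0, 0.71),
    "C4": (0.71, 0.0, 0.71),
    "T7": (-1.0, 0.0, 0.0),
    "T8": (1.0, 0.0, 0.0),
    "F7": (-0.81, 0.59, 0.0),
    "F8": (0.81, 0.59, 0.0),
    "Fp1": (-0.31, 0.95, 0.0),
    "Fp2": (0.31, 0.95, 0.0),
    "VEOGU": (-0.29, 0.93, 0.22),
    "VEOGL": (-0.29, 0.93, -0.22),
    "HEOGL": (-0.88, 0.47, -0.08),
    "HEOGR": (0.88, 0.47, -0.08),
}

_ROLES = {
    "Cz": REFERENCE,
    "VEOGU": VEOG,
    "VEOGL": VEOG,
    "HEOGL": HEOG,
    "HEOGR": HEOG,
}

# Channels every montage must carry, in fill order.
_CORE = ["Cz", "P7", "P8", "VEOGU", "VEOGL", "HEOGL", "HEOGR",
         "Pz", "O1", "O2", "P3", "P4", "F3", "F4", "Fz", "Fp1",
         "Fp2", "C3", "C4", "T7", "T8", "F7", "F8"]

FRONTAL_LABELS = frozenset({"Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"})

MIN_CHANNELS = 16


@dataclass
class Montage:
    channel_labels: list[str]
    positions: dict[str, np.ndarray]
    neighbor_map: dict[str, frozenset[str]]
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = self.channel_labels
        if len(set(labels)) != len(labels):
            raise ConfigurationError("montage labels must be unique")
        for required in ("P7", "P8", "Cz"):
            if required not in labels:
                raise ConfigurationError(f"montage must contain {required}")
        for lab in labels:
            pos = np.asarray(self.positions[lab], dtype=float)
            if abs(np.linalg.norm(pos) - 1.0) > 1e-6:
                raise ConfigurationError(f"position of {lab} is not unit-norm")
            self.positions[lab] = pos
        for lab in self.scalp_channels():
            if len(self.neighbor_map.get(lab, ())) < 2:
                raise ConfigurationError(f"scalp channel {lab} has <2 neighbors")

    def role(self, label: str) -> str:
        return self.roles.get(label, SCALP)

    def scalp_channels(self) -> list[str]:
        return [c for c in self.channel_labels if self.role(c) == SCALP]

    def ocular_channels(self, which: str) -> list[str]:
        return [c for c in self.channel_labels if self.role(c) == which]

    def frontal_scalp_channels(self) -> list[str]:
        return [c for c in self.scalp_channels() if c in FRONTAL_LABELS]

    def distance(self, a: str, b: str) -> float:
        return float(np.linalg.norm(self.positions[a] - self.positions[b]))

    # -- serialisation -------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "channel_labels": self.channel_labels,
            "positions": {k: list(map(float, v)) for k, v in self.positions.items()},
            "neighbor_map": {k: sorted(v) for k, v in self.neighbor_map.items()},
            "roles": self.roles,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "Montage":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            channel_labels=payload["channel_labels"],
            positions={k: np.asarray(v, float) for k, v in payload["positions"].items()},
            neighbor_map={k: frozenset(v) for k, v in payload["neighbor_map"].items()},
            roles=payload["roles"],
        )


def _fibonacci_points(n: int) -> np.ndarray:
    """Deterministic extra sensor directions on the upper hemisphere."""
    i = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    z = 0.05 + 0.9 * (i + 0.5) / n          # keep off the vertex and the rim
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z ** 2)
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def build_montage(n_channels: int = MIN_CHANNELS, n_neighbors: int = 4) -> Montage:
    """Build a deterministic montage with ``n_channels`` sensors (≥ 16).

    The first channels come from a 10-20 table (always including Cz, P7, P8
    and the four ocular sensors); any surplus is placed on a Fibonacci
    lattice over the upper hemisphere. Scalp neighbourhoods are symmetrised
    k-nearest-neighbour sets by chord distance.
    """
    if n_channels < MIN_CHANNELS:
        raise ConfigurationError(
            f"n_channels must be ≥ {MIN_CHANNELS}, got {n_channels}")
    labels = list(_CORE[:n_channels])
    positions = {lab: np.asarray(_POSITIONS[lab], float) for lab in labels}
    if n_channels > len(_CORE):
        extra = _fibonacci_points(n_channels - len(_CORE))
        for k, vec in enumerate(extra):
            lab = f"E{k + 1}"
            labels.append(lab)
            positions[lab] = vec
    positions = {lab: v / np.linalg.norm(v) for lab, v in positions.items()}
    roles = {lab: _ROLES.get(lab, SCALP) for lab in labels}

    scalp = [lab for lab in labels if roles[lab] == SCALP]
    neighbor_map: dict[str, set[str]] = {lab: set() for lab in scalp}
    for lab in scalp:
        dists = sorted(
            (float(np.linalg.norm(positions[lab] - positions[o])), o)
            for o in scalp if o != lab
        )
        for _, other in dists[:n_neighbors]:
            neighbor_map[lab].add(other)
            neighbor_map[other].add(lab)
    return Montage(
        channel_labels=labels,
        positions=positions,
        neighbor_map={k: frozenset(v) for k, v in neighbor_map.items()},
        roles=roles,
    )
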