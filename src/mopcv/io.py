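"""Persistence: COLVAR-style time series, polymer archives, run configs.

Time series of CV and bias values use the whitespace-delimited COLVAR
convention of the biasing ecosystem (`#! FIELDS time <names...>` header,
17-significant-digit floats, exact round trip). Polymer snapshot archives
are HDF5 containers with one group per sample, so individual samples can be
read back without loading the whole archive.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import h5py
import numpy as np
import yaml

from .dynamics import Trajectory
from .mop import PathSample


class ColvarParseError(ValueError):
    """Malformed COLVAR file."""


def write_colvar(path, trajectory: Trajectory, cv_name: str = "cv") -> None:
    """Write time / CV / bias columns; positions are not stored here."""
    fields = ["time"]
    cols = [trajectory.times]
    if trajectory.cv_values is not None:
        fields.append(cv_name)
        cols.append(trajectory.cv_values)
    if trajectory.bias_values is not None:
        fields.append("bias")
        cols.append(trajectory.bias_values)
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_colvar(path) -> dict[str, np.ndarray]:
    """Parse a COLVAR file into {field name: column array}."""
    with open(path, "r", newline=None) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise ColvarParseError(f"{path}: line 1: missing '#! FIELDS' header")
    names = lines[0].split()[2:]
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != len(names):
            raise ColvarParseError(
                f"{path}: line {i}: expected {len(names)} columns, "
                f"got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ColvarParseError(f"{path}: line {i}: {exc}") from exc
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(names))
    return {name: data[:, j] for j, name in enumerate(names)}


class ArchiveError(RuntimeError):
    """Truncated or inconsistent polymer archive."""


def write_polymer_archive(path, samples: Sequence[PathSample]) -> None:
    """Store PathSamples losslessly in an HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.attrs["n_samples"] = len(samples)
        for i, s in enumerate(samples):
            g = fh.create_group(f"sample_{i:06d}")
            g.create_dataset("beads", data=s.beads)
            g.attrs["v_eff"] = s.v_eff
            g.attrs["S"] = s.S
            g.attrs["step"] = s.step


def read_polymer_archive(path, indices: Optional[Sequence[int]] = None
                         ) -> list[PathSample]:
    """Read samples back; ``indices`` selects a subset without a full scan."""
    out = []
    with h5py.File(path, "r") as fh:
        n = int(fh.attrs.get("n_samples", -1))
        idxs = range(n) if indices is None else indices
        for i in idxs:
            key = f"sample_{i:06d}"
            if key not in fh:
                last = i - 1
                raise ArchiveError(
                    f"{path}: truncated archive; last valid sample {last}")
            g = fh[key]
            out.append(PathSample(beads=g["beads"][...],
                                  v_eff=float(g.attrs["v_eff"]),
                                  S=float(g.attrs["S"]),
                                  step=int(g.attrs["step"])))
    return out


def iter_polymer_archive(path) -> Iterator[PathSample]:
    """Stream samples one by one (constant memory)."""
    with h5py.File(path, "r") as fh:
        n = int(fh.attrs.get("n_samples", 0))
        for i in range(n):
            key = f"sample_{i:06d}"
            if key not in fh:
                raise ArchiveError(
                    f"{path}: truncated archive; last valid sample {i - 1}")
            g = fh[key]
            yield PathSample(beads=g["beads"][...],
                             v_eff=float(g.attrs["v_eff"]),
                             S=float(g.attrs["S"]),
                             step=int(g.attrs["step"]))


# --- run configuration -------------------------------------------------------

_DEFAULT_CONFIG: dict = {
    "potential": {"name": "muller_brown_modified", "params": {}},
    "thermo": {"temperature": 0.1},
    "dynamics": {"mass": 1.0, "damping": 10.0, "dt": 0.01},
    "bias": {"barrier": 17.0, "pace": 300, "sigma": 0.03,
             "adaptive_sigma": False},
    "training": {"alpha": 1.0, "beta_loss": 250.0, "learning_rate": 1.0e-3,
                 "l2": 1.0e-5, "patience": 15},
    "protocol": {"trapped_threshold": 0.3, "reactive_threshold": 1.0,
                 "ts_multiplier": 3.0, "per_state_cap": 6000},
    "seed": 0,
    "output_dir": "runs",
}


@dataclass
class RunConfig:
    """YAML-backed run configuration with a mandatory global seed."""

    sections: dict = field(default_factory=lambda: json.loads(
        json.dumps(_DEFAULT_CONFIG)))

    def __post_init__(self) -> None:
        if "seed" not in self.sections:
            raise ValueError("config must declare a global seed")

    @property
    def seed(self) -> int:
        return int(self.sections["seed"])

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global one."""
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        merged = json.loads(json.dumps(_DEFAULT_CONFIG))
        for key, val in data.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
        return cls(sections=merged)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.sections, fh, sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.sections, sort_keys=True).encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        import numpy
        import scipy

        from . import __version__
        return {"config_hash": self.content_hash(), "seed": self.seed,
                "versions": {"mopcv": __version__, "numpy": numpy.__version__,
                             "scipy": scipy.__version__}}
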