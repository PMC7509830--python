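"""Sensor geometry for the 128-channel geodesic net.

The montage lives on a unit sphere (nose +y, vertex +z). Absolute positions
only matter for neighbor structure (bad-channel interpolation) and 2D
topography plotting, so a standard geodesic layout packaged as a plain-text
table is sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = ["Montage", "MontageFormatError", "load_montage"]

N_SENSORS = 128
N_NEIGHBORS = 6  # default interpolation set size


class MontageFormatError(ValueError):
    """Raised when a montage resource is missing or malformed."""


@dataclass(frozen=True)
class Montage:
    """128 sensors on a unit sphere with a symmetric neighbor relation.

    Attributes
    ----------
    positions : (128, 3) float array
        Unit-norm sensor coordinates, row ``i`` is sensor id ``i + 1``.
    neighbors : dict[int, tuple[int, ...]]
        Symmetrized 6-nearest-neighbor adjacency keyed by 1-based sensor id.
    """

    positions: np.ndarray
    neighbors: dict[int, tuple[int, ...]] = field(repr=False)

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    def position(self, sensor_id: int) -> np.ndarray:
        self._check_id(sensor_id)
        return self.positions[sensor_id - 1]

    def nearest(self, sensor_id: int, k: int = N_NEIGHBORS,
                exclude: set[int] | None = None) -> list[int]:
        """The ``k`` nearest other sensors by chord distance.

        ``exclude`` removes candidates (e.g. other bad channels); the search
        widens automatically since ranking covers all remaining sensors.
        """
        self._check_id(sensor_id)
        exclude = set(exclude or ())
        d = np.linalg.norm(self.positions - self.positions[sensor_id - 1], axis=1)
        order = np.argsort(d, kind="stable")
        out = []
        for idx in order:
            sid = int(idx) + 1
            if sid == sensor_id or sid in exclude:
                continue
            out.append(sid)
            if len(out) == k:
                break
        if len(out) < k:
            raise ValueError(f"fewer than {k} candidate neighbors for sensor {sensor_id}")
        return out

    def _check_id(self, sensor_id: int) -> None:
        if not 1 <= sensor_id <= self.n_sensors:
            raise KeyError(f"sensor id {sensor_id} outside 1..{self.n_sensors}")

    def project_2d(self) -> np.ndarray:
        """Azimuthal-equidistant projection (vertex at origin, nose up)."""
        x, y, z = self.positions.T
        theta = np.arccos(np.clip(z, -1.0, 1.0))
        phi = np.arctan2(x, y)  # 0 at nose, clockwise seen from above
        return np.column_stack([theta * np.sin(phi), theta * np.cos(phi)])


def _build_neighbors(positions: np.ndarray, k: int = N_NEIGHBORS) -> dict[int, tuple[int, ...]]:
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    knn = np.argsort(d, axis=1, kind="stable")[:, :k]
    adj: dict[int, set[int]] = {i + 1: set() for i in range(len(positions))}
    for i, row in enumerate(knn):
        for j in row:
            adj[i + 1].add(int(j) + 1)
            adj[int(j) + 1].add(i + 1)  # symmetrize
    return {i: tuple(sorted(s)) for i, s in adj.items()}


def load_montage(resource_name: str = "hsn128") -> Montage:
    """Load a packaged sensor layout by name (currently only ``"hsn128"``)."""
    fname = f"{resource_name}.tsv"
    ref = resources.files("ssvepkit.data").joinpath(fname)
    if not ref.is_file():
        raise MontageFormatError(f"no packaged montage named {resource_name!r}")
    ids, rows = [], []
    for line in ref.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("sensor_id"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise MontageFormatError(f"malformed montage row: {line!r}")
        ids.append(int(parts[0]))
        rows.append([float(v) for v in parts[1:]])
    if ids != list(range(1, N_SENSORS + 1)):
        raise MontageFormatError(
            f"montage {resource_name!r} must list sensors 1..{N_SENSORS} in order")
    positions = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(positions, axis=1, keepdims=True)
    positions = positions / norms
    return Montage(positions=positions, neighbors=_build_neighbors(positions))
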