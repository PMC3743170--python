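"""Toroidal Kohonen self-organizing map for chemical-space projection.

An online-trained SOM on a rectangular grid whose opposite edges are
identified (torus), removing border effects. Defaults follow the production
setup used for descriptor-space projection of screening collections: a 16x10
grid (160 cells), 10^6 training cycles, and an initial Gaussian neighborhood
radius of 8. Codebook initialization, the linear decay schedules, and BMU
tie-breaking are fully determined by the seed, so identical configuration and
data reproduce identical models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "SOMConfig",
    "SOMModel",
    "torus_cell_distance",
    "train_som",
    "density_map",
    "quantization_error",
]

FINAL_RADIUS = 0.5
FINAL_LEARNING_RATE = 0.01


@dataclass
class SOMConfig:
    width: int = 16
    height: int = 10
    toroidal: bool = True
    cycles: int = 10**6
    radius0: float = 8.0
    learning_rate0: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width * self.height < 2:
            raise ValueError("grid must have >= 2 cells")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if self.radius0 <= 0:
            raise ValueError("radius0 must be > 0")

    @property
    def n_cells(self) -> int:
        return self.width * self.height


@dataclass
class SOMModel:
    config: SOMConfig
    codebook: np.ndarray                      # (n_cells, dim), row = y*width + x
    assignments: dict[str, tuple[int, int]]   # compound id -> (x, y)

    def cell_of(self, compound_id: str) -> tuple[int, int]:
        return self.assignments[compound_id]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": asdict(self.config),
            "codebook": self.codebook.tolist(),
            "assignments": {k: list(v) for k, v in self.assignments.items()},
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SOMModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            SOMConfig(**payload["config"]),
            np.asarray(payload["codebook"], dtype=float),
            {k: (int(x), int(y)) for k, (x, y) in payload["assignments"].items()},
        )


def torus_cell_distance(c1: tuple[int, int], c2: tuple[int, int],
                        width: int, height: int) -> float:
    """Euclidean cell distance with wrap-around coordinate deltas."""
    (x1, y1), (x2, y2) = c1, c2
    for (x, y) in (c1, c2):
        if not (0 <= x < width and 0 <= y < height):
            raise ValueError(f"cell ({x}, {y}) outside {width}x{height} grid")
    dx = min(abs(x1 - x2), width - abs(x1 - x2))
    dy = min(abs(y1 - y2), height - abs(y1 - y2))
    return float(np.hypot(dx, dy))


def _cell_distance_matrix(config: SOMConfig) -> np.ndarray:
    """(n_cells, n_cells) grid distances; toroidal wrap if configured."""
    w, h = config.width, config.height
    xs, ys = np.meshgrid(np.arange(w), np.arange(h))   # row-major: cell = y*w + x
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    diff = np.abs(coords[:, None, :] - coords[None, :, :])
    if config.toroidal:
        diff[:, :, 0] = np.minimum(diff[:, :, 0], w - diff[:, :, 0])
        diff[:, :, 1] = np.minimum(diff[:, :, 1], h - diff[:, :, 1])
    return np.sqrt((diff**2).sum(axis=2))


def train_som(
    data: np.ndarray,
    config: SOMConfig,
    ids: Sequence[str] | None = None,
) -> SOMModel:
    """Online Kohonen training.

    Per cycle one input row is drawn (seeded RNG), its best-matching unit
    (BMU: codebook row at minimal Euclidean distance, ties broken toward the
    lowest flattened cell index) is found, and every codebook row w is moved by
    eta(t) * exp(-d_grid^2 / (2 sigma(t)^2)) * (x - w), where d_grid is the
    (toroidal) grid distance to the BMU cell. sigma decays linearly from
    radius0 to 0.5 and eta from learning_rate0 to 0.01 over the cycles. The
    codebook is initialized by sampling input rows. ``cycles=0`` returns the
    initial codebook unchanged.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] == 0:
        raise ValueError("data must be a nonempty 2-D matrix")
    ids = list(ids) if ids is not None else [str(i) for i in range(data.shape[0])]
    if len(ids) != data.shape[0]:
        raise ValueError("ids length must match data rows")
    bad = np.flatnonzero(~np.isfinite(data).all(axis=1))
    if bad.size:
        raise ValueError(f"non-finite descriptor row for id {ids[bad[0]]!r}")
    n_rows, _ = data.shape
    if n_rows < config.n_cells / 4:
        log.warning("only %d rows for %d cells; map may be underdetermined",
                    n_rows, config.n_cells)

    rng = np.random.default_rng(config.seed)
    init_idx = rng.choice(n_rows, size=config.n_cells, replace=n_rows < config.n_cells)
    codebook = data[init_idx].copy()
    grid_dist = _cell_distance_matrix(config)

    cycles = config.cycles
    denom = max(cycles - 1, 1)
    for t in range(cycles):
        frac = t / denom
        sigma = config.radius0 + (FINAL_RADIUS - config.radius0) * frac
        eta = config.learning_rate0 + (FINAL_LEARNING_RATE - config.learning_rate0) * frac
        x = data[rng.integers(n_rows)]
        bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
        influence = eta * np.exp(-grid_dist[bmu] ** 2 / (2.0 * sigma**2))
        codebook += influence[:, None] * (x - codebook)

    assignments: dict[str, tuple[int, int]] = {}
    for i, cid in enumerate(ids):
        bmu = int(np.argmin(((codebook - data[i]) ** 2).sum(axis=1)))
        assignments[cid] = (bmu % config.width, bmu // config.width)
    return SOMModel(config, codebook, assignments)


def quantization_error(codebook: np.ndarray, data: np.ndarray) -> float:
    """Mean Euclidean distance from each input row to its BMU."""
    data = np.asarray(data, dtype=float)
    d2 = ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())


def density_map(model: SOMModel, subset: Sequence[str] | set[str]) -> np.ndarray:
    """Per-cell occupancy counts (height x width grid) for a compound subset."""
    grid = np.zeros((model.config.height, model.config.width), dtype=int)
    for cid in subset:
        if cid not in model.assignments:
            raise KeyError(f"compound {cid!r} is not assigned to any cell")
        x, y = model.assignments[cid]
        grid[y, x] += 1
    return grid
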