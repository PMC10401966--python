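"""Self-organizing map clustering of compound activity profiles.

Compounds screened in a quantitative high-throughput screen are summarized
as integer "curve rank" scores in [-9, 9] per assay (positive = activation,
negative = inhibition).  A Kohonen self-organizing map (SOM) is trained on
these activity profiles with a Euclidean metric; each compound is then
assigned to its best-matching unit (BMU), and occupied units define the
pre-merge clusters.

Training is the classical online algorithm: per presented sample, find the
BMU and pull every unit toward the sample, weighted by a neighborhood
kernel over grid distance.  Learning rate and radius decay linearly over
the run.  Everything is deterministic given the config seed, which controls
both weight initialization (sampling of data rows) and presentation order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CURVE_RANK_MIN = -9
CURVE_RANK_MAX = 9


@dataclass
class ActivityMatrix:
    """Compounds x assays matrix of curve-rank activity scores."""

    compound_ids: list[str]
    assay_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.assay_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.compound_ids)} compounds x {len(self.assay_ids)} assays"
            )

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_assays(self) -> int:
        return len(self.assay_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.compound_ids, name="compound_id"),
                            columns=self.assay_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ActivityMatrix":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)),
                   frame.to_numpy(dtype=float))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "ActivityMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


def filter_complete(matrix: ActivityMatrix | pd.DataFrame) -> tuple[ActivityMatrix, int]:
    """Drop compounds with any missing assay value.

    Mirrors the activity-complete filter applied to the screening library:
    only compounds with curve-rank data across *all* assays are clustered.

    Returns the filtered matrix and the number of compounds removed.
    Raises ``ValueError`` if no complete compound remains.
    """
    if isinstance(matrix, pd.DataFrame):
        matrix = ActivityMatrix.from_frame(matrix)
    keep = np.isfinite(matrix.values).all(axis=1)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("no compound has complete activity data")
    if n_removed:
        logger.info("filter_complete: removed %d of %d compounds with missing values",
                    n_removed, matrix.n_compounds)
    filtered = ActivityMatrix(
        [cid for cid, k in zip(matrix.compound_ids, keep) if k],
        list(matrix.assay_ids),
        matrix.values[keep],
    )
    return filtered, n_removed


@dataclass(frozen=True)
class SomConfig:
    """Hyperparameters for online SOM training.

    The grid defaults to 12x12, sized for a library on the order of
    10,000 compounds; smaller studies should scale the grid down so that
    compounds outnumber units.
    """

    grid_rows: int = 12
    grid_cols: int = 12
    topology: str = "rectangular"  # or "hexagonal"
    n_epochs: int = 20
    alpha_start: float = 0.5
    alpha_end: float = 0.01
    radius_start: float | None = None  # default: max(grid_rows, grid_cols) / 2
    radius_end: float = 0.5
    neighborhood: str = "gaussian"  # or "bubble"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must have at least one unit")
        if self.topology not in ("rectangular", "hexagonal"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.neighborhood not in ("gaussian", "bubble"):
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")
        if self.alpha_end > self.alpha_start:
            raise ValueError("alpha must decay: alpha_end <= alpha_start")
        if self.radius_start is not None and self.radius_end > self.radius_start:
            raise ValueError("radius must decay: radius_end <= radius_start")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be >= 0")

    @property
    def n_units(self) -> int:
        return self.grid_rows * self.grid_cols

    def effective_radius_start(self) -> float:
        if self.radius_start is not None:
            return float(self.radius_start)
        return max(self.grid_rows, self.grid_cols) / 2.0


def grid_coordinates(rows: int, cols: int, topology: str) -> np.ndarray:
    """Planar layout coordinates of the units, row-major unit order.

    Rectangular grids use integer (x, y); hexagonal grids offset odd rows
    by half a unit and compress row spacing by sqrt(3)/2, the usual
    hex-lattice embedding, so Euclidean distance in the layout is the grid
    distance used by the neighborhood kernel.
    """
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = cc.astype(float)
    y = rr.astype(float)
    if topology == "hexagonal":
        x = x + 0.5 * (rr % 2)
        y = y * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel(), y.ravel()])


@dataclass
class Codebook:
    """Trained SOM unit weight vectors plus their grid layout."""

    weights: np.ndarray              # (n_units, n_assays)
    grid_positions: np.ndarray       # (n_units, 2) integer (row, col)
    layout: np.ndarray               # (n_units, 2) planar coordinates
    topology: str
    assay_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.assay_ids and self.weights.shape[1] != len(self.assay_ids):
            raise ValueError("weight dimensionality does not match assay count")

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    def grid_distances(self) -> np.ndarray:
        """Pairwise unit-to-unit distances on the grid layout."""
        diff = self.layout[:, None, :] - self.layout[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))

    def to_frame(self) -> pd.DataFrame:
        cols = self.assay_ids or [f"dim{j}" for j in range(self.weights.shape[1])]
        frame = pd.DataFrame(self.weights, columns=cols)
        frame.insert(0, "col", self.grid_positions[:, 1])
        frame.insert(0, "row", self.grid_positions[:, 0])
        frame.index.name = "unit"
        return frame

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path, topology: str = "rectangular") -> "Codebook":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        pos = frame[["row", "col"]].to_numpy(dtype=int)
        weights = frame.drop(columns=["row", "col"]).to_numpy(dtype=float)
        rows, cols = pos[:, 0].max() + 1, pos[:, 1].max() + 1
        layout = grid_coordinates(rows, cols, topology)
        return cls(weights, pos, layout, topology,
                   [c for c in frame.columns if c not in ("row", "col")])


@dataclass
class ClusterAssignment:
    """Compound -> cluster labels (cluster = codebook unit index pre-merge)."""

    compound_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.compound_ids),):
            raise ValueError("one label per compound required")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts)}

    def cluster_labels(self) -> list[int]:
        return sorted(self.sizes())

    def members(self, label: int) -> list[str]:
        return [cid for cid, lab in zip(self.compound_ids, self.labels) if lab == label]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"compound_id": self.compound_ids, "cluster": self.labels})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ClusterAssignment":
        frame = pd.read_csv(path, sep="\t", dtype={"compound_id": str})
        return cls(list(frame["compound_id"]), frame["cluster"].to_numpy(dtype=int))


def train_som(matrix: ActivityMatrix, config: SomConfig) -> Codebook:
    """Train a SOM on the activity matrix by online Kohonen updates.

    Per presented sample x: the best-matching unit b minimizes
    ||x - w_u||; every unit is updated as

        w_u <- w_u + alpha(t) * h(d_grid(u, b), r(t)) * (x - w_u)

    with h a Gaussian kernel exp(-d^2 / (2 r^2)) (or a bubble kernel
    d <= r), and alpha, r interpolating linearly from their start to end
    values over ``n_epochs`` passes through the data.  ``n_epochs=0``
    returns the initialization (seeded sampling of data rows).
    """
    X = np.asarray(matrix.values, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("activity matrix contains non-finite values; run filter_complete first")
    n, m = X.shape
    if n < config.n_units:
        warnings.warn(
            f"fewer compounds ({n}) than SOM units ({config.n_units}); "
            "consider a smaller grid", stacklevel=2)

    rng = np.random.default_rng(config.seed)
    init_idx = rng.choice(n, size=config.n_units, replace=n < config.n_units)
    weights = X[init_idx].copy()

    layout = grid_coordinates(config.grid_rows, config.grid_cols, config.topology)
    pos = np.column_stack(np.unravel_index(np.arange(config.n_units),
                                           (config.grid_rows, config.grid_cols)))
    diff = layout[:, None, :] - layout[None, :, :]
    grid_d2 = (diff ** 2).sum(axis=2)
    grid_d = np.sqrt(grid_d2)

    a0, a1 = config.alpha_start, config.alpha_end
    r0, r1 = config.effective_radius_start(), config.radius_end
    total = config.n_epochs * n
    t = 0
    for _ in range(config.n_epochs):
        order = rng.permutation(n)
        for i in order:
            x = X[i]
            bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
            frac = t / (total - 1) if total > 1 else 0.0
            alpha = a0 + (a1 - a0) * frac
            radius = r0 + (r1 - r0) * frac
            if config.neighborhood == "gaussian":
                h = np.exp(-grid_d2[bmu] / (2.0 * radius * radius))
            else:
                h = (grid_d[bmu] <= radius).astype(float)
            weights += alpha * h[:, None] * (x - weights)
            t += 1

    return Codebook(weights, pos, layout, config.topology, list(matrix.assay_ids))


def assign_bmu(codebook: Codebook, matrix: ActivityMatrix) -> ClusterAssignment:
    """Label each compound with its nearest codebook unit (Euclidean).

    Ties are broken by the lowest unit index.
    """
    X = np.asarray(matrix.values, dtype=float)
    W = codebook.weights
    labels = np.empty(X.shape[0], dtype=int)
    # direct (not expanded) squared distances so exact ties stay exact;
    # chunked over compounds to bound memory at chunk x units x assays
    chunk = max(1, 2_000_000 // max(1, W.shape[0] * W.shape[1]))
    for start in range(0, X.shape[0], chunk):
        block = X[start:start + chunk]
        d2 = ((block[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
        # argmin returns the first (lowest) unit index on ties
        labels[start:start + chunk] = d2.argmin(axis=1)
    return ClusterAssignment(list(matrix.compound_ids), labels)


def quantization_error(codebook: Codebook, matrix: ActivityMatrix,
                       assignment: ClusterAssignment | None = None) -> float:
    """Mean Euclidean distance from each compound to its BMU."""
    if assignment is None:
        assignment = assign_bmu(codebook, matrix)
    X = np.asarray(matrix.values, dtype=float)
    W = codebook.weights[assignment.labels]
    return float(np.sqrt(((X - W) ** 2).sum(axis=1)).mean())
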