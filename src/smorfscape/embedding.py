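"""Sequence embedding and the 2-D PCA landscape.

Embedders are pluggable: any callable mapping a sequence to a fixed-length
real vector can be wrapped, including adapters around external transformer
protein language models producing 1280-dimensional vectors.  The built-in
``composition`` embedder is fully deterministic and dependency-free: a
400-dimensional dipeptide-frequency profile pushed through a fixed seeded
near-orthogonal projection to the requested dimension.

The landscape is a mean-centered PCA (via SVD) keeping the first two
components, with a fixed sign convention so plots are reproducible.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .io import ProteinRecord

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}

EmbedFn = Callable[[str], np.ndarray]


@dataclass(frozen=True)
class EmbedderSpec:
    name: str = "composition"
    dimension: int = 1280
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("embedding dimension must be >= 2")


@dataclass
class EmbeddingMatrix:
    ids: list[str]
    vectors: np.ndarray  # (n, D)
    embedder: EmbedderSpec

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("EmbeddingMatrix ids must be unique")
        if self.vectors.shape[0] != len(self.ids):
            raise ValueError("row count must equal number of ids")
        if self.vectors.size and not np.all(np.isfinite(self.vectors)):
            raise ValueError("EmbeddingMatrix contains non-finite values")


@dataclass
class LandscapeModel:
    mean_vector: np.ndarray  # (D,)
    components: np.ndarray  # (2, D), orthonormal rows
    explained_variance: np.ndarray  # (2,)


_projection_cache: dict[tuple[int, int], np.ndarray] = {}


def _projection(seed: int, dim: int) -> np.ndarray:
    """Fixed seeded projection 400 -> dim with near-orthonormal rows of the
    transpose (exactly orthonormal when dim >= 400, via QR)."""
    key = (seed, dim)
    if key not in _projection_cache:
        rng = np.random.default_rng(seed)
        if dim >= 400:
            g = rng.standard_normal((dim, 400))
            q, _ = np.linalg.qr(g)  # (dim, 400), orthonormal columns
            proj = q.T  # (400, dim)
        else:
            proj = rng.standard_normal((400, dim)) / np.sqrt(dim)
        _projection_cache[key] = proj
    return _projection_cache[key]


def embed_composition(record: ProteinRecord, spec: EmbedderSpec) -> np.ndarray:
    """Dipeptide-frequency embedding projected to ``spec.dimension`` dims.

    Frequencies sum to 1 over observed dipeptides; dipeptides containing X
    are ignored.  Identical sequences always map to identical vectors.
    """
    seq = record.sequence
    if len(seq) < 2:
        raise ValueError(
            f"record {record.id!r}: sequence shorter than 2 cannot be embedded"
        )
    counts = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        ia, ib = _AA_INDEX.get(a), _AA_INDEX.get(b)
        if ia is not None and ib is not None:
            counts[ia * 20 + ib] += 1
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts @ _projection(spec.seed, spec.dimension)


def get_embedder(spec: EmbedderSpec, adapter: EmbedFn | None = None) -> EmbedFn:
    """Resolve a spec to an embedding function; ``adapter`` plugs in an
    external model (e.g. a transformer producing 1280-dim vectors)."""
    if adapter is not None:
        return adapter
    if spec.name == "composition":
        return lambda s: embed_composition(
            ProteinRecord(id="_", sequence=s), spec
        )
    raise ValueError(f"unknown embedder {spec.name!r}")


def embed_batch(
    records: Sequence[ProteinRecord],
    spec: EmbedderSpec = EmbedderSpec(),
    adapter: EmbedFn | None = None,
    n_workers: int = 1,
) -> EmbeddingMatrix:
    """Embed records in order; parallel execution is bit-identical to
    sequential because each row depends only on its own sequence."""
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("embed_batch: duplicate record ids")
    fn = get_embedder(spec, adapter)

    def run_one(r: ProteinRecord) -> np.ndarray:
        try:
            return np.asarray(fn(r.sequence), dtype=float)
        except Exception as exc:
            raise RuntimeError(f"embedding failed for record {r.id!r}: {exc}") from exc

    if n_workers > 1 and records:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            rows = list(pool.map(run_one, records))
    else:
        rows = [run_one(r) for r in records]
    vectors = (
        np.vstack(rows) if rows else np.empty((0, spec.dimension))
    )
    return EmbeddingMatrix(ids=ids, vectors=vectors, embedder=spec)


def fit_landscape(matrix: EmbeddingMatrix) -> LandscapeModel:
    """Mean-centered PCA keeping the top two components.

    The sign of each component is fixed so that its largest-magnitude
    loading is positive, making coordinates reproducible across runs.
    """
    x = matrix.vectors
    if x.shape[0] < 3:
        raise ValueError("landscape needs at least 3 points")
    mean = x.mean(axis=0)
    centered = x - mean
    if not np.any(np.abs(centered) > 1e-12):
        raise ValueError("landscape input has zero variance")
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    components = vt[:2].copy()
    for i in range(2):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    explained = (s[:2] ** 2) / (x.shape[0] - 1)
    return LandscapeModel(
        mean_vector=mean, components=components, explained_variance=explained
    )


def project_landscape(
    model: LandscapeModel, matrix: EmbeddingMatrix
) -> list[tuple[str, float, float]]:
    """Project rows onto the fitted landscape: (row - mean) @ components.T."""
    if matrix.vectors.shape[1] != model.mean_vector.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix has {matrix.vectors.shape[1]}, "
            f"model expects {model.mean_vector.shape[0]}"
        )
    coords = (matrix.vectors - model.mean_vector) @ model.components.T
    return [
        (rid, float(x), float(y)) for rid, (x, y) in zip(matrix.ids, coords)
    ]


def write_embeddings_tsv(matrix: EmbeddingMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(
            f"d{i}" for i in range(matrix.vectors.shape[1])) + "\n")
        for rid, row in zip(matrix.ids, matrix.vectors):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_embeddings_tsv(
    path: str | Path, spec: EmbedderSpec | None = None
) -> EmbeddingMatrix:
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        dim = len(header) - 1
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    vectors = np.asarray(rows) if rows else np.empty((0, dim))
    spec = spec or EmbedderSpec(name="composition", dimension=dim)
    return EmbeddingMatrix(ids=ids, vectors=vectors, embedder=spec)


def plot_landscape(
    coords: Sequence[tuple[str, float, float]],
    path: str | Path,
    overlay: Sequence[tuple[str, float, float]] | None = None,
) -> None:
    """Dot plot of landscape coordinates with an optional sample overlay."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xs = [c[1] for c in coords]
    ys = [c[2] for c in coords]
    ax.scatter(xs, ys, s=4, alpha=0.4, label="database")
    if overlay:
        ax.scatter(
            [c[1] for c in overlay],
            [c[2] for c in overlay],
            s=12,
            color="crimson",
            label="sample",
        )
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
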