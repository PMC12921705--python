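"""Patch tiling, patch encoding, and spatial k-NN graph construction.

The masked tissue at x5 is tiled into non-overlapping 256 x 256 patches
(grid anchored at the origin, row-major order); patches keeping at least
`tissue_fraction` of their pixels inside the mask survive. Each patch is
encoded to a 512-dim vector through a pluggable encoder, and patch centers
are linked by k-nearest-neighbour (k = 8) Euclidean edges, symmetrized by
union so every node keeps at least k neighbours.

The default encoder is a deterministic stand-in for a pretrained
histopathology foundation encoder: concatenated per-channel 64-bin
histograms plus channel means/stds, projected to 512 dims by a fixed seeded
random matrix. It honours the 512-dim interface contract so a real
pretrained encoder can be plugged in without touching the graph code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Protocol

import numpy as np

from .mask import TissueMask
from .wsi import SlideHandle, read_region

PATCH_SIZE = 256
WORKING_MAGNIFICATION = 5.0


class EmptySlideError(ValueError):
    """No patch passed the tissue-fraction filter."""


@dataclass
class PatchSet:
    slide_id: str
    coords: np.ndarray            # N x 2 int, patch top-left in x5 pixels (x, y)
    patch_size: int = PATCH_SIZE
    magnification: float = WORKING_MAGNIFICATION


class PatchEncoder(Protocol):
    name: str
    dim: int

    def encode(self, pixels: np.ndarray) -> np.ndarray: ...


class HistogramEncoder:
    """Deterministic seeded histogram-projection encoder (512-dim stand-in)."""

    def __init__(self, dim: int = 512, seed: int = 0, bins: int = 64):
        self.name = f"histogram-{bins}x3+moments/seed{seed}"
        self.dim = dim
        self.bins = bins
        rng = np.random.default_rng(seed)
        raw_dim = 3 * bins + 6
        self.projection = rng.normal(0.0, 1.0 / np.sqrt(raw_dim), (raw_dim, dim))

    def encode(self, pixels: np.ndarray) -> np.ndarray:
        px = np.asarray(pixels, dtype=float)
        feats = []
        for c in range(3):
            hist, _ = np.histogram(px[:, :, c], bins=self.bins, range=(0, 256))
            feats.append(hist / px[:, :, c].size)
        means = px.reshape(-1, 3).mean(axis=0) / 255.0
        stds = px.reshape(-1, 3).std(axis=0) / 255.0
        raw = np.concatenate([*feats, means, stds])
        return raw @ self.projection


@dataclass
class SlideGraph:
    slide_id: str
    features: np.ndarray   # N x 512
    coords: np.ndarray     # N x 2 (patch centers, x5 px)
    edges: np.ndarray      # E x 2 int, undirected, deduplicated, lexsorted
    k: int

    @property
    def n_nodes(self) -> int:
        return self.features.shape[0]

    def save(self, directory) -> Path:
        """Write features/coords/edges arrays plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        npz = directory / f"{self.slide_id}.graph.npz"
        np.savez_compressed(
            npz,
            features=self.features.astype(np.float32),
            coords=self.coords.astype(np.int32),
            edges=self.edges.astype(np.int32),
        )
        sidecar = directory / f"{self.slide_id}.graph.json"
        sidecar.write_text(json.dumps({
            "slide_id": self.slide_id, "k": self.k,
            "magnification": WORKING_MAGNIFICATION,
            "n_nodes": int(self.n_nodes),
        }, indent=2))
        return npz

    @classmethod
    def load(cls, npz_path) -> "SlideGraph":
        npz_path = Path(npz_path)
        meta = json.loads(npz_path.with_suffix(".json").read_text())
        with np.load(npz_path) as z:
            return cls(
                slide_id=meta["slide_id"],
                features=z["features"].astype(float),
                coords=z["coords"].astype(float),
                edges=z["edges"].astype(int),
                k=int(meta["k"]),
            )


def tile_patches(mask: TissueMask, tissue_fraction: float = 0.5,
                 patch_size: int = PATCH_SIZE, slide_id: str = "slide") -> PatchSet:
    """Regular-grid tiling of the mask; keep patches >= tissue_fraction in-mask."""
    m = mask.mask
    h, w = m.shape
    coords = []
    for y in range(0, h - patch_size + 1, patch_size):
        for x in range(0, w - patch_size + 1, patch_size):
            frac = m[y:y + patch_size, x:x + patch_size].mean()
            if frac >= tissue_fraction:
                coords.append((x, y))
    if not coords:
        raise EmptySlideError("no patch met the tissue-fraction threshold")
    return PatchSet(slide_id=slide_id, coords=np.array(coords, dtype=int),
                    patch_size=patch_size, magnification=mask.magnification)


def encode_patches(slide: SlideHandle, patches: PatchSet,
                   encoder: PatchEncoder) -> np.ndarray:
    """Encode each patch's RGB pixels (read at the working magnification)."""
    scale = slide.base_magnification / patches.magnification
    out = np.empty((len(patches.coords), encoder.dim))
    for i, (x, y) in enumerate(patches.coords):
        bbox = (int(x * scale), int(y * scale),
                int(patches.patch_size * scale), int(patches.patch_size * scale))
        try:
            region = read_region(slide, patches.magnification, bbox)
            out[i] = encoder.encode(region.pixels)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"encoder failed on patch {i} at {(x, y)}: {exc}") from exc
        if not np.all(np.isfinite(out[i])):
            raise RuntimeError(f"encoder produced non-finite values on patch {i}")
    return out


def knn_edges(coords: np.ndarray, k: int) -> np.ndarray:
    """Directed k-NN by Euclidean distance, union-symmetrized, deduplicated.

    Ties in distance break toward the lower node index. k is capped at N-1.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n <= 1:
        return np.empty((0, 2), dtype=int)
    k = min(k, n - 1)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    pairs = set()
    idx = np.arange(n)
    for i in range(n):
        # lexicographic (distance, index) order makes the tie rule explicit
        order = np.lexsort((idx, d2[i]))[:k]
        for j in order:
            pairs.add((min(i, int(j)), max(i, int(j))))
    edges = np.array(sorted(pairs), dtype=int)
    return edges


def build_knn_graph(coords: np.ndarray, features: np.ndarray, k: int = 8,
                    slide_id: str = "slide") -> SlideGraph:
    """Spatial k-NN graph on patch centers; features live on the nodes."""
    coords = np.asarray(coords, dtype=float)
    features = np.asarray(features, dtype=float)
    if len(coords) != len(features):
        raise ValueError("coords and features must have the same length")
    if len(coords) < 1:
        raise ValueError("need at least one node")
    return SlideGraph(slide_id=slide_id, features=features, coords=coords,
                      edges=knn_edges(coords, k), k=k)


def patch_centers(patches: PatchSet) -> np.ndarray:
    return patches.coords + patches.patch_size / 2.0
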