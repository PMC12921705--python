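"""Synthetic slides and synthetic patch-graph cohorts with planted hazards.

Two generators make every pipeline stage testable without external data:

* ``simulate_slide`` paints smooth saturated "stain" blobs on a near-white
  background — plus sub-threshold specks and carved holes — and emits the
  ground-truth tissue mask alongside the image, so the masking stage can be
  scored by IoU against a known answer.

* ``simulate_cohort`` builds patient cohorts of spatial patch graphs whose
  survival follows a proportional-hazards law driven by a planted
  graph-level signal: each patient has an "aggressive fraction" rho, that
  fraction of each slide's nodes gets a mean shift on a fixed block of
  feature dimensions, and the true linear predictor is eta = beta_true*rho.
  Event times are exponential with rate baseline_rate*exp(eta), censoring is
  an independent exponential, so the event fraction and the achievable
  concordance have closed forms to check against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from skimage.color import hsv2rgb

from .patchgraph import SlideGraph, build_knn_graph
from .risk import SurvivalRecord


# ---------------------------------------------------------------------------
# slides
# ---------------------------------------------------------------------------

@dataclass
class SlideSimConfig:
    width: int = 768
    height: int = 768
    n_blobs: int = 3
    blob_scale: float = 90.0          # px, Gaussian bump scale
    stain_hue: float = 0.83           # H&E-like purple-pink
    background: Tuple[int, int, int] = (246, 246, 244)
    speck_count: int = 6              # saturated specks below the area threshold
    hole_spec: Sequence[int] = (100, 64)  # carved hole areas (px)
    seed: int = 0

    def __post_init__(self):
        if self.width < 256 or self.height < 256:
            raise ValueError("slide must be at least 256x256")


def simulate_slide(cfg: SlideSimConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Return (RGB image uint8, ground-truth boolean tissue mask).

    The truth mask is the blob region minus the carved holes that the
    masking stage is expected to preserve (area > 16 px); smaller carved
    holes count as tissue because the pipeline fills them.
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.height, cfg.width
    yy, xx = np.mgrid[0:h, 0:w]

    field_ = np.zeros((h, w))
    for _ in range(max(cfg.n_blobs, 0)):
        cx = rng.uniform(0.2 * w, 0.8 * w)
        cy = rng.uniform(0.2 * h, 0.8 * h)
        sx = cfg.blob_scale * rng.uniform(0.7, 1.3)
        sy = cfg.blob_scale * rng.uniform(0.7, 1.3)
        field_ += np.exp(-(((xx - cx) / sx) ** 2 + ((yy - cy) / sy) ** 2) / 2.0)
    blob_mask = field_ > 0.5

    # stained tissue color with mild value noise
    hsv = np.zeros((h, w, 3))
    hsv[:, :, 0] = cfg.stain_hue
    hsv[:, :, 1] = 0.55 + 0.1 * rng.standard_normal((h, w)).clip(-2, 2) * 0.1
    hsv[:, :, 2] = 0.7 + 0.05 * rng.standard_normal((h, w)).clip(-2, 2)
    tissue_rgb = (hsv2rgb(np.clip(hsv, 0, 1)) * 255).astype(np.uint8)

    bg = np.array(cfg.background, dtype=float)
    image = bg[None, None, :] + rng.normal(0, 2.0, (h, w, 3))
    image = np.clip(image, 0, 255).astype(np.uint8)
    image[blob_mask] = tissue_rgb[blob_mask]

    # carve holes into the blob interior (background-coloured)
    truth = blob_mask.copy()
    carved = np.zeros((h, w), dtype=bool)
    interior = blob_mask.copy()
    interior[:32], interior[-32:], interior[:, :32], interior[:, -32:] = 0, 0, 0, 0
    ys, xs = np.nonzero(interior)
    for area in cfg.hole_spec:
        if len(ys) == 0:
            break
        side = max(int(round(np.sqrt(area))), 1)
        j = rng.integers(len(ys))
        cy, cx = ys[j], xs[j]
        sl = (slice(cy, cy + side), slice(cx, cx + side))
        if not blob_mask[sl].all() or carved[max(cy - 4, 0):cy + side + 4,
                                             max(cx - 4, 0):cx + side + 4].any():
            continue
        image[sl] = np.clip(bg + rng.normal(0, 2.0, (side, side, 3)), 0, 255).astype(np.uint8)
        carved[sl] = True
        if side * side > 16:  # preserved as a cavity by the masking stage
            truth[sl] = False

    # saturated specks on background, below the 100 px area threshold
    free = ~blob_mask
    free[:8], free[-8:], free[:, :8], free[:, -8:] = 0, 0, 0, 0
    ys, xs = np.nonzero(free)
    placed = 0
    while placed < cfg.speck_count and len(ys):
        j = rng.integers(len(ys))
        cy, cx = ys[j], xs[j]
        side = int(rng.integers(3, 6))  # area 9..25 << 100
        sl = (slice(cy, cy + side), slice(cx, cx + side))
        if free[sl].all():
            image[sl] = tissue_rgb[sl]
            free[max(cy - 8, 0):cy + side + 8, max(cx - 8, 0):cx + side + 8] = False
            placed += 1

    return image, truth


def write_slide(image: np.ndarray, path, magnification: float = 5.0,
                mpp: Optional[float] = None) -> Path:
    """Write a slide PNG plus the magnification sidecar the reader honours."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(image).save(path)
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(json.dumps(
        {"base_magnification": magnification, "mpp": mpp}))
    return path


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSimConfig:
    n_patients: int = 80
    slides_per_patient: Tuple[int, int] = (1, 3)      # inclusive range
    nodes_per_graph: Tuple[int, int] = (20, 60)       # inclusive range
    n_features: int = 512
    signal_dim_count: int = 16
    signal_shift: float = 2.0
    aggressive_fraction_range: Tuple[float, float] = (0.05, 0.95)
    beta_true: float = 2.0            # log-hazard per unit aggressive fraction
    baseline_rate: float = 0.01       # events / month at rho = 0
    censor_rate: float = 0.012        # censorings / month
    k: int = 8
    coord_extent: float = 2048.0      # x5 px
    weibull_shape: Optional[float] = None  # None -> exponential event times
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.aggressive_fraction_range
        if hi <= lo:
            raise ValueError("aggressive_fraction_range must have hi > lo")
        if self.baseline_rate <= 0 or self.censor_rate <= 0:
            raise ValueError("rates must be positive")
        if self.n_patients < 8:
            raise ValueError("need at least 8 patients")


Cohort = Dict[str, Tuple[SurvivalRecord, List[SlideGraph]]]


def simulate_cohort(cfg: CohortSimConfig) -> Tuple[Cohort, pd.DataFrame, pd.DataFrame]:
    """Generate a cohort of patch-graph patients with planted hazards.

    Returns (cohort, survival table, truth table). The survival table has one
    row per slide (patient_id, slide_id, time_months, event); the truth table
    stores each patient's aggressive fraction rho and linear predictor eta.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.aggressive_fraction_range
    signal_dims = np.arange(min(cfg.signal_dim_count, cfg.n_features))

    cohort: Cohort = {}
    surv_rows, truth_rows = [], []
    for i in range(cfg.n_patients):
        pid = f"P{i:03d}"
        rho = float(rng.uniform(lo, hi))
        eta = cfg.beta_true * rho
        rate = cfg.baseline_rate * np.exp(eta)
        if cfg.weibull_shape is None:
            t_event = rng.exponential(1.0 / rate)
        else:
            kshape = cfg.weibull_shape
            t_event = rng.weibull(kshape) * (1.0 / rate) ** (1.0 / kshape)
        t_cens = rng.exponential(1.0 / cfg.censor_rate)
        time = max(min(t_event, t_cens), 1e-3)
        event = bool(t_event <= t_cens)
        record = SurvivalRecord(patient_id=pid, time=time, event=event)

        n_slides = int(rng.integers(cfg.slides_per_patient[0],
                                    cfg.slides_per_patient[1] + 1))
        graphs = []
        for s in range(n_slides):
            sid = f"{pid}_S{s}"
            n_nodes = int(rng.integers(cfg.nodes_per_graph[0],
                                       cfg.nodes_per_graph[1] + 1))
            coords = rng.uniform(0, cfg.coord_extent, (n_nodes, 2))
            feats = rng.standard_normal((n_nodes, cfg.n_features))
            n_aggr = int(round(rho * n_nodes))
            if n_aggr > 0:
                aggr_nodes = rng.choice(n_nodes, size=n_aggr, replace=False)
                feats[np.ix_(aggr_nodes, signal_dims)] += cfg.signal_shift
            graphs.append(build_knn_graph(coords, feats, k=cfg.k, slide_id=sid))
            surv_rows.append({"patient_id": pid, "slide_id": sid,
                              "time_months": time, "event": int(event)})
        cohort[pid] = (record, graphs)
        truth_rows.append({"patient_id": pid, "rho": rho, "eta": eta})

    return cohort, pd.DataFrame(surv_rows), pd.DataFrame(truth_rows)


def signal_node_graph(n_nodes: int = 30, n_features: int = 16,
                      signal_node: int = 0, shift: float = 3.0,
                      seed: int = 0) -> SlideGraph:
    """A graph where a single node carries the entire planted risk signal."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 1000, (n_nodes, 2))
    feats = rng.standard_normal((n_nodes, n_features)) * 0.1
    feats[signal_node] += shift
    return build_knn_graph(coords, feats, k=8, slide_id=f"signal{seed}")


# ---------------------------------------------------------------------------
# persistence helpers (used by the CLI)
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, survival: pd.DataFrame, truth: pd.DataFrame,
                out_dir) -> Path:
    out_dir = Path(out_dir)
    graphs_dir = out_dir / "graphs"
    graphs_dir.mkdir(parents=True, exist_ok=True)
    for _, graphs in cohort.values():
        for g in graphs:
            g.save(graphs_dir)
    survival.to_csv(out_dir / "survival.csv", index=False)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return out_dir


def load_cohort(graphs_dir, survival_csv) -> Cohort:
    """Rebuild the cohort mapping from a graphs directory + survival CSV."""
    df = pd.read_csv(survival_csv)
    graphs_dir = Path(graphs_dir)
    cohort: Cohort = {}
    for pid, group in df.groupby("patient_id", sort=True):
        extra_cols = [c for c in group.columns
                      if c not in ("patient_id", "slide_id", "time_months", "event")]
        first = group.iloc[0]
        record = SurvivalRecord(
            patient_id=str(pid), time=float(first["time_months"]),
            event=bool(first["event"]),
            covariates={c: first[c] for c in extra_cols},
        )
        graphs = [SlideGraph.load(graphs_dir / f"{sid}.graph.npz")
                  for sid in group["slide_id"]]
        cohort[str(pid)] = (record, graphs)
    return cohort
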