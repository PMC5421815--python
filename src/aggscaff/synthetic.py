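"""Synthetic observations with the statistical structure the fit assumes.

The experimental inputs of the likelihood fit are per-culture cluster-size
histograms counted from PALM localisations.  This module generates such
inputs from known ground-truth parameters so that every stage of the
pipeline can be exercised and validated end to end:

* :func:`sample_cluster_counts` draws per-size counts as independent
  Poisson variables with means ``A_exp * c_i`` — exactly the sampling
  model the likelihood assumes;
* :func:`emulate_localizations` expands counts into 2D localisation
  clouds with labeling efficiency, multiple detections per fluorophore
  (blinking) and Gaussian localisation error;
* :func:`cluster_localizations` re-clusters a cloud by single-link at a
  minimal distance (50 nm by default), mirroring the PALM analysis;
* :func:`detections_to_sizes` converts per-cluster detection counts back
  to sizes in trimers through a fixed calibration factor.

A cluster of i trimers contains 3i gephyrin monomers; monomer positions
are packed in a disc at density 3*rho so the cloud footprint matches the
disc radius sqrt(i/(pi*rho)) of the model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .fit import RHO_TRIMER, ObservedCounts, predicted_counts

__all__ = [
    "GroundTruth",
    "DetectionModel",
    "LocalizationCloud",
    "sample_cluster_counts",
    "emulate_localizations",
    "cluster_localizations",
    "detections_to_sizes",
    "make_reference_fixture",
    "write_counts_csv",
    "read_counts_csv",
]


@dataclass(frozen=True)
class GroundTruth:
    """True parameters behind a synthetic multi-culture dataset."""

    sigma: float
    D0_over_k: float            # um^2
    c0: tuple[float, ...]       # um^-2, one per culture
    A_exp: tuple[float, ...]    # um^2, one per culture
    rho: float = RHO_TRIMER
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.c0) != len(self.A_exp):
            raise ValueError("c0 and A_exp must have one entry per culture")
        if not self.D0_over_k > 0:
            raise ValueError("D0_over_k must be positive")
        if any(c <= 0 for c in self.c0) or any(a < 0 for a in self.A_exp):
            raise ValueError("c0 must be positive and A_exp nonnegative")


@dataclass(frozen=True)
class DetectionModel:
    """Detection/blinking model of the localisation emulation.

    ``detections_per_monomer`` is the mean number of localisations a
    labeled monomer produces (geometric, support >= 1, so 1.0 means
    exactly one detection); ``localization_sd`` is the localisation
    precision in um; ``cluster_linking_distance`` the single-link cutoff.
    """

    detections_per_monomer: float = 1.0
    labeling_efficiency: float = 1.0
    localization_sd: float = 0.02
    cluster_linking_distance: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.labeling_efficiency <= 1:
            raise ValueError("labeling_efficiency must be in [0, 1]")
        if self.detections_per_monomer < 1:
            raise ValueError("detections_per_monomer must be >= 1 (geometric mean)")
        if self.localization_sd < 0 or self.cluster_linking_distance <= 0:
            raise ValueError("distances must be positive")

    @property
    def detections_per_trimer(self) -> float:
        """Calibration factor: mean detections per trimer."""
        return 3.0 * self.labeling_efficiency * self.detections_per_monomer


@dataclass
class LocalizationCloud:
    """Synthetic pointillist field: one row per detection, in um."""

    points: np.ndarray            # (N, 2)
    true_labels: np.ndarray       # ground-truth cluster index per detection
    field: float                  # square field side (um)
    metadata: dict[str, Any] = field(default_factory=dict)


def sample_cluster_counts(
    truth: GroundTruth, rng: np.random.Generator | None = None
) -> list[ObservedCounts]:
    """Per-culture Poisson-sampled cluster counts, #_i ~ Poisson(A_exp * c_i).

    Deterministic given ``truth.seed``; support is truncated where the
    expected counts become negligible (< 1e-8 clusters).
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    cultures = []
    for j, (c0, area) in enumerate(zip(truth.c0, truth.A_exp)):
        means = predicted_counts(
            1.0 / truth.D0_over_k, truth.sigma, c0, area=area, rho=truth.rho
        )
        support = np.nonzero(means > 1e-8)[0]
        i_hi = int(support[-1]) + 1 if len(support) else 1
        counts = rng.poisson(means[:i_hi])
        cultures.append(ObservedCounts(f"culture_{j + 1}", counts, area))
    return cultures


def _place_clusters(
    n_clusters: int, radii: np.ndarray, min_sep: float, rng: np.random.Generator,
    field: float | None,
) -> tuple[np.ndarray, float]:
    """Cluster centres on a shuffled, jittered grid with guaranteed separation."""
    pitch = 2.0 * float(radii.max(initial=0.0)) + min_sep
    n_cells = math.ceil(math.sqrt(n_clusters))
    needed = n_cells * pitch
    if field is None:
        field = needed
    elif field < needed:
        raise ValueError(
            f"field of {field} um cannot hold {n_clusters} clusters at pitch {pitch:.3f} um"
        )
    n_cells = int(field // pitch)
    cells = rng.permutation(n_cells * n_cells)[:n_clusters]
    cx, cy = np.divmod(cells, n_cells)
    jitter = rng.uniform(0.25, 0.75, size=(n_clusters, 2))
    centres = (np.stack([cx, cy], axis=1) + jitter) * pitch
    return centres, field


def emulate_localizations(
    counts: ObservedCounts,
    model: DetectionModel,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    field: float | None = None,
    min_separation: float = 0.2,
) -> LocalizationCloud:
    """Expand a size histogram into a synthetic PALM localisation cloud.

    Each cluster of i trimers holds 3i monomers packed uniformly in a disc
    of radius sqrt(i/(pi*rho)) (monomer density 3*rho).  Each monomer is
    labeled with probability ``labeling_efficiency`` and emits a geometric
    number of detections (mean ``detections_per_monomer``), each scattered
    with isotropic Gaussian error ``localization_sd``.  Clusters are placed
    with at least ``min_separation`` um between disc edges so single-link
    re-clustering does not merge distinct clusters by construction.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 1)
    sizes = counts.cluster_sizes
    order = rng.permutation(len(sizes))
    sizes = sizes[order]
    radii = np.sqrt(sizes / (math.pi * truth.rho))
    centres, field = _place_clusters(len(sizes), radii, min_separation, rng, field)

    pts, labels = [], []
    p_geom = 1.0 / model.detections_per_monomer
    for idx, (size, centre, r_disc) in enumerate(zip(sizes, centres, radii)):
        n_mono = 3 * int(size)
        th = rng.uniform(0.0, 2.0 * math.pi, n_mono)
        rr = r_disc * np.sqrt(rng.uniform(0.0, 1.0, n_mono))
        mono = centre + np.stack([rr * np.cos(th), rr * np.sin(th)], axis=1)
        labeled = rng.random(n_mono) < model.labeling_efficiency
        mono = mono[labeled]
        if len(mono) == 0:
            continue
        n_det = rng.geometric(p_geom, size=len(mono))
        det_pos = np.repeat(mono, n_det, axis=0)
        if model.localization_sd > 0:
            det_pos = det_pos + rng.normal(
                0.0, model.localization_sd, size=det_pos.shape
            )
        pts.append(det_pos)
        labels.append(np.full(len(det_pos), idx))
    points = np.concatenate(pts) if pts else np.empty((0, 2))
    true_labels = np.concatenate(labels) if labels else np.empty(0, dtype=int)
    return LocalizationCloud(
        points=points, true_labels=true_labels, field=field,
        metadata={"culture_id": counts.culture_id, "model": model},
    )


def cluster_localizations(
    cloud: LocalizationCloud | np.ndarray, dmin: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Single-link clustering of detections at a minimal distance ``dmin`` (um).

    Clusters are the connected components of the graph linking every pair
    of detections within ``dmin``.  Returns (assignment per detection,
    per-cluster detection counts); components are numbered in order of
    first appearance, so the output is deterministic.
    """
    if not dmin > 0:
        raise ValueError("dmin must be positive")
    points = cloud.points if isinstance(cloud, LocalizationCloud) else np.asarray(cloud)
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    tree = cKDTree(points)
    pairs = tree.query_pairs(dmin, output_type="ndarray")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    # renumber components by first appearance for determinism
    first = np.full(n_comp, n, dtype=int)
    np.minimum.at(first, labels, np.arange(n))
    rank = np.argsort(np.argsort(first))
    labels = rank[labels]
    return labels, np.bincount(labels)


def detections_to_sizes(
    detection_counts: np.ndarray, model: DetectionModel
) -> np.ndarray:
    """Convert per-cluster detection counts to sizes in trimers.

    size = round(detections / f) with f = 3 * labeling_efficiency *
    detections_per_monomer detections per trimer, clamped to >= 1;
    clusters with zero detections are dropped.
    """
    f = model.detections_per_trimer
    if not f > 0:
        raise ValueError("calibration factor must be positive")
    det = np.asarray(detection_counts, dtype=float)
    det = det[det > 0]
    return np.maximum(np.rint(det / f).astype(int), 1)


def write_counts_csv(cultures: Sequence[ObservedCounts], path: str | Path) -> None:
    """Counts table CSV: columns culture_id, size_trimers, count (sizes with
    zero counts omitted)."""
    rows = []
    for obs in cultures:
        for i, cnt in enumerate(obs.counts, start=1):
            if cnt > 0:
                rows.append({"culture_id": obs.culture_id, "size_trimers": i,
                             "count": int(cnt)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_counts_csv(
    counts_path: str | Path, areas: dict[str, float] | str | Path
) -> list[ObservedCounts]:
    """Read a counts table plus per-culture areas (dict or JSON sidecar).

    Accepts the binned format (culture_id, size_trimers, count) and the
    long format with one row per cluster (culture_id, size_trimers).
    """
    df = pd.read_csv(counts_path)
    if isinstance(areas, (str, Path)):
        with open(areas) as fh:
            areas = json.load(fh)
    cultures = []
    for cid, sub in df.groupby("culture_id", sort=True):
        if str(cid) not in areas:
            raise KeyError(f"no observed area A_exp for culture {cid!r}")
        sizes = sub["size_trimers"].to_numpy(dtype=int)
        counts = sub["count"].to_numpy(dtype=int) if "count" in sub.columns \
            else np.ones(len(sub), dtype=int)
        hist = np.zeros(int(sizes.max()), dtype=int)
        np.add.at(hist, sizes - 1, counts)
        cultures.append(ObservedCounts(str(cid), hist, float(areas[str(cid)])))
    return cultures


def make_reference_fixture(
    seed: int = 0, out_dir: str | Path | None = None
) -> tuple[list[ObservedCounts], GroundTruth]:
    """Small three-culture synthetic dataset in the experimentally observed
    regime (sigma = 0.5, D0/k = 30 um^2, c0 = 0.5/2/5 um^-2, A_exp = 1e3 um^2).

    If ``out_dir`` is given, writes ``counts.csv`` and ``areas.json`` in the
    likelihood-fit input format.
    """
    truth = GroundTruth(
        sigma=0.5, D0_over_k=30.0, c0=(0.5, 2.0, 5.0),
        A_exp=(1e3, 1e3, 1e3), rho=RHO_TRIMER, seed=seed,
    )
    cultures = sample_cluster_counts(truth)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_counts_csv(cultures, out_dir / "counts.csv")
        with open(out_dir / "areas.json", "w") as fh:
            json.dump({obs.culture_id: obs.area for obs in cultures}, fh, indent=1)
    return cultures, truth
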