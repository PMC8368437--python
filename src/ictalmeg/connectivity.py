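"""Source-space functional connectivity with a correlation t-threshold.

Virtual sensors are the beamformed time series at selected voxels.  For
every unordered pair (a, b) the Pearson correlation R is converted to a
t-value

    Tp = R * sqrt(K - 2) / sqrt(1 - R^2)

with K the number of connected data points (time samples).  An edge enters
the network when its |Tp| reaches the critical two-sided Student t at
alpha = 0.05 with K - 2 degrees of freedom; the edge sign is the sign of R
(positive = excitatory-like, negative = inhibitory-like in the display
convention).  No correction across pairs is applied within one network;
multiplicity is handled across frequency bands at the group level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import ConfigurationError
from .sources import AsiMap, RegionAtlas, SourceGrid

__all__ = [
    "VirtualSensorSet",
    "Edge",
    "ConnectivityNetwork",
    "RoiNetworkSummary",
    "extract_virtual_sensors",
    "pairwise_correlation",
    "tp_threshold",
    "tp_critical",
    "build_network",
    "summarize_roi",
    "network_to_tsv",
    "network_to_graphml",
]

FRONTAL_LABELS = frozenset({"FC", "MFC", "LFL"})


@dataclass
class VirtualSensorSet:
    """Reconstructed source signals at selected voxels (nodes x samples)."""

    node_voxels: np.ndarray
    signals: np.ndarray
    selection_rule: str = ""

    def __post_init__(self) -> None:
        self.node_voxels = np.asarray(self.node_voxels, dtype=int)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.node_voxels.size < 2:
            raise ConfigurationError("need at least 2 virtual sensors")
        if self.signals.shape[0] != self.node_voxels.size:
            raise ConfigurationError("one signal row per node required")
        if not np.all(np.isfinite(self.signals)):
            raise ConfigurationError("virtual sensor signals must be finite")

    @property
    def n_nodes(self) -> int:
        return self.node_voxels.size

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass(frozen=True)
class Edge:
    node_a: int
    node_b: int
    r: float
    tp: float
    sign: str


@dataclass
class ConnectivityNetwork:
    """Thresholded signed edge set over source-space nodes."""

    edges: list[Edge]
    threshold_tp: float
    k: int
    alpha: float = 0.05
    node_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class RoiNetworkSummary:
    roi_label: str
    n_local_frontal_edges: int
    n_anterior_posterior_edges: int
    n_positive: int
    n_negative: int


def extract_virtual_sensors(
    Q: np.ndarray,
    asi: AsiMap,
    rule: str = "top-fraction",
    param=0.01,
    atlas: RegionAtlas | None = None,
    grid: SourceGrid | None = None,
) -> VirtualSensorSet:
    """Select network nodes from the accumulated-source map.

    ``top-fraction`` keeps voxels whose strength reaches the (1 - param)
    quantile (param = 0.01 keeps the strongest ~1%).  ``roi-seeded`` keeps
    every voxel of the named atlas region plus the global top 1%.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[0] != asi.strength.shape[0]:
        raise ConfigurationError("Q and ASI map disagree on voxel count")
    if rule == "top-fraction":
        frac = float(param)
        if not 0.0 < frac <= 1.0:
            raise ConfigurationError("top fraction must lie in (0, 1]")
        thr = np.quantile(asi.strength, 1.0 - frac)
        nodes = np.flatnonzero(asi.strength >= thr)
    elif rule == "roi-seeded":
        if atlas is None or grid is None:
            raise ConfigurationError("roi-seeded selection needs atlas and grid")
        label = str(param)
        if label not in atlas.labels:
            raise ConfigurationError(f"unknown ROI label {label!r}")
        labels = atlas.label_of(grid.voxel_centres_mm)
        roi_nodes = np.flatnonzero(labels == label)
        thr = np.quantile(asi.strength, 0.99)
        nodes = np.union1d(roi_nodes, np.flatnonzero(asi.strength >= thr))
    else:
        raise ConfigurationError(f"unknown selection rule {rule!r}")
    if nodes.size < 2:
        raise ConfigurationError("selection rule yielded fewer than 2 nodes")
    return VirtualSensorSet(nodes, Q[nodes], selection_rule=f"{rule}:{param}")


def pairwise_correlation(vs: VirtualSensorSet) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson correlation matrix of the virtual sensors.

    Returns ``(R, kept)`` where ``kept`` indexes the rows of ``vs.signals``
    that entered the matrix; zero-variance signals are excluded with a
    warning rather than propagating NaN.
    """
    if vs.n_samples < 2:
        raise ConfigurationError("need at least 2 samples per signal")
    sd = vs.signals.std(axis=1)
    kept = np.flatnonzero(sd > 0)
    if kept.size < vs.n_nodes:
        warnings.warn(
            f"{vs.n_nodes - kept.size} zero-variance virtual sensors excluded"
        )
    if kept.size < 2:
        raise ConfigurationError("fewer than 2 non-constant signals remain")
    R = np.corrcoef(vs.signals[kept])
    np.fill_diagonal(R, 1.0)
    return R, kept


def tp_threshold(R, K: int):
    """t-value of a correlation with K connected data points.

    Vectorized; |R| = 1 maps to +/- infinity (always significant).
    """
    if K < 3:
        raise ConfigurationError("K must be >= 3")
    R = np.asarray(R, dtype=float)
    if np.any(np.abs(R) > 1.0 + 1e-12):
        raise ConfigurationError("|R| cannot exceed 1")
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        out = R * np.sqrt(K - 2) / np.sqrt(1.0 - R**2)
    out = np.where(np.abs(R) >= 1.0, np.copysign(np.inf, R), out)
    return out if out.ndim else float(out)


def tp_critical(K: int, alpha: float = 0.05) -> float:
    """Critical two-sided Student t at ``alpha`` with K - 2 degrees of freedom."""
    if K < 3:
        raise ConfigurationError("K must be >= 3")
    return float(sps.t.ppf(1.0 - alpha / 2.0, K - 2))


def build_network(vs: VirtualSensorSet, alpha: float = 0.05) -> ConnectivityNetwork:
    """Threshold all pairs at the critical t and keep signed edges."""
    R, kept = pairwise_correlation(vs)
    K = vs.n_samples
    tcrit = tp_critical(K, alpha)
    Tp = tp_threshold(R, K)
    edges: list[Edge] = []
    n = R.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = np.abs(Tp[iu, ju]) >= tcrit
    for i, j in zip(iu[keep], ju[keep]):
        a = int(vs.node_voxels[kept[i]])
        b = int(vs.node_voxels[kept[j]])
        if a > b:
            a, b = b, a
        r = float(R[i, j])
        edges.append(Edge(a, b, r, float(Tp[i, j]),
                          "positive" if r >= 0 else "negative"))
    edges.sort(key=lambda e: (e.node_a, e.node_b))
    return ConnectivityNetwork(edges, tcrit, K, alpha,
                               node_voxels=vs.node_voxels.copy())


def summarize_roi(
    network: ConnectivityNetwork,
    atlas: RegionAtlas,
    grid: SourceGrid,
    roi: str = "MFC",
) -> RoiNetworkSummary:
    """Count local-frontal and anterior-posterior edges, split by sign.

    Local frontal: both endpoints in the frontal territory {FC, MFC, LFL}.
    Anterior-posterior: the edge crosses the y = 0 coronal plane of the
    head frame.
    """
    if roi not in atlas.labels:
        raise ConfigurationError(f"unknown ROI label {roi!r}")
    n_front = n_ap = n_pos = n_neg = 0
    for e in network.edges:
        pa = grid.voxel_centres_mm[e.node_a]
        pb = grid.voxel_centres_mm[e.node_b]
        la = atlas.label_of(pa[None, :])[0]
        lb = atlas.label_of(pb[None, :])[0]
        if la in FRONTAL_LABELS and lb in FRONTAL_LABELS:
            n_front += 1
        if (pa[1] > 0) != (pb[1] > 0):
            n_ap += 1
        if e.sign == "positive":
            n_pos += 1
        else:
            n_neg += 1
    return RoiNetworkSummary(roi, n_front, n_ap, n_pos, n_neg)


def network_to_tsv(
    network: ConnectivityNetwork,
    path,
    atlas: RegionAtlas | None = None,
    grid: SourceGrid | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tR\tTp\tsign\tregion_a\tregion_b\n")
        for e in network.edges:
            ra = rb = ""
            if atlas is not None and grid is not None:
                ra = atlas.label_of(grid.voxel_centres_mm[e.node_a][None, :])[0]
                rb = atlas.label_of(grid.voxel_centres_mm[e.node_b][None, :])[0]
            fh.write(f"{e.node_a}\t{e.node_b}\t{e.r:.6f}\t{e.tp:.6f}\t{e.sign}\t{ra}\t{rb}\n")


def network_to_graphml(network: ConnectivityNetwork, path) -> None:
    import networkx as nx

    g = nx.Graph(threshold_tp=network.threshold_tp, k=network.k,
                 alpha=network.alpha)
    for v in network.node_voxels:
        g.add_node(int(v))
    for e in network.edges:
        g.add_edge(e.node_a, e.node_b, r=e.r, tp=e.tp, sign=e.sign)
    nx.write_graphml(g, str(path))
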