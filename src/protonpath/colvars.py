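"""Collective variables for hydration-coupled proton transfer.

Two families of CVs are computed from explicit coordinates:

* the **water-wire connectivity** ``phi``: per-node water occupancies are
  averaged over adjacent node pairs, f_{i,i+1} = (o_i + o_{i+1})/2, and phi
  is the geometric mean of the pair averages,
  phi = (prod f_{i,i+1})^(1/(N-1)).  phi is 1 only for a fully hydrated wire
  and collapses to 0 when any node pair is dry, which makes it sharply
  sensitive to the few water molecules bridging a weakly hydrated gap.
  The localized variant ``phi*`` weights each node pair by a Gaussian in its
  distance from the excess-charge probe, so it reflects the water
  arrangement in the immediate vicinity of the proton.

* the **path-progress CV** ``xi``: a continuous node index locating the
  excess-charge probe along the ordered path nodes, built from the vectors
  v1, v2 from the probe to the closest node (index i1) and to the adjacent
  node nearer the probe (index i2), and v3 from node i1 to node i2:

      xi' = i2 - sign(i2 - i1) * sqrt(D) / |v3|^2,
      D   = (v1.v3)^2 - |v3|^2 (|v1|^2 - |v2|^2)

  On a straight equidistant path this equals the signed arc-length
  projection in units of node spacing, and it is continuous as the probe
  crosses the mid-plane between nodes.  The shifted/rescaled form
  xi* = (xi' - origin_index) * spacing * orientation is numerically
  comparable to distance in Angstrom along the path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from protonpath.path_geometry import PathNodes
from protonpath.free_energy import BiasedTimeSeries

__all__ = [
    "HydrationFrame",
    "OccupancyProfile",
    "ConnectivityValue",
    "ProbeNodeGeometry",
    "PathProgress",
    "switching_function",
    "node_occupancy",
    "occupancy_profile",
    "water_wire_connectivity",
    "local_connectivity",
    "path_progress",
    "cv_timeseries",
]


@dataclass(frozen=True)
class HydrationFrame:
    """One snapshot: water-oxygen positions plus the excess-charge probe.

    ``box``, when given, holds orthorhombic box lengths (Angstrom) and
    switches water-node distances to the minimum-image convention.
    """

    water_oxygens: np.ndarray
    probe: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        wo = np.asarray(self.water_oxygens, dtype=float).reshape(-1, 3)
        pr = np.asarray(self.probe, dtype=float).reshape(3)
        if not (np.all(np.isfinite(wo)) and np.all(np.isfinite(pr))):
            raise ValueError("non-finite coordinates in hydration frame")
        object.__setattr__(self, "water_oxygens", wo)
        object.__setattr__(self, "probe", pr)
        if self.box is not None:
            box = np.asarray(self.box, dtype=float).reshape(3)
            if np.any(box <= 0):
                raise ValueError("box lengths must be positive")
            object.__setattr__(self, "box", box)


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-node water occupancies o_i, each in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("need a 1D profile with at least 2 nodes")
        if np.any(v < 0) or np.any(v > 1) or not np.all(np.isfinite(v)):
            raise ValueError("occupancies must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_nodes(self) -> int:
        return self.values.size

    def pair_averages(self) -> np.ndarray:
        """f_{i,i+1} = (o_i + o_{i+1}) / 2 for i = 0..N-2."""
        v = self.values
        return 0.5 * (v[:-1] + v[1:])


@dataclass(frozen=True)
class ConnectivityValue:
    phi: float
    phi_local: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")
        if self.phi_local is not None and not (0.0 <= self.phi_local <= 1.0):
            raise ValueError("phi_local must lie in [0, 1]")


@dataclass(frozen=True)
class ProbeNodeGeometry:
    """Probe-node vectors entering the path-progress CV.

    i1 is the node closest to the probe, i2 the adjacent node nearer the
    probe; v1 and v2 run from the probe to nodes i1 and i2, v3 from node i1
    to node i2.
    """

    i1: int
    i2: int
    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray

    def __post_init__(self) -> None:
        if self.i1 == self.i2 or abs(self.i1 - self.i2) != 1:
            raise ValueError("i1 and i2 must be adjacent and distinct")


@dataclass(frozen=True)
class PathProgress:
    """Raw continuous node index xi' and the Angstrom-comparable xi*."""

    xi_raw: float
    xi_star: float


def switching_function(r, r0: float, n: int = 6, m: int = 12):
    """Rational switching function sigma(r) = (1-(r/r0)^n) / (1-(r/r0)^m).

    sigma(0) = 1, sigma(r0) = n/m (removable singularity), and sigma decays
    like (r/r0)^(n-m) at long range.  Smooth and differentiable in r.
    """
    if r0 <= 0:
        raise ValueError("switch_r0 must be positive")
    if not n < m:
        raise ValueError("switching exponents require n < m")
    x = np.asarray(r, dtype=float) / r0
    xn = x**n
    xm = x**m
    den = 1.0 - xm
    near = np.abs(den) < 1e-10
    # limit at x -> 1 is n/m; elsewhere direct evaluation
    safe_den = np.where(near, 1.0, den)
    out = np.where(near, n / m, (1.0 - xn) / safe_den)
    return out if out.ndim else float(out)


def _water_node_dist(frame: HydrationFrame, node: np.ndarray) -> np.ndarray:
    d = frame.water_oxygens - np.asarray(node, dtype=float)
    if frame.box is not None:
        d = d - frame.box * np.round(d / frame.box)
    return np.linalg.norm(d, axis=1)


def node_occupancy(
    frame: HydrationFrame,
    node,
    switch_r0: float = 2.5,
    switch_exponents: tuple[int, int] = (6, 12),
    cap: str = "hard",
    cap_k: float = 20.0,
) -> float:
    """Water occupancy of one node: the switching-function sum over waters,
    capped at 1.

    ``cap="hard"`` applies min(1, s); ``cap="soft"`` applies the smooth
    soft-min s - ln(1 + exp(cap_k (s-1)))/cap_k, which is differentiable
    everywhere at the cost of a small downward shift near s = 1.
    """
    n, m = switch_exponents
    r = _water_node_dist(frame, node)
    s = float(np.sum(switching_function(r, switch_r0, n, m)))
    if cap == "hard":
        return min(1.0, s)
    if cap == "soft":
        return s - float(np.logaddexp(0.0, cap_k * (s - 1.0))) / cap_k
    raise ValueError(f"unknown cap {cap!r}")


def occupancy_profile(
    frame: HydrationFrame,
    nodes: PathNodes,
    switch_r0: float = 2.5,
    switch_exponents: tuple[int, int] = (6, 12),
    cap: str = "hard",
    cap_k: float = 20.0,
) -> OccupancyProfile:
    """Occupancy of every path node for one frame."""
    vals = [
        node_occupancy(frame, node, switch_r0, switch_exponents, cap, cap_k)
        for node in nodes.nodes
    ]
    return OccupancyProfile(np.clip(vals, 0.0, 1.0))


def water_wire_connectivity(occ: OccupancyProfile) -> float:
    """Water-wire connectivity: the geometric mean of the adjacent-pair
    occupancy averages, computed in log space.  Returns 0 if any pair
    average vanishes."""
    f = occ.pair_averages()
    if np.any(f <= 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(f))))


def local_connectivity(
    occ: OccupancyProfile,
    nodes: PathNodes,
    probe,
    locality_sigma: float = 3.0,
) -> float:
    """Proton-localized connectivity phi*: a weighted geometric mean of the
    pair averages with Gaussian weights w_i = exp(-d_i^2 / (2 sigma^2)),
    where d_i is the distance from the probe to the midpoint of nodes i and
    i+1.  Reduces to phi as locality_sigma -> infinity."""
    if locality_sigma <= 0:
        raise ValueError("locality_sigma must be positive")
    if occ.n_nodes != nodes.n_nodes:
        raise ValueError("occupancy profile and path have different node counts")
    probe = np.asarray(probe, dtype=float).reshape(3)
    mids = 0.5 * (nodes.nodes[:-1] + nodes.nodes[1:])
    d = np.linalg.norm(mids - probe, axis=1)
    # subtract the minimum distance before exponentiating: the weights are
    # normalized, so this rescaling is exact and avoids total underflow for
    # any probe that is merely far (not infinitely far) from the path
    w = np.exp(-(d**2 - d.min() ** 2) / (2.0 * locality_sigma**2))
    raw = np.exp(-(d**2) / (2.0 * locality_sigma**2))
    if np.max(raw) < 1e-12:
        raise ValueError("probe off-path")
    f = occ.pair_averages()
    if np.any((f <= 0.0) & (w > 0.0)):
        return 0.0
    return float(np.exp(np.sum(w * np.log(f)) / np.sum(w)))


def probe_node_geometry(probe, nodes: PathNodes) -> ProbeNodeGeometry:
    """Identify the closest node i1, the adjacent node i2 nearer the probe,
    and the three vectors entering the path-progress CV.  Distance ties
    break toward the lower node index."""
    probe = np.asarray(probe, dtype=float).reshape(3)
    pts = nodes.nodes
    dist = np.linalg.norm(pts - probe, axis=1)
    i1 = int(np.argmin(dist))
    cands = [i for i in (i1 - 1, i1 + 1) if 0 <= i < nodes.n_nodes]
    i2 = min(cands, key=lambda i: (dist[i], i))
    v1 = pts[i1] - probe
    v2 = pts[i2] - probe
    v3 = pts[i2] - pts[i1]
    return ProbeNodeGeometry(i1=i1, i2=i2, v1=v1, v2=v2, v3=v3)


def path_progress(
    probe,
    nodes: PathNodes,
    cutoff: float | None = None,
) -> PathProgress:
    """Continuous progress of the excess-charge probe along the path.

    ``cutoff`` (Angstrom), when given, raises "probe off-path" if the probe
    is farther than that from every node.  At a terminus the single
    available neighbor is used, which linearly extrapolates the index
    beyond the end nodes.
    """
    probe = np.asarray(probe, dtype=float).reshape(3)
    dist = np.linalg.norm(nodes.nodes - probe, axis=1)
    if cutoff is not None and float(dist.min()) > cutoff:
        raise ValueError("probe off-path")
    g = probe_node_geometry(probe, nodes)
    v3sq = float(g.v3 @ g.v3)
    disc = (float(g.v1 @ g.v3)) ** 2 - v3sq * (
        float(g.v1 @ g.v1) - float(g.v2 @ g.v2)
    )
    disc = max(disc, 0.0)  # round-off guard at exact node hits
    xi_raw = g.i2 - np.sign(g.i2 - g.i1) * np.sqrt(disc) / v3sq
    xi_star = nodes.xi_star_of_index(xi_raw)
    return PathProgress(xi_raw=float(xi_raw), xi_star=float(xi_star))


def cv_timeseries(
    frames,
    nodes: PathNodes,
    switch_r0: float = 2.5,
    switch_exponents: tuple[int, int] = (6, 12),
    locality_sigma: float = 3.0,
    dt: float = 1.0,
    cutoff: float | None = None,
) -> BiasedTimeSeries:
    """Per-frame (time, xi*, phi, phi*) table for a sequence of frames."""
    frames = list(frames)
    if not frames:
        raise ValueError("empty frame sequence")
    rows = []
    for k, frame in enumerate(frames):
        occ = occupancy_profile(frame, nodes, switch_r0, switch_exponents)
        phi = water_wire_connectivity(occ)
        phi_loc = local_connectivity(occ, nodes, frame.probe, locality_sigma)
        prog = path_progress(frame.probe, nodes, cutoff=cutoff)
        rows.append((k * dt, prog.xi_star, phi, phi_loc))
    arr = np.asarray(rows, dtype=float)
    return BiasedTimeSeries.from_arrays(
        time=arr[:, 0],
        cvs={"xi_star": arr[:, 1], "phi": arr[:, 2], "phi_star": arr[:, 3]},
    )
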