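"""Free-energy reconstruction from biased sampling.

Two estimators are provided:

* **WHAM** — the standard self-consistent weighted histogram analysis for
  harmonic umbrella windows on a 1D or 2D collective-variable grid, with
  block-averaged convergence assessment (the profile is averaged over the
  last blocks of each window once the early, still-relaxing blocks are
  discarded, and the spread across retained blocks gives a per-bin
  standard error).

* **well-tempered metadynamics inversion** — the accumulated Gaussian bias
  V(s) of a (possibly multiple-walker) hill log evaluated on a grid, with
  F(s) = -(gamma/(gamma-1)) V(s).

All energies are kcal/mol; free-energy grids are shifted so the sampled
minimum is zero, and unsampled bins are masked, never interpolated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from protonpath.constants import kT as _kT

__all__ = [
    "RestraintSpec",
    "BiasedTimeSeries",
    "HillsLog",
    "GridAxis",
    "FreeEnergyGrid",
    "BlockReport",
    "wham",
    "block_averaged_wham",
    "metad_free_energy",
    "merge_walkers",
]


@dataclass(frozen=True)
class RestraintSpec:
    """Harmonic restraint U(x) = 0.5 * kappa * (x - center)^2 on one CV.

    ``kappa`` is in kcal/mol per (CV unit)^2.
    """

    cv: str
    center: float
    kappa: float

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("force constant must be positive")

    def energy(self, x):
        return 0.5 * self.kappa * (np.asarray(x, dtype=float) - self.center) ** 2


@dataclass(frozen=True)
class BiasedTimeSeries:
    """COLVAR-style record: time stamps, named CV columns, optional
    instantaneous bias energy, and the window restraints when applicable."""

    data: pd.DataFrame
    restraints: tuple[RestraintSpec, ...] = ()

    def __post_init__(self) -> None:
        df = self.data
        if "time" not in df.columns:
            raise ValueError("time column required")
        t = df["time"].to_numpy()
        if t.size == 0:
            raise ValueError("empty time series")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if df.isna().any().any():
            raise ValueError("missing values in time series")
        object.__setattr__(self, "restraints", tuple(self.restraints))

    @classmethod
    def from_arrays(cls, time, cvs: dict, bias=None, restraints=()):
        cols = {"time": np.asarray(time, dtype=float)}
        for name, vals in cvs.items():
            cols[name] = np.asarray(vals, dtype=float)
        if bias is not None:
            cols["bias"] = np.asarray(bias, dtype=float)
        return cls(pd.DataFrame(cols), restraints=tuple(restraints))

    @property
    def cv_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.data.columns if c not in ("time", "bias"))

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def cv(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def time_blocks(self, n_blocks: int) -> list["BiasedTimeSeries"]:
        """Split into n_blocks equal consecutive time blocks."""
        n = self.n_samples
        if n < n_blocks:
            raise ValueError("series too short to split into requested blocks")
        edges = np.linspace(0, n, n_blocks + 1).astype(int)
        out = []
        for b in range(n_blocks):
            df = self.data.iloc[edges[b]:edges[b + 1]].reset_index(drop=True)
            out.append(BiasedTimeSeries(df, restraints=self.restraints))
        return out


@dataclass(frozen=True)
class HillsLog:
    """Metadynamics hill records: per hill a time, center and width per CV,
    the deposited (already well-tempered-scaled) height, the bias factor and
    the depositing walker id."""

    cv_names: tuple[str, ...]
    times: np.ndarray
    centers: np.ndarray   # (n_hills, n_cv)
    sigmas: np.ndarray    # (n_hills, n_cv)
    heights: np.ndarray   # (n_hills,)
    bias_factor: float
    walkers: np.ndarray   # (n_hills,) int

    def __post_init__(self) -> None:
        c = np.atleast_2d(np.asarray(self.centers, dtype=float))
        s = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        h = np.asarray(self.heights, dtype=float)
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.walkers, dtype=int)
        if not (len(c) == len(s) == h.size == t.size == w.size):
            raise ValueError("inconsistent hill record lengths")
        if h.size and (np.any(h <= 0) or np.any(s <= 0)):
            raise ValueError("hill heights and widths must be positive")
        if not self.bias_factor > 1:
            raise ValueError("bias factor must exceed 1")
        object.__setattr__(self, "cv_names", tuple(self.cv_names))
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "sigmas", s)
        object.__setattr__(self, "heights", h)
        object.__setattr__(self, "walkers", w)

    @property
    def n_hills(self) -> int:
        return self.heights.size


@dataclass(frozen=True)
class GridAxis:
    """One grid dimension: CV name, range and bin count.  Bins are
    half-open [low, high) with deterministic edge assignment."""

    cv: str
    lo: float
    hi: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.hi <= self.lo or self.n_bins < 1:
            raise ValueError("invalid grid axis")

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n_bins

    @property
    def centers(self) -> np.ndarray:
        return self.lo + (np.arange(self.n_bins) + 0.5) * self.width

    def bin_of(self, x) -> np.ndarray:
        """Bin index per sample; -1 marks samples outside [lo, hi)."""
        x = np.asarray(x, dtype=float)
        idx = np.floor((x - self.lo) / self.width).astype(int)
        idx[(x < self.lo) | (x >= self.hi)] = -1
        return idx


@dataclass(frozen=True)
class FreeEnergyGrid:
    """1D/2D PMF on a CV grid, shifted so the sampled minimum is zero.
    ``mask`` is True for sampled bins; unsampled bins hold NaN."""

    axes: tuple[GridAxis, ...]
    free_energy: np.ndarray
    mask: np.ndarray
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        axes = tuple(self.axes)
        if len(axes) not in (1, 2):
            raise ValueError("only 1D and 2D grids supported")
        shape = tuple(a.n_bins for a in axes)
        F = np.asarray(self.free_energy, dtype=float).reshape(shape)
        m = np.asarray(self.mask, dtype=bool).reshape(shape)
        if not m.any():
            raise ValueError("grid has no sampled bins")
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "free_energy", F)
        object.__setattr__(self, "mask", m)
        if self.se is not None:
            se = np.asarray(self.se, dtype=float).reshape(shape)
            object.__setattr__(self, "se", se)

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def min_shifted(self) -> "FreeEnergyGrid":
        F = self.free_energy.copy()
        F -= np.nanmin(F[self.mask])
        return FreeEnergyGrid(self.axes, F, self.mask, self.se)


@dataclass(frozen=True)
class BlockReport:
    """Per-block PMFs and which blocks entered the retained average."""

    n_blocks: int
    keep_last: int
    block_grids: tuple[FreeEnergyGrid, ...]
    retained: tuple[int, ...]
    se: np.ndarray

    def __post_init__(self) -> None:
        if len(self.retained) > self.n_blocks:
            raise ValueError("cannot retain more blocks than exist")


# ---------------------------------------------------------------------------
# WHAM

def _histogram(series: BiasedTimeSeries, axes) -> np.ndarray:
    idx = [ax.bin_of(series.cv(ax.cv)) for ax in axes]
    ok = np.all([i >= 0 for i in idx], axis=0)
    shape = tuple(ax.n_bins for ax in axes)
    flat = np.zeros(int(np.prod(shape)))
    if ok.any():
        if len(axes) == 1:
            lin = idx[0][ok]
        else:
            lin = idx[0][ok] * shape[1] + idx[1][ok]
        np.add.at(flat, lin, 1.0)
    return flat


def _bias_matrix(windows, axes) -> np.ndarray:
    """Window bias energy evaluated at every bin center, (K, M)."""
    grids = np.meshgrid(*[ax.centers for ax in axes], indexing="ij")
    coords = {ax.cv: g.ravel() for ax, g in zip(axes, grids)}
    M = grids[0].size
    C = np.zeros((len(windows), M))
    for k, w in enumerate(windows):
        for r in w.restraints:
            if r.cv in coords:
                C[k] += r.energy(coords[r.cv])
    return C


def _check_overlap(windows, hists, axes) -> None:
    """The windows' sampled-bin sets must form one connected component (two
    windows are linked when they share at least one sampled bin); otherwise
    WHAM cannot tie their free-energy offsets together."""
    K = len(windows)
    if K < 2:
        return
    occ = np.asarray([h > 0 for h in hists], dtype=float)   # (K, M)
    shared = occ @ occ.T                                     # shared-bin counts
    # union-find over the window-overlap graph
    parent = list(range(K))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(K):
        for b in range(a + 1, K):
            if shared[a, b] > 0:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    roots = {find(k) for k in range(K)}
    if len(roots) > 1:
        comps = {}
        for k in range(K):
            comps.setdefault(find(k), []).append(k)
        groups = sorted(comps.values(), key=len, reverse=True)
        raise ValueError(
            "non-overlapping windows: sampled histograms split into "
            f"{len(groups)} disconnected groups; gap between window sets "
            f"{groups[0][:5]}... and {groups[1][:5]}..."
        )
    # weak-overlap warning: a window whose best pairwise overlap is thin
    counts = np.asarray(hists)
    for k in range(K):
        best = 0.0
        for b in range(K):
            if b != k and shared[k, b] > 0:
                best = max(best, float(np.minimum(counts[k], counts[b]).sum()))
        if best < 10:
            warnings.warn(
                f"weak overlap: window {k} shares fewer than 10 counts with "
                "every other window", stacklevel=3,
            )
            break


def wham(
    windows,
    grid,
    temperature: float = 310.0,
    tol: float = 1e-7,
    max_iter: int = 100000,
) -> FreeEnergyGrid:
    """Self-consistent WHAM on a 1D or 2D grid.

    Iterates the per-window free-energy constants f_k and the unbiased bin
    probabilities until max |delta f_k| < tol (kcal/mol).  Returns the
    minimum-shifted PMF with unsampled bins masked.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one window")
    axes = tuple(grid)
    kT = _kT(temperature)
    hists = [_histogram(w, axes) for w in windows]
    for k, h in enumerate(hists):
        if h.sum() == 0:
            raise ValueError(f"window {k} has no samples inside the grid")
    _check_overlap(windows, hists, axes)
    H = np.asarray(hists)              # (K, M)
    C = _bias_matrix(windows, axes)    # (K, M)
    N = H.sum(axis=1)                  # (K,)
    Htot = H.sum(axis=0)               # (M,)
    sampled = Htot > 0

    # work on sampled bins only; unsampled bins stay masked
    S = np.flatnonzero(sampled)
    b = -C[:, S] / kT                  # log Boltzmann factor of window bias
    logN = np.log(N)
    Hs = Htot[S]
    logH = np.log(Hs)

    def sc_update(f):
        """One self-consistent sweep: f (kcal/mol) -> (f', log p)."""
        denom = logsumexp(logN[:, None] + f[:, None] / kT + b, axis=0)
        logp = logH - denom
        fnew = -kT * logsumexp(b + logp[None, :], axis=1)
        return fnew - fnew[0], logp

    # warm start: the self-consistent equations are the stationarity
    # conditions of a convex objective (binned MBAR); quasi-Newton descent
    # gets within polishing range orders of magnitude faster than direct
    # iteration for many stiff windows
    def objective(g):
        # g = f/kT
        lse = logsumexp(logN[:, None] + g[:, None] + b, axis=0)
        val = float(Hs @ lse - N @ g)
        w = np.exp(logN[:, None] + g[:, None] + b - lse[None, :])
        grad = (w @ Hs) - N
        return val, grad

    res = minimize(objective, np.zeros(len(windows)), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10})
    f = kT * (res.x - res.x[0])
    # polish to the requested fixed-point tolerance
    logp = None
    for it in range(max_iter):
        fnew, logp = sc_update(f)
        resid = float(np.max(np.abs(fnew - f)))
        f = fnew
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {resid:.3e} kcal/mol)"
        )
    F = np.full(Htot.shape, np.nan)
    F[S] = -kT * logp
    shape = tuple(ax.n_bins for ax in axes)
    g = FreeEnergyGrid(axes, F.reshape(shape), sampled.reshape(shape))
    return g.min_shifted()


def block_averaged_wham(
    windows,
    grid,
    temperature: float = 310.0,
    n_blocks: int = 8,
    keep_last: int = 4,
    tol: float = 1e-7,
    max_iter: int = 100000,
) -> tuple[FreeEnergyGrid, BlockReport]:
    """WHAM with block-averaged convergence assessment.

    Every window's series is split into ``n_blocks`` equal time blocks,
    WHAM is run per block, and the PMF is averaged bin-wise over the last
    ``keep_last`` blocks (early blocks, which typically still relax toward
    the window's stationary distribution, are discarded).  Block PMFs are
    aligned on their common sampled bins before averaging; the per-bin
    standard error across retained blocks is reported.
    """
    if not (1 <= keep_last <= n_blocks):
        raise ValueError("keep_last must lie in [1, n_blocks]")
    axes = tuple(grid)
    split = []
    for k, w in enumerate(windows):
        try:
            split.append(w.time_blocks(n_blocks))
        except ValueError as e:
            raise ValueError(f"window {k}: {e}") from e
    block_grids = []
    for b in range(n_blocks):
        per_block = [s[b] for s in split]
        for k, s in enumerate(per_block):
            if _histogram(s, axes).sum() == 0:
                raise ValueError(f"window {k}, block {b}: empty histogram")
        block_grids.append(
            wham(per_block, axes, temperature, tol=tol, max_iter=max_iter)
        )
    retained = tuple(range(n_blocks - keep_last, n_blocks))
    ref = block_grids[retained[0]]
    mask = np.all([block_grids[b].mask for b in retained], axis=0)
    if not mask.any():
        raise ValueError("no bin sampled in every retained block")
    stack = []
    for b in retained:
        g = block_grids[b]
        # align to the first retained block on the common sampled bins
        shift = np.mean(g.free_energy[mask] - ref.free_energy[mask])
        stack.append(np.where(mask, g.free_energy - shift, np.nan))
    stack = np.asarray(stack)
    avg = np.where(mask, stack.mean(axis=0), np.nan)
    se = np.where(
        mask,
        stack.std(axis=0, ddof=1) / math.sqrt(len(retained)) if len(retained) > 1
        else 0.0,
        np.nan,
    )
    grid_out = FreeEnergyGrid(axes, avg, mask, se).min_shifted()
    report = BlockReport(
        n_blocks=n_blocks,
        keep_last=keep_last,
        block_grids=tuple(block_grids),
        retained=retained,
        se=se,
    )
    return grid_out, report


# ---------------------------------------------------------------------------
# metadynamics

def accumulated_bias(hills: HillsLog, grid, weights=None) -> np.ndarray:
    """(Weighted) sum of deposited Gaussians evaluated at every bin center."""
    axes = tuple(grid)
    mesh = np.meshgrid(*[ax.centers for ax in axes], indexing="ij")
    pts = np.stack([g.ravel() for g in mesh], axis=1)   # (M, d)
    h_all = hills.heights if weights is None else hills.heights * weights
    V = np.zeros(pts.shape[0])
    # chunk over hills to bound memory
    for start in range(0, hills.n_hills, 512):
        c = hills.centers[start:start + 512]
        s = hills.sigmas[start:start + 512]
        h = h_all[start:start + 512]
        z = (pts[None, :, :] - c[:, None, :]) / s[:, None, :]
        V += (h[:, None] * np.exp(-0.5 * np.sum(z * z, axis=2))).sum(axis=0)
    return V.reshape(tuple(ax.n_bins for ax in axes))


def metad_free_energy(
    hills: HillsLog,
    grid,
    temperature: float = 310.0,
    method: str = "bias-inversion",
    average_last: float = 0.5,
) -> FreeEnergyGrid:
    """Well-tempered metadynamics free energy by bias inversion:
    F(s) = -(gamma/(gamma-1)) V(s), minimum-shifted.  In the
    gamma -> infinity (standard metadynamics) limit F(s) = -V(s).

    With a large bias factor hill heights decay slowly and the
    instantaneous bias oscillates around the converged profile by roughly
    one hill height; ``average_last`` therefore averages V over the final
    fraction of the deposition history (0 uses the final bias only).  The
    time average of a cumulative sum is a per-hill weighted sum, computed
    in one pass.
    """
    if method != "bias-inversion":
        raise ValueError(f"unknown method {method!r}")
    if hills.n_hills == 0:
        raise ValueError("empty hills log")
    if not 0.0 <= average_last < 1.0:
        raise ValueError("average_last must lie in [0, 1)")
    axes = tuple(grid)
    for ax in axes:
        if ax.cv not in hills.cv_names:
            raise ValueError(f"hills log has no CV {ax.cv!r}")
    n = hills.n_hills
    # deposition must be chronological for the running-average weights
    order = np.argsort(hills.times, kind="stable")
    t0 = int(math.floor((1.0 - average_last) * n))
    t0 = min(max(t0, 1), n)
    # <V> over snapshots after t0..n hills: hill i (0-based, time order)
    # appears in snapshots t > i, so its weight is the covered fraction
    n_snap = n - t0 + 1
    w_sorted = np.clip(n + 1 - np.maximum(t0, np.arange(1, n + 1)), 0, None) / n_snap
    weights = np.empty(n)
    weights[order] = w_sorted
    V = accumulated_bias(hills, axes, weights=weights)
    g = hills.bias_factor
    factor = 1.0 if math.isinf(g) else g / (g - 1.0)
    F = -factor * V
    mask = np.ones_like(F, dtype=bool)
    return FreeEnergyGrid(axes, F, mask).min_shifted()


def merge_walkers(logs) -> HillsLog:
    """Merge per-walker hill logs into one time-ordered log.

    Ties in deposition time break by walker id, so the merge is independent
    of input order.  CV definitions and the bias factor must match.
    """
    logs = list(logs)
    if not logs:
        raise ValueError("no hill logs given")
    ref = logs[0]
    for lg in logs[1:]:
        if lg.cv_names != ref.cv_names:
            raise ValueError("mismatched CV names across walker logs")
        if not (math.isinf(lg.bias_factor) and math.isinf(ref.bias_factor)) \
                and lg.bias_factor != ref.bias_factor:
            raise ValueError("mismatched bias factor across walker logs")
    times = np.concatenate([lg.times for lg in logs])
    centers = np.concatenate([lg.centers for lg in logs])
    sigmas = np.concatenate([lg.sigmas for lg in logs])
    heights = np.concatenate([lg.heights for lg in logs])
    walkers = np.concatenate([lg.walkers for lg in logs])
    order = np.lexsort((walkers, times))
    return HillsLog(
        cv_names=ref.cv_names,
        times=times[order],
        centers=centers[order],
        sigmas=sigmas[order],
        heights=heights[order],
        bias_factor=ref.bias_factor,
        walkers=walkers[order],
    )
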