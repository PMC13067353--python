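"""Synthetic biased sampling in collective-variable space.

Stands in for reactive MD: overdamped Langevin (Euler-Maruyama) dynamics on
a closed-form model free-energy surface in (xi*, phi*), under harmonic
umbrella restraints or well-tempered metadynamics bias, plus a generator of
explicit hydration frames (water oxygens + excess-charge probe) along a
channel with a tunable weakly hydrated gap.  Every generator is
deterministic given its seed, so the full downstream analysis chain
(WHAM, block averaging, metadynamics inversion, MFEP, rates) can be
exercised end to end with known ground truth.

The model surface couples a double well in the path-progress coordinate xi
to the hydration coordinate phi:

    F(xi, phi) = g(u) + kappa_phi * (phi - phi_min(u))^2,
    u = (xi - xi_R) / (xi_P - xi_R)

where g is a quartic double-well profile calibrated so that its interior
maximum equals the requested barrier dF and g(1) - g(0) = dG, and
phi_min(u) is the quadratic through (0, phi_R), (u_s, phi_S), (1, phi_P).
By construction the reactant/product minima and the saddle of F sit exactly
at the requested locations with the requested free energies, which makes
the surface an analytic oracle for the whole pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from protonpath.constants import kT as _kT
from protonpath.free_energy import BiasedTimeSeries, HillsLog, RestraintSpec
from protonpath.path_geometry import PathNodes, resample_equidistant, set_frame
from protonpath.colvars import HydrationFrame

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSurface",
    "DoubleWell1D",
    "SamplerConfig",
    "RestraintSpec",
    "MetadSpec",
    "make_surface",
    "make_double_well_1d",
    "langevin_sample",
    "run_umbrella_set",
    "run_metadynamics",
    "generate_hydration_frames",
    "umbrella_windows_1d",
    "umbrella_windows_2d",
    "SURFACE_PRESETS",
]


# ---------------------------------------------------------------------------
# barrier profile g(u)

class _BarrierProfile:
    """g(u) = 16 a u^2 (1-u)^2 + dg u^2 (3 - 2u), with the amplitude a
    calibrated so the interior maximum equals the requested barrier.

    g(0) = 0, g(1) = dg, g'(0) = g'(1) = 0; the interior stationary point
    sits at u_s = 1/2 + 3 dg / (32 a) (closed form)."""

    def __init__(self, barrier: float, dg: float):
        if barrier <= max(dg, 0.0):
            raise ValueError(
                "barrier must exceed max(dg, 0) for a saddle to exist "
                f"(barrier={barrier}, dg={dg})"
            )
        self.dg = float(dg)
        a_lo = 3.0 * abs(dg) / 16.0 * (1.0 + 1e-9) + 1e-12

        def top(a):
            us = 0.5 + 3.0 * dg / (32.0 * a)
            return self._g(us, a) - barrier

        a_hi = max(barrier, a_lo * 2, 1.0)
        while top(a_hi) < 0:
            a_hi *= 2.0
            if a_hi > 1e12:
                raise ValueError("no saddle between basins for these parameters")
        if top(a_lo) > 0:
            raise ValueError("no saddle between basins for these parameters")
        self.a = brentq(top, a_lo, a_hi, xtol=1e-14, rtol=1e-15)
        self.u_s = 0.5 + 3.0 * dg / (32.0 * self.a)
        self.barrier = barrier

    def _g(self, u, a):
        u = np.asarray(u, dtype=float)
        return 16.0 * a * u**2 * (1.0 - u) ** 2 + self.dg * u**2 * (3.0 - 2.0 * u)

    def g(self, u):
        return self._g(u, self.a)

    def dg_du(self, u):
        u = np.asarray(u, dtype=float)
        return u * (1.0 - u) * (32.0 * self.a * (1.0 - 2.0 * u) + 6.0 * self.dg)


@dataclass(frozen=True)
class ModelSurface:
    """Coupled 2D model free-energy surface F(xi, phi) in kcal/mol.

    Parameters place the reactant minimum at (xi_r, phi_r) with F = 0, the
    product minimum at (xi_p, phi_p) with F = dg, and the saddle at
    hydration phi_s with F = barrier; kappa_phi (kcal/mol per phi^2) sets
    the stiffness of the hydration channel.
    """

    xi_r: float = 0.0
    phi_r: float = 0.75
    xi_p: float = 10.0
    phi_p: float = 0.85
    phi_s: float = 0.92
    barrier: float = 6.0
    dg: float = 3.0
    kappa_phi: float = 60.0
    cv_names: tuple[str, str] = ("xi_star", "phi_star")
    _profile: _BarrierProfile = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.xi_p <= self.xi_r:
            raise ValueError("xi_p must exceed xi_r")
        if self.kappa_phi <= 0:
            raise ValueError("kappa_phi must be positive")
        object.__setattr__(self, "_profile", _BarrierProfile(self.barrier, self.dg))

    # --- geometry -----------------------------------------------------
    @property
    def ndim(self) -> int:
        return 2

    @property
    def span(self) -> float:
        return self.xi_p - self.xi_r

    @property
    def u_s(self) -> float:
        return self._profile.u_s

    @property
    def xi_saddle(self) -> float:
        return self.xi_r + self.u_s * self.span

    @property
    def bounds(self):
        """Per-CV (lo, hi, mode) domain guards: xi errors out on divergence,
        phi reflects at [0, 1] (phi is bounded by construction)."""
        m = 0.5 * self.span
        return (
            (self.xi_r - m, self.xi_p + m, "error"),
            (0.0, 1.0, "reflect"),
        )

    def _u(self, xi):
        return (np.asarray(xi, dtype=float) - self.xi_r) / self.span

    def phi_min_of_xi(self, xi):
        """Quadratic hydration valley floor through (xi_r, phi_r),
        (xi_saddle, phi_s), (xi_p, phi_p)."""
        u = self._u(xi)
        us = self.u_s
        l0 = (u - us) * (u - 1.0) / (us * 1.0)          # basis at u=0
        l1 = u * (u - 1.0) / (us * (us - 1.0))          # basis at u=us
        l2 = u * (u - us) / (1.0 * (1.0 - us))          # basis at u=1
        return self.phi_r * l0 + self.phi_s * l1 + self.phi_p * l2

    def _dphimin_du(self, u):
        us = self.u_s
        d0 = (2.0 * u - us - 1.0) / us
        d1 = (2.0 * u - 1.0) / (us * (us - 1.0))
        d2 = (2.0 * u - us) / (1.0 - us)
        return self.phi_r * d0 + self.phi_s * d1 + self.phi_p * d2

    # --- energetics ---------------------------------------------------
    def value(self, xi, phi):
        u = self._u(xi)
        dphi = np.asarray(phi, dtype=float) - self.phi_min_of_xi(xi)
        return self._profile.g(u) + self.kappa_phi * dphi**2

    def grad(self, xi, phi):
        """(dF/dxi, dF/dphi), vectorized."""
        u = self._u(xi)
        phim = self.phi_min_of_xi(xi)
        dphi = np.asarray(phi, dtype=float) - phim
        dgdu = self._profile.dg_du(u) - 2.0 * self.kappa_phi * dphi * self._dphimin_du(u)
        return dgdu / self.span, 2.0 * self.kappa_phi * dphi

    def value_at(self, x):
        x = np.asarray(x, dtype=float)
        return self.value(x[..., 0], x[..., 1])

    def grad_at(self, x):
        x = np.asarray(x, dtype=float)
        gx, gp = self.grad(x[..., 0], x[..., 1])
        return np.stack([gx, gp], axis=-1)

    # --- verification -------------------------------------------------
    def stationary_points(self):
        """Exact stationary points: ((xi, phi, F) for reactant, saddle,
        product)."""
        return (
            (self.xi_r, self.phi_r, 0.0),
            (self.xi_saddle, self.phi_s, self._profile.g(self.u_s)),
            (self.xi_p, self.phi_p, self.dg),
        )


@dataclass(frozen=True)
class DoubleWell1D:
    """1D double well F(x) in kcal/mol using the same calibrated quartic
    profile, for a phi-like bounded coordinate."""

    x_r: float = 0.25
    x_p: float = 0.75
    barrier: float = 4.0
    dg: float = 1.0
    cv_names: tuple[str, ...] = ("phi",)
    lo: float = 0.0
    hi: float = 1.0
    _profile: _BarrierProfile = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.x_p <= self.x_r:
            raise ValueError("x_p must exceed x_r")
        object.__setattr__(self, "_profile", _BarrierProfile(self.barrier, self.dg))

    @property
    def ndim(self) -> int:
        return 1

    @property
    def span(self) -> float:
        return self.x_p - self.x_r

    @property
    def x_saddle(self) -> float:
        return self.x_r + self._profile.u_s * self.span

    @property
    def bounds(self):
        return ((self.lo, self.hi, "reflect"),)

    def value(self, x):
        u = (np.asarray(x, dtype=float) - self.x_r) / self.span
        return self._profile.g(u)

    def grad(self, x):
        u = (np.asarray(x, dtype=float) - self.x_r) / self.span
        return (self._profile.dg_du(u) / self.span,)

    def value_at(self, x):
        x = np.asarray(x, dtype=float)
        return self.value(x[..., 0])

    def grad_at(self, x):
        x = np.asarray(x, dtype=float)
        return self.grad(x[..., 0])[0][..., None]


SURFACE_PRESETS: dict[str, dict] = {
    # desk-scale analog of the hydration-coupled landscape: reactant minimum
    # near (0, 0.75), saddle near (6, 0.92), endergonic product
    "e_channel": dict(
        xi_r=0.0, phi_r=0.75, xi_p=10.0, phi_p=0.85, phi_s=0.92,
        barrier=6.0, dg=3.0, kappa_phi=60.0,
    ),
    "symmetric": dict(
        xi_r=0.0, phi_r=0.75, xi_p=10.0, phi_p=0.75, phi_s=0.92,
        barrier=6.0, dg=0.0, kappa_phi=60.0,
    ),
}


def make_surface(preset: str | dict = "e_channel", verify: bool = True, **overrides) -> ModelSurface:
    """Build a model surface from a preset name or parameter dict and
    numerically verify its stationary points.

    Verification re-locates the minima by local grid refinement and checks
    F(product) - F(reactant) = dg to 1e-6 and that the saddle value matches
    the requested barrier; the stationary free energies are logged.
    """
    params = dict(SURFACE_PRESETS[preset]) if isinstance(preset, str) else dict(preset)
    params.update(overrides)
    surf = ModelSurface(**params)
    if verify:
        for (xi0, phi0, f0), label in zip(
            surf.stationary_points(), ("reactant", "saddle", "product")
        ):
            gx, gp = surf.grad(xi0, phi0)
            if abs(gx) > 1e-8 or abs(gp) > 1e-8:
                raise RuntimeError(f"{label} is not stationary: grad=({gx}, {gp})")
            if abs(surf.value(xi0, phi0) - f0) > 1e-9:
                raise RuntimeError(f"{label} free energy mismatch")
            logger.info("surface %s at (%.3f, %.3f): F = %.4f kcal/mol",
                        label, xi0, phi0, f0)
        if abs((surf.value(surf.xi_p, surf.phi_p)
                - surf.value(surf.xi_r, surf.phi_r)) - surf.dg) > 1e-6:
            raise RuntimeError("product-reactant free energy != dg")
    return surf


def make_double_well_1d(**params) -> DoubleWell1D:
    return DoubleWell1D(**params)


# ---------------------------------------------------------------------------
# Langevin dynamics

@dataclass(frozen=True)
class SamplerConfig:
    """Overdamped Langevin parameters (reduced units; temperature in K,
    energies kcal/mol, so k_B T enters in kcal/mol).

    ``friction`` may be a scalar or a per-CV tuple: the stationary
    distribution is friction-independent, so a smaller friction on a slow,
    softly restrained CV shortens its correlation time without changing
    any equilibrium average."""

    timestep: float = 2e-5
    friction: float | tuple[float, ...] = 1.0
    temperature: float = 310.0
    n_steps: int = 100_000
    seed: int = 0
    initial: tuple[float, ...] = (0.0,)
    stride: int = 10
    burn_in: int = 0

    def __post_init__(self) -> None:
        fr = self.friction if isinstance(self.friction, tuple) else (self.friction,)
        if self.timestep <= 0 or self.temperature <= 0 or min(fr) <= 0:
            raise ValueError("timestep, friction and temperature must be positive")
        if self.n_steps < 1 or self.stride < 1 or self.burn_in < 0:
            raise ValueError("invalid step counts")

    def friction_per_dim(self, ndim: int) -> np.ndarray:
        fr = self.friction
        if isinstance(fr, tuple):
            if len(fr) != ndim:
                raise ValueError("friction tuple length must match CV count")
            return np.asarray(fr, dtype=float)
        return np.full(ndim, float(fr))


@dataclass(frozen=True)
class MetadSpec:
    """Well-tempered metadynamics protocol.

    ``sigma`` maps CV name to hill width; hills of initial height
    ``height`` (kcal/mol) are deposited every ``pace`` steps by each of
    ``n_walkers`` walkers, scaled by exp(-V/( (gamma-1) k_B T )); walkers
    refresh the shared bias every ``share_interval`` steps.
    """

    height: float = 0.6
    sigma: dict = field(default_factory=lambda: {"phi": 0.02})
    pace: int = 1000
    bias_factor: float = 35.0
    n_walkers: int = 8
    share_interval: int = 100

    def __post_init__(self) -> None:
        if self.height <= 0 or any(s <= 0 for s in self.sigma.values()):
            raise ValueError("hill height and widths must be positive")
        if not self.bias_factor > 1:
            raise ValueError("bias factor must exceed 1")
        if self.pace < 1 or self.n_walkers < 1 or self.share_interval < 1:
            raise ValueError("pace, n_walkers and share_interval must be >= 1")


def _apply_bounds(x: np.ndarray, bounds, step: int) -> None:
    """Reflect or error per dimension, in place."""
    for d, (lo, hi, mode) in enumerate(bounds):
        col = x[:, d]
        if mode == "reflect":
            # a single reflection suffices for overdamped step sizes
            np.copyto(col, np.where(col < lo, 2.0 * lo - col, col))
            np.copyto(col, np.where(col > hi, 2.0 * hi - col, col))
            if np.any((col < lo) | (col > hi)):
                raise RuntimeError(f"divergence at step {step}: CV {d} left the domain")
        else:
            if np.any((col < lo) | (col > hi)):
                raise RuntimeError(f"divergence at step {step}: CV {d} left the domain")


def _restraint_arrays(surface, windows):
    """Per-window (centers, kappas) arrays aligned with surface CV order;
    kappa = 0 where a CV is unrestrained."""
    names = list(surface.cv_names)
    K = len(windows)
    centers = np.zeros((K, len(names)))
    kappas = np.zeros((K, len(names)))
    for k, win in enumerate(windows):
        for r in win:
            if r.cv not in names:
                raise ValueError(f"restraint on unknown CV {r.cv!r}")
            d = names.index(r.cv)
            centers[k, d] = r.center
            kappas[k, d] = r.kappa
    return centers, kappas


def _integrate(surface, x, n_steps, cfg, rng, *,
               centers=None, kappas=None, bias_force=None,
               stride=None, on_step=None, step0=0):
    """Batched Euler-Maruyama integration of replicas ``x`` (R, d) in place.

    Optional harmonic restraints (centers/kappas per replica), an external
    ``bias_force(x) -> (R, d)`` callable (metadynamics), a recording stride
    and an ``on_step(step, x)`` hook (hill deposition).  Returns recorded
    (times, positions, bias_energies) when ``stride`` is set.
    """
    dt = cfg.timestep
    gamma = cfg.friction_per_dim(surface.ndim)
    pref = dt / gamma
    noise = np.sqrt(2.0 * _kT(cfg.temperature) * dt / gamma)
    bounds = surface.bounds
    rec_t, rec_x, rec_b = [], [], []
    for step in range(n_steps):
        force = -surface.grad_at(x)
        if kappas is not None:
            force -= kappas * (x - centers)
        if bias_force is not None:
            force += bias_force(x)
        x += pref * force + noise * rng.standard_normal(x.shape)
        _apply_bounds(x, bounds, step0 + step)
        if on_step is not None:
            on_step(step0 + step + 1, x)
        if stride is not None and (step + 1) % stride == 0:
            rec_t.append((step0 + step + 1) * dt)
            rec_x.append(x.copy())
            if kappas is not None:
                rec_b.append(0.5 * np.sum(kappas * (x - centers) ** 2, axis=1))
    if stride is None:
        return None
    return (
        np.asarray(rec_t),
        np.asarray(rec_x),
        np.asarray(rec_b) if rec_b else None,
    )


def langevin_sample(surface, restraints=None, cfg: SamplerConfig | None = None) -> BiasedTimeSeries:
    """Sample one trajectory on ``surface`` (plus optional harmonic
    restraints) and return the recorded CV/bias time series.  Deterministic
    given ``cfg.seed``."""
    cfg = cfg or SamplerConfig()
    restraints = tuple(restraints or ())
    x = np.array([cfg.initial], dtype=float)
    if x.shape[1] != surface.ndim:
        raise ValueError("initial point dimensionality mismatch")
    centers, kappas = _restraint_arrays(surface, [restraints]) if restraints else (None, None)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    if cfg.burn_in:
        _integrate(surface, x, cfg.burn_in, cfg, rng,
                   centers=centers, kappas=kappas)
    t, xs, bias = _integrate(
        surface, x, cfg.n_steps, cfg, rng,
        centers=centers, kappas=kappas, stride=cfg.stride,
    )
    cvs = {name: xs[:, 0, d] for d, name in enumerate(surface.cv_names)}
    return BiasedTimeSeries.from_arrays(
        time=t, cvs=cvs,
        bias=bias[:, 0] if bias is not None else None,
        restraints=restraints,
    )


def _normalize_windows(windows):
    out = []
    for w in windows:
        out.append(tuple(w) if isinstance(w, (list, tuple)) else (w,))
    return out


def run_umbrella_set(surface, windows, cfg: SamplerConfig,
                     drag_steps: int = 4000) -> list[BiasedTimeSeries]:
    """Run one umbrella-sampling set.

    Each window is first equilibrated for ``drag_steps`` starting from the
    previous window's final point (sequential "dragging" of the system
    along the path); production then runs for all windows simultaneously
    for ``cfg.n_steps``, recording every ``cfg.stride`` steps.  Each
    returned series carries its restraints, as WHAM requires.
    """
    windows = _normalize_windows(windows)
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    centers, kappas = _restraint_arrays(surface, windows)
    ss = np.random.SeedSequence(cfg.seed)
    drag_seeds, prod_seed = ss.spawn(2)
    drag_rngs = [np.random.default_rng(s) for s in drag_seeds.spawn(len(windows))]

    # sequential drag
    state = np.array(cfg.initial, dtype=float)
    if state.size != surface.ndim:
        raise ValueError("initial point dimensionality mismatch")
    inits = np.empty((len(windows), surface.ndim))
    for k in range(len(windows)):
        x = state[None, :].copy()
        _integrate(surface, x, drag_steps, cfg, drag_rngs[k],
                   centers=centers[k:k + 1], kappas=kappas[k:k + 1])
        state = x[0].copy()
        inits[k] = state

    # batched production
    x = inits.copy()
    rng = np.random.default_rng(prod_seed)
    t, xs, bias = _integrate(surface, x, cfg.n_steps, cfg, rng,
                             centers=centers, kappas=kappas, stride=cfg.stride)
    series = []
    for k, win in enumerate(windows):
        cvs = {name: xs[:, k, d] for d, name in enumerate(surface.cv_names)}
        series.append(BiasedTimeSeries.from_arrays(
            time=t, cvs=cvs, bias=bias[:, k], restraints=win,
        ))
    return series


# ---------------------------------------------------------------------------
# metadynamics

class _BiasGrid:
    """Accumulated metadynamics bias and its gradient on a regular grid,
    queried by (bi)linear interpolation."""

    def __init__(self, bounds, n_points=801):
        self.ndim = len(bounds)
        ns = [n_points] * self.ndim if np.isscalar(n_points) else list(n_points)
        self.axes = [np.linspace(lo, hi, n) for (lo, hi, _), n in zip(bounds, ns)]
        shape = tuple(len(a) for a in self.axes)
        self.V = np.zeros(shape)
        self.G = [np.zeros(shape) for _ in range(self.ndim)]

    def add_hill(self, center, sigma, height):
        zs = [(a - c) / s for a, c, s in zip(self.axes, center, sigma)]
        if self.ndim == 1:
            e = height * np.exp(-0.5 * zs[0] ** 2)
            self.V += e
            self.G[0] += -e * zs[0] / sigma[0]
        else:
            e0 = np.exp(-0.5 * zs[0] ** 2)[:, None]
            e1 = np.exp(-0.5 * zs[1] ** 2)[None, :]
            e = height * e0 * e1
            self.V += e
            self.G[0] += -e * (zs[0] / sigma[0])[:, None]
            self.G[1] += -e * (zs[1] / sigma[1])[None, :]

    def _locate(self, x):
        idx, frac = [], []
        for d, a in enumerate(self.axes):
            h = a[1] - a[0]
            f = np.clip((x[:, d] - a[0]) / h, 0.0, len(a) - 1.000001)
            i = f.astype(int)
            idx.append(i)
            frac.append(f - i)
        return idx, frac

    def _interp(self, arr, idx, frac):
        if self.ndim == 1:
            i, f = idx[0], frac[0]
            return arr[i] * (1 - f) + arr[i + 1] * f
        i, j = idx
        fi, fj = frac
        return (arr[i, j] * (1 - fi) * (1 - fj)
                + arr[i + 1, j] * fi * (1 - fj)
                + arr[i, j + 1] * (1 - fi) * fj
                + arr[i + 1, j + 1] * fi * fj)

    def value(self, x):
        idx, frac = self._locate(np.atleast_2d(x))
        return self._interp(self.V, idx, frac)

    def grad(self, x):
        x = np.atleast_2d(x)
        idx, frac = self._locate(x)
        return np.stack([self._interp(g, idx, frac) for g in self.G], axis=-1)


def run_metadynamics(surface, spec: MetadSpec, cfg: SamplerConfig,
                     grid_points=None):
    """Multiple-walker well-tempered metadynamics on ``surface``.

    All walkers step synchronously for ``cfg.n_steps`` each; every
    ``spec.pace`` steps each walker deposits a Gaussian hill whose height is
    the well-tempered rescaling w0 * exp(-V(s) / ((gamma-1) k_B T)) of the
    initial height.  Deposited hills become visible to the walkers' bias
    force when the shared bias is refreshed, every ``spec.share_interval``
    steps (mirroring walkers that re-read a shared hills file); the
    depositing walker's own pending hills do enter its next deposition
    height.  Returns (merged HillsLog, per-walker BiasedTimeSeries).
    """
    names = list(surface.cv_names)
    sigma = np.array([spec.sigma[n] for n in names], dtype=float)
    kTval = _kT(cfg.temperature)
    gamma = spec.bias_factor
    if grid_points is None:
        grid_points = 801 if surface.ndim == 1 else 201
    shared = _BiasGrid(surface.bounds, grid_points)
    pending: list[tuple[np.ndarray, float]] = []
    hills = {"t": [], "c": [], "h": [], "w": []}

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    x = np.tile(np.asarray(cfg.initial, dtype=float), (spec.n_walkers, 1))
    if x.shape[1] != surface.ndim:
        raise ValueError("initial point dimensionality mismatch")
    # small deterministic spread so walkers decorrelate immediately
    x += 0.01 * sigma * rng.standard_normal(x.shape)
    _apply_bounds(x, surface.bounds, 0)

    def pending_bias_at(pt):
        v = 0.0
        for c, h in pending:
            z = (pt - c) / sigma
            v += h * math.exp(-0.5 * float(z @ z))
        return v

    def on_step(step, x):
        if step % spec.pace == 0:
            for wk in range(spec.n_walkers):
                v = float(shared.value(x[wk:wk + 1])[0]) + pending_bias_at(x[wk])
                h = spec.height if math.isinf(gamma) else \
                    spec.height * math.exp(-v / ((gamma - 1.0) * kTval))
                pending.append((x[wk].copy(), h))
                hills["t"].append(step * cfg.timestep)
                hills["c"].append(x[wk].copy())
                hills["h"].append(h)
                hills["w"].append(wk)
        if step % spec.share_interval == 0 and pending:
            for c, h in pending:
                shared.add_hill(c, sigma, h)
            pending.clear()

    t, xs, _ = _integrate(
        surface, x, cfg.n_steps, cfg, rng,
        bias_force=lambda s: -shared.grad(s),
        stride=cfg.stride, on_step=on_step,
    )
    # flush anything still pending so the log and grid agree
    for c, h in pending:
        shared.add_hill(c, sigma, h)
    pending.clear()

    n = len(hills["h"])
    log = HillsLog(
        cv_names=tuple(names),
        times=np.asarray(hills["t"]),
        centers=np.asarray(hills["c"]).reshape(n, surface.ndim),
        sigmas=np.tile(sigma, (n, 1)),
        heights=np.asarray(hills["h"]),
        bias_factor=gamma,
        walkers=np.asarray(hills["w"], dtype=int),
    )
    series = []
    for wk in range(spec.n_walkers):
        cvs = {name: xs[:, wk, d] for d, name in enumerate(names)}
        series.append(BiasedTimeSeries.from_arrays(time=t, cvs=cvs))
    return log, series


# ---------------------------------------------------------------------------
# window presets

def umbrella_windows_1d(xi_lo: float = -1.0, xi_hi: float = 11.0,
                        n_windows: int = 24, kappa: float = 10.0,
                        cv: str = "xi_star") -> list[tuple[RestraintSpec, ...]]:
    """1D protocol: harmonic windows along the path-progress CV
    (24 windows, force constant in the 10-30 kcal/mol range)."""
    return [(RestraintSpec(cv, c, kappa),)
            for c in np.linspace(xi_lo, xi_hi, n_windows)]


def umbrella_windows_2d(surface: ModelSurface,
                        xi_margin: float = 0.5,
                        n_xi: int = 26, n_phi: int = 5,
                        dphi: float = 0.033,
                        kappa_xi: float = 10.0, kappa_phi: float = 2500.0,
                        ) -> list[tuple[RestraintSpec, ...]]:
    """2D protocol: 26 x 5 = 130 windows over (xi*, phi*).

    The strong hydration restraint (2500 kcal/mol per phi^2) confines phi*
    to a ~0.016 band, so a regular phi grid would waste most windows on
    high-free-energy hydration states; instead each xi column carries
    ``n_phi`` rows centered on the hydration valley floor phi_min(xi) at
    offsets k*dphi, tiling the corridor the minimum free energy path can
    explore.  Columns are xi-ordered with serpentine phi ordering so every
    consecutive window is adjacent, as dragging requires.
    """
    cv_xi, cv_phi = surface.cv_names
    xi_centers = np.linspace(surface.xi_r - xi_margin,
                             surface.xi_p + xi_margin, n_xi)
    offsets = dphi * (np.arange(n_phi) - (n_phi - 1) / 2.0)
    wins = []
    for col, c_xi in enumerate(xi_centers):
        xi_ref = float(np.clip(c_xi, surface.xi_r, surface.xi_p))
        floor = float(surface.phi_min_of_xi(xi_ref))
        rows = offsets if col % 2 == 0 else offsets[::-1]
        for off in rows:
            c_phi = float(np.clip(floor + off, 0.02, 0.995))
            wins.append((RestraintSpec(cv_xi, float(c_xi), kappa_xi),
                         RestraintSpec(cv_phi, c_phi, kappa_phi)))
    return wins


# ---------------------------------------------------------------------------
# hydration frames

def generate_hydration_frames(
    n_frames: int,
    channel_length: float = 24.0,
    n_waters: int = 24,
    gap_center: float = 12.0,
    gap_width: float = 4.5,
    gap_occupancy_factor: float = 1.0,
    seed: int = 0,
    n_nodes: int = 25,
    jitter: float = 0.5,
    probe_arc: float | None = None,
) -> tuple[PathNodes, list[HydrationFrame]]:
    """Generate hydration snapshots along a straight channel with a tunable
    weakly hydrated gap (emulating the ~4.5 A poorly hydrated separation
    between acidic residues in the channel).

    Waters are placed uniformly along the channel axis with lateral
    Gaussian jitter; a water falling inside the gap is, with probability
    1 - gap_occupancy_factor, relocated outside it, thinning the gap
    density by the stated factor.  The excess-charge probe sits on the axis
    at arc position ``probe_arc`` (channel midpoint by default).
    Deterministic given ``seed``.
    """
    if n_waters < 1:
        raise ValueError("n_waters must be >= 1")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0.0 <= gap_occupancy_factor <= 1.0:
        raise ValueError("gap_occupancy_factor must lie in [0, 1]")
    if min(channel_length, gap_width, jitter) <= 0:
        raise ValueError("lengths must be positive")
    L = channel_length
    lo, hi = gap_center - gap_width / 2.0, gap_center + gap_width / 2.0
    lo, hi = max(lo, 0.0), min(hi, L)
    if hi - lo >= L:
        raise ValueError("gap covers the whole channel")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    probe_x = L / 2.0 if probe_arc is None else float(probe_arc)
    frames = []
    for _ in range(n_frames):
        xpos = rng.uniform(0.0, L, size=n_waters)
        in_gap = (xpos >= lo) & (xpos < hi)
        # relocate each gap water with probability 1 - factor; draws are
        # made for every water so the stream is factor-independent
        relocate = rng.uniform(size=n_waters) >= gap_occupancy_factor
        move = in_gap & relocate
        if move.any():
            outside = rng.uniform(0.0, L - (hi - lo), size=int(move.sum()))
            xpos[move] = np.where(outside < lo, outside, outside + (hi - lo))
        yz = jitter * rng.standard_normal((n_waters, 2))
        waters = np.column_stack([xpos, yz])
        frames.append(HydrationFrame(
            water_oxygens=waters,
            probe=np.array([probe_x, 0.0, 0.0]),
        ))
    line = np.array([[0.0, 0.0, 0.0], [L, 0.0, 0.0]])
    nodes = resample_equidistant(line, n_nodes)
    nodes = set_frame(nodes, origin_index=n_nodes // 2, orientation=1)
    return nodes, frames
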