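"""Method-of-lines reaction-diffusion solver on intervals and rectangles.

Space is discretized by second-order finite differences with a zero-flux
(mirror) closure on boundary nodes; time integration uses SciPy's BDF with
an analytically assembled sparse Jacobian, which is unconditionally stable
for the stiff linear diffusion part and applies local error control to the
reaction terms.  The run protocol follows the convergence convention used
throughout this package's worked examples: initial conditions are uniform
random perturbations of total width ``ic_range`` about the (possibly
heterogeneous) steady state, and a run counts as converged once the
sup-norm of the time derivative drops below ``deriv_tol`` *and* simulated
time has reached ``t_min``.  Piecewise-constant parameter schedules are
honoured by restarting the integrator at every switch time.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .fields import Grid1D, Grid2D, ParamField
from .kinetics import KineticSystem, verify_kinetics

__all__ = [
    "SimConfig",
    "SimResult",
    "BlowUpError",
    "initial_condition",
    "rhs",
    "run",
    "sweep_polar",
    "refine_check",
]


class BlowUpError(RuntimeError):
    """Raised when a field exceeds the blow-up bound or turns non-finite."""

    def __init__(self, t: float, message: str | None = None):
        self.t = t
        super().__init__(message or f"solution blew up at t ≈ {t:g}")


@dataclass
class SimConfig:
    """Simulation control parameters.

    ``D`` is the diffusion ratio of v relative to u (whose diffusivity is
    1 in nondimensional units).  A run stops once sup|∂u/∂t| and
    sup|∂v/∂t| are below ``deriv_tol`` *and* t ≥ ``t_min``; it is
    abandoned (``converged=False``) at ``t_cap``.  ``ic_range`` is the
    *total* width of the uniform initial perturbation about the steady
    state (±ic_range/2); set ``ic_range_is_halfwidth`` to interpret it as
    the half-width ±ic_range instead.
    """

    D: float = 8.0
    grid: Grid1D | Grid2D = field(default_factory=lambda: Grid1D(256, 50.0))
    t_min: float = 1e4
    t_cap: float = 5e4
    deriv_tol: float = 1e-3
    ic_range: float = 0.1
    ic_range_is_halfwidth: bool = False
    seed: int = 0
    dt_max: float = 10.0
    rtol: float = 1e-5
    atol: float = 1e-8
    blowup_bound: float = 1e6
    snapshot_times: tuple[float, ...] = ()
    check_kinetics: bool = True

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("diffusion ratio must be positive")
        if self.deriv_tol <= 0:
            raise ValueError("deriv_tol must be positive")
        if self.ic_range < 0:
            raise ValueError("ic_range must be nonnegative")


@dataclass
class SimResult:
    """Final state of a simulation with convergence diagnostics."""

    u: np.ndarray
    v: np.ndarray
    t_final: float
    converged: bool
    positivity_ok: bool
    deriv_sup: float
    seed: int
    config: SimConfig
    oscillatory: bool = False
    history: list[tuple[float, np.ndarray, np.ndarray]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Initial conditions
# ---------------------------------------------------------------------------

_POSITIVITY_FLOOR = 1e-9


def initial_condition(
    steady_state, shape: tuple[int, ...], ic_range: float, seed: int,
    halfwidth: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random perturbation about the steady state.

    Each node is drawn independently from U(s − w, s + w) with
    w = ic_range/2 (total spread ``ic_range``) where s is the local steady
    value; ``steady_state`` is a (U, V) pair of scalars or fields.
    Deterministic for a fixed seed.  Nodes pushed to zero or below are
    clipped at a small positive floor with a warning.
    """
    if ic_range < 0:
        raise ValueError("ic_range must be nonnegative")
    w = ic_range if halfwidth else ic_range / 2.0
    rng = np.random.default_rng(seed)
    U, V = steady_state
    u0 = np.broadcast_to(np.asarray(U, dtype=float), shape) + rng.uniform(-w, w, shape)
    v0 = np.broadcast_to(np.asarray(V, dtype=float), shape) + rng.uniform(-w, w, shape)
    if np.any(u0 <= 0) or np.any(v0 <= 0):
        warnings.warn("initial perturbation crossed zero; clipping at a positive floor")
        u0 = np.maximum(u0, _POSITIVITY_FLOOR)
        v0 = np.maximum(v0, _POSITIVITY_FLOOR)
    return u0, v0


# ---------------------------------------------------------------------------
# Discrete operators
# ---------------------------------------------------------------------------

def neumann_laplacian_1d(n: int, h: float) -> sp.csr_matrix:
    """3-point Laplacian with second-order zero-flux (mirror) closure."""
    main = np.full(n, -2.0)
    off = np.ones(n - 1)
    L = sp.diags([off, main, off], [-1, 0, 1], format="lil")
    L[0, 1] = 2.0
    L[n - 1, n - 2] = 2.0
    return (L / h**2).tocsr()


def neumann_laplacian_2d(grid: Grid2D) -> sp.csr_matrix:
    """5-point Laplacian on the rectangle, zero-flux on all edges.

    Acts on fields flattened in C order from shape (ny, nx).
    """
    Lx = neumann_laplacian_1d(grid.nx, grid.hx)
    Ly = neumann_laplacian_1d(grid.ny, grid.hy)
    Ix = sp.identity(grid.nx, format="csr")
    Iy = sp.identity(grid.ny, format="csr")
    return (sp.kron(Iy, Lx) + sp.kron(Ly, Ix)).tocsr()


def laplacian_for(grid) -> sp.csr_matrix:
    if isinstance(grid, Grid1D):
        return neumann_laplacian_1d(grid.nx, grid.hx)
    return neumann_laplacian_2d(grid)


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------

def _coeffs_as_float(coeffs: dict, shape) -> dict:
    out = {}
    for k, c in coeffs.items():
        arr = np.asarray(c, dtype=float)
        out[k] = float(arr) if arr.ndim == 0 else arr.reshape(-1)
    return out


class _Reaction:
    """Vectorized reaction evaluation with analytic partial derivatives."""

    def __init__(self, sys: KineticSystem, shape: tuple[int, ...]):
        self.sys = sys
        self.shape = shape
        U = np.asarray(sys.steady_state[0], dtype=float)
        self.U_flat = float(U) if U.ndim == 0 else U.reshape(-1)
        self.C = np.asarray(sys.C, dtype=float)
        self.C_flat = float(self.C) if self.C.ndim == 0 else self.C.reshape(-1)
        # flatten any heterogeneous coefficients once
        from .kinetics import _poly_diff  # local: shared monomial helpers
        self.f_c = _coeffs_as_float(sys.f_coeffs, shape)
        self.g_c = _coeffs_as_float(sys.g_coeffs, shape)
        self.fu_c = _coeffs_as_float(_poly_diff(sys.f_coeffs, 0), shape)
        self.fv_c = _coeffs_as_float(_poly_diff(sys.f_coeffs, 1), shape)
        self.gu_c = _coeffs_as_float(_poly_diff(sys.g_coeffs, 0), shape)
        self.gv_c = _coeffs_as_float(_poly_diff(sys.g_coeffs, 1), shape)
        self.sat = float(sys.saturation_eps or 0.0)

    @staticmethod
    def _eval(coeffs: dict, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        total = np.zeros_like(u)
        for (i, j), c in coeffs.items():
            total = total + c * (u**i if i else 1.0) * (v**j if j else 1.0)
        return total

    def f(self, u, v):
        val = self._eval(self.f_c, u, v)
        if self.sat:
            c = self.f_c.get((2, 0), 0.0)
            e2 = self.sat**2
            val = val - c * u**2 + c * u**2 / (1.0 + e2 * u**2)
        cz = np.any(self.C != 0)
        return val - self.C_flat * (u - self.U_flat) ** 3 if cz else val

    def g(self, u, v):
        return self._eval(self.g_c, u, v)

    def partials(self, u, v):
        fu = self._eval(self.fu_c, u, v)
        fv = self._eval(self.fv_c, u, v)
        gu = self._eval(self.gu_c, u, v)
        gv = self._eval(self.gv_c, u, v)
        if self.sat:
            c = self.f_c.get((2, 0), 0.0)
            e2 = self.sat**2
            fu = fu - 2.0 * c * u + 2.0 * c * u / (1.0 + e2 * u**2) ** 2
        if np.any(self.C != 0):
            fu = fu - 3.0 * self.C_flat * (u - self.U_flat) ** 2
        return fu, fv, gu, gv


def rhs(
    u: np.ndarray,
    v: np.ndarray,
    sys: KineticSystem,
    grid,
    D: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Full right-hand side (diffusion + reaction) on grid-shaped fields."""
    L = laplacian_for(grid)
    react = _Reaction(sys, grid.shape)
    uf, vf = u.reshape(-1), v.reshape(-1)
    du = L @ uf + react.f(uf, vf)
    dv = D * (L @ vf) + react.g(uf, vf)
    return du.reshape(grid.shape), dv.reshape(grid.shape)


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------

def _integrate_epoch(
    react: _Reaction,
    L: sp.csr_matrix,
    D: float,
    y0: np.ndarray,
    t0: float,
    t1: float,
    cfg: SimConfig,
    max_step: float | None,
) -> tuple[np.ndarray, float]:
    n = L.shape[0]

    def odes(t, y):
        u, v = y[:n], y[n:]
        du = L @ u + react.f(u, v)
        dv = D * (L @ v) + react.g(u, v)
        return np.concatenate([du, dv])

    DL = (D * L).tocsr()

    def jac(t, y):
        u, v = y[:n], y[n:]
        fu, fv, gu, gv = react.partials(u, v)
        A = L + sp.diags(fu)
        Bm = sp.diags(fv)
        Cm = sp.diags(gu)
        E = DL + sp.diags(gv)
        return sp.bmat([[A, Bm], [Cm, E]], format="csc")

    def blowup(t, y):
        return cfg.blowup_bound - float(np.max(np.abs(y)))

    blowup.terminal = True
    blowup.direction = -1

    sol = solve_ivp(
        odes,
        (t0, t1),
        y0,
        method="BDF",
        jac=jac,
        rtol=cfg.rtol,
        atol=cfg.atol,
        max_step=max_step if max_step else np.inf,
        events=blowup,
        dense_output=False,
    )
    if sol.status == 1:  # terminal event: blow-up bound crossed
        raise BlowUpError(float(sol.t_events[0][0]))
    if not sol.success:
        yl = sol.y[:, -1] if sol.y.size else y0
        if not np.all(np.isfinite(yl)) or np.max(np.abs(yl)) > cfg.blowup_bound:
            raise BlowUpError(float(sol.t[-1] if sol.t.size else t0))
        raise RuntimeError(f"integrator failed at t={sol.t[-1]:g}: {sol.message}")
    y_end = sol.y[:, -1]
    if not np.all(np.isfinite(y_end)):
        raise BlowUpError(float(sol.t[-1]))
    return y_end, float(sol.t[-1])


def run(
    sys: KineticSystem,
    config: SimConfig,
    fields: Mapping[str, ParamField] | None = None,
    schedule: Sequence[tuple[float, KineticSystem]] | None = None,
    u0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
) -> SimResult:
    """Integrate a kinetic system to (near) steady state.

    ``schedule`` optionally lists ``(t_switch, system)`` pairs replacing
    the kinetics from each switch time onward (piecewise-constant time
    heterogeneity); the integrator is restarted at every switch and the
    step size is capped at ``dt_max`` within scheduled epochs.  Spatially
    heterogeneous parameters are carried by the system itself
    (array-valued coefficients built from ParamField values).

    Raises :class:`BlowUpError` when any field exceeds
    ``config.blowup_bound`` or turns non-finite.
    """
    cfg = config
    grid = cfg.grid
    n = int(np.prod(grid.shape))
    L = laplacian_for(grid)

    if cfg.check_kinetics and np.ndim(sys.S_value) == 0:
        rep = verify_kinetics(sys)
        if not rep.passed:
            warnings.warn(
                f"kinetics failed self-verification (f residual {rep.f_residual:.2e}, "
                f"g residual {rep.g_residual:.2e}); continuing anyway"
            )

    if u0 is None or v0 is None:
        u0, v0 = initial_condition(
            sys.steady_state, grid.shape, cfg.ic_range, cfg.seed,
            halfwidth=cfg.ic_range_is_halfwidth,
        )
    y = np.concatenate([np.asarray(u0, float).reshape(-1),
                        np.asarray(v0, float).reshape(-1)])
    positivity_ok = bool(np.all(y >= 0))

    switches = sorted(t for t, _ in (schedule or []) if t > 0)
    sys_at: list[tuple[float, KineticSystem]] = [(0.0, sys)] + sorted(
        schedule or [], key=lambda p: p[0]
    )

    def system_for(t: float) -> KineticSystem:
        cur = sys
        for ts, s in sys_at:
            if t >= ts:
                cur = s
        return cur

    history: list[tuple[float, np.ndarray, np.ndarray]] = []
    snap_iter = sorted(t for t in cfg.snapshot_times if t > 0)

    def record(t: float) -> None:
        history.append((t, y[:n].reshape(grid.shape).copy(),
                        y[n:].reshape(grid.shape).copy()))

    t = 0.0
    converged = False
    oscillatory = False
    deriv_sup = math.inf
    prev_deriv: float | None = None
    prev_amp: float | None = None
    while t < cfg.t_cap and not converged and not oscillatory:
        # next stopping point: schedule switch, snapshot, or check time
        t_check = max(cfg.t_min, t * 2.0) if t > 0 else cfg.t_min
        t_next = min(t_check, cfg.t_cap)
        for ts in switches:
            if t < ts < t_next:
                t_next = ts
                break
        for tsnap in snap_iter:
            if t < tsnap < t_next:
                t_next = tsnap
                break

        cur_sys = system_for(t + 1e-12)
        react = _Reaction(cur_sys, grid.shape)
        in_epoch = bool(schedule)
        y, t = _integrate_epoch(
            react, L, cfg.D, y, t, t_next, cfg,
            max_step=cfg.dt_max if in_epoch else None,
        )
        positivity_ok = positivity_ok and bool(np.all(y >= 0))
        if any(abs(t - tsnap) < 1e-9 for tsnap in snap_iter):
            record(t)

        pending_switch = any(ts > t + 1e-9 for ts in switches)
        if t >= cfg.t_min and not pending_switch and not any(
            abs(t - ts) < 1e-9 for ts in switches
        ):
            u, v = y[:n], y[n:]
            du = L @ u + react.f(u, v)
            dv = cfg.D * (L @ v) + react.g(u, v)
            deriv_sup = float(max(np.max(np.abs(du)), np.max(np.abs(dv))))
            amp_u = float(np.ptp(u))
            if deriv_sup < cfg.deriv_tol:
                converged = True
            elif prev_deriv is not None:
                # On the trace-zero boundary of the design region the uniform
                # mode is a linear centre and the pattern "breathes": the time
                # derivative plateaus at the oscillation amplitude instead of
                # decaying.  When the residual has stopped shrinking while the
                # spatial structure is unchanged, report a (statistically)
                # steady oscillatory pattern rather than integrating to t_cap.
                plateaued = deriv_sup > 0.5 * prev_deriv
                amp_steady = abs(amp_u - prev_amp) <= 0.05 * max(amp_u, 1e-12)
                if plateaued and amp_steady:
                    oscillatory = True
            prev_deriv, prev_amp = deriv_sup, amp_u

    return SimResult(
        u=y[:n].reshape(grid.shape),
        v=y[n:].reshape(grid.shape),
        t_final=t,
        converged=converged,
        oscillatory=oscillatory,
        positivity_ok=positivity_ok,
        deriv_sup=deriv_sup,
        seed=cfg.seed,
        config=cfg,
        history=history,
    )


# ---------------------------------------------------------------------------
# Sweep driver and mesh-refinement check
# ---------------------------------------------------------------------------

def _cell_seed(master: int, idx: int) -> int:
    # splitmix-style hash keeps per-cell streams decorrelated and < 2^31
    x = (master * 2654435761 + idx * 40503 + 12345) % (2**31 - 1)
    return int(x)


def sweep_polar(
    builder: Callable[[float, float], KineticSystem],
    r_values: Sequence[float],
    theta_values: Sequence[float],
    config: SimConfig,
    classify: Callable | None = None,
) -> list[dict]:
    """Run one simulation per (r, θ) with a = r·cosθ, b = r·sinθ.

    ``builder(a, b)`` maps polar parameters to a kinetic system.  Each cell
    gets an independent seed derived from ``config.seed``; per-cell
    blow-ups are recorded and the sweep continues.  Returns a tidy list of
    row dicts (r, theta, a, b, seed, converged/error plus the
    classification fields when a classifier is supplied).
    """
    if classify is None:
        from .patterns import classify as classify_fn
    else:
        classify_fn = classify
    rows: list[dict] = []
    idx = 0
    for r in r_values:
        for th in theta_values:
            a = r * math.cos(th)
            b = r * math.sin(th)
            seed = _cell_seed(config.seed, idx)
            idx += 1
            row: dict = {"r": r, "theta": th, "a": a, "b": b, "seed": seed}
            try:
                sysab = builder(a, b)
                res = run(sysab, replace(config, seed=seed))
                rep = classify_fn(res)
                row.update(
                    converged=res.converged,
                    classification=rep.classification,
                    amplitude=rep.amplitude,
                    n_modes=rep.n_modes,
                    phase=rep.phase,
                    error=None,
                )
            except BlowUpError as exc:
                row.update(
                    converged=False, classification="blowup", amplitude=math.nan,
                    n_modes=None, phase=None, error=str(exc),
                )
            rows.append(row)
    return rows


def _refine_grid(grid):
    if isinstance(grid, Grid1D):
        return Grid1D(2 * grid.nx - 1, grid.Lx)
    return Grid2D(2 * grid.nx - 1, 2 * grid.ny - 1, grid.Lx, grid.Ly)


def refine_check(
    sys: KineticSystem,
    config: SimConfig,
    classify: Callable | None = None,
) -> bool:
    """Re-run at half the mesh size and compare classifications.

    The coarse-grid initial condition is injected onto the fine grid
    (linear interpolation) so both runs see the same random perturbation.
    Returns True iff the pattern classification and 1D mode count agree.
    """
    if classify is None:
        from .patterns import classify as classify_fn
    else:
        classify_fn = classify
    grid_c = config.grid
    u0, v0 = initial_condition(
        sys.steady_state, grid_c.shape, config.ic_range, config.seed,
        halfwidth=config.ic_range_is_halfwidth,
    )
    res_c = run(sys, config, u0=u0, v0=v0)

    grid_f = _refine_grid(grid_c)
    if isinstance(grid_c, Grid1D):
        u0f = np.interp(grid_f.x, grid_c.x, u0)
        v0f = np.interp(grid_f.x, grid_c.x, v0)
    else:
        from scipy.ndimage import zoom

        fy = grid_f.ny / grid_c.ny
        fx = grid_f.nx / grid_c.nx
        u0f = zoom(u0, (fy, fx), order=1, mode="nearest")[: grid_f.ny, : grid_f.nx]
        v0f = zoom(v0, (fy, fx), order=1, mode="nearest")[: grid_f.ny, : grid_f.nx]
    sys_f = sys
    if np.ndim(sys.S_value) != 0 or any(
        np.ndim(c) for c in list(sys.f_coeffs.values()) + list(sys.g_coeffs.values())
    ):
        raise ValueError("refine_check supports homogeneous parameters only")
    res_f = run(sys_f, replace(config, grid=grid_f), u0=u0f, v0=v0f)

    rep_c = classify_fn(res_c)
    rep_f = classify_fn(res_f)
    same = rep_c.classification == rep_f.classification
    if rep_c.n_modes is not None and rep_f.n_modes is not None:
        same = same and rep_c.n_modes == rep_f.n_modes
    return bool(same)
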