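"""Linear Turing analysis for two-species reaction-diffusion systems.

A homogeneous steady state of

    u_t = Du ∇²u + f(u, v),    v_t = Dv ∇²v + g(u, v)

is *diffusion-driven unstable* (Turing unstable) when it is linearly stable
to spatially uniform perturbations but a band of finite wavenumbers grows
once the two species diffuse at different rates.  This module evaluates the
classical inequalities on the Jacobian J = [[fu, fv], [gu, gv]] and the
diffusivities, reduces an admissible system to the two dimensionless groups

    F = |gu| fv / fu²,    G = |gv| / fu,    D = Dv / Du,

and computes the derived design quantities: the critical diffusion ratio
Dc = (sqrt(F−G) + sqrt(F))², the unstable wavenumber band (k²₋, k²₊), the
minimum 1D domain length Lc = π/k₊ at which the first cosine mode fits into
the band, and suprema of these quantities over a user-defined parameter
region {S(p) ≥ 0}.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "MARGINAL_TOL",
    "DimensionalRD",
    "NondimRD",
    "TuringReport",
    "DispersionResult",
    "classify_sign_structure",
    "check_turing_dimensional",
    "nondimensionalize",
    "critical_diffusion",
    "wavenumber_band",
    "min_domain_length",
    "dispersion",
    "sup_over_region",
]

#: Relative tolerance under which an inequality is treated as an equality
#: and flagged as marginal (never silently rounded).
MARGINAL_TOL = 1e-9


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DimensionalRD:
    """A dimensional two-species reaction-diffusion linearization.

    Parameters
    ----------
    Du, Dv : float
        Positive diffusivities of u and v (same units).
    fu, fv, gu, gv : float
        Jacobian entries of the kinetics at the homogeneous steady state
        (units 1/time).
    L : float, optional
        Domain length; enables admissible-mode counting.
    """

    Du: float
    Dv: float
    fu: float
    fv: float
    gu: float
    gv: float
    L: float | None = None

    def __post_init__(self) -> None:
        for name in ("Du", "Dv", "fu", "fv", "gu", "gv"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.Du <= 0 or self.Dv <= 0:
            raise ValueError("diffusivities must be positive")

    @property
    def jacobian(self) -> np.ndarray:
        return np.array([[self.fu, self.fv], [self.gu, self.gv]], dtype=float)


@dataclass(frozen=True)
class NondimRD:
    """Nondimensional reduction of an admissible linearization.

    ``F`` couples the activator's effect on the inhibitor back to the
    activator, ``G`` is the inhibitor's self-decay relative to activator
    self-activation, and ``D`` is the diffusivity ratio Dv/Du.  Time is
    measured in units of 1/fu and length in units of sqrt(Du/fu).
    """

    F: float
    G: float
    D: float
    sign_type: str = "cross"
    time_scale: float = 1.0
    length_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.F > 0 and self.G > 0):
            raise ValueError("F and G are defined from magnitudes and must be > 0")
        if self.sign_type not in ("pure", "cross"):
            raise ValueError(f"sign_type must be 'pure' or 'cross', got {self.sign_type!r}")

    @property
    def F_prime(self) -> float:
        return self.F - 1.0

    @property
    def G_prime(self) -> float:
        return self.G - 1.0


@dataclass
class TuringReport:
    """Outcome of the full set of Turing inequalities."""

    stable_without_diffusion: bool
    diffusion_driven: bool
    band: tuple[float, float] | None
    Dc: float | None
    Lc: float | None
    admissible_modes: list[int] = field(default_factory=list)
    marginal: bool = False
    inequalities: dict[str, bool] = field(default_factory=dict)

    @property
    def turing_unstable(self) -> bool:
        return self.stable_without_diffusion and self.diffusion_driven

    def to_json(self) -> str:
        return json.dumps(
            {
                "inequalities": self.inequalities,
                "stable_without_diffusion": self.stable_without_diffusion,
                "diffusion_driven": self.diffusion_driven,
                "Dc": self.Dc,
                "Lc": self.Lc,
                "band": list(self.band) if self.band is not None else None,
                "marginal": self.marginal,
                "admissible_modes": self.admissible_modes,
            }
        )


@dataclass
class DispersionResult:
    """Dominant linear growth rate Re λ(k²) over a grid of squared wavenumbers."""

    k_squared_grid: np.ndarray
    growth_rate: np.ndarray

    @property
    def k_max(self) -> float:
        """Squared wavenumber with the largest growth rate."""
        return float(self.k_squared_grid[int(np.argmax(self.growth_rate))])


# ---------------------------------------------------------------------------
# Sign structure and the dimensional inequalities
# ---------------------------------------------------------------------------

def classify_sign_structure(J, tol: float = MARGINAL_TOL) -> str:
    """Classify a 2x2 kinetic Jacobian as ``pure``, ``cross`` or ``none``.

    Pure kinetics have sign pattern (+,−; +,−) and give in-phase patterns;
    cross kinetics have (+,+; −,−) and give out-of-phase patterns.  The
    convention fu > 0 is enforced; entries within ``tol`` of zero are
    treated as zero and classified ``none``.
    """
    J = np.asarray(J, dtype=float)
    if J.shape != (2, 2):
        raise ValueError("expected a 2x2 Jacobian")
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian entries must be finite")
    fu, fv, gu, gv = J.ravel()
    if any(abs(x) < tol for x in (fu, fv, gu, gv)):
        return "none"
    if fu > 0 and fv < 0 and gu > 0 and gv < 0:
        return "pure"
    if fu > 0 and fv > 0 and gu < 0 and gv < 0:
        return "cross"
    return "none"


def _near_equal(a: float, b: float, tol: float = MARGINAL_TOL) -> bool:
    scale = max(1.0, abs(a), abs(b))
    return abs(a - b) <= tol * scale


def _dimensional_band(sys: DimensionalRD) -> tuple[float, float] | None:
    """Roots in k² of Du·Dv·k⁴ − (Dv·fu + Du·gv)·k² + det J = 0."""
    a = sys.Du * sys.Dv
    b = sys.Dv * sys.fu + sys.Du * sys.gv
    det = sys.fu * sys.gv - sys.fv * sys.gu
    disc = b * b - 4.0 * a * det
    if disc < 0:
        return None
    root = math.sqrt(disc)
    k2m = (b - root) / (2.0 * a)
    k2p = (b + root) / (2.0 * a)
    if k2p <= 0:
        return None
    return (k2m, k2p)


def check_turing_dimensional(sys: DimensionalRD, L: float | None = None) -> TuringReport:
    """Evaluate the Turing inequalities for a dimensional linearization.

    Checks, in order: trace < 0, det > 0 (stability without diffusion);
    Dv·fu + Du·gv > 2·sqrt(Du·Dv·det) > 0 (diffusion can destabilise);
    and reports the unstable band of squared wavenumbers.  When ``L`` is
    supplied, the cosine modes n with k₋ < nπ/L < k₊ are listed.
    """
    if L is None:
        L = sys.L
    tr = sys.fu + sys.gv
    det = sys.fu * sys.gv - sys.fv * sys.gu
    h = sys.Dv * sys.fu + sys.Du * sys.gv
    rhs = 2.0 * math.sqrt(sys.Du * sys.Dv * det) if det > 0 else math.nan

    ineq = {
        "trace_negative": tr < 0,
        "det_positive": det > 0,
        "diffusive_destabilization": det > 0 and h > rhs,
    }
    marginal = (
        _near_equal(tr, 0.0)
        or _near_equal(det, 0.0)
        or (det > 0 and _near_equal(h, rhs))
    )

    stable = ineq["trace_negative"] and ineq["det_positive"]
    band = _dimensional_band(sys) if (stable and ineq["diffusive_destabilization"]) else None
    driven = stable and band is not None and band[1] > band[0]

    Dc = Lc = None
    if sys.fu > 0 and classify_sign_structure(sys.jacobian) != "none":
        nd = nondimensionalize(sys)
        if nd.F > nd.G:
            Dc_nd = critical_diffusion(nd.F, nd.G)
            Dc = Dc_nd  # the ratio Dv/Du is already dimensionless
        if band is not None:
            Lc = math.pi / math.sqrt(band[1])

    modes: list[int] = []
    if L is not None and band is not None:
        k2m, k2p = band
        n = 1
        while (n * math.pi / L) ** 2 < k2p:
            if (n * math.pi / L) ** 2 > max(k2m, 0.0):
                modes.append(n)
            n += 1

    return TuringReport(
        stable_without_diffusion=stable,
        diffusion_driven=driven,
        band=band,
        Dc=Dc,
        Lc=Lc,
        admissible_modes=modes,
        marginal=marginal,
        inequalities=ineq,
    )


# ---------------------------------------------------------------------------
# Nondimensional reduction and design quantities
# ---------------------------------------------------------------------------

def nondimensionalize(sys: DimensionalRD) -> NondimRD:
    """Reduce a dimensional linearization to the groups (F, G, D).

    Rescales time by 1/fu and length by sqrt(Du/fu); requires fu > 0 and an
    admissible (pure or cross) sign structure so that the magnitudes
    F = |gu|·|fv|/fu² and G = |gv|/fu capture the whole linear problem.
    """
    if sys.fu <= 0:
        raise ValueError("the reduction takes fu > 0 by convention")
    sign = classify_sign_structure(sys.jacobian)
    if sign == "none":
        raise ValueError("Jacobian sign structure is neither pure nor cross")
    F = abs(sys.gu) * abs(sys.fv) / sys.fu**2
    G = abs(sys.gv) / sys.fu
    return NondimRD(
        F=F,
        G=G,
        D=sys.Dv / sys.Du,
        sign_type=sign,
        time_scale=1.0 / sys.fu,
        length_scale=math.sqrt(sys.Du / sys.fu),
    )


def critical_diffusion(F: float, G: float) -> float:
    """Critical diffusion ratio Dc = (sqrt(F−G) + sqrt(F))².

    The wavenumber band first opens at D = Dc; defined only for F > G
    (positive determinant of the nondimensional Jacobian).
    """
    if not F > G:
        raise ValueError("Dc requires F > G (determinant F−G must be positive)")
    return (math.sqrt(F - G) + math.sqrt(F)) ** 2


def wavenumber_band(F: float, G: float, D: float) -> tuple[float, float] | None:
    """Unstable band (k²₋, k²₊): roots of D·k⁴ − (D−G)·k² + (F−G) = 0.

    Returns ``None`` when the discriminant is negative or no positive root
    exists (no unstable finite wavenumber).  A degenerate band with
    k²₋ = k²₊ is returned at D = Dc.
    """
    disc = (D - G) ** 2 - 4.0 * D * (F - G)
    if disc < 0:
        # roundoff guard: exactly-critical D should give a degenerate band
        if disc > -MARGINAL_TOL * max(1.0, (D - G) ** 2):
            disc = 0.0
        else:
            return None
    root = math.sqrt(disc)
    k2m = (D - G - root) / (2.0 * D)
    k2p = (D - G + root) / (2.0 * D)
    if k2p <= 0:
        return None
    return (k2m, k2p)


def min_domain_length(F: float, G: float, D: float) -> float:
    """Smallest 1D domain on which the n=1 cosine mode is unstable.

    The mode k = π/L enters the band when π/L > k₋ first becomes possible,
    i.e. Lc = π / k₊ — for any L > Lc the wavenumber π/L lies inside
    (k₋, k₊) until it exits at π/k₋.
    """
    band = wavenumber_band(F, G, D)
    if band is None or band[1] <= 0:
        raise ValueError("no unstable wavenumber band: Lc is undefined")
    return math.pi / math.sqrt(band[1])


def dispersion(
    F: float,
    G: float,
    D: float,
    k_squared: Iterable[float],
    sign_type: str = "cross",
) -> DispersionResult:
    """Dominant Re λ of the nondimensional linearization per squared wavenumber.

    The mode matrix is [[1−k², σ], [−σF, −G−Dk²]] with σ = +1 (cross) or
    σ = −1 (pure); both choices share trace and determinant, hence the same
    spectrum.
    """
    if sign_type not in ("pure", "cross"):
        raise ValueError("sign_type must be 'pure' or 'cross'")
    k2 = np.asarray(list(k_squared) if not isinstance(k_squared, np.ndarray) else k_squared,
                    dtype=float)
    if np.any(k2 < 0):
        raise ValueError("squared wavenumbers must be nonnegative")
    tr = (1.0 - k2) + (-G - D * k2)
    det = (1.0 - k2) * (-G - D * k2) + F
    disc = tr * tr - 4.0 * det
    growth = np.where(
        disc >= 0,
        (tr + np.sqrt(np.maximum(disc, 0.0))) / 2.0,
        tr / 2.0,
    )
    return DispersionResult(k_squared_grid=k2, growth_rate=growth)


# ---------------------------------------------------------------------------
# Suprema over level-set regions
# ---------------------------------------------------------------------------

def _region_FG(region) -> tuple[Callable, Callable]:
    """F(p), G(p) callables for a region: explicit if provided, else the
    canonical level-set family F = S+2, G = 2."""
    F = getattr(region, "F", None)
    G = getattr(region, "G", None)
    if F is not None and G is not None:
        return F, G
    return (lambda *p: region.S(*p) + 2.0), (lambda *p: np.full_like(np.asarray(p[0], float), 2.0) + 0.0)


def _quantity_func(region, quantity: str, D: float | None):
    S = region.S
    Ffun, Gfun = _region_FG(region)

    if quantity == "S":
        return S
    if quantity == "F":
        return Ffun
    if quantity == "Dc":
        def dc(*p):
            F = np.asarray(Ffun(*p), dtype=float)
            G = np.asarray(Gfun(*p), dtype=float)
            det = F - G
            with np.errstate(invalid="ignore"):
                out = (np.sqrt(np.maximum(det, 0.0)) + np.sqrt(np.maximum(F, 0.0))) ** 2
            return np.where(det >= 0, out, -np.inf)
        return dc
    if quantity == "Lc":
        if D is None:
            raise ValueError("quantity 'Lc' needs a diffusion ratio D")
        def lc(*p):
            F = np.asarray(Ffun(*p), dtype=float)
            G = np.asarray(Gfun(*p), dtype=float)
            disc = (D - G) ** 2 - 4.0 * D * (F - G)
            with np.errstate(invalid="ignore"):
                k2p = (D - G + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * D)
                out = math.pi / np.sqrt(np.where(k2p > 0, k2p, np.nan))
            return np.where((disc >= 0) & (k2p > 0), out, -np.inf)
        return lc
    raise ValueError(f"unknown quantity {quantity!r}; expected one of Dc, Lc, F, S")


def sup_over_region(
    region,
    quantity: str,
    D: float | None = None,
    resolution: int | None = None,
    refine_iters: int = 6,
) -> tuple[float, tuple[float, ...]]:
    """Supremum of a design quantity over the closed region {S(p) ≥ 0} ∩ box.

    The region is scanned on a dense grid over its bounding box (default
    401 points per axis) and the best point is refined by repeatedly
    zooming a local grid, keeping the S ≥ 0 constraint.  Deterministic for
    a fixed resolution.  Returns ``(value, argmax_point)``.

    ``quantity`` is one of ``"Dc"``, ``"Lc"`` (needs ``D``), ``"F"``,
    ``"S"``.
    """
    box = [tuple(map(float, b)) for b in region.box]
    ndim = len(box)
    res = resolution or getattr(region, "grid_resolution", None) or 401
    func = _quantity_func(region, quantity, D)

    axes = [np.linspace(lo, hi, res) for lo, hi in box]
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = [m.ravel() for m in mesh]
    Sv = np.asarray(region.S(*flat), dtype=float)
    inside = Sv >= -MARGINAL_TOL
    if not np.any(inside):
        raise ValueError("region is empty within its bounding box")
    vals = np.where(inside, np.asarray(func(*flat), dtype=float), -np.inf)
    best = int(np.argmax(vals))
    best_val = float(vals[best])
    best_pt = np.array([f[best] for f in flat])

    # local zooming refinement around the incumbent grid maximum
    widths = np.array([(hi - lo) / (res - 1) for lo, hi in box])
    for _ in range(refine_iters):
        local_axes = []
        for d in range(ndim):
            lo = max(box[d][0], best_pt[d] - widths[d])
            hi = min(box[d][1], best_pt[d] + widths[d])
            local_axes.append(np.linspace(lo, hi, 21))
        lm = np.meshgrid(*local_axes, indexing="ij")
        lf = [m.ravel() for m in lm]
        lS = np.asarray(region.S(*lf), dtype=float)
        lin = lS >= -MARGINAL_TOL
        if not np.any(lin):
            break
        lv = np.where(lin, np.asarray(func(*lf), dtype=float), -np.inf)
        j = int(np.argmax(lv))
        if lv[j] > best_val:
            best_val = float(lv[j])
            best_pt = np.array([f[j] for f in lf])
        widths = widths / 10.0

    return best_val, tuple(float(x) for x in best_pt)
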