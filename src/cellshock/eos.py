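"""Area-pressure state equations for a single cell under shock loading.

A cell observed top-down responds to a fast hydraulic pressure ramp by
changing its projected area A.  Treating the loading as a sequence of
equilibrium states, the relation A(p) plays the role of an equation of
state.  Three families are implemented:

``exponential``
    Constant-gradient area modulus B(p̂) = B0 + B'·p̂ (the 2D analogue of
    a pressure-dependent compressibility) integrates to
    A = A0 · exp(B0·p̂ + ½B'·p̂²), with p̂ = (p − p0)/p_ref the
    nondimensional overpressure.  For B' < 0 the curve has an interior
    inflection — the point of maximum area-growth rate.

``tait``
    Power-law (Tait-like) form p = α₃·p0·(A/A0)^κ + p0 with composite
    exponent κ.  Forward and inverse are algebraic; the fixed exponent
    admits no interior inflection.

``li``
    Continuously varying area properties lead to
    (p − p0)/p0 = exp(α₁·li(A/A0)), where li is the logarithmic
    integral, regularised at its A/A0 = 1 divergence by a fixed offset
    ε.  The forward map is closed-form in li; the area inverse is
    obtained by bracketed root finding.

All pressures are kPa, areas µm²; ζ = A/A0 is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import expi

__all__ = [
    "StateEquationParams",
    "InflectionPoint",
    "TwoCompartmentParams",
    "IsobaricTrajectory",
    "DomainError",
    "area_exponential",
    "area_modulus",
    "li_regularized",
    "pressure_li_model",
    "area_li_model",
    "tait_pressure",
    "tait_area",
    "area_model",
    "zeta_model",
    "find_inflection",
    "two_compartment_area",
    "isobaric_trajectory",
    "loading_rate_continuation",
    "check_surface_signs",
]

FAMILIES = ("exponential", "tait", "li")


class DomainError(ValueError):
    """Pressure/area outside the admissible domain of a state equation."""


@dataclass(frozen=True)
class StateEquationParams:
    """Parameter set for one state-equation family.

    Only the fields of the selected ``family`` are used:
    exponential -> (B0, Bprime); tait -> (kappa, alpha3);
    li -> (alpha1, eps, s_ref).  ``p_ref`` (default: p0) sets the
    nondimensionalisation p̂ = (p − p0)/p_ref.
    """

    family: str
    A0: float = 450.0          # µm², initial projected area
    p0: float = 101.325        # kPa, baseline (ambient) pressure
    p_ref: float | None = None  # kPa; None -> p0
    B0: float = 1.0            # initial area modulus (dimensionless)
    Bprime: float = 0.0        # dB/dp̂, constant by assumption
    alpha1: float = 1.0        # li-family correction factor
    s_ref: float = 1.0         # µm²/kPa, reference slope (li-family diagnostics)
    kappa: float = 1.5         # composite Tait exponent α₂(1+γ)
    alpha3: float = 0.8        # Tait prefactor
    eps: float = 1e-6          # li regularisation offset

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.A0 <= 0 or self.p0 <= 0:
            raise ValueError("A0 and p0 must be positive")
        if self.p_ref is not None and self.p_ref <= 0:
            raise ValueError("p_ref must be positive")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.family == "tait" and self.kappa == 0:
            raise ValueError("tait family requires kappa != 0")

    @property
    def pref(self) -> float:
        return self.p0 if self.p_ref is None else self.p_ref

    def phat(self, p):
        """Nondimensional overpressure p̂ = (p − p0)/p_ref."""
        return (np.asarray(p, dtype=float) - self.p0) / self.pref

    def with_(self, **kw) -> "StateEquationParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class InflectionPoint:
    """Location of the maximum area-growth rate, if the family has one."""

    exists: bool
    p_k: float = float("nan")     # kPa
    A_k: float = float("nan")     # µm²
    zeta_k: float = float("nan")  # A_k/A0


# ---------------------------------------------------------------------------
# exponential family

def _exp_g(phat, params: StateEquationParams):
    return params.B0 * phat + 0.5 * params.Bprime * phat**2


def area_exponential(p, params: StateEquationParams):
    """A(p) = A0·exp(B0·p̂ + ½B'·p̂²); exact A0 at p = p0.

    Domain: B0 + B'·p̂ > 0 (dA/dp > 0 throughout).
    """
    ph = params.phat(p)
    if np.any(params.B0 + params.Bprime * ph < 0):
        raise DomainError("exponential family: B0 + B'*phat must stay non-negative")
    return params.A0 * np.exp(_exp_g(ph, params))


def area_exponential_d1(p, params: StateEquationParams):
    """dA/dp (kPa⁻¹ scale restored through p_ref)."""
    ph = params.phat(p)
    b = params.B0 + params.Bprime * ph
    return params.A0 * b * np.exp(_exp_g(ph, params)) / params.pref


def area_exponential_d2(p, params: StateEquationParams):
    """d²A/dp².  Includes the additive B' term from differentiating the
    pressure-dependent modulus; vanishes where (B0 + B'p̂)² = −B'."""
    ph = params.phat(p)
    b = params.B0 + params.Bprime * ph
    return params.A0 * (params.Bprime + b * b) * np.exp(_exp_g(ph, params)) / params.pref**2


def area_modulus(p, params: StateEquationParams):
    """Linear area modulus B(p̂) = B0 + B'·p̂.

    Returns (B, admissible) where ``admissible`` flags B > 0, the
    physical requirement for a growing area.
    """
    B = params.B0 + params.Bprime * params.phat(p)
    return B, np.asarray(B) > 0


# ---------------------------------------------------------------------------
# logarithmic-integral family

def li_regularized(x, eps: float = 1e-6):
    """Regularised logarithmic integral ∫_{1+eps}^{x} du/ln u.

    Evaluated as Ei(ln x) − Ei(ln(1+eps)); the integrand diverges at
    u = 1, hence the fixed offset eps > 0.  Requires x ≥ 1 + eps.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < 1.0 + eps - 1e-15 * (1 + eps)):
        raise DomainError("li_regularized requires x >= 1 + eps")
    return expi(np.log(x)) - expi(np.log(1.0 + eps))


def li_regularized_quad(x: float, eps: float = 1e-6) -> float:
    """Adaptive-quadrature evaluation of the same integral (slow path,
    kept as an independent route for cross-checking)."""
    if x < 1.0 + eps:
        raise DomainError("li_regularized requires x >= 1 + eps")
    val, _ = quad(lambda u: 1.0 / np.log(u), 1.0 + eps, x, limit=200)
    return val


def pressure_li_model(A, params: StateEquationParams):
    """p(A) = p0·(1 + exp(α₁·li(A/A0))); domain A ≥ A0·(1+eps).

    Note the anchoring: A → A0(1+eps)⁺ gives p → 2·p0.
    """
    z = np.asarray(A, dtype=float) / params.A0
    return params.p0 * (1.0 + np.exp(params.alpha1 * li_regularized(z, params.eps)))


def area_li_model(p, params: StateEquationParams):
    """Inverse of :func:`pressure_li_model` by bracketed root finding.

    Requires α₁ > 0 and p ≥ p(A0(1+eps)) = 2·p0 (up to rounding).
    """
    if params.alpha1 <= 0:
        raise DomainError("area inverse of the li model needs alpha1 > 0")

    def solve_one(pi: float) -> float:
        if pi <= params.p0:
            raise DomainError("li model inverse requires p > p0")
        target = np.log((pi - params.p0) / params.p0) / params.alpha1
        lo = 1.0 + params.eps
        if target <= 0.0:
            if target < -1e-9:
                raise DomainError("pressure below the li model's 2*p0 anchor")
            return lo
        hi = 2.0
        while li_regularized(hi, params.eps) < target:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover - unreachable for sane targets
                raise DomainError("li model inverse failed to bracket")
        z = brentq(lambda u: li_regularized(u, params.eps) - target, lo, hi,
                   xtol=1e-14, rtol=1e-14)
        return z

    p_arr = np.asarray(p, dtype=float)
    z = np.vectorize(solve_one)(p_arr)
    return params.A0 * z


# ---------------------------------------------------------------------------
# Tait family

def tait_pressure(A, params: StateEquationParams):
    """p(A) = α₃·p0·(A/A0)^κ + p0 (Tait-like power law)."""
    z = np.asarray(A, dtype=float) / params.A0
    if np.any(z <= 0):
        raise DomainError("tait_pressure requires A > 0")
    return params.alpha3 * params.p0 * z**params.kappa + params.p0


def tait_area(p, params: StateEquationParams):
    """Exact inverse A(p) = A0·((p − p0)/(α₃·p0))^(1/κ); needs p > p0, α₃ > 0."""
    if params.alpha3 <= 0:
        raise DomainError("tait_area requires alpha3 > 0")
    x = (np.asarray(p, dtype=float) - params.p0) / (params.alpha3 * params.p0)
    if np.any(x <= 0):
        raise DomainError("tait_area requires p > p0")
    return params.A0 * x ** (1.0 / params.kappa)


# ---------------------------------------------------------------------------
# family dispatch

def area_model(p, params: StateEquationParams):
    """Forward area A(p) for any family."""
    if params.family == "exponential":
        return area_exponential(p, params)
    if params.family == "tait":
        return tait_area(p, params)
    return area_li_model(p, params)


def zeta_model(p, params: StateEquationParams):
    """Final-to-initial area ratio ζ(p) = A(p)/A0."""
    return area_model(p, params) / params.A0


def _central_second(f: Callable[[float], float], p: float, h: float) -> float:
    return (f(p + h) - 2.0 * f(p) + f(p - h)) / (h * h)


def find_inflection(
    family: str,
    params: StateEquationParams,
    p_range: tuple[float, float],
    n_grid: int = 400,
    rel_step: float = 1e-4,
) -> InflectionPoint:
    """Locate the sign change of d²A/dp² inside ``p_range``.

    Uses the analytic curvature where available (exponential family),
    always confirmed by a bracketed sign-change search on a
    central-difference estimate; ties broken by the smallest pressure.
    Absence of an inflection (curvature of constant sign, e.g. the
    fixed-exponent Tait family) is a valid result with exists=False.
    """
    params = params.with_(family=family)
    lo, hi = float(p_range[0]), float(p_range[1])
    if not hi > lo:
        raise ValueError("empty pressure range")

    if family == "tait":
        # A ∝ (p − p0)^(1/κ): curvature sign is fixed by κ alone.
        return InflectionPoint(exists=False)

    if family == "exponential":
        d2 = lambda p: float(area_exponential_d2(p, params))
    else:
        h = rel_step * max(abs(hi), params.p0)
        f = lambda p: float(area_model(p, params))
        d2 = lambda p: _central_second(f, p, h)

    margin = 1e-9 * (hi - lo)
    grid = np.linspace(lo + margin, hi - margin, n_grid)
    try:
        vals = np.array([d2(p) for p in grid])
    except DomainError:
        raise DomainError("p_range extends outside the family's domain")

    sign = np.sign(vals)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if flips.size == 0:
        return InflectionPoint(exists=False)
    i = flips[0]  # smallest-p crossing
    p_k = brentq(d2, grid[i], grid[i + 1], xtol=1e-12 * max(1.0, hi))

    if family == "exponential" and params.Bprime < 0:
        # analytic root of (B0 + B'p̂)² = −B' (branch inside the domain)
        ph_k = (np.sqrt(-params.Bprime) - params.B0) / params.Bprime
        p_ana = params.p0 + params.pref * ph_k
        if lo < p_ana < hi:
            p_k = float(p_ana)

    A_k = float(area_model(p_k, params))
    return InflectionPoint(exists=True, p_k=float(p_k), A_k=A_k, zeta_k=A_k / params.A0)


# ---------------------------------------------------------------------------
# two-compartment (cytoplasm + porous core) model

@dataclass(frozen=True)
class TwoCompartmentParams:
    """Cell area split into fluid-like cytoplasm and a stiffer porous core.

    The core response A_core(p) must be concave (pore collapse slows its
    expansion); the cytoplasm contributes a constant slope.  ``C`` is the
    dimensionless core-coupling constant.
    """

    A_core0: float                      # µm²
    A_cyto0: float                      # µm²
    C: float = 1.0
    cyto_slope: float = 0.05            # µm²/kPa, dA_cyto/dp
    core_a: float = field(default=0.0)  # quadratic core: A_core(p) = A_core0 + core_b·(p−p0) − core_c·(p−p0)²
    core_b: float = 0.10                # µm²/kPa
    core_c: float = 1e-5                # µm²/kPa², must be > 0 (concavity)
    p0: float = 101.325                 # kPa

    def __post_init__(self):
        if self.A_core0 <= 0 or self.A_cyto0 <= 0:
            raise ValueError("compartment areas must be positive")

    @property
    def A_cell0(self) -> float:
        return self.A_core0 + self.A_cyto0

    def core(self, p):
        dp = np.asarray(p, dtype=float) - self.p0
        return self.A_core0 + self.core_b * dp - self.core_c * dp**2

    def core_d1(self, p):
        dp = np.asarray(p, dtype=float) - self.p0
        return self.core_b - 2.0 * self.core_c * dp

    def core_d2(self, p):
        return -2.0 * self.core_c * np.ones_like(np.asarray(p, dtype=float))


def two_compartment_area(p_grid, params: TwoCompartmentParams) -> dict:
    """Integrate the two-compartment area balance along a pressure grid.

    dA_cell/dp = ((A_cell − A_core)/A_cell)·dA_cyto/dp
               + C·(A_core/A_cell)·(dA_core/dp + p·d²A_core/dp²)

    The two right-hand terms are accumulated as the cytoplasm and core
    contributions with the same fixed-step 4th-order (RK4) scheme, so the
    balance ΔA_cell = ΔA_cyto + ΔA_core holds to integrator roundoff and
    is verified on return.
    """
    p = np.asarray(p_grid, dtype=float)
    if p.ndim != 1 or p.size < 2 or np.any(np.diff(p) <= 0):
        raise ValueError("p_grid must be a 1D increasing array")
    if np.any(params.core_d2(p) >= 0):
        raise ValueError("core concavity d2A_core/dp2 < 0 violated on the grid")

    def rhs(pi: float, y: np.ndarray) -> np.ndarray:
        a_cell = y[0]
        a_core = float(params.core(pi))
        t_cyto = (a_cell - a_core) / a_cell * params.cyto_slope
        t_core = params.C * (a_core / a_cell) * (
            float(params.core_d1(pi)) + pi * float(params.core_d2(pi))
        )
        return np.array([t_cyto + t_core, t_cyto, t_core])

    y = np.zeros((p.size, 3))
    y[0, 0] = params.A_cell0
    for i in range(p.size - 1):
        h = p[i + 1] - p[i]
        yi = y[i]
        k1 = rhs(p[i], yi)
        k2 = rhs(p[i] + h / 2, yi + h / 2 * k1)
        k3 = rhs(p[i] + h / 2, yi + h / 2 * k2)
        k4 = rhs(p[i + 1], yi + h * k3)
        y[i + 1] = yi + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

    d_cell = y[:, 0] - params.A_cell0
    residual = np.max(np.abs(d_cell - (y[:, 1] + y[:, 2])))
    scale = max(1.0, np.max(np.abs(d_cell)))
    if residual > 1e-9 * scale:  # pragma: no cover - construction guarantees this
        raise AssertionError("two-compartment conservation identity violated")
    return {
        "p": p,
        "A_cell": y[:, 0],
        "dA_cell": d_cell,
        "dA_cyto": y[:, 1],
        "dA_core": y[:, 2],
        "conservation_residual": float(residual),
    }


# ---------------------------------------------------------------------------
# discrete isobaric trajectory / loading-rate continuation

@dataclass(frozen=True)
class IsobaricTrajectory:
    """Discrete loading path: equilibrium states at stepped pressures."""

    pressures: np.ndarray   # kPa, non-decreasing
    areas: np.ndarray       # µm²
    step_ratios: np.ndarray  # ζ_i = A_{i+1}/A_i


def isobaric_trajectory(
    family: str,
    params: StateEquationParams,
    p_start: float,
    p_end: float,
    n_steps: int,
) -> IsobaricTrajectory:
    """Equal-pressure-increment trajectory through the family's A(p).

    With a constant loading rate ṗ, equal time steps are equal pressure
    increments; each step ratio ζ_i = A_{i+1}/A_i telescopes to
    A(p_end)/A(p_start).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if not p_end > p_start:
        raise ValueError("p_end must exceed p_start")
    params = params.with_(family=family)
    p = np.linspace(p_start, p_end, n_steps + 1)
    A = np.asarray(area_model(p, params), dtype=float)
    return IsobaricTrajectory(pressures=p, areas=A, step_ratios=A[1:] / A[:-1])


def loading_rate_continuation(
    family: str,
    params: StateEquationParams,
    p_start: float,
    p_end: float,
    steps_list: Sequence[int],
):
    """Trace the maximum-deformation-rate step across loading rates.

    All step counts share the same end state (p_end, A(p_end)); coarser
    steps stand in for faster loading.  For each count the step with the
    largest area increment ΔA_i = A_{i+1} − A_i — the discrete dA/dp,
    whose maximum marks the inflection in the continuous limit — is
    reported by its right-endpoint (pressure, area) and step ratio ζ_i.
    Returns a DataFrame ordered by pressure-step size (ascending, i.e.
    slow loading first).
    """
    import pandas as pd

    rows = []
    for n in steps_list:
        traj = isobaric_trajectory(family, params, p_start, p_end, int(n))
        i = int(np.argmax(np.diff(traj.areas)))
        rows.append(
            {
                "n_steps": int(n),
                "dp": (p_end - p_start) / int(n),
                "max_step_index": i,
                "p_at_max": float(traj.pressures[i + 1]),
                "A_at_max": float(traj.areas[i + 1]),
                "zeta_max_step": float(traj.step_ratios[i]),
            }
        )
    out = pd.DataFrame(rows).sort_values("dp", ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# sign-constraint audit of a ζ(A0, p) surface

def check_surface_signs(zeta, A0_axis, p_axis, A_k: float | None = None) -> dict:
    """Audit the qualitative shape of a ζ(A_initial, p) surface.

    Central-difference estimates on interior cells of four expected
    signs: ∂ζ/∂A < 0, ∂²ζ/∂A² > 0, ∂ζ/∂p > 0 (restricted to columns
    with A_initial < A_k when ``A_k`` is given), and the cross product
    (∂ζ/∂p)·(∂ζ/∂A) < 0.  Returns the fraction of interior cells
    satisfying each.
    """
    z = np.asarray(zeta, dtype=float)
    a = np.asarray(A0_axis, dtype=float)
    p = np.asarray(p_axis, dtype=float)
    if z.shape != (a.size, p.size):
        raise ValueError("zeta must have shape (len(A0_axis), len(p_axis))")
    if a.size < 3 or p.size < 3:
        raise ValueError("grid must be at least 3x3")
    if not np.all(np.isfinite(z)):
        raise ValueError("zeta surface contains non-finite values")

    dz_da = np.gradient(z, a, axis=0)
    d2z_da2 = np.gradient(dz_da, a, axis=0)
    dz_dp = np.gradient(z, p, axis=1)

    interior = (slice(1, -1), slice(1, -1))
    da, d2a, dp = dz_da[interior], d2z_da2[interior], dz_dp[interior]

    if A_k is None:
        p_mask = np.ones_like(dp, dtype=bool)
    else:
        p_mask = np.broadcast_to((a[1:-1] < A_k)[:, None], dp.shape)

    n = da.size
    frac_p = float(np.mean(dp[p_mask] > 0)) if p_mask.any() else float("nan")
    return {
        "frac_dzeta_dA_neg": float(np.mean(da < 0)),
        "frac_d2zeta_dA2_pos": float(np.mean(d2a > 0)),
        "frac_dzeta_dp_pos": frac_p,
        "frac_cross_product_neg": float(np.mean(dp * da < 0)),
        "n_interior": int(n),
    }
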