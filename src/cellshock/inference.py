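"""Statistical analysis of deformation records.

Distribution checks on the initial-shape descriptors, grouping of
experiments by peak pressure, per-group linear trends of ζ against the
initial area, nonlinear state-equation fits, and a Monte-Carlo
parameter-recovery harness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import eos, synthdata

__all__ = [
    "PressureGroup", "FitResult", "DistributionReport",
    "test_distributions", "group_by_pressure", "fit_group_lines",
    "fit_state_equation", "count_shrinking", "recovery_harness",
]


@dataclass(frozen=True)
class PressureGroup:
    """Records sharing a peak pressure within the grouping tolerance."""

    label: str
    indices: np.ndarray   # row positions into the records table
    mean_pmax: float      # kPa
    sd_pmax: float        # kPa
    n: int


@dataclass(frozen=True)
class FitResult:
    """Outcome of one nonlinear state-equation fit."""

    family: str
    params: dict            # fitted parameter values
    stderr: dict            # delta-method standard errors
    rss: float              # residual sum of squares
    converged: bool
    n_used: int
    seed: int


@dataclass(frozen=True)
class DistributionReport:
    feature: str
    test: str
    statistic: float
    p_value: float
    passed: bool            # null (assumed distribution) not rejected
    error: str | None = None


# ---------------------------------------------------------------------------

def test_distributions(records: pd.DataFrame, alpha: float = 0.01,
                       angle_range: tuple[float, float] = (0.0, 180.0)):
    """Validate the assumed initial-shape distributions.

    Shapiro–Wilk normality on area, perimeter (and elongation if
    present); Kolmogorov–Smirnov uniformity on the angle.  A feature
    with no variation yields a degenerate-input entry instead of a test.
    """
    if len(records) < 8:
        raise ValueError("need at least 8 records for distribution tests")
    out: list[DistributionReport] = []

    def shapiro_entry(name: str, col: str):
        x = np.asarray(records[col], dtype=float)
        if np.ptp(x) == 0:
            out.append(DistributionReport(name, "shapiro", np.nan, np.nan, False,
                                          error="degenerate: constant values"))
            return
        stat, p = stats.shapiro(x)
        out.append(DistributionReport(name, "shapiro", float(stat), float(p), bool(p > alpha)))

    shapiro_entry("A_initial", "A_initial_um2")
    shapiro_entry("perimeter", "perimeter_um")
    if "elongation" in records.columns:
        shapiro_entry("elongation", "elongation")

    ang = np.asarray(records["angle_deg"], dtype=float)
    if np.ptp(ang) == 0:
        out.append(DistributionReport("angle", "ks_uniform", np.nan, np.nan, False,
                                      error="degenerate: constant values"))
    else:
        lo, hi = angle_range
        stat, p = stats.kstest(ang, stats.uniform(loc=lo, scale=hi - lo).cdf)
        out.append(DistributionReport("angle", "ks_uniform", float(stat), float(p), bool(p > alpha)))
    return out


def group_by_pressure(
    records: pd.DataFrame,
    cv_max: float = 0.05,
    min_size: int = 4,
    gap_factor: float = 0.8,
):
    """Cluster records into peak-pressure groups.

    Records are sorted by p_max and accreted greedily left to right: a
    candidate joins the open group while the group's coefficient of
    variation (including the candidate) stays ≤ ``cv_max`` and the
    relative gap to the previous (sorted) member is at most
    ``gap_factor``·cv_max.  The gap condition applies the
    within-group-variation rule to the newcomer: consecutive pressures
    inside a tight cluster are far closer than the spacing between
    pressure levels, so a cluster cannot silently absorb the next level
    even though one stray point barely moves a 13-point group's CV.
    Groups smaller than ``min_size`` go to the ungrouped residue.

    Returns (groups, ungrouped_indices); deterministic and
    permutation-invariant because of the initial sort.
    """
    p = np.asarray(records["pmax_kPa"], dtype=float)
    order = np.argsort(p, kind="stable")
    clusters: list[list[int]] = []
    current: list[int] = []
    for idx in order:
        if not current:
            current = [int(idx)]
            continue
        vals = p[current]
        prev = p[current[-1]]
        cand = np.append(vals, p[idx])
        cv = cand.std(ddof=0) / cand.mean() if cand.mean() > 0 else np.inf
        if cv <= cv_max and (p[idx] - prev) / prev <= gap_factor * cv_max:
            current.append(int(idx))
        else:
            clusters.append(current)
            current = [int(idx)]
    if current:
        clusters.append(current)

    groups: list[PressureGroup] = []
    ungrouped: list[int] = []
    for members in clusters:
        if len(members) < min_size:
            ungrouped.extend(members)
            continue
        vals = p[members]
        groups.append(PressureGroup(
            label=f"G{len(groups) + 1:02d}",
            indices=np.array(sorted(members)),
            mean_pmax=float(vals.mean()),
            sd_pmax=float(vals.std(ddof=1)) if len(members) > 1 else 0.0,
            n=len(members),
        ))
    return groups, sorted(ungrouped)


def fit_group_lines(records: pd.DataFrame, groups: list[PressureGroup]):
    """Ordinary least-squares line ζ = a + b·A_initial within each group.

    Returns a DataFrame (label, slope, intercept, r_value, n, error);
    a group with no spread in A_initial gets an error entry.
    """
    rows = []
    for g in groups:
        sub = records.iloc[g.indices]
        x = np.asarray(sub["A_initial_um2"], dtype=float)
        y = np.asarray(sub["zeta"], dtype=float)
        if np.ptp(x) == 0:
            rows.append({"label": g.label, "slope": np.nan, "intercept": np.nan,
                         "r_value": np.nan, "n": g.n, "mean_pmax_kPa": g.mean_pmax,
                         "error": "degenerate A_initial spread"})
            continue
        res = stats.linregress(x, y)
        rows.append({"label": g.label, "slope": float(res.slope),
                     "intercept": float(res.intercept), "r_value": float(res.rvalue),
                     "n": g.n, "mean_pmax_kPa": g.mean_pmax, "error": None})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonlinear state-equation fitting

_FIT_PARAMS = {"tait": ("kappa", "alpha3"), "exponential": ("B0", "Bprime"),
               "li": ("alpha1",)}


def _predict_zeta(theta: np.ndarray, family: str, base: eos.StateEquationParams,
                  A0: np.ndarray, pmax: np.ndarray,
                  coupling: synthdata.SizeCouplingSpec | None) -> np.ndarray:
    """Vectorised ζ(p_max; θ, A_initial) with per-cell size coupling.

    Mirrors :func:`cellshock.synthdata.couple_params` family by family
    but evaluates all records at once (the fit loop calls this often).
    """
    names = _FIT_PARAMS[family]
    model = base.with_(family=family, **dict(zip(names, theta)))
    c = coupling.factor(A0) if coupling is not None else np.ones_like(A0)
    p0 = model.p0
    if family == "tait":
        alpha3 = model.alpha3 / c
        x = (pmax - p0) / (alpha3 * p0)
        if np.any(x <= 0) or model.alpha3 <= 0:
            raise eos.DomainError("tait prediction outside domain")
        return x ** (1.0 / model.kappa)
    if family == "exponential":
        # the quadratic exponent is evaluable everywhere; leaving the
        # B>0 region simply predicts shrinkage the data contradict, so
        # the optimiser sees a smooth penalty instead of a cliff
        ph = (pmax - p0) / model.pref
        b0, bp = model.B0 * c, model.Bprime * c
        return np.exp(b0 * ph + 0.5 * bp * ph**2)
    out = np.empty_like(pmax)
    for i in range(pmax.size):  # li family: scalar root-finds, used rarely
        params = synthdata.couple_params(model, float(A0[i]), coupling)
        out[i] = float(eos.area_model(pmax[i], params)) / params.A0
    return out


def fit_state_equation(
    records: pd.DataFrame,
    family: str,
    base: eos.StateEquationParams | None = None,
    coupling: synthdata.SizeCouplingSpec | None = synthdata.SizeCouplingSpec(),
    seed: int = 0,
    n_starts: int = 16,
    include_detached: bool = False,
    relative: bool = True,
) -> FitResult:
    """Nonlinear least squares of observed ζ against a family's prediction.

    By default the fit minimises relative residuals
    (ζ_obs − ζ_pred)/ζ_pred, matching the multiplicative character of
    the water-exchange fluctuations (constant variance on that scale,
    hence calibrated Wald intervals); ``relative=False`` gives plain
    absolute residuals.  Detached records are excluded by default
    (their peak pressure is censored).  Multi-start initialisation,
    seeded; the start with the lowest residual sum of squares wins.
    Standard errors come from the Gauss–Newton covariance at the
    optimum.  Non-convergence is reported in the result, not raised.
    """
    if family not in _FIT_PARAMS:
        raise ValueError(f"unknown family {family!r}")
    sub = records if include_detached else records[~records["detached"].astype(bool)]
    if len(sub) < 10:
        raise ValueError("need at least 10 non-detached records to fit")
    A0 = np.asarray(sub["A_initial_um2"], dtype=float)
    pmax = np.asarray(sub["pmax_kPa"], dtype=float)
    zeta = np.asarray(sub["zeta"], dtype=float)
    base = base or eos.StateEquationParams(family=family)
    names = _FIT_PARAMS[family]

    def residuals(theta):
        try:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                pred = _predict_zeta(theta, family, base, A0, pmax, coupling)
                r = (zeta - pred) / pred if relative else zeta - pred
        except (eos.DomainError, FloatingPointError, OverflowError):
            return np.full(zeta.shape, 1e6)
        r[~np.isfinite(r)] = 1e6
        return r

    rng = np.random.default_rng(seed)
    defaults = {"kappa": 1.5, "alpha3": 1.0, "B0": 1.0, "Bprime": -0.1, "alpha1": 1.0}
    starts = [np.array([defaults[nm] for nm in names])]
    for _ in range(n_starts - 1):
        starts.append(np.array([defaults[nm] * rng.uniform(0.4, 2.5) for nm in names]))

    best = None
    for theta0 in starts:
        try:
            sol = optimize.least_squares(residuals, theta0, method="lm",
                                         xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                         max_nfev=2000)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = 2.0 * sol.cost
        if best is None or rss < best[0]:
            best = (rss, sol)

    if best is None:
        return FitResult(family=family, params={}, stderr={}, rss=np.inf,
                         converged=False, n_used=len(sub), seed=seed)
    rss, sol = best
    dof = max(len(sub) - len(names), 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(len(names), np.nan)
    return FitResult(
        family=family,
        params={nm: float(v) for nm, v in zip(names, sol.x)},
        stderr={nm: float(s) for nm, s in zip(names, se)},
        rss=float(rss),
        converged=bool(sol.success),
        n_used=len(sub),
        seed=seed,
    )


def count_shrinking(records: pd.DataFrame):
    """Number and fraction of records whose projected area decreased (ζ < 1)."""
    z = np.asarray(records["zeta"], dtype=float)
    n = int(np.sum(z < 1.0))
    return n, (n / z.size if z.size else 0.0)


# ---------------------------------------------------------------------------
# Monte-Carlo recovery harness

@dataclass(frozen=True)
class RecoveryConfig:
    """Replicated generate -> fit study of parameter recovery."""

    family: str = "tait"
    true_params: dict = field(default_factory=lambda: {"kappa": 1.5, "alpha3": 0.8})
    n_replicates: int = 100
    noise: synthdata.NoiseSpec = synthdata.NoiseSpec(amplitude=0.05)
    dataset: synthdata.DatasetConfig | None = None
    n_starts: int = 6
    seed: int = 0
    use_imaging: bool = False


def recovery_harness(config: RecoveryConfig) -> dict:
    """Bias, RMSE and 95%-interval coverage of state-equation fits.

    Each replicate generates a fresh dataset from the true parameters
    (optionally routed through render -> segment -> measure) and refits
    the family; nominal 95% Wald intervals are scored against truth.
    """
    base_ds = config.dataset or synthdata.DatasetConfig()
    model = base_ds.model.with_(family=config.family, **config.true_params)
    per_param: dict[str, list[float]] = {k: [] for k in config.true_params}
    covered: dict[str, list[bool]] = {k: [] for k in config.true_params}
    n_converged = 0
    for r in range(config.n_replicates):
        seed_r = (config.seed + 977 * r) % (2**31)
        ds = dataclasses.replace(base_ds, model=model, noise=config.noise,
                                 seed=seed_r, detach_prob=base_ds.detach_prob)
        records, _ = synthdata.generate_dataset(ds)
        if config.use_imaging:
            from .pipeline import measure_records  # local import: optional heavy path
            records = measure_records(records, ds, seed_r)
        fit = fit_state_equation(records, config.family, base=model,
                                 coupling=ds.coupling, seed=seed_r,
                                 n_starts=config.n_starts)
        if not fit.converged:
            continue
        n_converged += 1
        for k, true_v in config.true_params.items():
            est, se = fit.params[k], fit.stderr[k]
            per_param[k].append(est)
            covered[k].append(abs(est - true_v) <= 1.96 * se)

    report: dict = {"family": config.family, "n_replicates": config.n_replicates,
                    "n_converged": n_converged, "params": {}}
    for k, true_v in config.true_params.items():
        est = np.asarray(per_param[k])
        if est.size == 0:
            report["params"][k] = {"error": "no converged fits"}
            continue
        err = est - true_v
        report["params"][k] = {
            "true": true_v,
            "mean_estimate": float(est.mean()),
            "bias": float(err.mean()),
            "rmse": float(np.sqrt(np.mean(err**2))),
            "median_rel_err": float(np.median(np.abs(err) / abs(true_v))),
            "coverage_95": float(np.mean(covered[k])),
        }
    return report
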