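"""Preprocessing and global refinement of liposome SAXS concentration series.

A series of 1-D curves (one empty-liposome control plus a protein
concentration series) is refined against the combined bilayer + micelle model
in one simultaneous least-squares problem: the bilayer geometry (L_t, L_h)
and interface roughness R are shared across all curves, while the protein
fraction x, the two scales C1/C2 and the flat background B are refined per
curve. Uncertainties are profile-likelihood confidence intervals at a
configurable level (default 63.8%, i.e. a Δχ² threshold of ≈0.874 for one
degree of freedom).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .saxs_model import (
    BilayerModel,
    SLDSet,
    combined_intensity,
)

__all__ = [
    "SAXSDataset",
    "GlobalFitProblem",
    "FitResult",
    "ConfidenceInterval",
    "read_dat",
    "write_dat",
    "subtract_background",
    "rebin_log",
    "q_from_angle",
    "fit_global",
    "profile_confidence_interval",
]

SHARED_PARAMETERS = ("L_t", "L_h", "R")
PER_DATASET_PARAMETERS = ("x", "C1", "C2", "B")

#: Physically motivated default bounds bracketing plausible PC-bilayer values.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "L_t": (8.0, 25.0),
    "L_h": (3.0, 12.0),
    "R": (0.0, 15.0),
    "x": (0.0, 0.5),
    "C1": (0.0, np.inf),
    "C2": (0.0, np.inf),
    "B": (0.0, np.inf),
}

DEFAULT_INITIAL: dict[str, float] = {
    "L_t": 15.0,
    "L_h": 7.0,
    "R": 3.0,
    "x": 0.02,
    "C1": 1.0,
    "C2": 1e-6,
    "B": 0.0,
}


# --------------------------------------------------------------------------
# Dataset container and ASCII I/O
# --------------------------------------------------------------------------

@dataclass
class SAXSDataset:
    """One 1-D SAXS curve: q [Å^-1], I(q) and 1-sigma uncertainties."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise ValueError("q, I and sigma must have identical shapes")
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("datasets must be non-empty 1-D curves")
        if np.any(self.q <= 0):
            raise ValueError("q values must be strictly positive")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma values must be strictly positive")

    def __len__(self) -> int:
        return self.q.size


def read_dat(path, label: str | None = None, **metadata) -> SAXSDataset:
    """Read a 3-column ASCII curve (q, I, sigma); '#' lines are comments.

    Whitespace- and comma-delimited dialects are both accepted.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.replace(",", " ").split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts[:3]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    arr = np.asarray(rows, dtype=float)
    name = label if label is not None else str(path)
    return SAXSDataset(arr[:, 0], arr[:, 1], arr[:, 2], label=name, metadata=metadata)


def write_dat(path, dataset: SAXSDataset) -> None:
    """Write a curve in the same 3-column ASCII dialect read by :func:`read_dat`."""
    header = f"label: {dataset.label}\n" + "\n".join(
        f"{k}: {v}" for k, v in sorted(dataset.metadata.items())
    )
    np.savetxt(path, np.column_stack([dataset.q, dataset.I, dataset.sigma]),
               header=header + ("\n" if header else "") + "q[1/A]  I(q)  sigma(I)")


# --------------------------------------------------------------------------
# Preprocessing
# --------------------------------------------------------------------------

def subtract_background(sample: SAXSDataset, buffer: SAXSDataset,
                        scale: float = 1.0, interpolate: bool = False) -> SAXSDataset:
    """Subtract a scaled buffer curve with Gaussian error propagation.

    I_out = I_sample - scale * I_buffer
    sigma_out = sqrt(sigma_sample^2 + scale^2 * sigma_buffer^2)

    The two curves must share the q grid; with ``interpolate=True`` the
    buffer is linearly interpolated onto the sample grid instead (flagged in
    the output metadata).
    """
    same_grid = sample.q.shape == buffer.q.shape and np.allclose(sample.q, buffer.q)
    meta = dict(sample.metadata)
    if same_grid:
        ib, sb = buffer.I, buffer.sigma
    elif interpolate:
        ib = np.interp(sample.q, buffer.q, buffer.I)
        sb = np.interp(sample.q, buffer.q, buffer.sigma)
        meta["buffer_interpolated"] = True
    else:
        raise ValueError(
            "sample and buffer q grids differ; pass interpolate=True to resample"
        )
    meta["background_scale"] = scale
    return SAXSDataset(
        q=sample.q.copy(),
        I=sample.I - scale * ib,
        sigma=np.sqrt(sample.sigma**2 + scale**2 * sb**2),
        label=sample.label,
        metadata=meta,
    )


def rebin_log(dataset: SAXSDataset, n_bins: int) -> SAXSDataset:
    """Logarithmic re-binning with inverse-variance weighting.

    Bin edges are geometric between q_min and q_max. Within each bin the
    intensity is the inverse-variance-weighted mean, the uncertainty the
    standard error of that weighted mean, and the q value the same-weighted
    mean q. Empty bins are dropped.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if n_bins > len(dataset):
        raise ValueError(
            f"n_bins ({n_bins}) exceeds the number of data points ({len(dataset)})"
        )
    edges = np.geomspace(dataset.q[0], dataset.q[-1], n_bins + 1)
    idx = np.clip(np.searchsorted(edges, dataset.q, side="right") - 1, 0, n_bins - 1)
    w = 1.0 / dataset.sigma**2
    q_out, i_out, s_out = [], [], []
    for b in range(n_bins):
        m = idx == b
        if not np.any(m):
            continue
        wsum = w[m].sum()
        q_out.append(float((w[m] * dataset.q[m]).sum() / wsum))
        i_out.append(float((w[m] * dataset.I[m]).sum() / wsum))
        s_out.append(float(1.0 / math.sqrt(wsum)))
    meta = dict(dataset.metadata)
    meta["rebinned"] = n_bins
    return SAXSDataset(np.array(q_out), np.array(i_out), np.array(s_out),
                       label=dataset.label, metadata=meta)


def q_from_angle(theta, wavelength: float):
    """Momentum transfer q = 4*pi*sin(theta)/lambda, theta the half angle [rad]."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    theta_arr = np.asarray(theta, dtype=float)
    if np.any(theta_arr < 0) or np.any(theta_arr > np.pi / 2):
        raise ValueError("theta must lie in [0, pi/2]")
    out = 4.0 * np.pi * np.sin(theta_arr) / wavelength
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# Global fit problem
# --------------------------------------------------------------------------

@dataclass
class GlobalFitProblem:
    """Simultaneous refinement problem over a concentration series.

    L_t, L_h and R are shared; x, C1, C2 and B are per-dataset. Bounds and
    initial values can be overridden per parameter name; the q window
    restricts which points enter the objective (the low-q end may be excluded
    where the flat-sheet approximation is known to degrade).
    """

    datasets: list
    slds: SLDSet = field(default_factory=SLDSet)
    bounds: dict = field(default_factory=dict)
    initial: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    q_min: float | None = None
    q_max: float | None = None

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one dataset is required")
        self.bounds = {**DEFAULT_BOUNDS, **self.bounds}
        self.initial = {**DEFAULT_INITIAL, **self.initial}
        for name, v in self.initial.items():
            lo, hi = self._bound(name)
            if not lo <= v <= hi:
                raise ValueError(f"initial value for {name} ({v}) outside bounds {lo, hi}")
        names = set(self.parameter_names)
        for name in self.fixed:
            if name not in names:
                raise ValueError(f"cannot fix unknown parameter {name!r}")
        self._masks = []
        for ds in self.datasets:
            m = np.ones(len(ds), dtype=bool)
            if self.q_min is not None:
                m &= ds.q >= self.q_min
            if self.q_max is not None:
                m &= ds.q <= self.q_max
            if not np.any(m):
                raise ValueError(f"q window excludes every point of dataset {ds.label!r}")
            self._masks.append(m)

    # -- parameter vector layout: [L_t, L_h, R, x_0, C1_0, C2_0, B_0, x_1, ...]

    @property
    def parameter_names(self) -> list[str]:
        names = list(SHARED_PARAMETERS)
        for i in range(len(self.datasets)):
            names += [f"{p}_{i}" for p in PER_DATASET_PARAMETERS]
        return names

    def _base_name(self, name: str) -> str:
        return name.rsplit("_", 1)[0] if name not in SHARED_PARAMETERS else name

    def _bound(self, name: str) -> tuple[float, float]:
        # per-dataset entries ("x_0") take precedence over base names ("x"),
        # so a control curve can have its protein fraction pinned at zero
        if name in self.bounds:
            return self.bounds[name]
        return self.bounds[self._base_name(name)]

    def bounds_vector(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self._bound(n)[0] for n in self.parameter_names])
        hi = np.array([self._bound(n)[1] for n in self.parameter_names])
        return lo, hi

    def initial_vector(self) -> np.ndarray:
        return np.array([
            self.fixed.get(n, self.initial.get(n, self.initial[self._base_name(n)]))
            for n in self.parameter_names
        ])

    def models(self, theta: np.ndarray) -> list[BilayerModel]:
        lt, lh, rough = theta[:3]
        out = []
        for i in range(len(self.datasets)):
            xi, c1, c2, b = theta[3 + 4 * i: 7 + 4 * i]
            out.append(BilayerModel(L_t=lt, L_h=lh, x=min(max(xi, 0.0), 1.0),
                                    R=rough, C1=c1, C2=c2, B=b, slds=self.slds))
        return out

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        parts = []
        for ds, mask, model in zip(self.datasets, self._masks, self.models(theta)):
            pred = combined_intensity(ds.q[mask], model)
            parts.append((ds.I[mask] - pred) / ds.sigma[mask])
        return np.concatenate(parts)

    def chisq(self, theta: np.ndarray) -> float:
        r = self.residuals(theta)
        return float(r @ r)

    @property
    def n_points(self) -> int:
        return int(sum(m.sum() for m in self._masks))


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    censored_lower: bool = False
    censored_upper: bool = False


@dataclass
class FitResult:
    """Outcome of :func:`fit_global`.

    ``params`` maps parameter names (L_t, L_h, R, x_0, C1_0, ...) to refined
    values; ``chi2_red`` is the minimized chi-square divided by
    (n_points - n_free). ``intervals`` is filled in lazily by
    :func:`profile_confidence_interval`.
    """

    params: dict
    chisq: float
    chi2_red: float
    n_points: int
    n_free: int
    residuals: list
    success: bool
    message: str
    nfev: int
    start_index: int
    stderr: dict = field(default_factory=dict)
    intervals: dict = field(default_factory=dict)

    @property
    def theta(self) -> np.ndarray:
        return np.array(list(self.params.values()))


def _linear_scale_init(problem: GlobalFitProblem, theta: np.ndarray) -> np.ndarray:
    """Initialize C1, C2, B per dataset by weighted non-negative least squares.

    The model is linear in the scales and background, so for any candidate
    (L_t, L_h, R, x) the optimal non-negative linear parameters are an NNLS
    solve on the whitened design matrix; this makes multistart candidates
    immediately competitive.
    """
    theta = theta.copy()
    lt, lh, rough = theta[:3]
    for i, (ds, mask) in enumerate(zip(problem.datasets, problem._masks)):
        xi = theta[3 + 4 * i]
        base = BilayerModel(L_t=lt, L_h=lh, x=xi, R=rough, C1=1.0, C2=0.0, B=0.0,
                            slds=problem.slds)
        q = ds.q[mask]
        damp = np.exp(-(rough**2) * q**2)
        from .saxs_model import lamellar_intensity, micelle_intensity_from_model
        cols = np.column_stack([
            lamellar_intensity(q, base) * damp,
            micelle_intensity_from_model(q, base) * damp,
            np.ones_like(q),
        ])
        w = 1.0 / ds.sigma[mask]
        try:
            sol, _ = optimize.nnls(cols * w[:, None], ds.I[mask] * w)
        except RuntimeError:  # NNLS failed to converge; keep current values
            continue
        theta[4 + 4 * i: 7 + 4 * i] = sol
    return theta


def _minimize(problem: GlobalFitProblem, theta0: np.ndarray,
              fixed: dict | None = None, **ls_kwargs):
    """Bounded trust-region least squares, optionally with parameters frozen."""
    names = problem.parameter_names
    lo, hi = problem.bounds_vector()
    fixed = fixed or {}
    free_idx = [i for i, n in enumerate(names) if n not in fixed]
    full = theta0.copy()
    for n, v in fixed.items():
        full[names.index(n)] = v

    def fun(free_theta):
        full[free_idx] = free_theta
        return problem.residuals(full)

    t0 = np.clip(full[free_idx], lo[free_idx], hi[free_idx])
    res = optimize.least_squares(
        fun, t0, bounds=(lo[free_idx], hi[free_idx]), method="trf",
        x_scale="jac", **ls_kwargs,
    )
    full[free_idx] = res.x
    return full, res


def fit_global(problem: GlobalFitProblem, n_starts: int = 10,
               seed: int = 0) -> FitResult:
    """Refine the global model by multistart bounded least squares.

    The first start is the problem's initial values; the remaining
    ``n_starts - 1`` draw the nonlinear parameters (L_t, L_h, R and the x's)
    from a seeded Sobol design over their bounds. Every start receives
    NNLS-optimal scales/backgrounds before refinement. The lowest final
    chi-square wins; exact ties break to the lowest start index, making the
    result deterministic for a given seed.

    A non-converged best fit is returned with ``success=False`` and the
    optimizer diagnostics — never silently.
    """
    names = problem.parameter_names
    lo, hi = problem.bounds_vector()
    nonlinear_idx = [i for i, n in enumerate(names)
                     if problem._base_name(n) in ("L_t", "L_h", "R", "x")
                     and n not in problem.fixed]

    starts = [problem.initial_vector()]
    if n_starts > 1:
        sampler = qmc.Sobol(d=len(nonlinear_idx), scramble=True, seed=seed)
        n_draw = 1 << (n_starts - 2).bit_length()  # next power of two
        unit = sampler.random(n_draw)[: n_starts - 1]
        for row in unit:
            t = problem.initial_vector()
            t[nonlinear_idx] = lo[nonlinear_idx] + row * (hi[nonlinear_idx] - lo[nonlinear_idx])
            starts.append(t)

    best = None
    for k, t0 in enumerate(starts):
        t0 = _linear_scale_init(problem, t0)
        theta, res = _minimize(problem, t0, fixed=problem.fixed)
        if best is None or res.cost < best[2].cost - 1e-12:
            best = (k, theta, res)
    k, theta, res = best

    free_names = [n for n in names if n not in problem.fixed]
    n_free = len(free_names)
    chisq = 2.0 * res.cost
    dof = max(problem.n_points - n_free, 1)
    params = dict(zip(names, theta))

    # Covariance-based standard errors from the whitened Jacobian; used to
    # seed the profile scans, not as the reported uncertainty.
    stderr = {}
    try:
        jac = res.jac
        # column-equilibrate before inverting: parameter scales span many
        # orders of magnitude (lengths in Å vs backgrounds in intensity units)
        norms = np.linalg.norm(jac, axis=0)
        norms[norms == 0] = 1.0
        cov_scaled = np.linalg.pinv((jac / norms).T @ (jac / norms))
        stderr = {n: float(np.sqrt(max(cov_scaled[i, i], 0.0)) / norms[i])
                  for i, n in enumerate(free_names)}
    except np.linalg.LinAlgError:
        pass

    resids = []
    pos = 0
    r_all = problem.residuals(theta)
    for m in problem._masks:
        n = int(m.sum())
        resids.append(r_all[pos:pos + n])
        pos += n

    return FitResult(
        params=params, chisq=chisq, chi2_red=chisq / dof,
        n_points=problem.n_points, n_free=n_free, residuals=resids,
        success=bool(res.success), message=res.message, nfev=int(res.nfev),
        start_index=k, stderr=stderr,
    )


def profile_confidence_interval(problem: GlobalFitProblem, result: FitResult,
                                parameter: str, level: float = 0.638,
                                rtol: float = 1e-3) -> ConfidenceInterval:
    """Profile-likelihood confidence interval for one refined parameter.

    The parameter is scanned away from its point estimate while all other
    parameters are re-minimized; the interval is the region where the profile
    chi-square stays within Δ of the minimum, Δ being the 1-dof chi-square
    quantile at ``level`` (≈0.874 at 63.8%). Endpoints are bracketed by
    doubling steps and refined by root bisection to relative tolerance
    ``rtol``. An endpoint pushed outside the parameter bounds is reported as
    the bound itself and flagged as censored.
    """
    if parameter not in result.params:
        raise KeyError(f"unknown parameter {parameter!r}")
    if parameter in problem.fixed:
        raise ValueError(f"parameter {parameter!r} is fixed, not refinable")
    if not result.success:
        raise ValueError("profile intervals require a converged fit result")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must lie in [0, 1)")
    delta = float(stats.chi2.ppf(level, df=1))
    hat = result.params[parameter]
    if delta == 0.0:
        return ConfidenceInterval(hat, hat, level)

    names = problem.parameter_names
    lo, hi = problem.bounds_vector()
    p_lo = lo[names.index(parameter)]
    p_hi = hi[names.index(parameter)]
    chisq_min = result.chisq
    target = chisq_min + delta
    theta_hat = result.theta

    cache_theta = {0.0: theta_hat}

    def profile(value: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
        # tighter-than-default tolerances: a sloppy re-minimization
        # overestimates the profile chi-square and shrinks the interval
        theta, res = _minimize(problem, warm,
                               fixed={**problem.fixed, parameter: value},
                               ftol=1e-12, xtol=1e-12, gtol=1e-12)
        return 2.0 * res.cost, theta

    se = result.stderr.get(parameter) or 0.0
    step0 = math.sqrt(delta) * se if se > 0 else 0.1 * abs(hat) + 1e-3 * (p_hi - p_lo if np.isfinite(p_hi) else 1.0)
    if step0 <= 0 or not math.isfinite(step0):
        step0 = 1e-3

    def find_endpoint(direction: int) -> tuple[float, bool]:
        bound = p_hi if direction > 0 else p_lo
        step = step0
        inside_v, inside_theta = hat, theta_hat
        for _ in range(60):
            cand = hat + direction * step
            censored = (direction > 0 and cand >= bound) or (direction < 0 and cand <= bound)
            cand_clamped = min(max(cand, p_lo), p_hi)
            chi, th = profile(cand_clamped, inside_theta)
            if chi >= target:
                # bracket found between inside_v and cand_clamped
                a, b = inside_v, cand_clamped
                fa = None
                th_warm = th
                for _ in range(200):
                    mid = 0.5 * (a + b)
                    chi_m, th_warm = profile(mid, th_warm)
                    if chi_m >= target:
                        b = mid
                    else:
                        a = mid
                    if abs(b - a) <= rtol * max(abs(hat), abs(b), step0):
                        break
                return 0.5 * (a + b), False
            inside_v, inside_theta = cand_clamped, th
            if censored:
                return bound, True
            step *= 2.0
        warnings.warn(f"profile scan for {parameter} did not cross the threshold")
        return inside_v, True

    upper, cens_up = find_endpoint(+1)
    lower, cens_lo = find_endpoint(-1)
    ci = ConfidenceInterval(lower=lower, upper=upper, level=level,
                            censored_lower=cens_lo, censored_upper=cens_up)
    result.intervals[parameter] = ci
    return ci
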