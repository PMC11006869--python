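"""Model-free lifetime distribution analysis (LDA) of transient absorption data.

Flash-photolysis and pump-probe experiments on microbial rhodopsins yield
absorbance-difference surfaces ΔA(t, λ).  Because the photocycle is a cascade
of quasi-first-order transitions, each kinetic trace is (to good
approximation) a sum of exponentials, and recovering the distribution of
lifetimes amounts to a discretized inverse Laplace transform — a classically
ill-posed problem.  This module stabilizes the inversion with Tikhonov (ridge)
regularization on a log-spaced lifetime grid and selects the regularization
factor by the L-curve criterion.  The signed amplitudes x(τ, λ) assembled over
all probe wavelengths form the lifetime distribution map (LDM): positive lobes
mark decaying absorption (or rising bleach) components, negative lobes the
converse, so a photointermediate transition appears as a bipolar feature at
its characteristic lifetime.

The inversion solves, independently per probe wavelength (or once globally),

    min_x || A x - y ||^2 + alpha^2 ||x||^2,   A[i, j] = exp(-t_i / tau_j)

with ``alpha`` scanned over a log-spaced path and chosen at the point of
maximum curvature of the (log residual norm, log solution norm) trade-off
curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TransientDataset",
    "LifetimeGrid",
    "RegularizationPath",
    "LifetimeDistributionMap",
    "build_lifetime_grid",
    "build_design_matrix",
    "tikhonov_solve",
    "regularization_path",
    "l_curve_corner",
    "compute_ldm",
    "peak_lifetimes",
    "reduce_transient",
    "normalize_at_time",
    "read_transient_csv",
    "write_transient_csv",
]

# Default lifetime-grid conventions for the two experimental timescales:
# ultrafast (fs pump-probe) runs 0.03 ps to 5400 ps; the ns-to-s flash
# photolysis grid starts at 0.0004 ms and ends at 3x the last measured time.
ULTRAFAST_TAU_START_S = 0.03e-12
ULTRAFAST_TAU_END_S = 5400e-12
SLOW_TAU_START_S = 0.0004e-3
SLOW_TAU_END_FACTOR = 3.0
DEFAULT_N_TAU = 200
DEFAULT_ALPHA_MIN = 0.01
DEFAULT_ALPHA_MAX = 5.0
DEFAULT_N_ALPHA = 200


@dataclass
class TransientDataset:
    """A ΔA(t, λ) surface with its measurement conditions.

    ``delta_A`` is indexed [time, wavelength] in ΔOD.  ``metadata`` carries
    free-form condition keys (pH, salt, salt_mM, excitation_nm, ...).
    """

    times: np.ndarray
    wavelengths: np.ndarray
    delta_A: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delta_A = np.asarray(self.delta_A, dtype=float)
        if self.delta_A.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"delta_A shape {self.delta_A.shape} does not match "
                f"({self.times.size} times, {self.wavelengths.size} wavelengths)"
            )
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.delta_A))):
            raise ValueError("non-finite values in dataset")

    def transient(self, wavelength: float) -> np.ndarray:
        """Kinetic trace at the grid wavelength nearest to ``wavelength``."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return self.delta_A[:, i]


@dataclass(frozen=True)
class LifetimeGrid:
    """Log-evenly spaced lifetimes tau_1 ... tau_n (seconds)."""

    lifetimes: np.ndarray
    start: float
    end: float
    n: int

    @property
    def log_step(self) -> float:
        """Constant log10 spacing between neighbouring lifetimes."""
        return np.log10(self.end / self.start) / (self.n - 1)


def build_lifetime_grid(start: float, end: float, n: int = DEFAULT_N_TAU) -> LifetimeGrid:
    """Geometric lifetime grid: tau_j = start * (end/start)^((j-1)/(n-1))."""
    if not (0 < start < end):
        raise ValueError("require 0 < start < end")
    if n < 2:
        raise ValueError("need at least two lifetimes")
    taus = start * (end / start) ** (np.arange(n) / (n - 1))
    return LifetimeGrid(lifetimes=taus, start=float(start), end=float(end), n=int(n))


def default_slow_grid(times: np.ndarray, n: int = DEFAULT_N_TAU) -> LifetimeGrid:
    """ns-to-s timescale convention: 0.0004 ms to 3x the last time point."""
    return build_lifetime_grid(SLOW_TAU_START_S, SLOW_TAU_END_FACTOR * float(np.max(times)), n)


def default_ultrafast_grid(n: int = DEFAULT_N_TAU) -> LifetimeGrid:
    """Ultrafast timescale convention: 0.03 ps to 5400 ps."""
    return build_lifetime_grid(ULTRAFAST_TAU_START_S, ULTRAFAST_TAU_END_S, n)


def build_design_matrix(times: np.ndarray, grid: LifetimeGrid) -> np.ndarray:
    """Multiexponential kernel A[i, j] = exp(-t_i / tau_j)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative times not allowed in the design matrix")
    return np.exp(-times[:, None] / grid.lifetimes[None, :])


def tikhonov_solve(A: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """Ridge solution x = argmin ||Ax - y||^2 + alpha^2 ||x||^2.

    Solves the normal equations (A^T A + alpha^2 I) x = A^T y.  At alpha = 0
    with a rank-deficient A the system is singular; a warning is issued and
    the minimum-norm least-squares solution is returned instead.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n = A.shape[1]
    M = A.T @ A + alpha**2 * np.eye(n)
    b = A.T @ y
    if alpha == 0 and np.linalg.matrix_rank(A) < n:
        warnings.warn("rank-deficient system at alpha=0; returning minimum-norm solution")
        return np.linalg.lstsq(A, y, rcond=None)[0]
    return np.linalg.solve(M, b)


@dataclass
class RegularizationPath:
    """Norms of the Tikhonov solution along a log-spaced alpha scan."""

    alphas: np.ndarray
    residual_norms: np.ndarray
    solution_norms: np.ndarray
    solutions: np.ndarray | None = None  # [n_alpha, n_tau] if kept
    chosen_alpha: float | None = None
    chosen_index: int | None = None


def _svd_path(A, y, alphas, keep_solutions=True):
    """All ridge solutions along the alpha path from one SVD of A."""
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    uty = U.T @ y
    n_alpha = len(alphas)
    res = np.empty(n_alpha)
    sol = np.empty(n_alpha)
    xs = np.empty((n_alpha, A.shape[1])) if keep_solutions else None
    # residual component orthogonal to the column space is alpha-independent
    r_perp2 = float(y @ y - uty @ uty)
    r_perp2 = max(r_perp2, 0.0)
    for k, a in enumerate(alphas):
        f = s / (s**2 + a**2)          # filter factors / s
        x = Vt.T @ (f * uty)
        res[k] = np.sqrt(r_perp2 + np.sum(((s * f - 1.0) * uty) ** 2))
        sol[k] = np.linalg.norm(x)
        if keep_solutions:
            xs[k] = x
    return res, sol, xs


def regularization_path(
    A: np.ndarray,
    y: np.ndarray,
    alpha_min: float = DEFAULT_ALPHA_MIN,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    m: int = DEFAULT_N_ALPHA,
    keep_solutions: bool = True,
) -> RegularizationPath:
    """Scan m log-spaced regularization factors in [alpha_min, alpha_max]."""
    if alpha_min <= 0:
        raise ValueError("alpha_min must be positive")
    if m < 3:
        raise ValueError("need at least 3 path points")
    alphas = np.geomspace(alpha_min, alpha_max, m)
    res, sol, xs = _svd_path(np.asarray(A, float), np.asarray(y, float), alphas, keep_solutions)
    return RegularizationPath(alphas=alphas, residual_norms=res, solution_norms=sol, solutions=xs)


def l_curve_corner(path: RegularizationPath) -> float:
    """Regularization factor at the corner of the L-curve.

    The corner is the point of maximum curvature of the parametric curve
    (log residual_norm, log solution_norm), estimated by central finite
    differences; the first and last points are excluded.  Ties resolve to the
    smaller alpha.  A degenerate flat curve falls back to the median alpha
    with a warning.
    """
    if len(path.alphas) < 5:
        raise ValueError("need at least 5 path points for corner detection")
    with np.errstate(divide="ignore"):
        lx = np.log(path.residual_norms)
        ly = np.log(path.solution_norms)
    if not (np.all(np.isfinite(lx)) and np.all(np.isfinite(ly))) or (
        np.ptp(lx) < 1e-12 and np.ptp(ly) < 1e-12
    ):
        warnings.warn("degenerate flat L-curve; falling back to median alpha")
        idx = len(path.alphas) // 2
        path.chosen_index, path.chosen_alpha = idx, float(path.alphas[idx])
        return path.chosen_alpha
    t = np.log(path.alphas)
    dx = np.gradient(lx, t)
    dy = np.gradient(ly, t)
    ddx = np.gradient(dx, t)
    ddy = np.gradient(dy, t)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (dx * ddy - dy * ddx) / denom
    kappa[~np.isfinite(kappa)] = -np.inf
    kappa[0] = kappa[-1] = -np.inf   # endpoints are not corner candidates
    idx = int(np.argmax(kappa))      # argmax takes the first (smallest alpha) on ties
    path.chosen_index, path.chosen_alpha = idx, float(path.alphas[idx])
    return path.chosen_alpha


@dataclass
class LifetimeDistributionMap:
    """Signed exponential amplitudes x(tau, lambda) with the chosen alphas."""

    grid: LifetimeGrid
    wavelengths: np.ndarray
    amplitudes: np.ndarray           # [n_tau, n_wavelength]
    chosen_alphas: np.ndarray        # per wavelength (repeated if global mode)
    residuals: np.ndarray            # ||Ax - y|| per wavelength at chosen alpha
    mode: str = "per-wavelength"

    def distribution(self, wavelength: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return self.amplitudes[:, i]


def compute_ldm(
    dataset: TransientDataset,
    grid: LifetimeGrid | None = None,
    alpha_min: float = DEFAULT_ALPHA_MIN,
    alpha_max: float = DEFAULT_ALPHA_MAX,
    n_alpha: int = DEFAULT_N_ALPHA,
    mode: str = "per-wavelength",
    min_time: float = 0.0,
) -> LifetimeDistributionMap:
    """Invert a ΔA surface into a lifetime distribution map.

    Times at or below ``min_time`` (default 0, dropping t<=0 pump-probe
    artifact points) are excluded.  ``mode='per-wavelength'`` chooses an
    independent L-curve alpha for each probe wavelength; ``mode='global'``
    picks one alpha from the aggregated residual/solution norms and applies
    it everywhere.
    """
    if mode not in ("per-wavelength", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    keep = dataset.times > min_time
    times = dataset.times[keep]
    Y = dataset.delta_A[keep, :]
    if np.any(np.all(np.isnan(Y), axis=0)):
        raise ValueError("at least one wavelength column is all-NaN")
    if grid is None:
        grid = default_slow_grid(times)
    A = build_design_matrix(times, grid)
    n_wl = dataset.wavelengths.size
    amplitudes = np.empty((grid.n, n_wl))
    chosen = np.empty(n_wl)
    residuals = np.empty(n_wl)

    paths = []
    for i in range(n_wl):
        p = regularization_path(A, Y[:, i], alpha_min, alpha_max, n_alpha)
        paths.append(p)

    if mode == "per-wavelength":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flat curves at silent wavelengths
            for i, p in enumerate(paths):
                a = l_curve_corner(p)
                k = p.chosen_index
                amplitudes[:, i] = p.solutions[k]
                chosen[i] = a
                residuals[i] = p.residual_norms[k]
    else:
        agg = RegularizationPath(
            alphas=paths[0].alphas,
            residual_norms=np.sqrt(sum(p.residual_norms**2 for p in paths)),
            solution_norms=np.sqrt(sum(p.solution_norms**2 for p in paths)),
        )
        a = l_curve_corner(agg)
        k = agg.chosen_index
        for i, p in enumerate(paths):
            amplitudes[:, i] = p.solutions[k]
            chosen[i] = a
            residuals[i] = p.residual_norms[k]

    return LifetimeDistributionMap(
        grid=grid,
        wavelengths=dataset.wavelengths.copy(),
        amplitudes=amplitudes,
        chosen_alphas=chosen,
        residuals=residuals,
        mode=mode,
    )


def peak_lifetimes(
    ldm: LifetimeDistributionMap, wavelength: float, floor: float = 0.1
) -> list[tuple[float, float]]:
    """Local maxima of |x(tau)| at one wavelength, as (tau, signed amplitude).

    ``floor`` is the amplitude threshold as a fraction of the largest |x| at
    that wavelength; peaks below it are suppressed.  Results sorted by tau.
    """
    x = ldm.distribution(wavelength)
    ax = np.abs(x)
    top = ax.max()
    if top == 0:
        return []
    peaks = []
    for j in range(1, len(ax) - 1):
        if ax[j] >= ax[j - 1] and ax[j] > ax[j + 1] and ax[j] >= floor * top:
            peaks.append((float(ldm.grid.lifetimes[j]), float(x[j])))
    return peaks


def reduce_transient(
    times: np.ndarray,
    values: np.ndarray,
    linear_segment_end: float,
    points_per_decade: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-average a raw transient onto a combined linear/log timescale.

    Points up to ``linear_segment_end`` pass through unchanged.  Beyond it,
    raw points are block-averaged in log-spaced bins (``points_per_decade``
    bins per decade): each non-empty bin contributes (mean time, mean value),
    preserving the signal mean within the bin exactly.  Empty bins are
    skipped, never interpolated.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size and not np.all(np.diff(times) > 0):
        raise ValueError("raw times must be strictly increasing")
    head = times <= linear_segment_end
    out_t = [times[head]]
    out_v = [values[head]]
    tail_t = times[~head]
    tail_v = values[~head]
    if tail_t.size:
        # log bin index relative to the linear segment boundary
        k = np.floor(np.log10(tail_t / linear_segment_end) * points_per_decade).astype(int)
        for kk in np.unique(k):
            sel = k == kk
            out_t.append([tail_t[sel].mean()])
            out_v.append([tail_v[sel].mean()])
    return np.concatenate(out_t), np.concatenate(out_v)


def normalize_at_time(
    transients: list[tuple[np.ndarray, np.ndarray]], t_ref: float = 1e-4
) -> tuple[list[tuple[np.ndarray, np.ndarray]], np.ndarray]:
    """Scale transients to share the first transient's ΔA at ``t_ref``.

    Values at ``t_ref`` are linearly interpolated.  Returns the scaled
    (times, values) pairs and the applied scale factors.
    """
    refs = []
    for t, v in transients:
        t = np.asarray(t, float)
        if not (t[0] <= t_ref <= t[-1]):
            raise ValueError(f"transient does not cover t_ref={t_ref}")
        refs.append(float(np.interp(t_ref, t, v)))
    if any(r == 0 for r in refs):
        raise ValueError("zero value at t_ref; normalization undefined")
    target = refs[0]
    factors = np.array([target / r for r in refs])
    scaled = [(np.asarray(t, float), np.asarray(v, float) * f) for (t, v), f in zip(transients, factors)]
    return scaled, factors


# ---------------------------------------------------------------------------
# I/O: CSV matrix (first column time/s, header row wavelengths/nm) + JSON
# sidecar carrying the condition metadata.


def write_transient_csv(dataset: TransientDataset, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(dataset.delta_A, columns=[f"{w:g}" for w in dataset.wavelengths])
    df.insert(0, "time_s", dataset.times)
    df.to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(dataset.metadata, indent=2, sort_keys=True) + "\n")
    return path


def read_transient_csv(path: str | Path) -> TransientDataset:
    path = Path(path)
    df = pd.read_csv(path)
    times = df.iloc[:, 0].to_numpy(dtype=float)
    wavelengths = np.array([float(c) for c in df.columns[1:]])
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return TransientDataset(
        times=times,
        wavelengths=wavelengths,
        delta_A=df.iloc[:, 1:].to_numpy(dtype=float),
        metadata=meta,
    )
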