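"""Stress time-series reduction and constant-strain elasticity.

Each constant-strain simulation of a periodic fibril yields one stress time
series; its equilibrated tail averages to one point (eps, <sigma> - sigma0)
on the stress-strain curve.  Young's modulus follows from a zero-intercept
Hooke fit restricted to the linear regime (strains below ~5%), and monomer
slippage is read off the end-to-end response L/L0 versus applied strain.

Statistical conventions used throughout: standard errors of correlated
series come from block averaging (default 10 equal blocks, trailing
remainder folded into the last block), and all standard deviations are
sample (n-1) estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StressSeries",
    "StressStrainPoint",
    "StressStrainCurve",
    "block_average",
    "detect_equilibration",
    "build_curve",
    "fit_youngs_modulus",
    "slippage_profile",
]


@dataclass
class StressSeries:
    """Axial stress sigma_par (MPa) sampled at strictly increasing times (ns).

    ``sigma0`` is the isotropic reference pressure regulated by the barostat
    (0.1 MPa by default); the elastic stress is ``<sigma_par> - sigma0``.
    """

    times: np.ndarray
    sigma_parallel: np.ndarray
    sigma0: float = 0.1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.sigma_parallel = np.asarray(self.sigma_parallel, dtype=float)
        if self.times.shape != self.sigma_parallel.shape:
            raise ValueError("times and stresses must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_ns": self.times, "sigma_MPa": self.sigma_parallel}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, sigma0: float = 0.1) -> "StressSeries":
        df = pd.read_csv(path)
        return cls(df["time_ns"].to_numpy(), df["sigma_MPa"].to_numpy(), sigma0=sigma0)


@dataclass
class StressStrainPoint:
    epsilon: float
    mean_stress: float  # <sigma_par> - sigma0, MPa
    se: float
    L_over_L0: float | None = None

    def __post_init__(self):
        if self.se < 0:
            raise ValueError("standard error must be non-negative")


@dataclass
class StressStrainCurve:
    """Ordered stress-strain points; must include the eps=0 reference that
    defines L0."""

    points: list
    youngs_modulus: float | None = None
    youngs_modulus_se: float | None = None

    def __post_init__(self):
        eps = [p.epsilon for p in self.points]
        if len(set(eps)) != len(eps):
            raise ValueError("duplicate strain values in curve")
        self.points = sorted(self.points, key=lambda p: p.epsilon)
        if not any(p.epsilon == 0.0 for p in self.points):
            raise ValueError("curve must include the eps=0 reference point (L0 undefined)")

    @property
    def epsilons(self) -> np.ndarray:
        return np.array([p.epsilon for p in self.points])

    @property
    def stresses(self) -> np.ndarray:
        return np.array([p.mean_stress for p in self.points])


def block_average(values, n_blocks: int = 10):
    """Mean and block-averaged standard error of a (correlated) series.

    The series is split into ``n_blocks`` contiguous blocks of equal size,
    any trailing remainder joining the last block.  The reported mean is the
    plain mean of all values; the SE is the sample (n-1) standard deviation
    of the block means divided by sqrt(n_blocks).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < n_blocks:
        raise ValueError(f"need at least n_blocks={n_blocks} values, got {n}")
    size = n // n_blocks
    means = [values[i * size: (i + 1) * size].mean() for i in range(n_blocks - 1)]
    means.append(values[(n_blocks - 1) * size:].mean())
    means = np.array(means)
    if n_blocks == 1:
        return float(values.mean()), 0.0
    se = float(means.std(ddof=1) / np.sqrt(n_blocks))
    return float(values.mean()), se


def detect_equilibration(series: StressSeries, n_blocks_half: int = 5,
                         n_candidates: int = 20, min_tail_fraction: float = 0.25):
    """Earliest time from which the series is statistically flat.

    Scans candidate start times; for each, the remaining tail is split into
    two halves and accepted when the half means agree within twice the
    pooled block SE.  Raises if no candidate leaves a flat tail (e.g. a
    monotone drift), advising a longer series.
    """
    v = series.sigma_parallel
    t = series.times
    n = len(v)
    if n < 50:
        raise ValueError("equilibration detection needs at least 50 points")
    max_start = int(n * (1.0 - min_tail_fraction))
    starts = np.unique(np.linspace(0, max_start, n_candidates).astype(int))
    for i in starts:
        tail = v[i:]
        half = len(tail) // 2
        if half < n_blocks_half:
            break
        h1, h2 = tail[:half], tail[half: 2 * half]
        m1, se1 = block_average(h1, n_blocks_half)
        m2, se2 = block_average(h2, n_blocks_half)
        pooled = np.hypot(se1, se2)
        scale = max(abs(m1), abs(m2), 1.0)
        if abs(m1 - m2) <= 2.0 * pooled + 1e-12 * scale:
            return float(t[i])
    raise ValueError(
        "no plateau found: series still drifting; extend the simulation"
    )


def build_curve(series_per_strain, L_per_strain=None, tail_window_ns=None,
                tail_fraction: float = 1.0 / 3.0, mode: str = "fixed",
                n_blocks: int = 10) -> StressStrainCurve:
    """Reduce per-strain stress series to a stress-strain curve.

    ``series_per_strain`` maps strain -> :class:`StressSeries` and must
    include the zero-strain reference.  In the default fixed-window mode the
    final ``tail_window_ns`` (or ``tail_fraction`` of the span) is averaged,
    mirroring the use of the final stretch of long constant-strain runs;
    ``mode='auto'`` instead starts the window at the detected equilibration
    time.  sigma0 is subtracted per series; ``L_per_strain`` (strain ->
    end-to-end distance, nm) attaches L/L0.
    """
    items = sorted(series_per_strain.items())
    eps_values = [e for e, _ in items]
    if len(set(eps_values)) != len(eps_values):
        raise ValueError("duplicate strain values")
    if 0.0 not in eps_values:
        raise ValueError("missing eps=0 reference series (L0 undefined)")
    L0 = None
    if L_per_strain is not None:
        if 0.0 not in L_per_strain:
            raise ValueError("L_per_strain must include eps=0 (L0)")
        L0 = L_per_strain[0.0]
    points = []
    for eps, series in items:
        t = series.times
        if mode == "auto":
            t_start = detect_equilibration(series)
        else:
            window = tail_window_ns
            if window is None:
                window = (t[-1] - t[0]) * tail_fraction
            t_start = t[-1] - window
        sel = t >= t_start - 1e-12
        if sel.sum() < n_blocks:
            raise ValueError(f"tail window too short at eps={eps}")
        mean, se = block_average(series.sigma_parallel[sel], n_blocks)
        lol0 = None
        if L0 is not None and eps in L_per_strain:
            lol0 = L_per_strain[eps] / L0
        points.append(StressStrainPoint(eps, mean - series.sigma0, se, lol0))
    return StressStrainCurve(points)


def fit_youngs_modulus(curve: StressStrainCurve, eps_max: float = 0.05):
    """Zero-intercept Hooke fit sigma = E * eps over 0 < eps <= eps_max.

    Weighted least squares with weights 1/se^2 when all selected points have
    se > 0, otherwise unweighted.  The fit SE propagates the per-point
    standard errors through the estimator (known-variance convention); for
    an unweighted fit it falls back to the residual-based OLS estimate.
    Stores E on the curve and returns ``(E, se_E)``.
    """
    sel = [p for p in curve.points if 0.0 < p.epsilon <= eps_max + 1e-12]
    if not sel:
        raise ValueError(f"no points with 0 < eps <= {eps_max}")
    x = np.array([p.epsilon for p in sel])
    y = np.array([p.mean_stress for p in sel])
    se = np.array([p.se for p in sel])
    if np.all(se > 0):
        w = 1.0 / se**2
        E = float(np.sum(w * x * y) / np.sum(w * x**2))
        se_E = float(np.sqrt(1.0 / np.sum(w * x**2)))
    else:
        E = float(np.sum(x * y) / np.sum(x**2))
        if len(x) > 1:
            resid = y - E * x
            s2 = float(np.sum(resid**2) / (len(x) - 1))
            se_E = float(np.sqrt(s2 / np.sum(x**2)))
        else:
            se_E = 0.0
    curve.youngs_modulus = E
    curve.youngs_modulus_se = se_E
    return E, se_E


def slippage_profile(curve: StressStrainCurve) -> dict:
    """Per-strain slippage s(eps) = 1 - (L/L0 - 1)/eps for eps > 0.

    s = 0 means the monomer elongates affinely with the cell (no sliding);
    s = 1 means the cell elongates entirely by monomers sliding past each
    other.  The eps = 0 point is skipped (undefined ratio).
    """
    out = {}
    for p in curve.points:
        if p.epsilon <= 0.0 or p.L_over_L0 is None:
            continue
        out[p.epsilon] = float(1.0 - (p.L_over_L0 - 1.0) / p.epsilon)
    if not out:
        raise ValueError("no positive-strain points with end-to-end data")
    return out
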