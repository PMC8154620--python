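"""Thermodynamic and kinetic decomposition of the coil-globule transition.

Equilibrium side: the equilibrium constant K_eq = p_globule / p_coil at
each temperature gives the transition free energy dG(T) = -R T ln K_eq,
and the temperature series is decomposed into a temperature-independent
enthalpy and entropy with the van't Hoff relation

    ln K_eq = -dH / (R T) + dS / R,

fit by ordinary least squares in the linearising coordinates
(ln K_eq vs 1/T).  The transition temperature T* = dH / dS is where
dG crosses zero.

Kinetic side: forward/backward rates come from mean first passage times
of the (hidden) Markov model, and their temperature dependence is fit
with an Eyring-type law with a linear frequency factor,

    k(T) = c T exp(-dG_dagger / (R T)),

again by OLS on ln(k/T) vs 1/T.  Both fits report the r^2 of the
linearised regression and of the back-transformed curve.

Uncertainties throughout are replica leave-one-out (LOO) spreads:
min / Q1 / Q3 / max of the estimate over subsets that exclude one
replica at a time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .constants import R_GAS, R_GAS_KJ

__all__ = [
    "equilibrium_constant",
    "free_energy",
    "VantHoffFit",
    "vant_hoff_fit",
    "EyringFit",
    "eyring_fit",
    "rates_from_mfpt",
    "FreeEnergyProfile",
    "free_energy_profile",
    "loo_cross_validate",
]


def equilibrium_constant(
    labels: np.ndarray | Sequence, pseudocount: bool = False
) -> float:
    """K_eq = N_globule / N_coil from per-frame macrostate labels.

    Labels may be the strings "coil"/"globule" or integers 0 (coil) /
    1 (globule).  ``pseudocount=True`` adds one frame to each count
    (Laplace), which keeps K_eq finite at temperatures where one state
    is never visited.
    """
    labels = np.asarray(labels)
    if labels.dtype.kind in "iub":
        n_glob = int((labels == 1).sum())
        n_coil = int((labels == 0).sum())
    else:
        n_glob = int((labels == "globule").sum())
        n_coil = int((labels == "coil").sum())
    if pseudocount:
        n_glob += 1
        n_coil += 1
    if n_coil == 0 or n_glob == 0:
        raise ValueError(
            "K_eq undefined: a macrostate has zero frames (use pseudocount=True)"
        )
    return n_glob / n_coil


def free_energy(K_eq: float, temperature: float) -> float:
    """dG = -R T ln K_eq in kJ/mol."""
    if K_eq <= 0 or temperature <= 0:
        raise ValueError("K_eq and temperature must be positive")
    return -R_GAS_KJ * temperature * np.log(K_eq)


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


@dataclass
class VantHoffFit:
    """Temperature-independent (dH, dS) decomposition of K_eq(T)."""

    dH: float  # kJ/mol
    dS: float  # J/(mol K)
    T_star: float | None  # K, dH/dS; None when undefined
    r_squared_linear: float  # on ln K vs 1/T
    r_squared_hyperbolic: float  # on K vs T after back-transform
    temperatures: np.ndarray = field(repr=False)
    K_eq: np.ndarray = field(repr=False)
    loo_spread: dict = field(default_factory=dict)

    def predict_lnK(self, T: np.ndarray) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return -self.dH * 1000.0 / (R_GAS * T) + self.dS / R_GAS

    def predict_K(self, T: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_lnK(T))

    def predict_dG(self, T: np.ndarray) -> np.ndarray:
        """dG(T) = dH - T dS in kJ/mol for the fitted model."""
        T = np.asarray(T, dtype=float)
        return self.dH - T * self.dS / 1000.0


def vant_hoff_fit(
    temperatures: np.ndarray, K_eq: np.ndarray
) -> VantHoffFit:
    """OLS of ln K_eq on 1/T; dH = -slope*R, dS = intercept*R."""
    T = np.asarray(temperatures, dtype=float)
    K = np.asarray(K_eq, dtype=float)
    if np.unique(T).size < 3:
        raise ValueError("need >= 3 distinct temperatures")
    if (K <= 0).any() or (T <= 0).any():
        raise ValueError("temperatures and K_eq must be positive")
    x = 1.0 / T
    y = np.log(K)
    slope, intercept = np.polyfit(x, y, 1)
    dH = -slope * R_GAS / 1000.0  # kJ/mol
    dS = intercept * R_GAS  # J/(mol K)
    T_star = dH * 1000.0 / dS if dS != 0 else None
    if T_star is not None and T_star <= 0:
        warnings.warn(
            f"T* = dH/dS = {T_star:.4g} K is unphysical (dH, dS opposite signs)",
            stacklevel=2,
        )
        T_star = None
    fit = VantHoffFit(
        dH=dH,
        dS=dS,
        T_star=T_star,
        r_squared_linear=_r_squared(y, slope * x + intercept),
        r_squared_hyperbolic=0.0,
        temperatures=T,
        K_eq=K,
    )
    fit.r_squared_hyperbolic = _r_squared(K, fit.predict_K(T))
    return fit


@dataclass
class EyringFit:
    """Transition-state decomposition of a rate-temperature series."""

    dG_dagger: float  # kJ/mol
    c: float  # 1/(ns K): frequency-factor slope, A(T) = c T
    r_squared_linear: float  # on ln(k/T) vs 1/T
    r_squared_exponential: float  # on k vs T after back-transform
    temperatures: np.ndarray = field(repr=False)
    rates: np.ndarray = field(repr=False)
    loo_spread: dict = field(default_factory=dict)

    def predict_rate(self, T: np.ndarray) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return self.c * T * np.exp(-self.dG_dagger * 1000.0 / (R_GAS * T))


def eyring_fit(temperatures: np.ndarray, rates: np.ndarray) -> EyringFit:
    """OLS of ln(k/T) on 1/T; dG_dagger = -slope*R, c = exp(intercept).

    Non-positive rates are excluded with a warning.
    """
    T = np.asarray(temperatures, dtype=float)
    k = np.asarray(rates, dtype=float)
    good = k > 0
    if not good.all():
        warnings.warn(
            f"excluding {int((~good).sum())} non-positive rate(s) from the Eyring fit",
            stacklevel=2,
        )
        T, k = T[good], k[good]
    if np.unique(T).size < 3:
        raise ValueError("need >= 3 distinct temperatures with positive rates")
    x = 1.0 / T
    y = np.log(k / T)
    slope, intercept = np.polyfit(x, y, 1)
    fit = EyringFit(
        dG_dagger=-slope * R_GAS / 1000.0,
        c=float(np.exp(intercept)),
        r_squared_linear=_r_squared(y, slope * x + intercept),
        r_squared_exponential=0.0,
        temperatures=T,
        rates=k,
    )
    fit.r_squared_exponential = _r_squared(k, fit.predict_rate(T))
    return fit


def rates_from_mfpt(
    transition_matrix: np.ndarray,
    macrostates: np.ndarray | Sequence[str],
    lag: int = 1,
    frame_spacing: float = 1.0,
    stationary: np.ndarray | None = None,
) -> tuple[float, float]:
    """(k_forward, k_backward) in 1/ns from mean first passage times.

    ``macrostates`` assigns each state of the matrix to "coil" or
    "globule"; forward is coil -> globule, and each rate is the
    reciprocal MFPT.
    """
    from .msm import mfpt

    macro = np.asarray(macrostates)
    coil = np.flatnonzero(macro == "coil")
    glob = np.flatnonzero(macro == "globule")
    if coil.size == 0 or glob.size == 0:
        raise ValueError("both macrostates must be populated")
    t_fwd = mfpt(transition_matrix, coil, glob, lag, frame_spacing, stationary)
    t_bwd = mfpt(transition_matrix, glob, coil, lag, frame_spacing, stationary)
    return 1.0 / t_fwd, 1.0 / t_bwd


@dataclass
class FreeEnergyProfile:
    """Boltzmann-inverted free energy along Rg, parabola-aligned at the flank."""

    bin_centers: np.ndarray  # nm
    free_energy: np.ndarray  # kJ/mol, aligned
    counts: np.ndarray
    temperature: float
    alignment_offset: float  # kJ/mol subtracted by the flank alignment
    flank_fit: tuple[float, float, float] | None = None  # parabola a, b, c


def free_energy_profile(
    rg: np.ndarray,
    temperature: float,
    bin_width: float = 0.02,
    min_count: int = 10,
    flank_margin: float = 0.1,
) -> FreeEnergyProfile:
    """F(Rg) = -R T ln p_hat(Rg), aligned by a right-flank parabola fit.

    Bins with fewer than ``min_count`` frames are dropped.  The parabola
    is fit to bins at Rg >= (Rg of the global F minimum) + ``flank_margin``
    (nm); all profiles built this way can be overlaid by construction,
    since each is shifted so its fitted parabola minimum sits at zero.
    Falls back to a minimum-at-zero shift when the flank has fewer than
    3 bins.
    """
    rg = np.asarray(rg, dtype=float)
    lo = np.floor(rg.min() / bin_width) * bin_width
    hi = np.ceil(rg.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, _ = np.histogram(rg, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts >= min_count
    if keep.sum() < 10:
        raise ValueError(
            f"only {int(keep.sum())} occupied bins (need >= 10); "
            "reduce bin_width or min_count"
        )
    centers, counts = centers[keep], counts[keep]
    p = counts / counts.sum()
    F = -R_GAS_KJ * temperature * np.log(p)

    rg_min = centers[np.argmin(F)]
    flank = centers >= rg_min + flank_margin
    fit_params = None
    if flank.sum() >= 3:
        a, b, c = np.polyfit(centers[flank], F[flank], 2)
        if a > 0:
            offset = c - b * b / (4 * a)  # parabola value at its vertex
            fit_params = (float(a), float(b), float(c))
        else:  # concave fit: no usable flank curvature
            offset = float(F.min())
    else:
        offset = float(F.min())
    return FreeEnergyProfile(
        bin_centers=centers,
        free_energy=F - offset,
        counts=counts,
        temperature=temperature,
        alignment_offset=float(offset),
        flank_fit=fit_params,
    )


def loo_cross_validate(
    replica_ids: Sequence, estimator: Callable[[list], float]
) -> dict:
    """Leave-one-replica-out spread of a scalar estimator.

    ``estimator`` receives the list of replica ids to include and
    returns the estimate.  Returns min/Q1/Q3/max (quartiles by linear
    interpolation) plus the raw values; subsets on which the estimator
    fails are skipped and recorded.
    """
    replica_ids = list(replica_ids)
    if len(replica_ids) < 3:
        raise ValueError("need >= 3 replicas for leave-one-out")
    values, failed = [], []
    for r in replica_ids:
        subset = [x for x in replica_ids if x != r]
        try:
            values.append(float(estimator(subset)))
        except Exception as err:  # noqa: BLE001 - estimator failures are data-driven
            warnings.warn(f"LOO subset without replica {r} failed: {err}", stacklevel=2)
            failed.append(r)
    if not values:
        raise ValueError("estimator failed on every LOO subset")
    q1, q3 = np.percentile(values, [25, 75])
    return {
        "min": float(min(values)),
        "q1": float(q1),
        "q3": float(q3),
        "max": float(max(values)),
        "values": values,
        "failed_replicas": failed,
    }
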