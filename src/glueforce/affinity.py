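"""One-site saturation binding fits and K_D -> ΔG_bin conversion.

Ternary-complex formation is read out by a TR-FRET-style titration: signal
ratio vs glue (or protein) concentration.  The one-site binding isotherm

    y(c) = Y_max * c / (K_D + c)

is fitted by least squares, optionally with Y_max constrained to a reference
value (the convention used when comparing mutants against the wild-type
ternary complex, whose saturated signal defines Y_max).  K_D converts to a
binding free energy at 1 M standard state, ΔG_bin = RT ln(K_D / 1 M).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import rt

__all__ = [
    "TitrationCurve",
    "BindingFit",
    "fit_saturation",
    "kd_to_deltaG",
    "synthetic_titration",
]


@dataclass(frozen=True)
class TitrationCurve:
    """Ligand concentration (M, strictly increasing) vs signal ratio."""

    concentrations: np.ndarray
    signals: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "signals", y)
        if c.size < 4:
            raise ValueError("a titration curve needs at least 4 points")
        if c.shape != y.shape:
            raise ValueError("concentrations and signals must align")
        if np.any(c <= 0):
            raise ValueError("concentrations must be > 0")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("signals must be finite")


@dataclass(frozen=True)
class BindingFit:
    """Result of a one-site saturation fit."""

    k_d: float  # M
    y_max: float
    y_max_fixed: bool
    rss: float
    k_d_se: float  # standard error from the fit's local curvature
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.k_d > 0:
            raise ValueError("k_d must be > 0")


def _isotherm(c, k_d, y_max):
    return y_max * c / (k_d + c)


def _grid_search(curve: TitrationCurve, y_max: float | None, n: int = 2001):
    """Dense log-grid RSS minimizer; initializer and non-convergence fallback."""
    c, y = curve.concentrations, curve.signals
    kd_grid = np.logspace(np.log10(c[0]) - 3, np.log10(c[-1]) + 3, n)
    if y_max is None:
        # optimal y_max for fixed k_d is the least-squares amplitude
        frac = c[None, :] / (kd_grid[:, None] + c[None, :])
        amp = (frac @ y) / np.einsum("ij,ij->i", frac, frac)
        rss = ((y[None, :] - amp[:, None] * frac) ** 2).sum(axis=1)
        i = int(np.argmin(rss))
        return float(kd_grid[i]), float(amp[i]), float(rss[i])
    pred = _isotherm(c[None, :], kd_grid[:, None], y_max)
    rss = ((y[None, :] - pred) ** 2).sum(axis=1)
    i = int(np.argmin(rss))
    return float(kd_grid[i]), float(y_max), float(rss[i])


def fit_saturation(
    curve: TitrationCurve,
    y_max: float | None = None,
    n_starts: int = 7,
) -> BindingFit:
    """Least-squares fit of y = Y_max c / (K_D + c).

    When ``y_max`` is given only K_D is free (constrained-maximum convention);
    it must exceed half the largest observed signal.  The optimizer is
    multi-started from a log-spaced K_D grid; if no start converges, a dense
    grid-search estimate is returned with ``converged=False``.
    """
    c, y = curve.concentrations, curve.signals
    if y_max is not None and y_max <= 0.5 * y.max():
        raise ValueError(
            f"fixed y_max ({y_max}) must exceed half the largest signal ({y.max()})"
        )
    starts = np.logspace(np.log10(c[0]) - 2, np.log10(c[-1]) + 2, n_starts)
    best = None
    for kd0 in starts:
        try:
            if y_max is None:
                popt, pcov = curve_fit(
                    _isotherm,
                    c,
                    y,
                    p0=[kd0, max(y.max(), 1e-12)],
                    bounds=([1e-300, 1e-300], [np.inf, np.inf]),
                    maxfev=10000,
                )
                kd, ym = popt
            else:
                popt, pcov = curve_fit(
                    lambda cc, kd: _isotherm(cc, kd, y_max),
                    c,
                    y,
                    p0=[kd0],
                    bounds=(1e-300, np.inf),
                    maxfev=10000,
                )
                kd, ym = popt[0], y_max
        except RuntimeError:
            continue
        rss = float(((y - _isotherm(c, kd, ym)) ** 2).sum())
        if best is None or rss < best[2]:
            se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
            best = (float(kd), float(ym), rss, se)
    if best is None:
        warnings.warn(
            f"saturation fit did not converge for {curve.label!r}; "
            "reporting grid-search estimate"
        )
        kd, ym, rss = _grid_search(curve, y_max)
        return BindingFit(
            k_d=kd,
            y_max=ym,
            y_max_fixed=y_max is not None,
            rss=rss,
            k_d_se=np.nan,
            converged=False,
        )
    kd, ym, rss, se = best
    return BindingFit(
        k_d=kd, y_max=ym, y_max_fixed=y_max is not None, rss=rss, k_d_se=se
    )


def kd_to_deltaG(k_d: float, temperature: float = 298.0) -> float:
    """Binding free energy ΔG_bin = RT ln(K_D / 1 M), kcal/mol.

    Standard state 1 M: ΔG_bin = 0 at K_D = 1 M and is negative for any
    sub-molar dissociation constant (~ -8.2 kcal/mol at K_D = 1 µM, 298 K).
    """
    if not k_d > 0:
        raise ValueError(f"k_d must be > 0 M, got {k_d}")
    return rt(temperature) * float(np.log(k_d))


def synthetic_titration(
    k_d: float,
    y_max: float,
    concentrations=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> TitrationCurve:
    """Generate a titration curve from the one-site isotherm.

    Default concentrations are 12 log-spaced points spanning K_D/100 to
    100*K_D (well into saturation); ``noise_sd`` adds i.i.d. Gaussian noise in
    signal units (e.g. 0.02*y_max for 2% noise).
    """
    if concentrations is None:
        concentrations = np.logspace(np.log10(k_d) - 2, np.log10(k_d) + 2, 12)
    c = np.asarray(concentrations, dtype=float)
    y = _isotherm(c, k_d, y_max)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=c.shape)
    return TitrationCurve(concentrations=c, signals=y, label=label)
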