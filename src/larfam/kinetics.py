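"""Enzyme-kinetics fitting: saturation curves, competitive inhibition, optima.

Models
------
* saturation: ``v = kcat * [E] * S / (Km + S)``
* competitive inhibition: ``v = kcat * [E] * S / (Km * (1 + I/Ki) + S)``

Units are declared once per dataset: substrate/inhibitor concentrations in
mM, enzyme concentration in µM, rates in µM/s, so ``kcat = Vmax / [E]`` is
in s⁻¹ and ``kcat/Km`` in s⁻¹·mM⁻¹.

Nonlinear least squares is initialised from the Hanes–Woolf linearisation
(deterministic, derivative-free start) and refined with
``scipy.optimize.curve_fit``; 95% confidence intervals are linearised (Wald)
half-widths with the t-quantile at ``n - p`` degrees of freedom. Rates that
are zero or negative after blank subtraction are retained in the loss, not
clipped, to avoid biasing low-substrate fits.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KineticsPoint:
    """One initial-rate measurement."""

    S: float  # substrate, mM
    v: float  # rate, µM/s
    I: Optional[float] = None  # inhibitor, mM (None when absent)
    replicate: int = 0

    def __post_init__(self):
        if self.S <= 0:
            raise ValidationError(f"substrate concentration must be > 0, got {self.S}")
        if self.I is not None and self.I < 0:
            raise ValidationError(f"inhibitor concentration must be >= 0, got {self.I}")


@dataclass(frozen=True)
class KineticsDataset:
    """Initial-rate measurements plus the assay's enzyme concentration."""

    points: tuple  # tuple[KineticsPoint, ...]
    enzyme_conc: float  # µM
    substrate: str = ""
    inhibitor: Optional[str] = None
    rate_unit: str = "uM/s"

    def __post_init__(self):
        if not self.points:
            raise ValidationError("kinetics dataset must contain at least one point")
        if self.enzyme_conc <= 0:
            raise ValidationError("enzyme concentration must be > 0")

    def arrays(self):
        S = np.array([p.S for p in self.points])
        v = np.array([p.v for p in self.points])
        I = np.array([0.0 if p.I is None else p.I for p in self.points])
        return S, I, v

    @property
    def has_inhibitor(self) -> bool:
        return any(p.I is not None and p.I > 0 for p in self.points)


@dataclass(frozen=True)
class MMFit:
    """Fitted saturation parameters with 95% Wald half-widths."""

    km: float  # mM
    kcat: float  # s^-1
    ci95_km: float
    ci95_kcat: float
    n_points: int
    rss: float

    def __post_init__(self):
        if self.km <= 0 or self.kcat <= 0:
            raise FitError(
                f"fitted parameters must be positive (km={self.km}, kcat={self.kcat})"
            )

    @property
    def efficiency(self) -> float:
        """kcat / Km in s⁻¹·mM⁻¹, always the quotient of the fitted values."""
        return self.kcat / self.km

    def to_dict(self) -> dict:
        return {
            "km_mM": self.km,
            "kcat_per_s": self.kcat,
            "ci95_km": self.ci95_km,
            "ci95_kcat": self.ci95_kcat,
            "efficiency_per_s_per_mM": self.efficiency,
            "n_points": self.n_points,
            "rss": self.rss,
        }


@dataclass(frozen=True)
class KiFit:
    """Fitted competitive-inhibition constant."""

    ki: float  # mM
    ci95_ki: float
    km: float
    kcat: float
    cofitted: bool
    n_points: int
    rss: float

    def __post_init__(self):
        if self.ki <= 0:
            raise FitError(f"fitted Ki must be positive, got {self.ki}")

    def to_dict(self) -> dict:
        return {
            "ki_mM": self.ki,
            "ci95_ki": self.ci95_ki,
            "km_mM": self.km,
            "kcat_per_s": self.kcat,
            "cofitted": self.cofitted,
            "n_points": self.n_points,
            "rss": self.rss,
        }


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _hanes_woolf_init(S: np.ndarray, v: np.ndarray):
    """Deterministic (Vmax, Km) start values from the S/v vs S regression."""
    mask = v > 0
    if mask.sum() < 2:
        return float(max(v.max(), 1e-9)), float(np.median(S))
    y = S[mask] / v[mask]
    slope, intercept = np.polyfit(S[mask], y, 1)
    if slope <= 0:
        vmax0 = float(v.max() * 1.2)
    else:
        vmax0 = float(1.0 / slope)
    km0 = intercept * vmax0 if intercept > 0 else float(np.median(S))
    return max(vmax0, 1e-9), max(float(km0), 1e-9)


def _wald_halfwidths(pcov: np.ndarray, n: int, n_params: int) -> np.ndarray:
    dof = max(n - n_params, 1)
    tq = stats.t.ppf(0.975, dof)
    return tq * np.sqrt(np.diag(pcov))


def fit_mm(data: KineticsDataset) -> MMFit:
    """Nonlinear least-squares fit of the saturation model (no inhibitor).

    Degrees of freedom for the 95% intervals are ``n - 2``. Fewer than 3
    distinct substrate levels, or levels that do not straddle the fitted Km,
    trigger a warning (the estimate is then poorly constrained).
    """
    if data.has_inhibitor:
        raise FitError("dataset contains inhibitor; use fit_ki_competitive")
    S, _, v = data.arrays()
    if np.all(v == 0):
        raise FitError("all rates are zero; nothing to fit")
    distinct = np.unique(S)
    if distinct.size < 3:
        logger.warning("only %d distinct substrate level(s); fit is fragile", distinct.size)
    vmax0, km0 = _hanes_woolf_init(S, v)

    def model(s, vmax, km):
        return vmax * s / (km + s)

    try:
        popt, pcov = optimize.curve_fit(
            model, S, v, p0=[vmax0, km0], maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(f"saturation fit did not converge: {exc}",
                       last_iterate={"vmax0": vmax0, "km0": km0}) from exc
    vmax, km = popt
    if vmax <= 0 or km <= 0:
        raise FitError(
            f"saturation fit converged to non-physical parameters "
            f"(vmax={vmax}, km={km})",
            last_iterate={"vmax": vmax, "km": km},
        )
    if not (distinct.min() < km < distinct.max()):
        logger.warning(
            "substrate levels [%g, %g] do not straddle fitted Km=%g",
            distinct.min(), distinct.max(), km,
        )
    resid = v - model(S, *popt)
    half = _wald_halfwidths(pcov, len(S), 2)
    kcat = vmax / data.enzyme_conc
    return MMFit(
        km=float(km),
        kcat=float(kcat),
        ci95_km=float(half[1]),
        ci95_kcat=float(half[0] / data.enzyme_conc),
        n_points=len(S),
        rss=float(resid @ resid),
    )


def fit_ki_competitive(
    data: KineticsDataset,
    km: Optional[float] = None,
    kcat: Optional[float] = None,
    cofit: bool = False,
) -> KiFit:
    """Fit the competitive-inhibition constant Ki.

    Either supply ``km``/``kcat`` from a prior saturation fit (1-parameter
    fit of Ki; default), or set ``cofit=True`` to estimate (Km, kcat, Ki)
    jointly — the latter needs uninhibited points (I = 0) in the dataset.
    """
    S, I, v = data.arrays()
    if not data.has_inhibitor:
        raise FitError("no inhibited points (I > 0) in dataset")
    E = data.enzyme_conc
    if not cofit:
        if km is None or kcat is None:
            # Fall back to a saturation fit on the uninhibited subset.
            base = [p for p in data.points if not p.I]
            if len(base) < 3:
                raise FitError(
                    "supply km/kcat, or include >= 3 uninhibited points, "
                    "or use cofit=True"
                )
            mm = fit_mm(
                KineticsDataset(tuple(base), E, data.substrate, None, data.rate_unit)
            )
            km, kcat = mm.km, mm.kcat
        vmax = kcat * E

        def model(x, ki):
            s, i = x
            return vmax * s / (km * (1 + i / ki) + s)

        ki0 = max(float(np.median(I[I > 0])), 1e-9)
        try:
            popt, pcov = optimize.curve_fit(
                model, (S, I), v, p0=[ki0], maxfev=10000
            )
        except RuntimeError as exc:
            raise FitError(f"Ki fit did not converge: {exc}",
                           last_iterate={"ki0": ki0}) from exc
        ki = float(popt[0])
        resid = v - model((S, I), *popt)
        half = _wald_halfwidths(pcov, len(S), 1)
        return KiFit(
            ki=ki, ci95_ki=float(half[0]), km=float(km), kcat=float(kcat),
            cofitted=False, n_points=len(S), rss=float(resid @ resid),
        )

    if not np.any(I == 0):
        raise FitError("cofit requires uninhibited (I = 0) points")
    base = S[I == 0], v[I == 0]
    vmax0, km0 = _hanes_woolf_init(*base)
    ki0 = max(float(np.median(I[I > 0])), 1e-9)

    def model(x, vmax, km_, ki):
        s, i = x
        return vmax * s / (km_ * (1 + i / ki) + s)

    try:
        popt, pcov = optimize.curve_fit(
            model, (S, I), v, p0=[vmax0, km0, ki0], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"cofit did not converge: {exc}",
                       last_iterate={"vmax0": vmax0, "km0": km0, "ki0": ki0}) from exc
    vmax, km_, ki = popt
    resid = v - model((S, I), *popt)
    half = _wald_halfwidths(pcov, len(S), 3)
    return KiFit(
        ki=float(ki), ci95_ki=float(half[2]), km=float(km_),
        kcat=float(vmax / E), cofitted=True,
        n_points=len(S), rss=float(resid @ resid),
    )


def catalytic_efficiency(fit: MMFit) -> float:
    """kcat/Km in s⁻¹·mM⁻¹ — always the self-consistent quotient."""
    return fit.efficiency


def round_efficiency(value: float) -> float:
    """Report rounding for efficiency columns.

    Values of at least 10 are printed to the nearest integer; smaller values
    to two significant figures — mirroring how the family's kinetics tables
    are typeset.
    """
    if value <= 0 or not math.isfinite(value):
        return value
    if value >= 10:
        return float(round(value))
    digits = 2 - 1 - math.floor(math.log10(abs(value)))
    return round(value, digits)


# ---------------------------------------------------------------------------
# Activity optimum
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivityProfile:
    """Activity (arbitrary units) versus pH or temperature."""

    points: tuple  # tuple[(x, activity), ...], x strictly increasing

    def __post_init__(self):
        xs = [x for x, _ in self.points]
        if not xs:
            raise ValidationError("activity profile is empty")
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValidationError("x values must be strictly increasing")


@dataclass(frozen=True)
class OptimumRange:
    low: float
    high: float


def optimum_range(profile: ActivityProfile, fraction: float = 0.90) -> OptimumRange:
    """Smallest/largest measured x with activity strictly above fraction*max.

    The maximal point always qualifies, so a profile with a single dominant
    point collapses to a degenerate range at that point.
    """
    if not 0 <= fraction < 1:
        raise ValidationError(f"fraction must be in [0, 1), got {fraction}")
    activities = [a for _, a in profile.points]
    peak = max(activities)
    qualifying = [x for x, a in profile.points if a > fraction * peak]
    if not qualifying:  # only possible when peak <= 0
        x_peak = next(x for x, a in profile.points if a == peak)
        return OptimumRange(x_peak, x_peak)
    return OptimumRange(min(qualifying), max(qualifying))


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def fit_report(fits: Mapping[str, object], path=None):
    """Serialise a mapping of fit labels to MMFit/KiFit as JSON."""
    payload = {label: fit.to_dict() for label, fit in sorted(fits.items())}
    for label, entry in payload.items():
        if "efficiency_per_s_per_mM" in entry:
            entry["efficiency_rounded"] = round_efficiency(
                entry["efficiency_per_s_per_mM"]
            )
    if path is None:
        return payload
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
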