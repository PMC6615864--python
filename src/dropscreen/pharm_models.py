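"""Pharmacology curve fitting and combination analysis.

* Four-parameter logistic (4PL) dose-response curves on the viability scale
  (% of untreated), with GI_p extraction by exact algebraic inversion:
  ``y = bottom + (top - bottom) / (1 + 10^{(log10 x - logIC50) * hill})``,
  so a positive hill slope means the response falls with dose (the usual
  inhibitor orientation) and y(IC50) = (top + bottom)/2.
* Bliss-independence synergy surfaces over a concentration grid: observed
  fractional inhibition versus the independence expectation
  ``I_a + I_b - I_a I_b`` from the single-agent margins, reported in
  percentage points with the peak and its coordinates (positive = synergy).
* One-site saturation binding ``y = Bmax x / (Kd + x)``.

All fits are deterministic: least squares from a fixed, data-derived set of
starting points, best RSS wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DropscreenError, ValidationError


# ---------------------------------------------------------------------------
# 4PL dose-response
# ---------------------------------------------------------------------------


def four_pl(
    x: np.ndarray | float, top: float, bottom: float, log_ic50: float, hill: float
) -> np.ndarray | float:
    """4PL response at concentration(s) x (> 0)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((np.log10(x) - log_ic50) * hill))


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with standard errors and residual sum of squares."""

    top: float
    bottom: float
    log_ic50: float
    hill: float
    se: dict = field(default_factory=dict)
    rss: float = float("nan")
    normalized: bool = False
    degenerate: bool = False

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50

    def predict(self, x) -> np.ndarray:
        return four_pl(x, self.top, self.bottom, self.log_ic50, self.hill)


def fit_4pl(
    dose: Sequence[float],
    response: Sequence[float],
    normalized: bool = False,
) -> FourPLFit:
    """Least-squares 4PL fit.

    ``normalized=True`` fixes top=100 and bottom=0 (response already scaled
    to % of untreated) and needs >= 2 distinct doses; the free fit needs
    >= 4.  Initialisation is deterministic: top/bottom from the data
    extremes, logIC50 candidates from the dose range, hill in {+1, -1};
    the start with the best final RSS wins.  Flat data yields a flagged
    degenerate fit with hill ~ 0.
    """
    x = np.asarray(dose, dtype=float)
    y = np.asarray(response, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("doses must be positive")
    n_distinct = np.unique(x).size
    if normalized and n_distinct < 2:
        raise DropscreenError("normalized 4PL fit needs >= 2 distinct doses")
    if not normalized and n_distinct < 4:
        raise DropscreenError("free 4PL fit needs >= 4 distinct doses")
    lx = np.log10(x)
    mid = (lx.min() + lx.max()) / 2.0
    l_starts = sorted({lx.min(), mid, lx.max(), float(np.median(lx))})

    if np.ptp(y) < 1e-12:
        return FourPLFit(
            top=float(y.mean()), bottom=float(y.mean()), log_ic50=mid, hill=0.0,
            rss=float(np.sum((y - y.mean()) ** 2)), normalized=normalized,
            degenerate=True,
        )

    if normalized:
        def model(params):
            return four_pl(x, 100.0, 0.0, params[0], params[1]) - y
        starts = [(l0, h0) for l0 in l_starts for h0 in (1.0, -1.0)]
        unpack = lambda p: (100.0, 0.0, p[0], p[1])
    else:
        t0, b0 = float(y.max()), float(y.min())

        def model(params):
            return four_pl(x, params[0], params[1], params[2], params[3]) - y
        starts = [(t0, b0, l0, h0) for l0 in l_starts for h0 in (1.0, -1.0)]
        unpack = lambda p: tuple(p)

    best = None
    for p0 in starts:
        res = optimize.least_squares(model, x0=np.array(p0), method="lm", max_nfev=2000)
        rss = float(2 * res.cost)
        if best is None or rss < best[0] - 1e-14:
            best = (rss, res)
    rss, res = best
    top, bottom, lic50, hill = unpack(res.x)
    # canonicalise so bottom <= top (flip sign of hill accordingly)
    if bottom > top:
        top, bottom, hill = bottom, top, -hill
    se = _least_squares_se(res)
    names = ("log_ic50", "hill") if normalized else ("top", "bottom", "log_ic50", "hill")
    return FourPLFit(
        top=float(top), bottom=float(bottom), log_ic50=float(lic50), hill=float(hill),
        se=dict(zip(names, se)), rss=rss, normalized=normalized,
        degenerate=abs(hill) < 1e-6,
    )


def _least_squares_se(res) -> np.ndarray:
    """Parameter standard errors from the Jacobian at the optimum."""
    m, p = res.jac.shape
    dof = max(m - p, 1)
    s2 = 2 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        return np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def gi_value(fit: FourPLFit, p: float) -> float:
    """Concentration giving ``p``% growth inhibition (response = 100 - p).

    Inverts the fitted 4PL exactly; GI_50 equals the IC50 for a normalized
    fit.  ``p`` must correspond to a response strictly between the fitted
    asymptotes.
    """
    if fit.degenerate or fit.hill == 0:
        raise DropscreenError("cannot invert a flat (degenerate) dose-response fit")
    y = 100.0 - p
    lo, hi = min(fit.top, fit.bottom), max(fit.top, fit.bottom)
    if not lo < y < hi:
        raise DropscreenError(
            f"target response {y} is outside the fitted asymptotes "
            f"({fit.bottom:.3g}, {fit.top:.3g})"
        )
    ratio = (fit.top - y) / (y - fit.bottom)
    return float(10.0 ** (fit.log_ic50 + np.log10(ratio) / fit.hill))


# ---------------------------------------------------------------------------
# Bliss synergy
# ---------------------------------------------------------------------------


@dataclass
class SynergySurface:
    """Observed/expected/synergy matrices over a dose grid (A rows, B columns)."""

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray       # observed fractional inhibition in [0, 1]
    expected: np.ndarray         # Bliss independence expectation
    synergy: np.ndarray          # 100 * (observed - expected), percentage points
    clamped: bool = False        # any viability > 100% clamped to I = 0

    @property
    def peak(self) -> tuple[float, float, float]:
        """(S_max, dose_A, dose_B) of the most synergistic combination."""
        i, j = np.unravel_index(np.argmax(self.synergy), self.synergy.shape)
        return float(self.synergy[i, j]), float(self.doses_a[i]), float(self.doses_b[j])


def bliss_surface(
    viability: np.ndarray | pd.DataFrame | Sequence[np.ndarray | pd.DataFrame],
    doses_a: Sequence[float] | None = None,
    doses_b: Sequence[float] | None = None,
    control_tolerance: float = 5.0,
) -> SynergySurface:
    """Bliss-independence synergy from a % viability matrix with margins.

    Layout: row 0 = drug B alone (dose A = 0), column 0 = drug A alone,
    cell (0, 0) = untreated, which must be 100% within
    ``control_tolerance``.  A list of replicate matrices is averaged before
    the surface is computed.  Viability above 100% is clamped (inhibition
    floor 0) and flagged.
    """
    if isinstance(viability, (list, tuple)):
        mats = [np.asarray(getattr(v, "values", v), dtype=float) for v in viability]
        if len({m.shape for m in mats}) != 1:
            raise DropscreenError("replicate matrices must share a shape")
        V = np.mean(mats, axis=0)
    else:
        if isinstance(viability, pd.DataFrame):
            if doses_a is None:
                doses_a = viability.index.to_numpy(dtype=float)
            if doses_b is None:
                doses_b = viability.columns.to_numpy(dtype=float)
            V = viability.to_numpy(dtype=float)
        else:
            V = np.asarray(viability, dtype=float)
    if V.ndim != 2 or V.shape[0] < 2 or V.shape[1] < 2:
        raise DropscreenError("viability matrix must be 2-D with single-agent margins")
    if abs(V[0, 0] - 100.0) > control_tolerance:
        raise DropscreenError(
            f"untreated cell (0,0) = {V[0, 0]:.1f}%, expected ~100%"
        )
    if doses_a is None:
        doses_a = np.arange(V.shape[0], dtype=float)
    if doses_b is None:
        doses_b = np.arange(V.shape[1], dtype=float)
    clamped = bool(np.any(V > 100.0))
    if clamped:
        warnings.warn("viability above 100% clamped to zero inhibition")
    I = np.clip(1.0 - V / 100.0, 0.0, 1.0)
    ia = I[:, 0][:, None]
    ib = I[0, :][None, :]
    expected = ia + ib - ia * ib
    synergy = 100.0 * (I - expected)
    return SynergySurface(
        doses_a=np.asarray(doses_a, dtype=float),
        doses_b=np.asarray(doses_b, dtype=float),
        inhibition=I,
        expected=expected,
        synergy=synergy,
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# One-site binding
# ---------------------------------------------------------------------------


@dataclass
class BindingFit:
    """One-site specific binding fit: y = Bmax x / (Kd + x)."""

    bmax: float
    kd: float
    se: dict = field(default_factory=dict)
    rss: float = float("nan")
    degenerate: bool = False

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.bmax * x / (self.kd + x)


def fit_one_site(x: Sequence[float], y: Sequence[float]) -> BindingFit:
    """Least-squares saturation-binding fit with deterministic multi-start.

    Needs >= 3 distinct concentrations.  Kd is constrained positive; the
    half-saturation point of the fitted curve is Kd by construction
    (y(Kd) = Bmax/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0):
        raise ValidationError("concentrations must be non-negative")
    if np.unique(x).size < 3:
        raise DropscreenError("one-site fit needs >= 3 distinct concentrations")
    if np.allclose(y, 0.0):
        return BindingFit(bmax=0.0, kd=float(np.median(x[x > 0]) or 1.0),
                          rss=0.0, degenerate=True)

    def model(params):
        bmax, kd = params
        return bmax * x / (kd + x) - y

    bmax0 = float(y.max())
    pos = x[x > 0]
    half = bmax0 / 2.0
    # deterministic Kd starts: interpolated half-max crossing plus dose scales
    kd_starts = {float(np.median(pos)), float(pos.min()), float(pos.max())}
    crossing = np.interp(half, np.sort(y), x[np.argsort(y)]) if y.max() > 0 else None
    if crossing and crossing > 0:
        kd_starts.add(float(crossing))
    best = None
    for kd0 in sorted(kd_starts):
        res = optimize.least_squares(
            model, x0=np.array([bmax0 if bmax0 > 0 else 1.0, kd0]),
            bounds=([0.0, 1e-12], [np.inf, np.inf]), max_nfev=2000,
        )
        rss = float(2 * res.cost)
        if best is None or rss < best[0] - 1e-14:
            best = (rss, res)
    rss, res = best
    se = _least_squares_se(res)
    return BindingFit(
        bmax=float(res.x[0]), kd=float(res.x[1]),
        se={"bmax": se[0], "kd": se[1]}, rss=rss,
        degenerate=not np.isfinite(res.x[1]),
    )
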