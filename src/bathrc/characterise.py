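"""Component characterisation from bench recordings.

Two procedures:

* **Restrictor characterisation** -- fit the pressure drop across a component
  against the mean of the two flowmeter readings with the quadratic law
  ``dp = K2 Qm^2 + K1 Qm + K0`` (turbulent + laminar losses), its linear
  restriction (``K2 = 0``) or the proportional one (``K2 = K0 = 0``).  With a
  proportional fit K1 *is* the component's resistance.  Fitting is
  iteratively reweighted least squares with Tukey bi-square weights
  (tuning constant 4.685) for outlier rejection, or plain least squares.

* **R/C estimation** -- recover a patient's airway resistance and compliance
  (or the tubing compliance from a blocked-line run) from recorded pressure
  and flow, using the single-compartment pressure balance
  ``p(t) = p0 + R q(t) + V(t)/C`` with ``V`` the running integral of flow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np
import statsmodels.api as sm
from scipy.integrate import cumulative_trapezoid
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .exceptions import (
    ConvergenceError,
    EstimationError,
    InvalidParameterError,
    RankDeficiencyError,
)

ModelKind = Literal["quadratic", "linear", "proportional"]

__all__ = [
    "FlowPressureSample",
    "RestrictorFit",
    "LungEstimate",
    "mean_flow",
    "fit_restrictor",
    "estimate_lung_rc",
    "estimate_tube_compliance",
]

#: Tukey bi-square tuning constant (95% Gaussian efficiency), the common
#: default of robust-fitting tools.
BISQUARE_C = 4.685


class FlowPressureSample(NamedTuple):
    """One co-registered (mean flow, pressure drop) observation."""

    q_mean: float  # L/s; negative during expiratory flow
    dp: float  # cmH2O


@dataclass(frozen=True)
class RestrictorFit:
    """Fitted pressure-drop law of a flow component.

    ``k1`` of a proportional fit is the component resistance in
    cmH2O/(L/s).  ``r_squared`` is computed against the uncentred total sum
    of squares for the no-intercept (proportional) model and against the
    centred one otherwise; both variants are always available.
    """

    model_kind: ModelKind
    k2: float
    k1: float
    k0: float
    r_squared: float
    r_squared_centred: float
    r_squared_uncentred: float
    ci_95: dict[str, tuple[float, float]]
    n_samples: int
    robust: bool
    weights: np.ndarray

    @property
    def resistance(self) -> float:
        """Alias for k1; meaningful for proportional fits."""
        return self.k1


@dataclass(frozen=True)
class LungEstimate:
    """Single-compartment R/C estimate with its regression diagnostics."""

    r: float
    c: float
    baseline: float
    residual_rms: float


def mean_flow(q_a, q_b):
    """Mean of the two flowmeter readings (the flow through the component)."""
    return 0.5 * (np.asarray(q_a, dtype=float) + np.asarray(q_b, dtype=float))


# ---------------------------------------------------------------------------
# Restrictor fits
# ---------------------------------------------------------------------------

_TERMS = {
    "quadratic": ("k2", "k1", "k0"),
    "linear": ("k1", "k0"),
    "proportional": ("k1",),
}


def _design(q: np.ndarray, model_kind: ModelKind) -> np.ndarray:
    cols = {"k2": q**2, "k1": q, "k0": np.ones_like(q)}
    return np.column_stack([cols[t] for t in _TERMS[model_kind]])


def fit_restrictor(
    q_mean,
    dp,
    model_kind: ModelKind = "quadratic",
    robust: bool = True,
) -> RestrictorFit:
    """Fit ``dp = K2 q^2 + K1 q + K0`` (or a constrained form) to samples.

    Parameters
    ----------
    q_mean, dp : array_like
        Mean flow (L/s) and pressure drop (cmH2O); inspiratory and
        expiratory samples are pooled (flow may be negative).
    model_kind : {"quadratic", "linear", "proportional"}
        Which coefficients are free; the constrained ones are exactly zero.
    robust : bool
        Tukey bi-square IRLS (outlier rejection) if True, ordinary least
        squares otherwise.  On outlier-free data the two coincide.
    """
    if model_kind not in _TERMS:
        raise InvalidParameterError(f"unknown model_kind {model_kind!r}")
    q = np.asarray(q_mean, dtype=float).ravel()
    y = np.asarray(dp, dtype=float).ravel()
    if q.shape != y.shape:
        raise InvalidParameterError("q_mean and dp must have the same length")
    if q.size < 3:
        raise InvalidParameterError(f"need >= 3 samples, got {q.size}")
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("samples must be finite")
    if np.ptp(q) == 0:
        raise RankDeficiencyError("all flow values are equal: degenerate design")
    x = _design(q, model_kind)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise RankDeficiencyError("design matrix is rank deficient")

    if robust:
        model = sm.RLM(y, x, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
        with warnings.catch_warnings():
            # a perfect fit drives the IRLS scale to zero; that is benign
            warnings.simplefilter("ignore", ConvergenceWarning)
            res = model.fit(maxiter=100, tol=1e-8, conv="coefs")
        try:
            weights = np.asarray(res.weights, dtype=float)
        except AttributeError:  # IRLS exited on a perfect fit before weighting
            weights = np.ones_like(y)
    else:
        res = sm.OLS(y, x).fit()
        weights = np.ones_like(y)
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)):
        raise ConvergenceError("restrictor fit did not converge", residual=np.nan)

    coeffs = dict.fromkeys(("k2", "k1", "k0"), 0.0)
    ci = {}
    conf = np.asarray(res.conf_int(alpha=0.05), dtype=float)
    for j, term in enumerate(_TERMS[model_kind]):
        coeffs[term] = float(params[j])
        ci[term] = (float(conf[j, 0]), float(conf[j, 1]))

    resid = y - x @ params
    ss_res = float(resid @ resid)
    ss_unc = float(y @ y)
    ss_cen = float(((y - y.mean()) ** 2).sum())
    r2_unc = 1.0 - ss_res / ss_unc if ss_unc > 0 else np.nan
    r2_cen = 1.0 - ss_res / ss_cen if ss_cen > 0 else np.nan
    r2 = r2_unc if model_kind == "proportional" else r2_cen
    return RestrictorFit(
        model_kind=model_kind,
        k2=coeffs["k2"],
        k1=coeffs["k1"],
        k0=coeffs["k0"],
        r_squared=float(r2),
        r_squared_centred=float(r2_cen),
        r_squared_uncentred=float(r2_unc),
        ci_95=ci,
        n_samples=int(q.size),
        robust=robust,
        weights=weights,
    )


# ---------------------------------------------------------------------------
# R/C estimation from waveforms
# ---------------------------------------------------------------------------


def _breath_starts(pressure: np.ndarray, min_gap: int) -> np.ndarray:
    """Indices where the pressure rises through its midline (breath onsets)."""
    thr = 0.5 * (pressure.min() + pressure.max())
    raw = np.flatnonzero((pressure[:-1] < thr) & (pressure[1:] >= thr)) + 1
    starts: list[int] = []
    for idx in raw:
        if not starts or idx - starts[-1] >= min_gap:
            starts.append(int(idx))
    return np.asarray(starts, dtype=int)


def _detrended_volume(flow: np.ndarray, dt: float, starts: np.ndarray) -> np.ndarray:
    """Running integral of flow with the breath-to-breath drift removed.

    Integration noise accumulates as a random walk; anchoring a piecewise
    linear baseline at the breath onsets and subtracting it removes the
    drift without touching the within-breath volume excursion.
    """
    v = cumulative_trapezoid(flow, dx=dt, initial=0.0)
    baseline = np.interp(np.arange(v.size), starts, v[starts])
    return v - baseline


def estimate_lung_rc(pressure, flow, dt: float) -> LungEstimate:
    """Estimate airway resistance and compliance from one recording.

    Least-squares fit of the single-compartment pressure balance

        p(t) = baseline + R q(t) + V(t)/C

    where ``V`` is the running (per-breath detrended) integral of flow.
    Needs co-registered, uniformly sampled series covering at least three
    full breaths.
    """
    p = np.asarray(pressure, dtype=float).ravel()
    q = np.asarray(flow, dtype=float).ravel()
    if p.shape != q.shape:
        raise InvalidParameterError("pressure and flow must have the same length")
    if dt <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    if np.ptp(q) == 0:
        raise RankDeficiencyError(
            "flow has no variation (e.g. identically zero): cannot estimate R and C"
        )
    min_gap = max(2, int(round(0.3 / dt)))
    starts = _breath_starts(p, min_gap)
    if starts.size < 3:
        raise EstimationError(
            f"detected only {starts.size} breaths; need >= 3 full breaths"
        )
    v = _detrended_volume(q, dt, starts)
    x = np.column_stack([np.ones_like(q), q, v])
    if np.linalg.matrix_rank(x) < 3:
        raise RankDeficiencyError("collinear regressors in R/C estimation")
    coef, *_ = np.linalg.lstsq(x, p, rcond=None)
    baseline, r, inv_c = (float(c) for c in coef)
    if inv_c <= 0:
        raise EstimationError(
            f"non-physical compliance (1/C = {inv_c:.3g} <= 0); "
            "check channel signs and registration"
        )
    resid = p - x @ coef
    return LungEstimate(
        r=r,
        c=1.0 / inv_c,
        baseline=baseline,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def estimate_tube_compliance(
    pressure, flow, dt: float, dp_floor: float = 1.0
) -> float:
    """Tubing compliance from a blocked-line recording.

    With the line blocked all delivered gas is stored in the tubing, so the
    integrated flow tracks the node pressure exactly: the volume delivered
    from the expiratory trough to the inspiratory plateau equals Cv times the
    pressure swing.  Per breath, the pressure change is taken between the
    means of the plateau samples (top quartile of the swing) and the trough
    samples (bottom quartile), the delivered volume between the means of the
    integrated flow over the same samples -- averaging that cancels sampling
    noise without assuming where within a sample interval the phase switch
    fell.  The compliance is the through-origin regression slope of the
    per-breath volumes on the per-breath pressure changes.

    Raises :class:`EstimationError` when the pressure swing stays below
    ``dp_floor`` (cmH2O): too small a swing makes the ratio unreliable.
    """
    p = np.asarray(pressure, dtype=float).ravel()
    q = np.asarray(flow, dtype=float).ravel()
    if p.shape != q.shape:
        raise InvalidParameterError("pressure and flow must have the same length")
    if dt <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    lo, hi = float(p.min()), float(p.max())
    if hi - lo < dp_floor:
        raise EstimationError(
            f"pressure swing {hi - lo:.3g} cmH2O below the {dp_floor:g} cmH2O "
            "floor: compliance estimate unreliable"
        )
    min_gap = max(2, int(round(0.3 / dt)))
    starts = _breath_starts(p, min_gap)
    if starts.size < 3:
        raise EstimationError(
            f"detected only {starts.size} breaths; need >= 3 full breaths"
        )
    v = cumulative_trapezoid(q, dx=dt, initial=0.0)
    thr_hi = lo + 0.75 * (hi - lo)
    thr_lo = lo + 0.25 * (hi - lo)
    dps: list[float] = []
    dvs: list[float] = []
    for a, b in zip(starts[:-1], starts[1:]):
        pp, vv = p[a:b], v[a:b]
        high = pp >= thr_hi
        low = pp <= thr_lo
        if high.sum() < 2 or low.sum() < 2:
            continue
        dps.append(float(pp[high].mean() - pp[low].mean()))
        dvs.append(float(vv[high].mean() - vv[low].mean()))
    dps_arr = np.asarray(dps)
    dvs_arr = np.asarray(dvs)
    if dps_arr.size == 0 or np.max(np.abs(dps_arr)) < dp_floor:
        raise EstimationError(
            f"per-phase pressure change below {dp_floor:g} cmH2O: "
            "compliance estimate unreliable"
        )
    return float(dvs_arr @ dps_arr / (dps_arr @ dps_arr))
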