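"""Equilibrium binding-curve fits.

One-site saturation binding, S(L) = Bmax * L / (Kd + L), fitted by
unweighted nonlinear least squares — the standard analysis of pull-down
and microtubule co-sedimentation titrations.  The model assumes no
ligand depletion (free ~ total concentration); a depletion-aware
quadratic variant is available for bead-bound assays at sub-µM Kd
where that assumption can fail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

KD_BOUNDS = (1e-4, 1e4)  # µM


@dataclass
class BindingFit:
    """Fitted one-site parameters with uncertainty.

    ``kd`` is the dissociation constant (µM, ligand concentration at
    half-maximal binding); ``bmax`` the saturation signal.  Standard
    errors come from the fit covariance.  ``converged`` is False when
    the optimiser failed or ``kd`` stuck at a bound; such fits carry a
    diagnostic ``message`` instead of silently passing downstream.
    """

    kd: float
    bmax: float
    kd_se: float
    bmax_se: float
    residual_sd: float
    n_points: int
    concentrations: np.ndarray = field(repr=False, default=None)
    signals: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    message: str = ""
    model: str = "hyperbola"

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.bmax * conc / (self.kd + conc)


def _hyperbola(conc, bmax, kd):
    return bmax * conc / (kd + conc)


def _quadratic_depletion(receptor_total: float):
    # fraction of receptor bound when free ligand is depleted by binding
    def f(conc, bmax, kd):
        s = receptor_total + conc + kd
        return bmax * (s - np.sqrt(s * s - 4 * receptor_total * conc)) / (2 * receptor_total)
    return f


def fit_one_site(concentrations, signals, normalize: bool = False, *,
                 weights: np.ndarray | None = None,
                 model: str = "hyperbola",
                 receptor_total: float | None = None) -> BindingFit:
    """Least-squares fit of a one-site saturation binding curve.

    ``kd`` is initialised at the concentration whose signal is nearest
    half-maximal and ``bmax`` at the maximal observed signal; ``kd`` is
    bounded to (1e-4, 1e4) µM.  With ``normalize=True`` the returned
    fit is rescaled so signals are fractions of the fitted maximum
    (bmax = 1); ``kd`` is unaffected.  ``weights`` are per-point
    standard deviations passed to the least-squares routine (e.g.
    proportional to signal for relative weighting).  ``model`` may be
    ``'quadratic'`` (requires ``receptor_total``, µM) for
    ligand-depletion-aware fits.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    sig = np.asarray(list(signals), dtype=float)
    if conc.shape != sig.shape:
        raise ValueError("concentrations and signals must have equal length")
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.any(sig < 0):
        raise ValueError("signals must be >= 0")
    if model == "hyperbola":
        fun = _hyperbola
    elif model == "quadratic":
        if receptor_total is None or receptor_total <= 0:
            raise ValueError("model='quadratic' requires receptor_total > 0")
        fun = _quadratic_depletion(receptor_total)
    else:
        raise ValueError(f"unknown model {model!r}")

    smax = float(sig.max())
    if smax <= 0:
        raise ValueError("all signals are zero; nothing to fit")
    kd0 = float(conc[np.argmin(np.abs(sig - smax / 2))])
    kd0 = min(max(kd0, KD_BOUNDS[0] * 10), KD_BOUNDS[1] / 10)
    p0 = [smax, kd0]
    bounds = ([0.0, KD_BOUNDS[0]], [np.inf, KD_BOUNDS[1]])
    converged = True
    message = ""
    try:
        popt, pcov = curve_fit(fun, conc, sig, p0=p0, bounds=bounds,
                               sigma=weights, absolute_sigma=False,
                               maxfev=20000)
    except RuntimeError as exc:
        return BindingFit(kd=float("nan"), bmax=float("nan"), kd_se=float("nan"),
                          bmax_se=float("nan"), residual_sd=float("nan"),
                          n_points=len(conc), concentrations=conc, signals=sig,
                          converged=False, message=f"fit failed: {exc}",
                          model=model)
    bmax, kd = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.diag(pcov))
    bmax_se, kd_se = float(perr[0]), float(perr[1])
    resid = sig - fun(conc, *popt)
    dof = max(len(conc) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    if kd <= KD_BOUNDS[0] * 1.01 or kd >= KD_BOUNDS[1] * 0.99:
        converged = False
        message = f"kd at bound ({kd:.4g} µM); the data do not constrain the fit"
    else:
        pos = conc[conc > 0]
        if kd > 100 * pos.max() or kd < 0.01 * pos.min():
            converged = False
            message = (f"kd = {kd:.4g} µM lies far outside the sampled "
                       f"concentration range [{pos.min():.4g}, {pos.max():.4g}]; "
                       "saturation is not constrained by the data")
    if normalize:
        sig = sig / bmax
        residual_sd /= bmax
        bmax_se /= bmax
        bmax = 1.0
    return BindingFit(kd=kd, bmax=bmax, kd_se=kd_se, bmax_se=bmax_se,
                      residual_sd=residual_sd, n_points=len(conc),
                      concentrations=conc, signals=sig, converged=converged,
                      message=message, model=model)


def fit_cosedimentation(mt_concentrations, fraction_sedimented) -> BindingFit:
    """Fit f(M) = fmax * M / (Kd + M) to co-sedimentation fractions.

    ``mt_concentrations`` in µM tubulin dimer; fractions must lie in
    [0, 1].  The returned ``bmax`` is the saturating fraction fmax.
    """
    frac = np.asarray(list(fraction_sedimented), dtype=float)
    if np.any(frac < 0) or np.any(frac > 1):
        raise ValueError("fraction_sedimented values must lie in [0, 1]")
    return fit_one_site(mt_concentrations, frac)


def kd_shift_ratio(fit_a: BindingFit, fit_b: BindingFit) -> tuple[float, float, bool]:
    """Kd ratio (b over a) with first-order (delta-method) standard error.

    Returns (ratio, se, ok); ``ok`` is False when either input fit is
    flagged, in which case the ratio is still computed but should not
    be trusted.
    """
    ok = fit_a.converged and fit_b.converged
    ratio = fit_b.kd / fit_a.kd
    rel_var = 0.0
    for f in (fit_a, fit_b):
        if f.kd > 0 and np.isfinite(f.kd_se):
            rel_var += (f.kd_se / f.kd) ** 2
    se = abs(ratio) * math.sqrt(rel_var)
    return float(ratio), float(se), ok
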