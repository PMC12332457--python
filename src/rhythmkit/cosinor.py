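"""Extended (antilogistically transformed) cosinor model.

The model is ``r(t) = minimum + amplitude * l(c(t))`` where
``c(t) = cos((t - phi) * pi/12)`` is the classic 24-h cosine and
``l(c) = exp(beta*(c - alpha)) / (1 + exp(beta*(c - alpha)))`` is a logistic
squash of the cosine.  ``alpha`` controls whether peaks are wider than
troughs (negative alpha: wide peaks, narrow troughs) and ``beta`` the
steepness of the rise and fall, with large beta approaching a square wave.

Derived quantities:

* MESOR = minimum + amplitude/2 — the rhythm midline, attained where
  ``c(t) = alpha``;
* acrotime = phi expressed in clock hours (the curve maximum);
* UpMesor / DownMesor = phi -/+ (12/pi) * arccos(alpha) mod 24 — the
  ascending / descending MESOR crossings, surrogates for activity onset and
  offset;
* F_pseudo = ((RSS0 - RSS)/4) / (RSS/(n-5)) against the intercept-only
  null — an index of rhythm robustness, not a calibrated F test.

Fitting pools all valid days with clock time as the sole predictor,
minimizing squared error with bounds (amplitude >= 0, |alpha| < 1,
0 < beta <= 100) from four phase starts seeded by the closed-form linear
cosinor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

logger = logging.getLogger(__name__)

_ALPHA_EPS = 1e-6
_DEGENERATE_AMP = 1e-3


def classic_cosine(t, acrophase):
    """24-h period cosine, value 1 at ``t == acrophase`` (clock hours)."""
    return np.cos((np.asarray(t, dtype=float) - acrophase) * np.pi / 12.0)


def antilogistic(c, alpha, beta):
    """Logistic transform of the cosine, in (0, 1); 0.5 at ``c == alpha``."""
    return expit(beta * (np.asarray(c, dtype=float) - alpha))


def evaluate_model(t, minimum, amplitude, alpha, beta, acrophase):
    """r(t) = minimum + amplitude * l(c(t))."""
    return minimum + amplitude * antilogistic(classic_cosine(t, acrophase), alpha, beta)


@dataclass
class CosinorFit:
    minimum: float
    amplitude: float
    alpha: float
    beta: float
    acrotime: float        # phi in clock hours [0, 24)
    acrophase_rad: float   # phi in radians
    mesor: float
    up_mesor: float
    down_mesor: float
    f_pseudo: float
    rss: float
    n_obs: int
    converged: bool
    degenerate: bool

    def predict(self, t):
        return evaluate_model(
            t, self.minimum, self.amplitude, self.alpha, self.beta, self.acrotime
        )


def derive_phase_metrics(
    minimum: float, amplitude: float, alpha: float, acrotime: float
) -> dict[str, float]:
    """MESOR and the MESOR-crossing clock times of the fitted curve.

    mesor = minimum + amplitude/2; up/down mesor = phi -/+ (12/pi)*arccos(alpha)
    mod 24.  Phase metrics are undefined when |alpha| >= 1.
    """
    mesor = minimum + amplitude / 2.0
    if abs(alpha) >= 1.0:
        logger.info("phase metrics undefined: |alpha| >= 1")
        return {
            "mesor": mesor,
            "up_mesor": np.nan,
            "down_mesor": np.nan,
            "acrotime": acrotime % 24.0,
        }
    half_width = (12.0 / np.pi) * np.arccos(alpha)
    return {
        "mesor": mesor,
        "up_mesor": (acrotime - half_width) % 24.0,
        "down_mesor": (acrotime + half_width) % 24.0,
        "acrotime": acrotime % 24.0,
    }


def _linear_cosinor_start(t: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Closed-form classic cosinor: returns (mean level, amplitude, phi)."""
    w = np.pi / 12.0
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    m, a, b = coef
    amp = float(np.hypot(a, b))
    phi = float(np.arctan2(b, a) / w) % 24.0
    return float(m), amp, phi


def fit_extended_cosinor(
    t: np.ndarray,
    values: np.ndarray,
    beta_max: float = 100.0,
) -> CosinorFit:
    """Least-squares fit of the extended cosinor to a masked stream.

    ``t`` is clock time in hours (day boundaries irrelevant, period 24);
    ``values`` may contain NaN (dropped).  Four phase starts around the
    linear-cosinor solution; the best residual sum of squares wins.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values) & ~np.isnan(t)
    t, x = t[ok], values[ok]
    n = len(x)
    nan_fit = CosinorFit(
        *([np.nan] * 11), n_obs=n, converged=False, degenerate=True
    )
    if n < 10:
        logger.info("cosinor fit skipped: only %d observations", n)
        return nan_fit

    mean_level, amp_lin, phi_lin = _linear_cosinor_start(t, x)
    rss0 = float(np.sum((x - x.mean()) ** 2))
    if rss0 == 0:
        logger.info("cosinor fit skipped: constant stream")
        return nan_fit

    def residuals(params):
        mn, amp, alpha, beta, phi = params
        return evaluate_model(t, mn, amp, alpha, beta, phi) - x

    x_lo, x_hi = float(x.min()), float(x.max())
    span = max(x_hi - x_lo, 1e-6)
    best = None
    for offset in (0.0, 6.0, 12.0, 18.0):
        phi0 = (phi_lin + offset) % 24.0
        p0 = [
            max(mean_level - amp_lin, x_lo - span),
            min(max(2.0 * amp_lin, 1e-3), 3.0 * span),
            0.0,
            2.0,
            phi0,
        ]
        lower = [x_lo - 2.0 * span, 0.0, -1.0 + _ALPHA_EPS, 1e-3, phi0 - 12.0]
        upper = [x_hi + 2.0 * span, 4.0 * span, 1.0 - _ALPHA_EPS, beta_max, phi0 + 12.0]
        p0 = np.clip(p0, lower, upper)
        try:
            res = least_squares(
                residuals, p0, bounds=(lower, upper), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=2000,
            )
        except Exception:  # singular Jacobian etc. from a bad start
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, res)
    if best is None:
        logger.info("cosinor fit failed from all starts")
        return nan_fit

    rss, res = best
    mn, amp, alpha, beta, phi = res.x
    phi = float(phi % 24.0)
    degenerate = amp < _DEGENERATE_AMP
    phase = derive_phase_metrics(mn, amp, alpha, phi)
    dof = n - 5
    f_pseudo = ((rss0 - rss) / 4.0) / (rss / dof) if rss > 0 and dof > 0 else np.inf
    return CosinorFit(
        minimum=float(mn),
        amplitude=float(amp),
        alpha=float(alpha),
        beta=float(beta),
        acrotime=phi if not degenerate else np.nan,
        acrophase_rad=phi * np.pi / 12.0 if not degenerate else np.nan,
        mesor=phase["mesor"],
        up_mesor=phase["up_mesor"] if not degenerate else np.nan,
        down_mesor=phase["down_mesor"] if not degenerate else np.nan,
        f_pseudo=float(f_pseudo),
        rss=rss,
        n_obs=n,
        converged=bool(res.success),
        degenerate=bool(degenerate),
    )


def plot_fit(fit: CosinorFit, t, values, ax=None):
    """Observed hourly means and the fitted curve over one 24-h cycle."""
    import matplotlib.pyplot as plt  # optional dependency

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = np.asarray(t, dtype=float) % 24.0
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    hours = np.floor(t[ok]).astype(int)
    means = [values[ok][hours == h].mean() if (hours == h).any() else np.nan for h in range(24)]
    ax.scatter(np.arange(24) + 0.5, means, s=18, color="0.3", label="hourly mean")
    grid = np.linspace(0, 24, 481)
    ax.plot(grid, fit.predict(grid), color="tab:green", label="extended cosinor")
    ax.axhline(fit.mesor, ls=":", color="tab:gray", label="MESOR")
    ax.set_xlabel("clock hour")
    ax.set_xlim(0, 24)
    ax.legend(loc="best", fontsize=8)
    return ax
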