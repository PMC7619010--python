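"""Response models and cross-level relations.

Contrast-response functions (CRFs) are described by Hill functions
R = R_max * S^h / (S^h + S_1/2^h).  The maximum contrast gain (MCG) is the
slope of an ordinary-least-squares line through the CRF sampled at 11
contrasts spanning a 20% window (+/-10% around C_1/2; 15-35% for the
behavior).  Information efficiency E (bits/vesicle) versus release rate R
(vesicles/s) follows a power law E = a * R^b fitted in log-log coordinates.
Cross-level correlations (per-condition neural metric vs behavioral MCG) are
reported as Pearson r and Spearman rho with two-sided p-values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ContrastResponseFunction",
    "HillFit",
    "GainFit",
    "PowerLawFit",
    "CorrelationResult",
    "fit_hill",
    "measure_mcg",
    "coarse_then_fine",
    "fit_power_law",
    "pool_efficiency",
    "correlate_levels",
]


@dataclass
class ContrastResponseFunction:
    """Mean response (+/- SEM across fish or synapses) per contrast."""

    contrasts: np.ndarray   # %
    responses: np.ndarray
    sems: np.ndarray | None = None
    n: np.ndarray | None = None

    def __post_init__(self):
        self.contrasts = np.asarray(self.contrasts, float)
        self.responses = np.asarray(self.responses, float)
        if self.contrasts.shape != self.responses.shape:
            raise ValueError("contrasts and responses must align")
        if self.sems is not None:
            self.sems = np.asarray(self.sems, float)
            if self.sems.shape != self.contrasts.shape or np.any(self.sems < 0):
                raise ValueError("SEMs must align and be >= 0")


@dataclass
class HillFit:
    r_max: float
    h: float
    c_half: float          # %
    covariance: np.ndarray
    extrapolated: bool = False

    def predict(self, contrast) -> np.ndarray:
        c = np.asarray(contrast, float)
        return self.r_max * c**self.h / (c**self.h + self.c_half**self.h)


@dataclass
class GainFit:
    mcg: float             # response units per % contrast
    intercept: float
    contrast_window: tuple

    def __post_init__(self):
        lo, hi = self.contrast_window
        if abs((hi - lo) - 20.0) > 1e-6:
            raise ValueError("MCG window must span 20% contrast")


@dataclass
class PowerLawFit:
    a: float               # prefactor
    b: float               # exponent
    r_domain: tuple        # (min, max) release rate fitted

    def predict(self, r) -> np.ndarray:
        return self.a * np.asarray(r, float) ** self.b


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int


def _hill(c, r_max, h, c_half):
    return r_max * c**h / (c**h + c_half**h)


def fit_hill(crf: ContrastResponseFunction, weighted: bool = True) -> HillFit:
    """Nonlinear least-squares Hill fit of a CRF.

    Initialised from the half-max crossing; bounded h in (0.1, 10],
    C_1/2 in (1, 200]%.  When SEMs are available (and ``weighted``), points
    are weighted by 1/SEM^2.  A fitted C_1/2 outside the sampled contrast
    range is flagged as an extrapolation.
    """
    c = crf.contrasts
    r = crf.responses
    if c.size < 4:
        raise ValueError("need >= 4 contrast points")
    r_max0 = float(r.max())
    half = r_max0 / 2
    above = np.flatnonzero(r >= half)
    c50_0 = float(c[above[0]]) if above.size else float(np.median(c))
    c50_0 = min(max(c50_0, 1.5), 199.0)
    sigma = None
    if weighted and crf.sems is not None and np.all(crf.sems > 0):
        sigma = crf.sems
    popt, pcov = optimize.curve_fit(
        _hill,
        c,
        r,
        p0=[max(r_max0, 1e-9), 2.0, c50_0],
        sigma=sigma,
        absolute_sigma=sigma is not None,
        bounds=([1e-12, 0.1, 1.0], [np.inf, 10.0, 200.0]),
        maxfev=20000,
    )
    fit = HillFit(
        r_max=float(popt[0]),
        h=float(popt[1]),
        c_half=float(popt[2]),
        covariance=pcov,
        extrapolated=not (c.min() <= popt[2] <= c.max()),
    )
    if fit.extrapolated:
        warnings.warn(
            f"fitted C_1/2 = {fit.c_half:.1f}% outside the sampled range", stacklevel=2
        )
    return fit


def measure_mcg(contrasts, responses) -> GainFit:
    """OLS slope of response vs contrast over 11 evenly spaced contrasts
    spanning a 20% window — the maximum contrast gain."""
    c = np.asarray(contrasts, float)
    r = np.asarray(responses, float)
    if c.size != 11:
        raise ValueError("MCG requires exactly 11 contrasts")
    steps = np.diff(np.sort(c))
    if not np.allclose(steps, 2.0, atol=1e-6):
        raise ValueError("MCG contrasts must be evenly spaced over a 20% window")
    slope, intercept = np.polyfit(c, r, 1)
    return GainFit(
        mcg=float(slope),
        intercept=float(intercept),
        contrast_window=(float(c.min()), float(c.max())),
    )


def coarse_then_fine(coarse_crf: ContrastResponseFunction, fine_response_fn) -> GainFit:
    """Synaptic MCG procedure: estimate C_1/2 from a coarse 11-point CRF
    (0-100% contrast), then measure the MCG finely at 11 contrasts within
    +/-10% of C_1/2 via ``fine_response_fn(contrasts) -> responses``.

    The fine window is shifted to stay within [0, 100]% when C_1/2 is within
    10% of either end.
    """
    fit = fit_hill(coarse_crf)
    center = float(np.clip(fit.c_half, 10.0, 90.0))
    window = np.linspace(center - 10.0, center + 10.0, 11)
    responses = np.asarray(fine_response_fn(window), float)
    return measure_mcg(window, responses)


def fit_power_law(efficiency, release_rate) -> PowerLawFit:
    """Least squares of log E on log R: E = a * R^b."""
    e = np.asarray(efficiency, float)
    r = np.asarray(release_rate, float)
    if e.size != r.size or e.size < 5:
        raise ValueError("need >= 5 aligned (E, R) points")
    if np.any(e <= 0) or np.any(r <= 0):
        raise ValueError("E and R must be > 0 for a log-log fit")
    b, log_a = np.polyfit(np.log(r), np.log(e), 1)
    return PowerLawFit(a=float(np.exp(log_a)), b=float(b),
                       r_domain=(float(r.min()), float(r.max())))


def pool_efficiency(release_rate, efficiency, group_size: int = 6):
    """Group synapses by release rate into consecutive blocks of
    ``group_size`` (4-8) and return per-block mean (R, E) points.

    A trailing remainder smaller than ``group_size`` is folded into the last
    block.
    """
    if not (4 <= group_size <= 8):
        raise ValueError("group_size must lie in [4, 8]")
    r = np.asarray(release_rate, float)
    e = np.asarray(efficiency, float)
    order = np.argsort(r)
    r, e = r[order], e[order]
    n_groups = max(r.size // group_size, 1)
    pooled_r = np.empty(n_groups)
    pooled_e = np.empty(n_groups)
    for i in range(n_groups):
        sl = slice(i * group_size, (i + 1) * group_size if i < n_groups - 1 else r.size)
        pooled_r[i] = r[sl].mean()
        pooled_e[i] = e[sl].mean()
    return pooled_r, pooled_e


def _spearman_exact_p(x, y, rho_obs: float) -> float:
    """Two-sided permutation p-value for Spearman's rho (exact for small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = rx.size
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        rho = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def correlate_levels(
    neural_metric, behavioral_mcg, normalize_to: int | None = 0
) -> CorrelationResult:
    """Correlate a per-condition neural metric with the behavioral MCG.

    Behavioral MCGs are normalised to the reference condition (index
    ``normalize_to``, the morning control by convention; None to skip).
    Pearson r is computed on the values and Spearman rho on ranks; the
    Spearman p-value is an exact permutation test for n <= 8, asymptotic
    otherwise.
    """
    x = np.asarray(neural_metric, float)
    y = np.asarray(behavioral_mcg, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 aligned condition points")
    if normalize_to is not None:
        y = y / y[normalize_to]
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    rho = float(sr.statistic)
    if x.size <= 8 and np.isfinite(rho):
        sp = _spearman_exact_p(x, y, rho)
    else:
        sp = float(sr.pvalue)
    return CorrelationResult(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=rho,
        spearman_p=sp,
        n=int(x.size),
    )
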