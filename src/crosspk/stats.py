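"""Paired crossover statistics for drug-interaction endpoints.

Geometric means with level-α confidence intervals, the geometric mean ratio
(GMR) of a paired endpoint with its CI and paired t-test on the log scale,
the regulatory 0.80–1.25 no-effect decision, and noncentral-t sample-size /
power calculations for the paired design parameterised by the intra-subject
coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GMRResult",
    "PairedEndpoint",
    "empirical_power",
    "geometric_mean_ci",
    "no_effect_decision",
    "paired_gmr",
    "power_paired",
    "sample_size_paired",
]

NO_EFFECT_BOUNDS = (0.80, 1.25)
DEFAULT_CI_LEVEL = 0.90


@dataclass(frozen=True)
class PairedEndpoint:
    """Per-subject (baseline, exposure) values of one positive endpoint."""

    endpoint_name: str
    pairs: np.ndarray  # shape (n, 2): columns baseline, exposure

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array of (baseline, exposure)")
        if pairs.shape[0] < 2:
            raise ValueError("a paired analysis needs at least 2 complete pairs")
        if np.any(~np.isfinite(pairs)) or np.any(pairs <= 0):
            raise ValueError("paired endpoint values must be finite and > 0")
        object.__setattr__(self, "pairs", pairs)

    @property
    def n(self) -> int:
        return int(self.pairs.shape[0])


@dataclass
class GMRResult:
    """Geometric mean ratio (exposure/baseline) with CI, p-value and decision."""

    endpoint_name: str
    n: int
    gmr: float
    ci_low: float
    ci_high: float
    p_value: float
    decision: str
    gm_baseline: tuple[float, float, float]
    gm_exposure: tuple[float, float, float]
    level: float = DEFAULT_CI_LEVEL


def geometric_mean_ci(values, level: float = DEFAULT_CI_LEVEL) -> tuple[float, float, float]:
    """Geometric mean with a t-based CI on the log scale.

    gm = exp(mean ln x); CI = exp(mean ± t_{(1+level)/2, n−1} · sd(ln x)/√n).
    """
    x = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("geometric mean requires finite positive values")
    n = x.size
    if n < 2:
        raise ValueError("CI undefined for fewer than 2 values")
    logs = np.log(x)
    mean = logs.mean()
    half = sps.t.ppf(0.5 + level / 2.0, n - 1) * logs.std(ddof=1) / math.sqrt(n)
    return math.exp(mean), math.exp(mean - half), math.exp(mean + half)


def no_effect_decision(
    ci_low: float, ci_high: float, bounds: tuple[float, float] = NO_EFFECT_BOUNDS
) -> str:
    """``no_interaction`` iff the whole CI lies inside the closed no-effect bounds."""
    if ci_low > ci_high:
        raise ValueError("ci_low must be <= ci_high")
    inside = bounds[0] <= ci_low and ci_high <= bounds[1]
    return "no_interaction" if inside else "interaction_possible"


def paired_gmr(
    endpoint: PairedEndpoint,
    level: float = DEFAULT_CI_LEVEL,
    bounds: tuple[float, float] = NO_EFFECT_BOUNDS,
) -> GMRResult:
    """Within-subject GMR analysis of a paired endpoint.

    Works on d_i = ln(exposure_i) − ln(baseline_i): GMR = exp(mean d) with a
    t-based CI, and a two-sided paired t-test of mean d = 0.  With zero
    variance the CI is degenerate at the GMR and the p-value is NaN (1.0
    when the GMR is exactly 1).
    """
    base = endpoint.pairs[:, 0]
    expo = endpoint.pairs[:, 1]
    d = np.log(expo) - np.log(base)
    n = endpoint.n
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        ci_low = ci_high = gmr = math.exp(mean)
        p = 1.0 if mean == 0.0 else math.nan
    else:
        half = sps.t.ppf(0.5 + level / 2.0, n - 1) * sd / math.sqrt(n)
        gmr = math.exp(mean)
        ci_low, ci_high = math.exp(mean - half), math.exp(mean + half)
        tstat = mean / (sd / math.sqrt(n))
        p = 2.0 * sps.t.sf(abs(tstat), n - 1)
    return GMRResult(
        endpoint_name=endpoint.endpoint_name,
        n=n,
        gmr=gmr,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        decision=no_effect_decision(ci_low, ci_high, bounds),
        gm_baseline=geometric_mean_ci(base, level),
        gm_exposure=geometric_mean_ci(expo, level),
        level=level,
    )


# ---------------------------------------------------------------------------
# Power and sample size
# ---------------------------------------------------------------------------

def _effect_size(delta: float, cv: float, convention: str) -> float:
    """Standardised paired effect size.

    ``proportional`` (default): d = delta/cv, treating the detectable change
    and the intra-subject CV both on the proportional scale.  ``log``:
    d = ln(1 + delta) / sqrt(ln(1 + cv²)), the log-normal-exact alternative
    (gives slightly different n).
    """
    if convention == "proportional":
        return delta / cv
    if convention == "log":
        return math.log1p(delta) / math.sqrt(math.log1p(cv * cv))
    raise ValueError(f"unknown effect-size convention {convention!r}")


def power_paired(
    n: int,
    cv: float,
    delta: float = 0.20,
    alpha: float = 0.05,
    convention: str = "proportional",
) -> float:
    """Power of the two-tailed paired t-test at sample size n.

    P(|T'| > t_{1−α/2, n−1}) for a noncentral t with df n−1 and
    noncentrality d·√n, d = delta/cv (see ``_effect_size``).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if cv <= 0 or delta < 0 or not 0 < alpha < 1:
        raise ValueError("require cv > 0, delta >= 0, 0 < alpha < 1")
    df = n - 1
    nc = _effect_size(delta, cv, convention) * math.sqrt(n)
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc))


def sample_size_paired(
    cv: float,
    delta: float = 0.20,
    alpha: float = 0.05,
    power_target: float = 0.80,
    convention: str = "proportional",
    n_max: int = 10**6,
) -> int:
    """Smallest n ≥ 2 whose paired-t power reaches ``power_target``."""
    if not 0 < power_target < 1:
        raise ValueError("power_target must lie in (0, 1)")
    n = 2
    while n <= n_max:
        if power_paired(n, cv, delta, alpha, convention) >= power_target:
            return n
        n += 1
    raise ValueError(f"power {power_target} unattainable within n <= {n_max}")


def empirical_power(
    n: int,
    cv: float,
    true_ratio_shift: float,
    alpha: float = 0.05,
    n_reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo twin of ``power_paired``.

    Draws ``n_reps`` samples of n paired differences ~ Normal(shift, cv) and
    returns the fraction rejected by a two-sided one-sample t-test at α.
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be >= 1000 for a stable estimate")
    rng = np.random.default_rng(seed)
    draws = rng.normal(true_ratio_shift, cv, size=(n_reps, n))
    means = draws.mean(axis=1)
    sds = draws.std(axis=1, ddof=1)
    tstats = means / (sds / math.sqrt(n))
    tcrit = sps.t.ppf(1.0 - alpha / 2.0, n - 1)
    return float(np.mean(np.abs(tstats) > tcrit))
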