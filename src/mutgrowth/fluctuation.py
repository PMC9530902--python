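"""Mutation-rate estimation from fluctuation tests.

The number of resistant mutants across parallel cultures follows the
Luria-Delbrueck (Lea-Coulson) distribution, whose exact pmf is computed by
the Ma-Sandri-Sarkar (MSS) recursion:

    p_0 = exp(-m)
    p_n = (m / n) * sum_{j=0}^{n-1} p_j / (n - j + 1)

(the Panjer recursion for a Poisson(m) number of mutant clones with the
clone-size law P(size = k) = 1/(k(k+1)))

where m is the expected number of mutation events per culture. m is
estimated by maximum likelihood over the pmf (primary) or by the P0 method
m = -ln(fraction of zero-mutant cultures) (fallback/diagnostic), then
converted to a per-bp per-division rate via the CFU-measured final
population size and the mutational target size.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .types import (
    ConfigurationError,
    FluctuationAssay,
    PlateCounts,
    QualityError,
    RateEstimate,
)

#: Default truncation of the pmf support; counts beyond are lumped into the
#: tail mass (jackpot cultures are expected under Luria-Delbrueck sampling).
DEFAULT_N_MAX = 1500

#: Reliable CFU plate window: colony counts outside [10, 500] are discarded.
CFU_MIN, CFU_MAX = 10, 500

_PROFILE_DROP = 1.92  # chi2(1)/2 at 95%


def mss_pmf(m: float, n_max: int) -> np.ndarray:
    """Lea-Coulson pmf p_0..p_n_max by the MSS recursion.

    Returns a vector of length n_max + 1; the mass sums to <= 1 (the
    remainder is the truncated tail).
    """
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    p = np.zeros(n_max + 1)
    p[0] = math.exp(-m)
    if n_max == 0:
        return p
    # Panjer weights: k * P(clone size = k) = 1 / (k + 1)
    w = 1.0 / np.arange(2.0, n_max + 2.0)
    for n in range(1, n_max + 1):
        # convolution term: sum_j p_j * w_{n-j}
        p[n] = (m / n) * float(p[:n] @ w[n - 1 :: -1])
    return p


def estimate_m_p0(mutant_counts: Sequence[int]) -> float:
    """P0 estimator: m = -ln(n_zero / n_total).

    Requires at least one zero-mutant culture; with none the zero fraction
    is uninformative and the caller should use the MLE.
    """
    counts = np.asarray(mutant_counts)
    n_zero = int((counts == 0).sum())
    if n_zero == 0:
        raise ValueError("no zero-mutant cultures: P0 method undefined, use MLE")
    return -math.log(n_zero / counts.size)


def _log_likelihood(m: float, hist: np.ndarray, n_tail: int, n_max: int) -> float:
    p = mss_pmf(m, n_max)
    ll = 0.0
    nz = hist > 0
    if nz.any():
        ll += float(hist[nz] @ np.log(p[: hist.size][nz]))
    if n_tail > 0:
        tail = max(1.0 - p.sum(), 1e-300)
        ll += n_tail * math.log(tail)
    return ll


def estimate_m_mle(
    mutant_counts: Sequence[int],
    n_max: int = DEFAULT_N_MAX,
    ci_level: float = 0.95,
) -> tuple[float, float, float]:
    """MSS maximum-likelihood estimate of m with a profile-likelihood CI.

    Counts above n_max are lumped into the truncated tail mass. Returns
    (m_hat, ci_low, ci_high). All-zero samples sit at the likelihood
    boundary: m_hat = 0 with the one-sided upper bound -ln(alpha)/n from
    p_0^n = e^(-m n).
    """
    counts = np.asarray(mutant_counts, dtype=np.int64)
    if counts.size < 2:
        raise ConfigurationError("need >= 2 cultures")
    if (counts < 0).any():
        raise ConfigurationError("counts must be non-negative")
    alpha = 1.0 - ci_level
    if (counts == 0).all():
        return 0.0, 0.0, -math.log(alpha) / counts.size

    # histogram over the retained support; everything beyond is tail mass
    support = int(min(counts.max(), n_max))
    hist = np.bincount(counts[counts <= support], minlength=support + 1)
    n_tail = int((counts > support).sum())

    def nll(log_m: float) -> float:
        return -_log_likelihood(math.exp(log_m), hist, n_tail, support)

    # seed near the P0 estimate when zeros exist, else near the mean scale
    if (counts == 0).any():
        m0 = max(estimate_m_p0(counts), 1e-3)
    else:
        m0 = max(float(np.median(counts)) / 2.0, 0.5)
    lo, hi = math.log(1e-4), math.log(1e4)
    res = minimize_scalar(
        nll,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    m_hat = math.exp(res.x)
    ll_max = -res.fun

    def profile(m: float) -> float:
        return _log_likelihood(m, hist, n_tail, support) - (ll_max - _PROFILE_DROP)

    ci_low = _bracketed_root(profile, m_hat, direction=-1, limit=math.exp(lo))
    ci_high = _bracketed_root(profile, m_hat, direction=+1, limit=math.exp(hi))
    return m_hat, ci_low, ci_high


def _bracketed_root(f, m_hat: float, direction: int, limit: float) -> float:
    """Root of the profile-likelihood equation on one side of the MLE."""
    m = m_hat
    step = 1.3
    for _ in range(60):
        m = m * step if direction > 0 else m / step
        if (direction > 0 and m >= limit) or (direction < 0 and m <= limit):
            return limit
        if f(m) < 0:
            a, b = (m_hat, m) if direction > 0 else (m, m_hat)
            return float(brentq(f, a, b, xtol=1e-10))
    return limit


def cfu_from_plates(
    plates: PlateCounts, min_count: int = CFU_MIN, max_count: int = CFU_MAX
) -> float:
    """Final population size from CFU plates, keeping only reliable counts.

    Plates with colony counts outside [min_count, max_count] are discarded;
    the estimate is the mean of colony_count / dilution over retained plates.
    """
    kept = [
        c / d
        for d, c in zip(plates.dilutions, plates.colony_counts)
        if min_count <= c <= max_count
    ]
    if not kept:
        raise QualityError(
            f"no reliable plate: all {len(plates)} counts outside "
            f"[{min_count}, {max_count}]"
        )
    return float(np.mean(kept))


def mutation_rate_from_assay(
    assay: FluctuationAssay,
    method: str = "mle",
    n_max: int = DEFAULT_N_MAX,
) -> RateEstimate:
    """Estimate the per-bp per-division mutation rate from one assay.

    mutation_rate = m_hat / (N_final * target_size_bp), with N_final from
    the attached CFU plates (falling back to the generator's recorded truth
    for plate-free synthetic assays). The CI is scaled identically.
    """
    if assay.plate_counts is not None:
        n_final = cfu_from_plates(assay.plate_counts)
    elif assay.n_final_true is not None:
        n_final = assay.n_final_true
    else:
        raise ConfigurationError("assay has neither CFU plates nor known N_final")

    counts = assay.mutant_counts
    scale = n_final * assay.target_size_bp
    if (counts == 0).all():
        m_hat, lo, hi = estimate_m_mle(counts, n_max=n_max)
        return RateEstimate(
            m_hat=0.0,
            mutation_rate=0.0,
            ci_low=0.0,
            ci_high=hi / scale,
            n_final_hat=n_final,
            method="MSS-MLE" if method == "mle" else "P0",
            all_zero=True,
        )

    if method == "p0":
        m_hat = estimate_m_p0(counts)
        lo = hi = float("nan")
        label = "P0"
    elif method == "mle":
        m_hat, lo, hi = estimate_m_mle(counts, n_max=n_max)
        label = "MSS-MLE"
    else:
        raise ConfigurationError(f"unknown method {method!r} (use 'mle' or 'p0')")

    return RateEstimate(
        m_hat=m_hat,
        mutation_rate=m_hat / scale,
        ci_low=lo / scale if math.isfinite(lo) else float("nan"),
        ci_high=hi / scale if math.isfinite(hi) else float("nan"),
        n_final_hat=n_final,
        method=label,
    )


def combine_rate_estimates(
    estimates: Sequence[RateEstimate],
) -> tuple[float, float]:
    """Aggregate replicate assays: mean rate and SE over replicates."""
    if len(estimates) == 0:
        raise ConfigurationError("no estimates to combine")
    rates = np.array([e.mutation_rate for e in estimates])
    mean = float(rates.mean())
    se = float(rates.std(ddof=1) / math.sqrt(rates.size)) if rates.size > 1 else 0.0
    return mean, se
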