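"""Exact binomial majority-vote aggregation over N independent spectra.

A sample is measured N times (N odd) and called ROD when more than N/2 of
its spectra score above 1, normal otherwise. If one spectrum is scored
correctly with probability p (p1 = specificity for a normal sample, p2 =
sensitivity for a ROD one), the probability that the majority vote errs is
the exact lower binomial tail

    Q(N) = sum_{k=0}^{k<N/2} C(N, k) (1-p)^(N-k) p^k ,

i.e. the probability that fewer than half of the N spectra are scored
correctly. Type I error (normal called ROD) is Q evaluated at p1, Type II
(ROD called normal) at p2. For p > 1/2 the tail decreases geometrically in
N, so a handful of spectra turn a mediocre ~80%-accurate single-spectrum
classifier into a near-certain sample call; ``minimal_odd_n`` finds the
smallest odd N whose error is below a target alpha.

Everything is exact — no normal approximation. Binomial coefficients use
integer arithmetic up to N = 60 and log-gamma accumulation beyond, where
C(N, k) would overflow a double.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import DiagnosticReport

__all__ = [
    "AggregationInputs",
    "AggregationResult",
    "majority_error",
    "majority_correct",
    "minimal_odd_n",
    "error_curves",
    "n_spectra_confusion",
    "monte_carlo_majority",
]

_EXACT_N_MAX = 60
_DEFAULT_N_CAP = 10001


def _check_p(p: float) -> None:
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1); got {p}")


def _check_odd(n: int) -> None:
    if n < 1 or n % 2 == 0:
        raise ValueError(
            f"N must be a positive odd integer (ties are undefined for even "
            f"N under the majority rule); got {n}"
        )


def majority_error(p: float, n: int) -> float:
    """Probability that the N-spectrum majority vote misclassifies a sample
    whose spectra are each scored correctly with probability ``p``.

    Exact lower binomial tail P[X < N/2] for X ~ Binomial(N, p).
    """
    _check_p(p)
    _check_odd(n)
    half = n // 2  # k ranges over 0 .. floor(N/2), i.e. k < N/2 for odd N
    if n <= _EXACT_N_MAX:
        return float(sum(
            math.comb(n, k) * (1.0 - p) ** (n - k) * p**k
            for k in range(half + 1)
        ))
    # log-gamma accumulation for large N
    lp, lq = math.log(p), math.log1p(-p)
    lgn = math.lgamma(n + 1)
    total = 0.0
    for k in range(half + 1):
        lt = lgn - math.lgamma(k + 1) - math.lgamma(n - k + 1) \
            + k * lp + (n - k) * lq
        total += math.exp(lt)
    return min(total, 1.0)


def majority_correct(p: float, n: int) -> float:
    """Complement of ``majority_error``: P[X > N/2], the probability the
    majority vote is right."""
    return 1.0 - majority_error(p, n)


def minimal_odd_n(p: float, alpha: float, n_cap: int = _DEFAULT_N_CAP) -> int:
    """Smallest odd N whose majority-vote error falls strictly below alpha.

    Requires p > 1/2: at or below chance the error never drops under 1/2, so
    no N can attain a sub-0.5 alpha.
    """
    _check_p(p)
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1); got {alpha}")
    if p <= 0.5:
        raise ValueError(
            "per-spectrum classifier is no better than chance (p <= 0.5); "
            "majority voting cannot reach the target error"
        )
    n = 1
    while majority_error(p, n) >= alpha:
        n += 2
        if n > n_cap:
            raise RuntimeError(
                f"no odd N <= {n_cap} attains error < {alpha} at p = {p}"
            )
    return n


@dataclass(frozen=True)
class AggregationInputs:
    """Single-spectrum probabilities feeding the majority-vote analysis.

    ``p1``: probability a normal spectrum scores below 1 (specificity);
    ``p2``: probability a ROD spectrum scores above 1 (sensitivity);
    ``prevalence``: ROD fraction of the cohort; ``alpha``: target error.
    """

    p1: float
    p2: float
    prevalence: float
    alpha: float = 0.05

    def __post_init__(self):
        for name in ("p1", "p2", "prevalence", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1); got {v}")


@dataclass(frozen=True)
class AggregationResult:
    """Majority-vote summary at one N plus the minimal-N readouts."""

    inputs: AggregationInputs
    n: int
    q1: float                  # Type I error at N (from p1)
    q2: float                  # Type II error at N (from p2)
    n_star_type1: int          # minimal odd N with Q_I < alpha
    n_star_type2: int          # minimal odd N with Q_II < alpha
    confusion: DiagnosticReport


def aggregate(inputs: AggregationInputs, n: int = 11) -> AggregationResult:
    """Full aggregation readout at ``n`` spectra."""
    _check_odd(n)
    return AggregationResult(
        inputs=inputs,
        n=n,
        q1=majority_error(inputs.p1, n),
        q2=majority_error(inputs.p2, n),
        n_star_type1=minimal_odd_n(inputs.p1, inputs.alpha),
        n_star_type2=minimal_odd_n(inputs.p2, inputs.alpha),
        confusion=n_spectra_confusion(inputs, n),
    )


def error_curves(inputs: AggregationInputs, n_max: int = 51) -> pd.DataFrame:
    """Type I / Type II error versus N for odd N = 1, 3, ..., n_max.

    Both curves are strictly decreasing whenever the corresponding p exceeds
    1/2.
    """
    _check_odd(n_max)
    rows = [(n, majority_error(inputs.p1, n), majority_error(inputs.p2, n))
            for n in range(1, n_max + 1, 2)]
    return pd.DataFrame(rows, columns=["N", "q1", "q2"])


def n_spectra_confusion(inputs: AggregationInputs, n: int) -> DiagnosticReport:
    """Closed-form N-spectra confusion matrix on the probability scale.

    The condition-ROD column is (1-q2, q2), the condition-normal column
    (q1, 1-q1), weighted by prevalence, so the entries sum to one and every
    diagnostic metric follows from the usual identities.
    """
    _check_odd(n)
    q1 = majority_error(inputs.p1, n)
    q2 = majority_error(inputs.p2, n)
    prev = inputs.prevalence
    return DiagnosticReport(
        tp=prev * (1.0 - q2),
        fn=prev * q2,
        fp=(1.0 - prev) * q1,
        tn=(1.0 - prev) * (1.0 - q1),
    )


def monte_carlo_majority(
    p: float, n: int, reps: int = 200_000, seed: int = 0
) -> tuple[float, float]:
    """Simulation estimate of the majority-vote error (verification oracle).

    Simulates ``reps`` votes of ``n`` Bernoulli(p) correctness draws; returns
    the error fraction and its binomial standard error.
    """
    _check_p(p)
    _check_odd(n)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    correct = rng.binomial(n, p, size=reps)
    err = float(np.mean(correct <= n // 2))
    se = math.sqrt(max(err * (1.0 - err), 1.0 / reps) / reps)
    return err, se
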