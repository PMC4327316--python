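"""Recovery statistics of random colony picking.

How many random colony picks does it take to recover every one of ``n``
unique library members?  With a uniform library, the probability that one
given species appears in ``N`` picks is ``P = 1 - (1 - 1/n)**N``; treating
species as independent, the whole-library recovery probability is ``P**n``.
That independence treatment slightly overstates recovery — the exact
coupon-collector answer by inclusion-exclusion,
``sum_k (-1)^k C(n,k) (1 - k/n)**N``, is provided as an oracle, and a Monte
Carlo simulator extends the question to biased abundances and imperfect
(synthesis-error-laden) colonies, where each picked colony is only usable
with probability ``f``.

All probability arithmetic is done in log space so that regimes like
n = 10^3, N = 10^4 are numerically exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "PickingModel", "p_single", "recovery_all", "exact_recovery_oracle",
    "min_pickings", "simulate_picking", "required_pickings_sim",
]


@dataclass(frozen=True)
class PickingModel:
    """Parameters of a random-picking campaign.

    n unique species, N picks, abundance bias factor B (max/min weight) and
    correct-colony fraction f (1 minus the synthesis-error fraction).
    """

    n: int
    N: int
    bias: float = 1.0
    correct_fraction: float = 1.0
    abundance_kind: str = "loguniform"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.bias < 1:
            raise ValueError("bias factor must be >= 1")
        if not (0 <= self.correct_fraction <= 1):
            raise ValueError("correct_fraction must be in [0, 1]")


def p_single(n: int, N: int) -> float:
    """P(a given species is picked at least once in N uniform picks)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if N < 0:
        raise ValueError("N must be >= 0")
    if n == 1:
        return 0.0 if N == 0 else 1.0
    # 1 - exp(N * log(1 - 1/n)), stable for large N
    return -math.expm1(N * math.log1p(-1.0 / n))


def recovery_all(n: int, N: int) -> float:
    """Whole-library recovery probability under the independence treatment.

    ``P**n`` with ``P = p_single(n, N)``; an upper bound on the exact
    probability (missing events are negatively correlated).
    """
    p = p_single(n, N)
    if p == 0.0:
        return 0.0 if n >= 1 else 1.0
    return math.exp(n * math.log(p))


def exact_recovery_oracle(n: int, N: int) -> float:
    """Exact P(all n species appear in N uniform draws), inclusion-exclusion.

    ``sum_{k=0..n} (-1)^k C(n,k) (1 - k/n)**N``; guarded to n <= 10^4 where
    the alternating sum is numerically tame (terms decay rapidly for N >> n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if N < 0:
        raise ValueError("N must be >= 0")
    if n > 10_000:
        raise ValueError("n > 1e4: inclusion-exclusion is unstable; "
                         "use simulate_picking instead")
    if N < n:
        return 0.0
    terms = []
    for k in range(n + 1):
        frac = 1.0 - k / n
        if frac == 0.0:
            term = 0.0 if N > 0 else 1.0
        else:
            log_mag = (math.lgamma(n + 1) - math.lgamma(k + 1)
                       - math.lgamma(n - k + 1) + N * math.log(frac))
            term = math.exp(log_mag)
        terms.append(term if k % 2 == 0 else -term)
    return min(1.0, max(0.0, math.fsum(terms)))


def min_pickings(n: int, target: float) -> int:
    """Smallest N with ``recovery_all(n, N) >= target``.

    Analytic inversion seeds an exact local integer scan, so floating-point
    boundary cases cannot shift the answer.
    """
    if not (0 < target < 1):
        raise ValueError("target must be in (0, 1)")
    if n == 1:
        return 1
    # invert: (1 - (1-1/n)^N)^n >= t  =>  N >= log(1 - t^(1/n)) / log(1-1/n)
    p_needed = math.exp(math.log(target) / n)
    guess = math.log1p(-p_needed) / math.log1p(-1.0 / n)
    N = max(0, int(math.floor(guess)) - 2)
    while recovery_all(n, N) < target:
        N += 1
    while N > 0 and recovery_all(n, N - 1) >= target:
        N -= 1
    return N


def _biased_probabilities(n: int, bias: float, kind: str, rng) -> np.ndarray:
    if bias == 1 or n == 1:
        return np.full(n, 1.0 / n)
    if kind == "loguniform":
        w = np.exp(rng.uniform(0.0, math.log(bias), size=n))
        w[0], w[-1] = 1.0, bias
        w = rng.permutation(w)
    elif kind == "twoclass":
        w = np.ones(n)
        w[n // 2:] = bias
        w = rng.permutation(w)
    else:
        raise ValueError(f"unknown abundance kind {kind!r}")
    return w / w.sum()


@dataclass(frozen=True)
class PickingEstimate:
    recovery: float
    ci_low: float
    ci_high: float
    reps: int


def simulate_picking(model: PickingModel, reps: int = 10_000,
                     seed: int = 0) -> PickingEstimate:
    """Monte Carlo whole-library recovery with bias and imperfect colonies.

    Each replicate draws N colonies from the (biased) multinomial; a species
    counts as recovered if at least one of its picked colonies is correct
    (each independently correct with probability f).  Returns the mean
    full-recovery indicator with a normal-approximation 95% CI.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    p = _biased_probabilities(model.n, model.bias, model.abundance_kind, rng)
    f = model.correct_fraction
    # chunk replicates to bound memory at large n * reps
    chunk = max(1, min(reps, int(5e7 // max(1, model.n))))
    successes = 0
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        counts = rng.multinomial(model.N, p, size=m)
        if f >= 1.0:
            good = counts > 0
        elif f <= 0.0:
            good = np.zeros_like(counts, dtype=bool)
        else:
            good = rng.binomial(counts, f) > 0
        successes += int(good.all(axis=1).sum())
        done += m
    est = successes / reps
    half = 1.96 * math.sqrt(max(est * (1 - est), 1e-12) / reps)
    return PickingEstimate(recovery=est, ci_low=max(0.0, est - half),
                           ci_high=min(1.0, est + half), reps=reps)


@dataclass(frozen=True)
class RequiredPickings:
    N: int
    N_low: int
    N_high: int
    target: float
    reps: int


def required_pickings_sim(n: int, target: float, bias: float = 1.0,
                          correct_fraction: float = 1.0, seed: int = 0,
                          reps: int = 400,
                          abundance_kind: str = "loguniform") -> RequiredPickings:
    """Smallest N reaching ``target`` recovery, estimated by simulation.

    Bisection on N against the Monte Carlo recovery estimate; the band
    [N_low, N_high] brackets where the 95% CI crosses the target.  Raises
    when the target is unreachable (f = 0).
    """
    if correct_fraction <= 0:
        raise ValueError("target unreachable: correct_fraction is 0")
    if not (0 < target < 1):
        raise ValueError("target must be in (0, 1)")

    def estimate(N: int) -> PickingEstimate:
        model = PickingModel(n=n, N=N, bias=bias,
                             correct_fraction=correct_fraction,
                             abundance_kind=abundance_kind)
        return simulate_picking(model, reps=reps, seed=seed)

    # analytic seed from the uniform model, inflated for bias/error
    hi = max(4, int(min_pickings(n, target) / max(correct_fraction, 1e-6)))
    while estimate(hi).recovery < target:
        hi *= 2
        if hi > 10 ** 9:
            raise RuntimeError("bisection failed to bracket the target")
    lo = 0
    while hi - lo > max(1, hi // 200):
        mid = (lo + hi) // 2
        if estimate(mid).recovery >= target:
            hi = mid
        else:
            lo = mid

    def crossing(attr: str) -> int:
        a, b = 0, max(hi * 2, 4)
        while getattr(estimate(b), attr) < target:
            b *= 2
            if b > 10 ** 9:
                return b
        while b - a > max(1, b // 200):
            m = (a + b) // 2
            if getattr(estimate(m), attr) >= target:
                b = m
            else:
                a = m
        return b

    return RequiredPickings(N=hi, N_low=crossing("ci_high"),
                            N_high=crossing("ci_low"), target=target, reps=reps)
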