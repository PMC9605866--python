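"""Photobleaching step detection and binomial stoichiometry inference.

Traces are scored automatically: penalized binary segmentation finds
candidate change points, then calls are kept only when the fitted levels
form a strictly decreasing staircase with drops of at least ``min_step``
ending at the baseline.  Step-count distributions are fitted with a
detection-conditioned binomial (k >= 1, dark complexes are invisible) mixed
with a uniform outlier kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from mechanomem.io_formats import Trace

_MAD_TO_SD = 1.0 / 0.6744897501960817   # MAD -> sd for a Gaussian


@dataclass
class StepCall:
    """Detected bleaching staircase for one trace."""

    trace_id: str
    k: int | None
    change_points: list[int]
    levels: list[float]
    quality: str                        # "clean" | "discarded"
    reason: str = ""

    @property
    def clean(self) -> bool:
        return self.quality == "clean"

    def to_dict(self) -> dict:
        return {
            "trace_id": self.trace_id, "k": self.k,
            "change_points": self.change_points, "levels": self.levels,
            "quality": self.quality, "reason": self.reason,
        }


def _noise_sd(x: np.ndarray) -> float:
    """Robust noise sd from first differences (steps barely perturb it)."""
    d = np.abs(np.diff(x))
    return float(np.median(d)) * _MAD_TO_SD / math.sqrt(2.0)


def _best_split(x: np.ndarray, min_size: int) -> tuple[int, float]:
    """Best single change point of a segment: (index, RSS reduction)."""
    n = len(x)
    if n < 2 * min_size:
        return -1, 0.0
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    total = c2[-1] - c1[-1] ** 2 / n
    i = np.arange(min_size, n - min_size + 1)
    left = c2[i - 1] - c1[i - 1] ** 2 / i
    right = (c2[-1] - c2[i - 1]) - (c1[-1] - c1[i - 1]) ** 2 / (n - i)
    rss = left + right
    j = int(np.argmin(rss))
    return int(i[j]), float(total - rss[j])


def _binary_segmentation(x: np.ndarray, threshold: float,
                         min_size: int) -> list[int]:
    """Change points by recursive binary segmentation on RSS reduction."""
    points: list[int] = []
    stack = [(0, len(x))]
    while stack:
        a, b = stack.pop()
        split, gain = _best_split(x[a:b], min_size)
        if split > 0 and gain > threshold:
            points.append(a + split)
            stack.append((a, a + split))
            stack.append((a + split, b))
    return sorted(points)


def detect_steps(trace: Trace, min_step: float = 50.0, penalty: float = 3.0,
                 baseline: float = 0.0, min_size: int = 2) -> StepCall:
    """Score one trace as a clean monotone bleaching staircase, or discard it.

    A split is accepted when its residual-sum-of-squares reduction exceeds
    penalty * sigma^2 * log(T), with sigma estimated from the median absolute
    first differences.  Post-filters: levels strictly decreasing with drops
    of at least ``min_step``, and the final level within 3 sigma of the
    terminal ``baseline``.  Deterministic; uncallable traces are discarded,
    never raised.
    """
    x = np.asarray(trace.intensities, dtype=float)
    T = len(x)
    if T < 10:
        return StepCall(trace.trace_id, None, [], [], "discarded", "trace too short")
    sigma = _noise_sd(x)
    threshold = penalty * sigma * sigma * math.log(T)
    cps = _binary_segmentation(x, threshold, min_size)
    bounds = [0, *cps, T]
    levels = [float(x[a:b].mean()) for a, b in zip(bounds[:-1], bounds[1:])]
    if not cps:
        return StepCall(trace.trace_id, None, [], levels, "discarded", "no steps")
    drops = [levels[i] - levels[i + 1] for i in range(len(levels) - 1)]
    if any(d <= 0 for d in drops):
        return StepCall(trace.trace_id, None, cps, levels, "discarded",
                        "levels not strictly decreasing")
    if any(d < min_step for d in drops):
        return StepCall(trace.trace_id, None, cps, levels, "discarded",
                        "step below minimum size")
    tol = max(3.0 * sigma, 1e-9)
    if abs(levels[-1] - baseline) > tol:
        return StepCall(trace.trace_id, None, cps, levels, "discarded",
                        "terminal level above baseline")
    return StepCall(trace.trace_id, len(cps), cps, levels, "clean")


@dataclass
class StepDistribution:
    """Clean step-count tallies plus the discard count."""

    counts: dict[int, int]
    discarded: int
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) + self.discarded != self.total:
            raise ValueError("counts + discarded must equal total")

    @property
    def k_max(self) -> int:
        return max(self.counts) if self.counts else 0

    def fractions(self) -> dict[int, float]:
        n = sum(self.counts.values())
        return {k: v / n for k, v in self.counts.items()}


def step_distribution(calls: list[StepCall]) -> StepDistribution:
    """Tally clean calls per step count; discarded traces counted separately."""
    clean = [c for c in calls if c.clean]
    if not clean:
        raise ValueError("no clean step calls")
    counts: dict[int, int] = {}
    for c in clean:
        counts[c.k] = counts.get(c.k, 0) + 1
    return StepDistribution(dict(sorted(counts.items())),
                            len(calls) - len(clean), len(calls))


@dataclass(frozen=True)
class OligomerModel:
    """Binomial labelling model with a uniform outlier component."""

    n_subunits: int
    maturation_p: float
    outlier_rate: float = 0.02
    k_max: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.maturation_p <= 1.0:
            raise ValueError("maturation probability must be in [0, 1]")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier rate must be in [0, 1)")
        if self.n_subunits < 1:
            raise ValueError("subunit count must be >= 1")


@dataclass
class BinomialStepDistribution:
    """Step-count pmf of an oligomer model.

    ``unconditional`` is the plain Binomial(n, p) pmf over k = 0..n;
    ``conditional`` is the detection-conditioned (k >= 1), outlier-mixed pmf
    over k = 1..k_max.
    """

    unconditional: np.ndarray
    conditional: np.ndarray
    model: OligomerModel

    def pmf(self, k: int) -> float:
        if 1 <= k <= self.model.k_max:
            return float(self.conditional[k - 1])
        return 0.0


def conditional_binomial(model: OligomerModel) -> BinomialStepDistribution:
    """Detection-conditioned binomial step-count distribution.

    cond(k) = B(k; n, p) / (1 - B(0; n, p)) for 1 <= k <= n, zero above n,
    then mixed with uniform outliers:
    P(k) = (1 - eps) cond(k) + eps / k_max.

    When k_max < n the truncated conditional is renormalised over 1..k_max
    so the pmf stays proper (unless the truncation removes all mass, in
    which case only the outlier component remains).
    """
    n, p, eps, k_max = (model.n_subunits, model.maturation_p,
                        model.outlier_rate, model.k_max)
    uncond = binom.pmf(np.arange(n + 1), n, p)
    p0 = uncond[0]
    if p0 >= 1.0 - 1e-300:
        raise ValueError("p = 0: detection impossible (all complexes dark)")
    cond = np.zeros(k_max)
    upto = min(n, k_max)
    cond[:upto] = uncond[1:upto + 1] / (1.0 - p0)
    mass = cond.sum()
    if k_max < n and mass > 0:
        cond /= mass
    if mass > 0:
        mixed = (1.0 - eps) * cond + eps / k_max
    elif eps > 0:
        # all binomial mass truncated away: any observation is an outlier
        mixed = np.full(k_max, 1.0 / k_max)
    else:
        mixed = cond
    return BinomialStepDistribution(uncond, mixed, model)


@dataclass
class OligomerFit:
    """Model-selection result over candidate subunit counts."""

    best_n: int
    p: float
    p_free: bool
    log_likelihood: dict[int, float]
    p_by_n: dict[int, float]
    predicted: np.ndarray            # conditional pmf of the best model

    def to_dict(self) -> dict:
        return {
            "best_n": self.best_n, "p": self.p, "p_free": self.p_free,
            "log_likelihood": self.log_likelihood,
            "p_by_n": self.p_by_n,
            "predicted": self.predicted.tolist(),
        }


def _golden_section_max(f, lo: float, hi: float, tol: float = 1e-8) -> float:
    """Golden-section maximiser of a unimodal function on [lo, hi]."""
    inv_phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - inv_phi * (b - a)
    d = a + inv_phi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - inv_phi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + inv_phi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def _multinomial_loglik(counts: dict[int, int], model: OligomerModel) -> float:
    dist = conditional_binomial(model)
    ll = 0.0
    for k, c in counts.items():
        pk = dist.pmf(k)
        if pk <= 0.0:
            return -math.inf
        ll += c * math.log(pk)
    return ll


def fit_oligomer(dist: StepDistribution, p: float | None = 0.8,
                 outlier_rate: float = 0.02,
                 n_range: range = range(1, 7)) -> OligomerFit:
    """Maximum-likelihood subunit count from a step-count distribution.

    ``p`` fixed (default 0.8) or None for golden-section ML per candidate n.
    Ties in log-likelihood (< 1e-9) break toward smaller n.
    """
    if not dist.counts:
        raise ValueError("empty step distribution")
    k_max = dist.k_max
    if outlier_rate == 0.0 and all(k_max > n for n in n_range):
        raise ValueError(
            "observed step count exceeds every candidate n and the outlier "
            "rate is 0; use outlier_rate > 0"
        )
    loglik: dict[int, float] = {}
    p_by_n: dict[int, float] = {}
    for n in n_range:
        if p is not None:
            p_n = p
        else:
            p_n = _golden_section_max(
                lambda q: _multinomial_loglik(
                    dist.counts, OligomerModel(n, q, outlier_rate, k_max)),
                1e-6, 1.0 - 1e-9)
        p_by_n[n] = p_n
        loglik[n] = _multinomial_loglik(
            dist.counts, OligomerModel(n, p_n, outlier_rate, k_max))
    if all(ll == -math.inf for ll in loglik.values()):
        raise ValueError("all candidate models have zero likelihood; "
                         "increase outlier_rate")
    best_ll = max(loglik.values())
    best_n = max(n_range)
    for n in sorted(n_range):
        if best_ll - loglik[n] < 1e-9:
            best_n = n
            break
    best = conditional_binomial(
        OligomerModel(best_n, p_by_n[best_n], outlier_rate, k_max))
    return OligomerFit(best_n, p_by_n[best_n], p is None, loglik, p_by_n,
                       best.conditional)


def intensity_ratio(calls: list[StepCall], baseline: float = 0.0) -> float:
    """Mean initial brightness of two-step traces over one-step traces.

    Both means are baseline-subtracted; a value near 2 indicates two equal
    fluorophores.
    """
    one = [c.levels[0] - baseline for c in calls if c.clean and c.k == 1]
    two = [c.levels[0] - baseline for c in calls if c.clean and c.k == 2]
    if not one or not two:
        raise ValueError("need at least one clean one-step and one clean "
                         "two-step call")
    return float(np.mean(two) / np.mean(one))
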