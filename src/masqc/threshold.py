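"""IPD-ratio threshold derivation and genome-wide application.

The IPD ratios of the conservative set are modelled as draws from a
normal population N(mu, sigma^2).  A simple random sample of size n
(default 30) is taken, and the lower bound of the two-sided confidence
interval for mu,

    threshold = mean(x) - t * s / sqrt(n),

with ``s`` the sample standard deviation (n-1 denominator) and ``t`` the
two-sided critical value at level alpha, becomes the genome-wide IPD
threshold: a call is retained iff its IPD ratio >= threshold (inclusive).

The historical default critical value is 1.96 — the normal quantile for
alpha=0.05 — even though a Student quantile (t_{0.025}(29) = 2.045 at
n=30) is the exact choice when sigma is unknown.  Pass
``critical_value="auto"`` for the exact Student quantile; the fixed 1.96
default reproduces the published behaviour.  Both the multiplier and the
RNG seed are recorded so any threshold can be reproduced bit for bit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import stats

from .filtering import ConservativeSet
from .io_formats import ModificationCall

__all__ = [
    "ThresholdModel",
    "FilterResult",
    "NormalityResult",
    "sample_ipd_ratios",
    "compute_threshold",
    "derive_threshold",
    "apply_threshold",
    "replicate_thresholds",
    "check_sample_normality",
]

logger = logging.getLogger(__name__)

_PAPER_CRITICAL = 1.96


def _values(source) -> np.ndarray:
    if isinstance(source, ConservativeSet):
        return source.ipd_ratios()
    values = np.asarray(
        [c.ipd_ratio if isinstance(c, ModificationCall) else c for c in source],
        dtype=float,
    )
    return values


def _resolve_seed(seed: int | None) -> int:
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
        logger.info("no RNG seed supplied; drew seed %d from entropy", seed)
    return int(seed)


@dataclass
class ThresholdModel:
    """A sampled IPD-ratio threshold with full reproduction metadata."""

    sample_values: tuple[float, ...]
    n: int
    alpha: float
    critical_value: float
    critical_mode: str
    sample_mean: float
    sample_sd: float
    threshold: float
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n": self.n,
            "alpha": self.alpha,
            "critical_value": self.critical_value,
            "critical_mode": self.critical_mode,
            "sample_mean": self.sample_mean,
            "sample_sd": self.sample_sd,
            "seed": self.seed,
        }


@dataclass
class FilterResult:
    """Partition of a call set at an IPD-ratio threshold (retained: ipd >= t)."""

    threshold_used: float
    retained: list[ModificationCall]
    removed: list[ModificationCall]
    n_input: int = field(default=0)

    def __post_init__(self) -> None:
        if not self.n_input:
            self.n_input = len(self.retained) + len(self.removed)


def sample_ipd_ratios(
    conservative,
    n: int = 30,
    seed: int | None = None,
    replace: bool = False,
) -> list[float]:
    """Simple random sample of ``n`` IPD ratios from the conservative set.

    Deterministic for a given seed.  Sampling is without replacement by
    default; a set of exactly ``n`` calls therefore returns the full
    multiset of its IPD ratios.
    """
    values = _values(conservative)
    if n < 2:
        raise ValueError(f"sample size must be >= 2, got {n}")
    if not replace and values.size < n:
        raise ValueError(
            f"conservative set holds {values.size} calls but the sample size "
            f"is {n}; relax the strict cutoffs or lower n"
        )
    rng = np.random.default_rng(_resolve_seed(seed))
    sample = rng.choice(values, size=n, replace=replace)
    return [float(x) for x in sample]


def compute_threshold(
    sample: Sequence[float],
    alpha: float = 0.05,
    critical_value: Union[float, str] = _PAPER_CRITICAL,
    seed: int | None = None,
) -> ThresholdModel:
    """Lower confidence bound of the sample mean, used as the IPD threshold.

    ``threshold = mean - critical * sd / sqrt(n)`` with the n-1 sd
    denominator.  ``critical_value`` is either a fixed multiplier
    (default 1.96) or ``"auto"`` for the two-sided Student quantile
    ``t_{alpha/2}(n-1)``.  A constant sample is allowed (sd 0, threshold
    equal to the mean).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError(f"threshold sample must hold >= 2 values, got {x.size}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    n = int(x.size)
    if critical_value == "auto":
        crit = float(stats.t.ppf(1.0 - alpha / 2.0, df=n - 1))
        mode = "auto"
    else:
        crit = float(critical_value)
        mode = "fixed"
    if crit <= 0:
        raise ValueError(f"critical value must be positive, got {crit}")
    # sort first: the statistics become independent of draw order, and an
    # exhaustive sample yields bitwise-reproducible thresholds
    xs = np.sort(x)
    if xs[0] == xs[-1]:  # constant sample: sd exactly 0, threshold = the value
        mean, sd = float(xs[0]), 0.0
    else:
        mean = float(np.mean(xs))
        sd = float(np.std(xs, ddof=1))
    threshold = mean - crit * sd / math.sqrt(n)
    return ThresholdModel(
        sample_values=tuple(float(v) for v in x),
        n=n,
        alpha=alpha,
        critical_value=crit,
        critical_mode=mode,
        sample_mean=mean,
        sample_sd=sd,
        threshold=threshold,
        seed=seed,
    )


def derive_threshold(
    conservative,
    n: int = 30,
    seed: int | None = None,
    alpha: float = 0.05,
    critical_value: Union[float, str] = _PAPER_CRITICAL,
    replace: bool = False,
) -> ThresholdModel:
    """Sample the conservative set and compute the threshold in one step."""
    seed = _resolve_seed(seed)
    sample = sample_ipd_ratios(conservative, n=n, seed=seed, replace=replace)
    return compute_threshold(sample, alpha=alpha, critical_value=critical_value, seed=seed)


def apply_threshold(
    calls: Sequence[ModificationCall], threshold: float
) -> FilterResult:
    """Partition calls at the threshold: retained iff ``ipd_ratio >= threshold``.

    The comparison is inclusive and input order is preserved in both parts.
    """
    if not math.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    retained: list[ModificationCall] = []
    removed: list[ModificationCall] = []
    for c in calls:
        (retained if c.ipd_ratio >= threshold else removed).append(c)
    return FilterResult(
        threshold_used=float(threshold),
        retained=retained,
        removed=removed,
        n_input=len(calls),
    )


def replicate_thresholds(
    conservative,
    k: int = 3,
    n: int = 30,
    seeds: Sequence[int] | None = None,
    alpha: float = 0.05,
    critical_value: Union[float, str] = _PAPER_CRITICAL,
) -> tuple[list[ThresholdModel], dict]:
    """Derive ``k`` thresholds from independent samplings and summarise
    their dispersion (stability check of the sampling step).

    Returns the models and a summary with min, max, mean, sd (n-1
    denominator, 0 for identical thresholds) and the maximum pairwise
    absolute difference.
    """
    if k < 2:
        raise ValueError(f"need at least 2 replicates, got {k}")
    if seeds is None:
        seeds = [_resolve_seed(None) for _ in range(k)]
    if len(seeds) != k:
        raise ValueError(f"expected {k} seeds, got {len(seeds)}")
    models = [
        derive_threshold(
            conservative, n=n, seed=s, alpha=alpha, critical_value=critical_value
        )
        for s in seeds
    ]
    thresholds = np.array([m.threshold for m in models])
    summary = {
        "k": k,
        "min": float(thresholds.min()),
        "max": float(thresholds.max()),
        "mean": float(thresholds.mean()),
        "sd": float(np.std(thresholds, ddof=1)),
        "max_pairwise_diff": float(thresholds.max() - thresholds.min()),
    }
    return models, summary


@dataclass
class NormalityResult:
    """Advisory Shapiro–Wilk diagnostic of the threshold sample."""

    statistic: float | None
    pvalue: float | None
    testable: bool
    message: str = ""


def check_sample_normality(sample: Sequence[float]) -> NormalityResult:
    """Shapiro–Wilk test of the threshold sample against normality.

    Advisory only: a low p-value raises a warning, never an error.  A
    constant sample is reported as non-testable.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError(f"normality check needs >= 3 values, got {x.size}")
    if np.ptp(x) == 0.0:
        return NormalityResult(
            statistic=None,
            pvalue=None,
            testable=False,
            message="constant sample; normality not testable",
        )
    stat, pvalue = stats.shapiro(x)
    result = NormalityResult(statistic=float(stat), pvalue=float(pvalue), testable=True)
    if pvalue < 0.05:
        result.message = (
            f"threshold sample deviates from normality (Shapiro-Wilk "
            f"p={pvalue:.3g}); the confidence bound assumes a normal population"
        )
        warnings.warn(result.message, stacklevel=2)
    return result
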