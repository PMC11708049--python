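"""Replicate summaries, Welch equivalence tests and CFU back-calculation.

Group comparisons in this package (contacting vs non-contacting dist50,
lysis levels between strains) use the two-tailed Welch t-test — a t-test
assuming unequal variances, with the Welch–Satterthwaite fractional
degrees of freedom — on biological-replicate means.  The
cross-contamination control back-calculates colony-forming units (CFU)
from serial-dilution plate counts and bounds the producer-contamination
rate with an exact one-sided binomial (Clopper–Pearson) limit, which for
zero observed producers reduces to the familiar rule of three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ReplicateSummary",
    "TTestResult",
    "DilutionSeries",
    "summarize",
    "welch_ttest",
    "serial_dilution_factors",
    "cfu_per_ml",
    "contamination_check",
]


@dataclass
class ReplicateSummary:
    group: str
    values: np.ndarray
    mean: float
    sd: float  # NaN (flagged undefined) for n = 1
    n: int

    @property
    def sd_defined(self) -> bool:
        return self.n > 1


@dataclass
class TTestResult:
    t: float
    df: float  # Welch–Satterthwaite, fractional
    p: float  # two-tailed


@dataclass
class DilutionSeries:
    """Plate counts from a serial dilution.

    ``dilution_factors[i]`` is the total dilution of plate i relative to
    the resuspended sample (≥ 1); ``plated_volume_ml`` is the volume
    plated from each dilution.
    """

    counts: Sequence[int]
    dilution_factors: Sequence[float]
    plated_volume_ml: float
    resuspension_volume_ml: float = 1.0

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.dilution_factors):
            raise ValueError("counts and dilution_factors must align")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if any(f < 1 for f in self.dilution_factors):
            raise ValueError("dilution factors must be at least 1")
        if self.plated_volume_ml <= 0 or self.resuspension_volume_ml <= 0:
            raise ValueError("volumes must be positive")


def summarize(group: str, values: Sequence[float]) -> ReplicateSummary:
    """Mean and sample SD (n-1) across biological replicates; SD is NaN
    (undefined) for a single replicate."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty replicate group")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return ReplicateSummary(group=group, values=arr, mean=float(arr.mean()),
                            sd=sd, n=arr.size)


def welch_ttest(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Two-tailed t-test assuming unequal variances (Welch), fractional df.

    Two groups with zero variance and equal means return p = 1 by
    convention (no evidence of any difference).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise ValueError("both groups have zero variance and different means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def serial_dilution_factors(n_dilutions: int, ratio: float = 2.0) -> list[float]:
    """Dilution factors for a serial scheme: index k -> ratio**k.

    A 1:1 serial dilution (equal volumes of sample and diluent) halves the
    concentration each step, so index k carries factor 2**k.  Index 0 is
    the undiluted resuspension.
    """
    if n_dilutions < 0:
        raise ValueError("n_dilutions must be non-negative")
    return [float(ratio) ** k for k in range(n_dilutions + 1)]


@dataclass
class CfuEstimate:
    per_plate: np.ndarray  # CFU/mL for each plate
    pooled: float  # count-weighted (inverse-variance under Poisson)
    total_cfu: float  # back-calculated CFU in the resuspension
    below_detection: np.ndarray = field(default_factory=lambda: np.array([], bool))


def cfu_per_ml(series: DilutionSeries) -> CfuEstimate:
    """Back-calculate CFU/mL from plate counts and dilution factors.

    Per plate: CFU/mL = count × dilution factor / plated volume.  The
    pooled estimate weights plates by raw counts — total colonies divided
    by total effective volume — which is the inverse-variance combination
    under Poisson counting.  Plates with zero colonies are flagged
    below-detection (their per-plate estimate is 0).
    """
    counts = np.asarray(series.counts, dtype=float)
    factors = np.asarray(series.dilution_factors, dtype=float)
    per_plate = counts * factors / series.plated_volume_ml
    effective_volumes = series.plated_volume_ml / factors
    pooled = float(counts.sum() / effective_volumes.sum())
    return CfuEstimate(
        per_plate=per_plate,
        pooled=pooled,
        total_cfu=pooled * series.resuspension_volume_ml,
        below_detection=counts == 0,
    )


@dataclass
class PurityReport:
    n_total: int
    n_producer: int
    producer_fraction: float
    upper_bound: float  # one-sided binomial upper confidence bound
    confidence: float


def contamination_check(
    n_total: int, n_producer: int, confidence: float = 0.95
) -> PurityReport:
    """Producer-colony fraction and an exact one-sided binomial upper
    confidence bound on the contamination rate.

    With zero producers observed among n colonies the bound is
    1 - (1 - confidence)**(1/n), approximately 3/n at 95% (rule of three).
    """
    if n_total <= 0:
        raise ValueError("need at least one colony")
    if not 0 <= n_producer <= n_total:
        raise ValueError("n_producer must lie in [0, n_total]")
    k, n = n_producer, n_total
    if k == n:
        upper = 1.0
    else:
        upper = float(sps.beta.ppf(confidence, k + 1, n - k))
    return PurityReport(
        n_total=n, n_producer=k, producer_fraction=k / n,
        upper_bound=upper, confidence=confidence,
    )
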