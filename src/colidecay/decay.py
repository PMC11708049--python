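"""Decay-curve analysis: smoothing, baseline, YFP50 and dist50.

The central metric of the spatial assays is dist50 — the distance from an
alignment origin (the YFP peak on a reporter lawn, or the producer-colony
edge in the colony-pair assay) at which the DNA-damage reporter signal
falls to YFP50, the intensity halfway between the profile's maximum and
its baseline.  Because the maximum grows with overall expression while the
shape of the gradient does not, dist50 is a spatial-penetrance measure
that is invariant to positive affine rescaling of the signal.

Procedure, in order: smooth the decay with a centered moving average
(window of 20 samples by default), estimate the baseline as the mean of
the 20 samples furthest from the producer colony, optionally subtract it
(done in the colony-pair assay to remove per-colony expression offsets),
form YFP50 = baseline + (max - baseline)/2, and take the first downward
crossing of YFP50 scanning outward from the peak, with linear
interpolation between the bracketing samples.  Non-contacting colonies do
not peak at the full reporter response, so their dist50 is inferred from a
reference YFP50 measured on contacting colonies; a crossing that falls in
the masked agar gap is flagged rather than reported.

No parametric curve (exponential or Hill) is ever fitted: the metric is
deliberately nonparametric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .profiles import CrossSectionProfile

__all__ = [
    "Dist50",
    "DecayResult",
    "smooth_profile",
    "smooth_masked",
    "estimate_baseline",
    "subtract_baseline",
    "compute_yfp50",
    "compute_dist50",
    "infer_dist50_noncontacting",
    "peak_signal",
    "minmax_scale",
    "average_decays",
    "analyze_contacting",
    "analyze_noncontacting",
]


class Dist50(NamedTuple):
    """A dist50 outcome: the distance in µm, or None with a reason flag."""

    value: float | None
    flag: str | None = None


@dataclass
class DecayResult:
    """Per-profile decay analysis output."""

    distances: np.ndarray  # µm, masked samples are NaN in `smoothed`
    smoothed: np.ndarray
    baseline: float
    max_signal: float
    yfp50: float
    dist50: float | None
    contact_class: str  # "contacting" | "non-contacting"
    valid: bool
    reasons: tuple[str, ...] = ()


def smooth_profile(y: np.ndarray, window: int = 20) -> np.ndarray:
    """Centered moving average; near the edges the window truncates
    symmetrically to the available samples (so the first and last samples
    pass through unchanged and linear trends are preserved in the
    interior).  ``window`` is in samples; output length equals input."""
    if window < 1:
        raise ValueError("window must be at least 1")
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("cannot smooth an empty vector")
    n = y.size
    half = window // 2
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    cs = np.concatenate([[0.0], np.cumsum(y)])
    lo = idx - h
    hi = idx + h + 1
    out = (cs[hi] - cs[lo]) / (hi - lo)
    out[h == 0] = y[h == 0]  # untouched samples pass through exactly
    return out


def smooth_masked(y: np.ndarray, mask: np.ndarray, window: int = 20) -> np.ndarray:
    """Smooth each contiguous run of unmasked samples independently, so the
    moving average never bleeds across a masked gap.  Masked positions are
    NaN in the output."""
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    out = np.full(y.shape, np.nan)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        run = idx[s : e + 1]
        out[run] = smooth_profile(y[run], window)
    return out


def estimate_baseline(
    y: np.ndarray, n_tail: int = 20, mask: np.ndarray | None = None
) -> float:
    """Mean of the last ``n_tail`` unmasked samples — the samples furthest
    from the producer colony."""
    y = np.asarray(y, dtype=float)
    if mask is not None:
        y = y[np.asarray(mask, dtype=bool)]
    y = y[~np.isnan(y)]
    if y.size < n_tail:
        raise ValueError(
            f"need at least {n_tail} unmasked samples for the baseline, got {y.size}"
        )
    return float(np.mean(y[-n_tail:]))


def subtract_baseline(y: np.ndarray, baseline: float) -> np.ndarray:
    if not np.isfinite(baseline):
        raise ValueError("baseline must be finite")
    return np.asarray(y, dtype=float) - baseline


def compute_yfp50(max_signal: float, baseline: float) -> float:
    """Intensity halfway between the maximum signal and the baseline."""
    if max_signal < baseline:
        raise ValueError("max_signal below baseline")
    return baseline + 0.5 * (max_signal - baseline)


def _check_aligned(d: np.ndarray) -> None:
    spacing = float(np.median(np.diff(d))) if d.size > 1 else 0.0
    if d.min() > spacing + 1e-9:
        raise ValueError(
            "profile not aligned: no sample at or near the distance origin"
        )


def compute_dist50(
    distances: np.ndarray,
    y: np.ndarray,
    yfp50: float,
    mask: np.ndarray | None = None,
) -> Dist50:
    """Distance of the first downward crossing of ``yfp50`` scanning
    outward from the profile peak, with linear interpolation between the
    bracketing samples.  The profile must already be aligned (origin at 0).
    Returns ``Dist50(None, "no-crossing")`` if the profile never falls
    below ``yfp50``."""
    d = np.asarray(distances, dtype=float)
    v = np.asarray(y, dtype=float)
    if mask is not None:
        keep = np.asarray(mask, dtype=bool) & ~np.isnan(v)
        d, v = d[keep], v[keep]
    else:
        keep = ~np.isnan(v)
        d, v = d[keep], v[keep]
    if d.size < 2:
        return Dist50(None, "too-few-samples")
    _check_aligned(d)
    i0 = int(np.argmax(v))
    for i in range(i0, v.size - 1):
        if v[i] >= yfp50 > v[i + 1]:
            t = (v[i] - yfp50) / (v[i] - v[i + 1])
            return Dist50(float(d[i] + t * (d[i + 1] - d[i])), None)
    return Dist50(None, "no-crossing")


def infer_dist50_noncontacting(
    distances: np.ndarray,
    y: np.ndarray,
    yfp50_reference: float,
    mask: np.ndarray | None = None,
) -> Dist50:
    """dist50 of a non-contacting colony against a reference YFP50.

    Scans outward from the producer edge (distance 0) over unmasked
    samples for the first downward crossing of the reference.  Flags
    ``"reference-above-profile"`` when the reference exceeds the profile
    maximum, and ``"crossing-in-gap"`` when the crossing falls inside a
    masked region (the agar gap between the colonies), where no reporter
    material exists to measure.
    """
    d = np.asarray(distances, dtype=float)
    v = np.asarray(y, dtype=float)
    if mask is None:
        mask = np.ones(d.size, dtype=bool)
    keep = np.asarray(mask, dtype=bool) & ~np.isnan(v)
    idx = np.flatnonzero(keep)
    if idx.size < 2:
        return Dist50(None, "too-few-samples")
    if v[idx[0]] < yfp50_reference:
        # already below the reference at the first measurable sample: if a
        # masked gap precedes it the crossing fell inside the gap; with no
        # preceding gap the reference simply exceeds the whole profile
        if idx[0] > 0:
            return Dist50(None, "crossing-in-gap")
        return Dist50(None, "reference-above-profile")
    for a, b in zip(idx[:-1], idx[1:]):
        if v[a] >= yfp50_reference > v[b]:
            if b != a + 1:
                return Dist50(None, "crossing-in-gap")
            t = (v[a] - yfp50_reference) / (v[a] - v[b])
            return Dist50(float(d[a] + t * (d[b] - d[a])), None)
    return Dist50(None, "no-crossing")


def peak_signal(
    distances: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Maximum unmasked intensity and its distance; ties break toward the
    smallest distance."""
    d = np.asarray(distances, dtype=float)
    v = np.asarray(y, dtype=float)
    keep = ~np.isnan(v)
    if mask is not None:
        keep &= np.asarray(mask, dtype=bool)
    if not keep.any():
        raise ValueError("profile fully masked; no peak to report")
    d, v = d[keep], v[keep]
    i = int(np.argmax(v))  # argmax returns the first (smallest-distance) tie
    return float(v[i]), float(d[i])


def minmax_scale(y: np.ndarray) -> np.ndarray:
    """(y - min)/(max - min); display normalization for representative
    profiles.  Raises on a constant vector (zero dynamic range)."""
    y = np.asarray(y, dtype=float)
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi <= lo:
        raise ValueError("zero dynamic range: cannot min-max scale")
    return (y - lo) / (hi - lo)


def average_decays(
    profiles: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray | None]],
    step: float | None = None,
    min_n: int = 2,
) -> pd.DataFrame:
    """Pointwise mean and SD of aligned decay profiles on a common grid.

    Each profile is ``(distances, values, mask)`` (mask may be None).
    Profiles are resampled by linear interpolation onto the intersection
    of their unmasked distance ranges.  Returns a DataFrame with columns
    distance_um, mean, sd (n-1 denominator; NaN when n < 2), n and low_n
    (True where fewer than ``min_n`` profiles contribute).
    """
    if not profiles:
        raise ValueError("no profiles to average")
    cleaned = []
    for d, v, m in profiles:
        d = np.asarray(d, dtype=float)
        v = np.asarray(v, dtype=float)
        keep = ~np.isnan(v)
        if m is not None:
            keep &= np.asarray(m, dtype=bool)
        if keep.sum() < 2:
            raise ValueError("a profile has fewer than 2 unmasked samples")
        cleaned.append((d[keep], v[keep]))
    lo = max(d.min() for d, _ in cleaned)
    hi = min(d.max() for d, _ in cleaned)
    if hi <= lo:
        raise ValueError("profiles share no common distance range")
    if step is None:
        step = float(np.median([np.median(np.diff(d)) for d, _ in cleaned]))
    grid = np.arange(lo, hi + step * 1e-9, step)
    stack = np.vstack([np.interp(grid, d, v) for d, v in cleaned])
    n = np.full(grid.size, stack.shape[0])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.full(grid.size, np.nan)
    return pd.DataFrame(
        {"distance_um": grid, "mean": mean, "sd": sd, "n": n, "low_n": n < min_n}
    )


# ---------------------------------------------------------------------------
# High-level per-profile analysis


def _prepare(
    profile: CrossSectionProfile,
    channel: str,
    window: int,
    n_tail: int,
    baseline_on: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Common smoothing/baseline stage; returns (d, smoothed, mask,
    baseline, tail_sd)."""
    if baseline_on not in ("smoothed", "raw"):
        raise ValueError("baseline_on must be 'smoothed' or 'raw'")
    d = profile.distances
    raw = profile.channel(channel)
    mask = profile.mask
    smoothed = smooth_masked(raw, mask, window)
    base_src = smoothed if baseline_on == "smoothed" else raw
    baseline = estimate_baseline(base_src, n_tail=n_tail, mask=mask)
    raw_tail = raw[mask][-n_tail:]
    tail_sd = float(np.std(raw_tail, ddof=1)) if raw_tail.size > 1 else 0.0
    return d, smoothed, mask, baseline, tail_sd


def analyze_contacting(
    profile: CrossSectionProfile,
    channel: str = "YFP",
    window: int = 20,
    n_tail: int = 20,
    response_floor_k: float = 5.0,
    subtract: bool = False,
    baseline_on: str = "smoothed",
) -> DecayResult:
    """Full decay analysis of an aligned contacting-geometry profile.

    A profile whose dynamic range (max - baseline) does not exceed
    ``response_floor_k`` times the raw tail SD is flagged invalid with a
    "no-response" reason instead of yielding a spurious dist50 — this is
    how non-producer (pks-) controls surface.  The floor default (k = 5)
    sits above the expected extreme of the raw noise because the profile's
    outermost sample — often the aligned peak itself — has no smoothing
    support and passes through at raw noise amplitude.
    """
    d, smoothed, mask, baseline, tail_sd = _prepare(
        profile, channel, window, n_tail, baseline_on
    )
    max_signal, _ = peak_signal(d, smoothed, mask)
    reasons: list[str] = []
    if max_signal - baseline <= response_floor_k * tail_sd:
        return DecayResult(
            distances=d, smoothed=smoothed, baseline=baseline,
            max_signal=max_signal, yfp50=np.nan, dist50=None,
            contact_class="contacting", valid=False, reasons=("no-response",),
        )
    if subtract:
        smoothed = subtract_baseline(smoothed, baseline)
        max_signal -= baseline
        baseline = 0.0
    yfp50 = compute_yfp50(max_signal, baseline)
    result = compute_dist50(d, smoothed, yfp50, mask)
    if result.flag:
        reasons.append(result.flag)
    return DecayResult(
        distances=d, smoothed=smoothed, baseline=baseline, max_signal=max_signal,
        yfp50=yfp50, dist50=result.value, contact_class="contacting",
        valid=result.value is not None, reasons=tuple(reasons),
    )


def analyze_noncontacting(
    profile: CrossSectionProfile,
    yfp50_reference: float,
    channel: str = "YFP",
    window: int = 20,
    n_tail: int = 20,
    subtract: bool = True,
    baseline_on: str = "smoothed",
) -> DecayResult:
    """Decay analysis of a non-contacting colony pair.

    The profile must be aligned to the producer edge with the agar gap
    masked.  ``yfp50_reference`` is the YFP50 measured on contacting
    colonies (averaged across replicates) on the same intensity scale —
    i.e. the baseline-subtracted scale when ``subtract`` is True, which is
    the default because per-colony baselines differ.
    """
    d, smoothed, mask, baseline, tail_sd = _prepare(
        profile, channel, window, n_tail, baseline_on
    )
    max_signal, _ = peak_signal(d, smoothed, mask)
    if subtract:
        smoothed = subtract_baseline(smoothed, baseline)
        max_signal -= baseline
        baseline = 0.0
    result = infer_dist50_noncontacting(d, smoothed, yfp50_reference, mask)
    return DecayResult(
        distances=d, smoothed=smoothed, baseline=baseline, max_signal=max_signal,
        yfp50=yfp50_reference, dist50=result.value, contact_class="non-contacting",
        valid=result.value is not None,
        reasons=(result.flag,) if result.flag else (),
    )
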