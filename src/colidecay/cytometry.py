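"""Flow-cytometry gating, classification and percent-positive analysis.

Mirrors the event-level analysis of the co-culture experiments: events
are first cleaned of debris on forward/side scatter area, then restricted
to single cells on the forward-scatter area/height relation; single cells
are classified as reporters (high CFP) or producers (high mCherry); and
the DNA-damage-positive fraction of reporters is the share of events whose
YFP exceeds a conservative cutoff of mean + 3 SD computed once on the
t = 0 h reporter distribution and reused at every later time point.

Gate geometry is configuration, not hard-coded numbers — cytometer scales
vary and the original gates were drawn visually on overlaid control
populations.  :func:`default_gates` derives a reasonable tree from a
reference (clean single-cell) sample: a scatter rectangle placed several
log-SDs below the reference cluster, and a singlet band on the
FSC-H/FSC-A ratio around the reference median (doublets sit near half the
singlet ratio).  Event tables are plain pandas DataFrames in the CSV
schema of :mod:`colidecay.scene`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GateSpec",
    "GatingResult",
    "ThresholdClassification",
    "apply_gates",
    "default_gates",
    "classify_populations",
    "compute_cutoff",
    "percent_positive",
    "timecourse",
    "lysis_fraction",
]

ROOT_GATE = "all_events"


@dataclass(frozen=True)
class GateSpec:
    """One node of a gating tree.

    kinds:
      - ``rectangle``: two channels, bounds (xmin, xmax, ymin, ymax);
        None means unbounded on that side.
      - ``threshold``: one channel, bounds (lo, hi).
      - ``ratio_band``: channels (numerator, denominator), bounds (lo, hi)
        on their ratio.
    """

    name: str
    kind: str
    channels: tuple[str, ...]
    bounds: tuple[float | None, ...]
    parent: str | None = None  # None = root ("all_events")


@dataclass
class GatingResult:
    membership: dict[str, np.ndarray]
    counts: pd.DataFrame

    def events_in(self, gate: str) -> np.ndarray:
        return self.membership[gate]


@dataclass
class ThresholdClassification:
    cutoff: float
    n_total: int
    n_positive: int

    @property
    def percent_positive(self) -> float:
        return 100.0 * self.n_positive / self.n_total


def _bounded(values: np.ndarray, lo: float | None, hi: float | None) -> np.ndarray:
    out = np.ones(values.shape, dtype=bool)
    if lo is not None:
        out &= values >= lo
    if hi is not None:
        out &= values <= hi
    return out


def _gate_predicate(table: pd.DataFrame, gate: GateSpec) -> np.ndarray:
    for ch in gate.channels:
        if ch not in table.columns:
            raise ValueError(f"gate {gate.name!r} references missing channel {ch!r}")
    if gate.kind == "rectangle":
        cx, cy = gate.channels
        xmin, xmax, ymin, ymax = gate.bounds
        return _bounded(table[cx].to_numpy(), xmin, xmax) & _bounded(
            table[cy].to_numpy(), ymin, ymax
        )
    if gate.kind == "threshold":
        (ch,) = gate.channels
        lo, hi = gate.bounds
        return _bounded(table[ch].to_numpy(), lo, hi)
    if gate.kind == "ratio_band":
        num, den = gate.channels
        lo, hi = gate.bounds
        ratio = table[num].to_numpy() / table[den].to_numpy()
        return _bounded(ratio, lo, hi)
    raise ValueError(f"unknown gate kind {gate.kind!r}")


def apply_gates(table: pd.DataFrame, gates: Sequence[GateSpec]) -> GatingResult:
    """Evaluate a gate tree; membership of a gate implies membership of its
    parent.  The tree must be rooted at ``all_events`` (parent None) and
    acyclic; violations raise ``ValueError``."""
    n = len(table)
    membership: dict[str, np.ndarray] = {ROOT_GATE: np.ones(n, dtype=bool)}
    pending = list(gates)
    names = {g.name for g in pending}
    if ROOT_GATE in names:
        raise ValueError(f"{ROOT_GATE!r} is reserved for the root")
    if len(names) != len(pending):
        raise ValueError("duplicate gate names")
    while pending:
        progressed = False
        for gate in list(pending):
            parent = gate.parent or ROOT_GATE
            if parent in membership:
                membership[gate.name] = membership[parent] & _gate_predicate(table, gate)
                pending.remove(gate)
                progressed = True
        if not progressed:
            stuck = [g.name for g in pending]
            raise ValueError(
                f"gate graph is not a tree rooted at {ROOT_GATE!r} "
                f"(cycle or missing parent) for gates: {stuck}"
            )
    counts = pd.DataFrame(
        {
            "gate": [ROOT_GATE, *(g.name for g in gates)],
            "parent": [None, *((g.parent or ROOT_GATE) for g in gates)],
            "n": [int(membership[ROOT_GATE].sum()),
                  *(int(membership[g.name].sum()) for g in gates)],
        }
    )
    return GatingResult(membership=membership, counts=counts)


def default_gates(
    reference: pd.DataFrame,
    debris_margin_logsd: float = 6.0,
    singlet_band: tuple[float, float] = (2.0 / 3.0, 3.0 / 2.0),
) -> list[GateSpec]:
    """Derive the standard debris + singlet tree from a reference sample.

    The reference should be a clean single-cell population (the role the
    overlaid control samples played when gates were drawn by eye).  The
    debris rectangle keeps events whose FSC-A and SSC-A exceed the
    reference log-mean minus ``debris_margin_logsd`` log-SDs — i.e. the
    bound sits in the empty valley below the cell cluster.  The singlet
    gate keeps events whose FSC-H/FSC-A ratio lies within
    ``singlet_band`` times the reference median ratio; doublets, whose
    area doubles while height does not, fall at about half the singlet
    ratio and are excluded.
    """
    bounds = {}
    for ch in ("FSC_A", "SSC_A"):
        logs = np.log(reference[ch].to_numpy())
        bounds[ch] = float(np.exp(logs.mean() - debris_margin_logsd * logs.std(ddof=1)))
    ratio = (reference["FSC_H"] / reference["FSC_A"]).to_numpy()
    med = float(np.median(ratio))
    return [
        GateSpec(
            name="cells",
            kind="rectangle",
            channels=("FSC_A", "SSC_A"),
            bounds=(bounds["FSC_A"], None, bounds["SSC_A"], None),
        ),
        GateSpec(
            name="singlets",
            kind="ratio_band",
            channels=("FSC_H", "FSC_A"),
            bounds=(med * singlet_band[0], med * singlet_band[1]),
            parent="cells",
        ),
    ]


def classify_populations(
    table: pd.DataFrame, cfp_cutoff: float, mcherry_cutoff: float
) -> np.ndarray:
    """Per-event class: reporter (high CFP, low mCherry), producer (high
    mCherry, low CFP), otherwise unclassified (both-high or both-low)."""
    if not (np.isfinite(cfp_cutoff) and np.isfinite(mcherry_cutoff)):
        raise ValueError("cutoffs must be finite")
    cfp_high = table["CFP_A"].to_numpy() >= cfp_cutoff
    mch_high = table["mCherry_A"].to_numpy() >= mcherry_cutoff
    out = np.full(len(table), "unclassified", dtype=object)
    out[cfp_high & ~mch_high] = "reporter"
    out[mch_high & ~cfp_high] = "producer"
    return out


def compute_cutoff(t0_values: np.ndarray) -> float:
    """Mean + 3 sample SD (n-1 denominator) of the t = 0 h distribution."""
    values = np.asarray(t0_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to compute a cutoff")
    return float(values.mean() + 3.0 * values.std(ddof=1))


def percent_positive(values: np.ndarray, cutoff: float) -> ThresholdClassification:
    """Fraction of values strictly above the cutoff (ties count negative —
    the conservative convention)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value vector")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    n_pos = int(np.sum(values > cutoff))
    return ThresholdClassification(cutoff=float(cutoff), n_total=values.size,
                                   n_positive=n_pos)


def _gated_reporter_values(
    table: pd.DataFrame,
    gates: Sequence[GateSpec],
    cfp_cutoff: float,
    mcherry_cutoff: float,
    channel: str,
    transform: Callable[[np.ndarray], np.ndarray] | None,
) -> tuple[np.ndarray, int, int]:
    gating = apply_gates(table, gates)
    leaf = gates[-1].name if gates else ROOT_GATE
    in_gate = gating.membership[leaf]
    classes = classify_populations(table, cfp_cutoff, mcherry_cutoff)
    sel = in_gate & (classes == "reporter")
    values = table.loc[sel, channel].to_numpy(dtype=float)
    if transform is not None:
        values = transform(values)
    return values, int(in_gate.sum()), int(sel.sum())


def timecourse(
    tables: Mapping[float, pd.DataFrame],
    gates: Sequence[GateSpec],
    cfp_cutoff: float,
    mcherry_cutoff: float,
    channel: str = "YFP_A",
    transform: Callable[[np.ndarray], np.ndarray] | None = np.log,
) -> pd.DataFrame:
    """Percent DNA-damage-positive reporters over time.

    One cutoff (mean + 3 SD) is computed on the gated, reporter-classified
    YFP distribution at t = 0 h and reused unchanged at every time point.
    Fluorescence is log-transformed by default before the cutoff rule,
    matching the log-normal shape of cytometer intensity distributions;
    pass ``transform=None`` to threshold raw intensities.
    Returns one row per time: time_h, n_gated, n_reporter, cutoff,
    percent_positive.
    """
    if 0 not in tables and 0.0 not in tables:
        raise ValueError("timecourse requires a t = 0 h table")
    t0 = tables[0] if 0 in tables else tables[0.0]
    t0_values, _, _ = _gated_reporter_values(
        t0, gates, cfp_cutoff, mcherry_cutoff, channel, transform
    )
    cutoff = compute_cutoff(t0_values)
    rows = []
    for time in sorted(tables):
        values, n_gated, n_reporter = _gated_reporter_values(
            tables[time], gates, cfp_cutoff, mcherry_cutoff, channel, transform
        )
        cls = percent_positive(values, cutoff)
        rows.append(
            {
                "time_h": float(time),
                "n_gated": n_gated,
                "n_reporter": n_reporter,
                "cutoff": cutoff,
                "percent_positive": cls.percent_positive,
            }
        )
    return pd.DataFrame(rows)


def lysis_fraction(
    table: pd.DataFrame,
    pe_cutoff: float,
    gates: Sequence[GateSpec] = (),
) -> float:
    """Percent of gated (singlet) events above the propidium-iodide (PE)
    cutoff — the lysed/dead-cell fraction."""
    if "PE_A" not in table.columns:
        raise ValueError("table has no PE_A channel")
    gating = apply_gates(table, list(gates))
    leaf = gates[-1].name if gates else ROOT_GATE
    values = table.loc[gating.membership[leaf], "PE_A"].to_numpy(dtype=float)
    return percent_positive(values, pe_cutoff).percent_positive
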