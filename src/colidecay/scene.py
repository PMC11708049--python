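"""Synthetic plate scenes and flow-event mixtures with known ground truth.

The experiments this package analyses were recorded as multichannel plate
microscopy (CFP-tagged reporter cells carrying a recA-promoter YFP fusion,
mCherry-tagged producer colonies) and as flow-cytometry event tables.  No
raw data are available, so every downstream stage is exercised against
synthetic scenes generated here, where every parameter of interest — the
toxin decay length, colony geometry, reporter gain, responder fraction —
is known exactly and therefore recoverable.

The toxin field is modelled as secretion with first-order loss: uniform at
amplitude ``A`` inside a producer colony footprint and decaying as
``A·exp(-(r - R)/λ)`` with edge distance outside it, ``λ`` being the decay
length in µm.  Fields of multiple colonies combine by maximum, which keeps
the single-colony closed form exact near each colony (a sum-combination is
available via ``combine="sum"``).  The reporter channel responds linearly:
``YFP = b + g·T`` inside reporter regions, with additive Gaussian noise,
clipped at zero and quantized to 16-bit.  This is deliberately simpler
than camera physics or a 2-D diffusion (Bessel-K0) solution; it is exactly
solvable, which is what the recovery tests need.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .profiles import ImageSet, write_image_set

__all__ = [
    "Colony",
    "SceneGroundTruth",
    "FlowPopulationSpec",
    "simulate_toxin_field",
    "render_scene",
    "render_colony_pair",
    "sample_flow_events",
    "write_scene",
    "read_ground_truth",
    "write_flow_csv",
    "read_flow_csv",
    "marker_cutoffs",
    "FLOW_COLUMNS",
    "FLOW_LABELS",
]


@dataclass(frozen=True)
class Colony:
    """A disc footprint: centre (x, y) in µm and radius in µm."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("colony radius must be positive")


@dataclass
class SceneGroundTruth:
    """Full parameterization of a synthetic plate scene.

    ``pixel_size`` is mandatory: the imaging magnification-to-µm
    calibration is instrument configuration, not something the model can
    guess.  Intensity units are arbitrary camera counts.
    """

    pixel_size: float  # µm / pixel
    producer_colonies: list[Colony]
    image_shape: tuple[int, int] = (512, 512)  # (rows, cols)
    reporter_lawn: bool = True
    reporter_colonies: list[Colony] = field(default_factory=list)
    toxin_amplitude: float = 1000.0  # A, arbitrary units
    decay_length: float = 300.0  # λ, µm
    yfp_baseline: float = 100.0  # b
    yfp_gain: float = 1.0  # g, counts per unit toxin
    cfp_level: float = 600.0
    mcherry_level: float = 800.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        rows, cols = self.image_shape
        if rows < 2 or cols < 2:
            raise ValueError("image_shape must be at least 2x2")
        width = (cols - 1) * self.pixel_size
        height = (rows - 1) * self.pixel_size
        for colony in [*self.producer_colonies, *self.reporter_colonies]:
            cx, cy = colony.center
            r = colony.radius
            if not (r <= cx <= width - r and r <= cy <= height - r):
                raise ValueError(
                    f"colony at {colony.center} with radius {r} µm does not lie "
                    "fully inside the image"
                )

    def grid_um(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-centre coordinate grids (xx, yy) in µm."""
        rows, cols = self.image_shape
        x = np.arange(cols) * self.pixel_size
        y = np.arange(rows) * self.pixel_size
        return np.meshgrid(x, y)


def _footprint_mask(gt: SceneGroundTruth, colonies: list[Colony]) -> np.ndarray:
    xx, yy = gt.grid_um()
    mask = np.zeros(gt.image_shape, dtype=bool)
    for colony in colonies:
        cx, cy = colony.center
        mask |= (xx - cx) ** 2 + (yy - cy) ** 2 <= colony.radius**2
    return mask


def simulate_toxin_field(gt: SceneGroundTruth, combine: str = "max") -> np.ndarray:
    """Evaluate the toxin concentration field on the image grid.

    Per colony the field equals the amplitude ``A`` inside the footprint
    and ``A·exp(-(r - R)/λ)`` outside, with ``r`` the distance to the
    colony centre.  Multi-colony fields combine by ``max`` (default) or
    ``sum``.
    """
    if not gt.producer_colonies:
        raise ValueError("scene has no source: no producer colonies")
    if combine not in ("max", "sum"):
        raise ValueError("combine must be 'max' or 'sum'")
    xx, yy = gt.grid_um()
    fields = []
    for colony in gt.producer_colonies:
        cx, cy = colony.center
        r = np.hypot(xx - cx, yy - cy)
        edge_dist = np.maximum(r - colony.radius, 0.0)
        fields.append(gt.toxin_amplitude * np.exp(-edge_dist / gt.decay_length))
    stacked = np.stack(fields)
    return stacked.max(axis=0) if combine == "max" else stacked.sum(axis=0)


def _quantize(arr: np.ndarray) -> np.ndarray:
    return np.rint(np.clip(arr, 0.0, 65535.0)).astype(np.uint16)


def render_scene(gt: SceneGroundTruth, combine: str = "max") -> ImageSet:
    """Render the CFP/YFP/mCherry channels of a scene as 16-bit rasters.

    Reporter regions (the lawn outside producer footprints, or explicit
    reporter colonies) express constitutive CFP and toxin-responsive YFP
    (``b + g·T``); producer footprints express constitutive mCherry.
    Zero-mean Gaussian noise (``noise_sd``) is added everywhere, then
    values are clipped at 0 and quantized to the 16-bit range.
    """
    producer_mask = _footprint_mask(gt, gt.producer_colonies)
    if gt.reporter_lawn:
        reporter_mask = ~producer_mask
    else:
        for rep in gt.reporter_colonies:
            for prod in gt.producer_colonies:
                dist = np.hypot(rep.center[0] - prod.center[0],
                                rep.center[1] - prod.center[1])
                if dist < rep.radius + prod.radius - 1e-9:
                    raise ValueError("reporter and producer footprints overlap")
        # tangent discs may share boundary pixels after rasterization;
        # those belong to the producer
        reporter_mask = _footprint_mask(gt, gt.reporter_colonies) & ~producer_mask

    toxin = simulate_toxin_field(gt, combine=combine)
    yfp = np.where(reporter_mask, gt.yfp_baseline + gt.yfp_gain * toxin, 0.0)
    cfp = np.where(reporter_mask, gt.cfp_level, 0.0)
    mcherry = np.where(producer_mask, gt.mcherry_level, 0.0)

    if gt.noise_sd > 0:
        rng = np.random.default_rng(gt.seed)
        yfp = yfp + rng.normal(0.0, gt.noise_sd, gt.image_shape)
        cfp = cfp + rng.normal(0.0, gt.noise_sd, gt.image_shape)
        mcherry = mcherry + rng.normal(0.0, gt.noise_sd, gt.image_shape)

    channels = {"CFP": _quantize(cfp), "YFP": _quantize(yfp), "mCherry": _quantize(mcherry)}
    return ImageSet(channels=channels, pixel_size=gt.pixel_size,
                    metadata={"ground_truth": ground_truth_dict(gt)})


def render_colony_pair(
    gt: SceneGroundTruth, gap: float, reporter_radius: float | None = None
) -> ImageSet:
    """Render a producer/reporter colony pair at a controlled edge gap.

    The producer disc is ``gt.producer_colonies[0]``; the reporter disc is
    placed to its right on the same horizontal line so that the
    nearest-edge distance equals ``gap`` (``gap = 0`` encodes contacting
    colonies).  Reporter YFP follows the same toxin-response law,
    restricted to the reporter footprint.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    producer = gt.producer_colonies[0]
    if reporter_radius is None:
        if gt.reporter_colonies:
            reporter_radius = gt.reporter_colonies[0].radius
        else:
            reporter_radius = producer.radius
    px, py = producer.center
    center = (px + producer.radius + gap + reporter_radius, py)
    rows, cols = gt.image_shape
    width = (cols - 1) * gt.pixel_size
    height = (rows - 1) * gt.pixel_size
    if not (
        reporter_radius <= center[0] <= width - reporter_radius
        and reporter_radius <= center[1] <= height - reporter_radius
    ):
        raise ValueError("gap too large: reporter colony leaves the image")
    reporter = Colony(center=center, radius=reporter_radius)
    pair_gt = dataclasses.replace(
        gt,
        producer_colonies=[producer],
        reporter_lawn=False,
        reporter_colonies=[reporter],
    )
    img = render_scene(pair_gt)
    img.metadata.update(
        producer_center=producer.center,
        producer_radius=producer.radius,
        reporter_center=reporter.center,
        reporter_radius=reporter.radius,
        gap_um=gap,
    )
    return img


# ---------------------------------------------------------------------------
# Ground-truth sidecar I/O


def ground_truth_dict(gt: SceneGroundTruth) -> dict:
    d = dataclasses.asdict(gt)
    d["producer_colonies"] = [
        {"center": list(c.center), "radius": c.radius} for c in gt.producer_colonies
    ]
    d["reporter_colonies"] = [
        {"center": list(c.center), "radius": c.radius} for c in gt.reporter_colonies
    ]
    d["image_shape"] = list(gt.image_shape)
    return d


def write_scene(gt: SceneGroundTruth, directory: str | Path, scene: str) -> dict[str, Path]:
    """Render and write a scene: per-channel TIFFs plus a YAML ground-truth
    sidecar ``<scene>_groundtruth.yaml`` recording all parameters."""
    img = render_scene(gt)
    paths = write_image_set(img, directory, scene)
    sidecar = Path(directory) / f"{scene}_groundtruth.yaml"
    with open(sidecar, "w") as fh:
        yaml.safe_dump(ground_truth_dict(gt), fh, sort_keys=True)
    paths["ground_truth"] = sidecar
    return paths


def read_ground_truth(path: str | Path) -> SceneGroundTruth:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["producer_colonies"] = [
        Colony(center=tuple(c["center"]), radius=c["radius"])
        for c in d["producer_colonies"]
    ]
    d["reporter_colonies"] = [
        Colony(center=tuple(c["center"]), radius=c["radius"])
        for c in d["reporter_colonies"]
    ]
    d["image_shape"] = tuple(d["image_shape"])
    return SceneGroundTruth(**d)


# ---------------------------------------------------------------------------
# Flow-event mixtures

FLOW_COLUMNS = (
    "event_id", "FSC_A", "FSC_H", "SSC_A", "CFP_A", "YFP_A", "mCherry_A", "PE_A", "label",
)
FLOW_LABELS = (
    "reporter-responder",
    "reporter-nonresponder",
    "producer",
    "debris",
    "doublet",
    "lysed",
)

_DEFAULT_LOG_MEANS = {
    "FSC_A": 11.0,
    "SSC_A": 10.0,
    "CFP_A": 6.0,
    "YFP_A": 6.0,
    "mCherry_A": 5.0,
    "PE_A": 4.0,
}
_DEFAULT_LOG_SDS = {
    "FSC_A": 0.25,
    "SSC_A": 0.25,
    "CFP_A": 0.3,
    "YFP_A": 0.4,
    "mCherry_A": 0.3,
    "PE_A": 0.4,
}


@dataclass
class FlowPopulationSpec:
    """Log-normal mixture of flow-cytometry subpopulations.

    Channel values are log-normal: per channel a base log-mean/log-SD
    describes the "low" state, and marker offsets (on the log scale) lift
    the relevant channel for each subpopulation.  Reporters carry the CFP
    marker, producers the mCherry marker; reporter-responders additionally
    carry the YFP shift.  FSC-H tracks FSC-A with a small multiplicative
    jitter; doublets double FSC-A (and SSC-A) while keeping singlet-like
    FSC-H, which is exactly the signature singlet gating exploits.  Lysed
    cells carry the propidium-iodide (PE) shift.  The defaults emulate a
    10:1 producer:reporter co-culture with a plateau responder fraction of
    0.4 and a six-log-SD YFP separation between responders and
    non-responders.
    """

    n_events: int = 100_000
    responder_fraction: float = 0.4
    channel_log_means: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOG_MEANS)
    )
    channel_log_sds: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_LOG_SDS)
    )
    yfp_shift: float = 2.4  # log-scale offset for responders (= 6 × YFP log-SD)
    marker_shift: float = 3.0  # log offset for the CFP (reporter) / mCherry (producer) tags
    debris_shift: float = 3.0  # log offset subtracted from debris FSC-A/SSC-A
    pe_shift: float = 4.0  # log offset added to lysed cells' PE-A
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.03
    lysed_fraction: float = 0.0
    producer_to_reporter_ratio: float = 10.0
    fsc_h_jitter_sd: float = 0.05
    count_mode: str = "deterministic"  # or "multinomial"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")
        for name in ("responder_fraction", "debris_fraction", "doublet_fraction",
                     "lysed_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.debris_fraction + self.doublet_fraction + self.lysed_fraction > 1.0:
            raise ValueError("mutually exclusive fractions sum to more than 1")
        if self.producer_to_reporter_ratio < 0:
            raise ValueError("producer_to_reporter_ratio must be non-negative")
        if self.count_mode not in ("deterministic", "multinomial"):
            raise ValueError("count_mode must be 'deterministic' or 'multinomial'")


def _label_fractions(spec: FlowPopulationSpec) -> dict[str, float]:
    cell = 1.0 - spec.debris_fraction - spec.doublet_fraction - spec.lysed_fraction
    ratio = spec.producer_to_reporter_ratio
    producer = cell * ratio / (1.0 + ratio)
    reporter = cell - producer
    return {
        "debris": spec.debris_fraction,
        "doublet": spec.doublet_fraction,
        "lysed": spec.lysed_fraction,
        "producer": producer,
        "reporter-responder": reporter * spec.responder_fraction,
        "reporter-nonresponder": reporter * (1.0 - spec.responder_fraction),
    }


def _group_counts(spec: FlowPopulationSpec, rng: np.random.Generator) -> dict[str, int]:
    if spec.count_mode == "multinomial":
        fractions = _label_fractions(spec)
        labels = list(fractions)
        draws = rng.multinomial(spec.n_events, [fractions[k] for k in labels])
        return dict(zip(labels, (int(v) for v in draws)))
    n = spec.n_events
    n_debris = int(round(n * spec.debris_fraction))
    n_doublet = int(round(n * spec.doublet_fraction))
    n_lysed = int(round(n * spec.lysed_fraction))
    n_cells = max(n - n_debris - n_doublet - n_lysed, 0)
    ratio = spec.producer_to_reporter_ratio
    n_producer = int(round(n_cells * ratio / (1.0 + ratio)))
    n_reporter = n_cells - n_producer
    n_resp = int(round(n_reporter * spec.responder_fraction))
    counts = {
        "debris": n_debris,
        "doublet": n_doublet,
        "lysed": n_lysed,
        "producer": n_producer,
        "reporter-responder": n_resp,
        "reporter-nonresponder": n_reporter - n_resp,
    }
    # deterministic counts: trim/extend the largest group on rounding drift
    drift = n - sum(counts.values())
    if drift:
        key = max(counts, key=counts.get)
        counts[key] += drift
    return counts


def sample_flow_events(spec: FlowPopulationSpec) -> pd.DataFrame:
    """Draw a seeded, bit-reproducible flow-event table with ground-truth
    labels.  Label counts always sum to ``n_events``: with the default
    ``count_mode="deterministic"`` group sizes are rounded from the
    requested fractions (so a recovery test sees the exact ground-truth
    fraction), while ``"multinomial"`` resamples them per draw, emulating
    the sampling variation between biological replicates."""
    rng = np.random.default_rng(spec.seed)
    counts = _group_counts(spec, rng)
    means = spec.channel_log_means
    sds = spec.channel_log_sds

    frames: list[pd.DataFrame] = []
    for label in FLOW_LABELS:
        k = counts[label]
        if k == 0:
            continue
        logs = {
            ch: rng.normal(means[ch], sds[ch], size=k)
            for ch in ("FSC_A", "SSC_A", "CFP_A", "YFP_A", "mCherry_A", "PE_A")
        }
        if label in ("reporter-responder", "reporter-nonresponder", "doublet", "lysed"):
            logs["CFP_A"] += spec.marker_shift  # reporter tag
        if label == "producer":
            logs["mCherry_A"] += spec.marker_shift
        if label == "reporter-responder":
            logs["YFP_A"] += spec.yfp_shift
        if label == "debris":
            logs["FSC_A"] -= spec.debris_shift
            logs["SSC_A"] -= spec.debris_shift
        if label == "lysed":
            logs["PE_A"] += spec.pe_shift
        logs["FSC_H"] = logs["FSC_A"] + rng.normal(0.0, spec.fsc_h_jitter_sd, size=k)
        if label == "doublet":
            # two cells in one event: areas double, height stays single-cell
            logs["FSC_A"] += np.log(2.0)
            logs["SSC_A"] += np.log(2.0)
        frame = pd.DataFrame({ch: np.exp(v) for ch, v in logs.items()})
        frame["label"] = label
        frames.append(frame)

    if frames:
        df = pd.concat(frames, ignore_index=True)
        order = rng.permutation(len(df))
        df = df.iloc[order].reset_index(drop=True)
    else:
        df = pd.DataFrame({ch: pd.Series(dtype=float)
                           for ch in ("FSC_A", "FSC_H", "SSC_A", "CFP_A",
                                      "YFP_A", "mCherry_A", "PE_A")})
        df["label"] = pd.Series(dtype=str)
    df.insert(0, "event_id", np.arange(len(df)))
    return df[list(FLOW_COLUMNS)]


def marker_cutoffs(spec: FlowPopulationSpec) -> tuple[float, float]:
    """Mid-valley CFP/mCherry cutoffs for reporter/producer classification,
    placed at the geometric midpoint between the low and tagged states."""
    cfp = np.exp(spec.channel_log_means["CFP_A"] + spec.marker_shift / 2.0)
    mcherry = np.exp(spec.channel_log_means["mCherry_A"] + spec.marker_shift / 2.0)
    return float(cfp), float(mcherry)


def write_flow_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_flow_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FLOW_COLUMNS if c not in df.columns and c != "label"]
    if missing:
        raise ValueError(f"flow CSV missing required columns: {missing}")
    return df
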