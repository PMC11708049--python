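"""End-to-end assay runs: simulate -> extract -> analyze -> report.

Each ``run_*`` function reproduces one assay of the study design on
synthetic scenes with known ground truth, from generation through the
final summary table:

- :func:`run_lawn_assay` — producer colony on a reporter lawn; radial
  YFP decay, dist50 per technical replicate, replicate-averaged curves.
- :func:`run_colony_assay` — contacting (gap 0) vs non-contacting
  (gap >= 10 µm) producer/reporter colony pairs; per-replicate mean dist50
  per group and the Welch equivalence test between groups.
- :func:`run_flow_timecourse` — percent DNA-damage-positive reporter
  cells over co-culture time, with the t = 0 h cutoff reused throughout.
- :func:`run_lysis` — propidium-iodide-positive fractions per strain with
  a Welch test between strains.
- :func:`run_contamination` — CFU back-calculation from a serial-dilution
  series and the exact upper bound on producer contamination.

The generator defaults emulate the study conditions: decay lengths are
set from the observed saturation dist50 values via dist50 = λ·ln 2
(engineered lawn 208 µm -> λ = 300 µm; natural lawn 116 µm -> λ = 167 µm;
engineered colony pairs 117 µm -> λ = 170 µm; natural 80 µm -> λ = 115 µm),
three biological replicates per condition, 10 technical
replicates/colony pairs each, a 10:1 producer:reporter co-culture and a
plateau responder fraction of 0.4.  All randomness flows from a single
integer seed; identical configuration yields bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import decay as dk
from . import profiles as pf
from . import scene as sc
from . import stats as st
from . import cytometry as cy

__all__ = [
    "ENGINEERED_LAWN_DECAY_UM",
    "NATURAL_LAWN_DECAY_UM",
    "ENGINEERED_COLONY_DECAY_UM",
    "NATURAL_COLONY_DECAY_UM",
    "RunConfig",
    "load_config",
    "run_from_config",
    "run_lawn_assay",
    "run_colony_assay",
    "run_flow_timecourse",
    "run_lysis",
    "run_contamination",
    "LawnAssayResult",
    "ColonyAssayResult",
    "LysisResult",
    "ContaminationResult",
]

# decay lengths emulating the two producer strains, fixed via dist50 = λ·ln 2
ENGINEERED_LAWN_DECAY_UM = 300.0
NATURAL_LAWN_DECAY_UM = 167.0
ENGINEERED_COLONY_DECAY_UM = 170.0
NATURAL_COLONY_DECAY_UM = 115.0


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] & 0x7FFFFFFF) for child in ss.spawn(n)]


def _write_manifest(outdir: Path, assay: str, params: dict) -> None:
    manifest = {"assay": assay, "parameters": params}
    with open(outdir / "run_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def _plot_average(average: pd.DataFrame, path: Path, title: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(average["distance_um"], average["mean"], color="goldenrod", lw=2)
    sd = average["sd"].fillna(0.0)
    ax.fill_between(
        average["distance_um"], average["mean"] - sd, average["mean"] + sd,
        color="goldenrod", alpha=0.3,
    )
    ax.set_xlabel("distance (µm)")
    ax.set_ylabel("YFP intensity (a.u.)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Lawn assay


@dataclass
class LawnAssayResult:
    results: pd.DataFrame  # one row per colony
    average: pd.DataFrame  # replicate-averaged decay curve
    dist50_summary: st.ReplicateSummary


def run_lawn_assay(
    n_colonies: int = 10,
    decay_length: float = ENGINEERED_LAWN_DECAY_UM,
    pixel_size: float = 4.0,
    colony_radius: float = 500.0,
    amplitude: float = 1000.0,
    baseline: float = 100.0,
    gain: float = 1.0,
    noise_sd: float = 20.0,
    profile_length: float | None = None,
    step: float | None = None,
    window: int = 20,
    n_tail: int = 20,
    seed: int = 0,
    outdir: str | Path | None = None,
    plot: bool = False,
) -> LawnAssayResult:
    """Lawn assay: one producer colony per scene, one radial cross-section
    per colony, aligned to the YFP peak.

    Each scene is a technical replicate (separate scenes keep the
    single-colony field exact; on a shared plate neighbouring tails would
    perturb each other's profile).  ``profile_length`` defaults to eight
    decay lengths so the baseline tail is effectively at the far field.
    """
    if profile_length is None:
        profile_length = 8.0 * decay_length
    pad = 8 * pixel_size
    cx = colony_radius + pad
    cy = colony_radius + pad
    width = cx + colony_radius + profile_length + pad
    height = 2 * cy
    shape = (int(np.ceil(height / pixel_size)) + 1, int(np.ceil(width / pixel_size)) + 1)

    rows = []
    aligned_profiles = []
    seeds = _child_seeds(seed, n_colonies)
    for i, scene_seed in enumerate(seeds):
        gt = sc.SceneGroundTruth(
            pixel_size=pixel_size,
            image_shape=shape,
            producer_colonies=[sc.Colony(center=(cx, cy), radius=colony_radius)],
            reporter_lawn=True,
            toxin_amplitude=amplitude,
            decay_length=decay_length,
            yfp_baseline=baseline,
            yfp_gain=gain,
            noise_sd=noise_sd,
            seed=scene_seed,
        )
        img = sc.render_scene(gt)
        profile = pf.extract_cross_section(
            img, p0=(cx, cy), p1=(cx + colony_radius + profile_length, cy), step=step
        )
        # lawn-assay origin: the YFP peak (raw argmax; the profile is then
        # re-smoothed on the aligned, masked samples only)
        _, peak_d = dk.peak_signal(profile.distances, profile.channel("YFP"))
        aligned = pf.align_profile(profile, peak_d, "yfp-peak")
        result = dk.analyze_contacting(
            aligned, window=window, n_tail=n_tail, subtract=False
        )
        rows.append(
            {
                "scene": f"lawn-{i:02d}",
                "contact_class": result.contact_class,
                "gap_um": 0.0,
                "baseline": result.baseline,
                "max_signal": result.max_signal,
                "yfp50": result.yfp50,
                "dist50_um": result.dist50,
                "valid": result.valid,
                "reason": ";".join(result.reasons),
            }
        )
        if result.valid:
            aligned_profiles.append((result.distances, result.smoothed, aligned.mask))

    results = pd.DataFrame(rows)
    valid_d50 = results.loc[results["valid"], "dist50_um"].to_numpy(dtype=float)
    if valid_d50.size == 0:
        raise ValueError(
            "no valid colonies in lawn assay; reasons: "
            + ", ".join(results["reason"].unique())
        )
    average = dk.average_decays(aligned_profiles)
    summary = st.summarize("lawn", valid_d50)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results.to_csv(outdir / "lawn_results.csv", index=False)
        average.to_csv(outdir / "lawn_average_decay.csv", index=False)
        _write_manifest(outdir, "lawn", {
            "n_colonies": n_colonies, "decay_length": decay_length,
            "pixel_size": pixel_size, "colony_radius": colony_radius,
            "amplitude": amplitude, "baseline": baseline, "gain": gain,
            "noise_sd": noise_sd, "profile_length": profile_length,
            "window": window, "n_tail": n_tail, "seed": seed,
        })
        if plot:
            _plot_average(average, outdir / "lawn_average_decay.png",
                          "Mean YFP decay from the producer-colony edge")
    return LawnAssayResult(results=results, average=average, dist50_summary=summary)


# ---------------------------------------------------------------------------
# Colony-pair assay


@dataclass
class ColonyAssayResult:
    results: pd.DataFrame  # one row per colony pair
    replicate_means: pd.DataFrame  # replicate × group mean dist50
    reference_yfp50: float
    ttest: st.TTestResult | None


def _analyze_pair(
    img: pf.ImageSet,
    gap: float,
    reference_yfp50: float | None,
    step: float | None,
    window: int,
    n_tail: int,
) -> dk.DecayResult:
    """Extract the producer-centre -> reporter-far-edge section, align to
    the detected mCherry edge, mask the agar gap, analyze."""
    ps = img.pixel_size
    px, py = img.metadata["producer_center"]
    rx, ry = img.metadata["reporter_center"]
    rr = img.metadata["reporter_radius"]
    direction = np.array([rx - px, ry - py])
    direction = direction / np.hypot(*direction)
    p1 = np.array([rx, ry]) + direction * (rr - 2 * ps)
    profile = pf.extract_cross_section(img, p0=(px, py), p1=tuple(p1), step=step)
    edge = pf.detect_producer_edge(profile, channel="mCherry", n_tail=n_tail)
    aligned = pf.align_profile(profile, edge, "mcherry-edge")
    if gap > 0:
        sample_step = step if step is not None else ps
        # mask generously (2 extra samples) against ±1 px edge-detection slack
        aligned = pf.mask_gap(aligned, -sample_step, gap + 2 * sample_step)
        assert reference_yfp50 is not None
        return dk.analyze_noncontacting(
            aligned, reference_yfp50, window=window, n_tail=n_tail, subtract=True
        )
    return dk.analyze_contacting(
        aligned, window=window, n_tail=n_tail, subtract=True
    )


def run_colony_assay(
    n_pairs: int = 10,
    n_replicates: int = 3,
    gap_noncontacting: float = 50.0,
    decay_length: float = ENGINEERED_COLONY_DECAY_UM,
    decay_length_noncontacting: float | None = None,
    pixel_size: float = 4.0,
    producer_radius: float = 300.0,
    reporter_radius: float = 500.0,
    amplitude: float = 1000.0,
    baseline: float = 100.0,
    gain: float = 1.0,
    noise_sd: float = 20.0,
    step: float | None = None,
    window: int = 20,
    n_tail: int = 20,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> ColonyAssayResult:
    """Contacting vs non-contacting colony pairs and the equivalence test.

    Both groups are generated from the same toxin field unless
    ``decay_length_noncontacting`` is set (the power-check configuration).
    Contacting pairs use their own per-pair YFP50; non-contacting pairs
    use the contacting YFP50 averaged across all replicates (their curves
    do not reach the full reporter response, so a per-pair YFP50 would be
    biased low).  The Welch test compares per-replicate group means.
    """
    if decay_length_noncontacting is None:
        decay_length_noncontacting = decay_length
    pad = 8 * pixel_size
    maxr = max(producer_radius, reporter_radius)
    cy = maxr + pad
    px = producer_radius + pad
    width = px + producer_radius + gap_noncontacting + 2 * reporter_radius + pad
    shape = (int(np.ceil(2 * cy / pixel_size)) + 1,
             int(np.ceil(width / pixel_size)) + 1)

    def base_gt(lam: float, scene_seed: int) -> sc.SceneGroundTruth:
        return sc.SceneGroundTruth(
            pixel_size=pixel_size,
            image_shape=shape,
            producer_colonies=[sc.Colony(center=(px, cy), radius=producer_radius)],
            reporter_lawn=False,
            toxin_amplitude=amplitude,
            decay_length=lam,
            yfp_baseline=baseline,
            yfp_gain=gain,
            noise_sd=noise_sd,
            seed=scene_seed,
        )

    seeds = iter(_child_seeds(seed, 2 * n_replicates * n_pairs))
    # first pass: contacting pairs (their YFP50s define the shared reference)
    contacting: list[tuple[int, int, dk.DecayResult]] = []
    for rep in range(n_replicates):
        for pair in range(n_pairs):
            img = sc.render_colony_pair(
                base_gt(decay_length, next(seeds)), gap=0.0,
                reporter_radius=reporter_radius,
            )
            res = _analyze_pair(img, 0.0, None, step, window, n_tail)
            contacting.append((rep, pair, res))
    yfp50s = [r.yfp50 for _, _, r in contacting if r.valid]
    if not yfp50s:
        raise ValueError("no valid contacting pairs; cannot form a reference YFP50")
    reference_yfp50 = float(np.mean(yfp50s))

    noncontacting: list[tuple[int, int, dk.DecayResult]] = []
    for rep in range(n_replicates):
        for pair in range(n_pairs):
            img = sc.render_colony_pair(
                base_gt(decay_length_noncontacting, next(seeds)),
                gap=gap_noncontacting, reporter_radius=reporter_radius,
            )
            res = _analyze_pair(
                img, gap_noncontacting, reference_yfp50, step, window, n_tail
            )
            noncontacting.append((rep, pair, res))

    rows = []
    for group, gap, triples in (
        ("contacting", 0.0, contacting),
        ("non-contacting", gap_noncontacting, noncontacting),
    ):
        for rep, pair, res in triples:
            rows.append(
                {
                    "scene": f"{group}-r{rep}-p{pair:02d}",
                    "replicate": rep,
                    "contact_class": group,
                    "gap_um": gap,
                    "baseline": res.baseline,
                    "max_signal": res.max_signal,
                    "yfp50": res.yfp50,
                    "dist50_um": res.dist50,
                    "valid": res.valid,
                    "reason": ";".join(res.reasons),
                }
            )
    results = pd.DataFrame(rows)

    means = (
        results[results["valid"]]
        .groupby(["contact_class", "replicate"])["dist50_um"]
        .mean()
        .reset_index()
        .rename(columns={"dist50_um": "mean_dist50_um"})
    )
    groups = {
        name: grp["mean_dist50_um"].to_numpy()
        for name, grp in means.groupby("contact_class")
    }
    ttest: st.TTestResult | None = None
    a = groups.get("contacting", np.array([]))
    b = groups.get("non-contacting", np.array([]))
    if a.size >= 2 and b.size >= 2:
        ttest = st.welch_ttest(a, b)
    else:
        warnings.warn(
            "a group has fewer than 2 replicates with valid dist50; "
            "equivalence test skipped",
            stacklevel=2,
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results.to_csv(outdir / "colony_results.csv", index=False)
        means.to_csv(outdir / "colony_replicate_means.csv", index=False)
        _write_manifest(outdir, "colonies", {
            "n_pairs": n_pairs, "n_replicates": n_replicates,
            "gap_noncontacting": gap_noncontacting, "decay_length": decay_length,
            "decay_length_noncontacting": decay_length_noncontacting,
            "pixel_size": pixel_size, "producer_radius": producer_radius,
            "reporter_radius": reporter_radius, "amplitude": amplitude,
            "baseline": baseline, "gain": gain, "noise_sd": noise_sd,
            "window": window, "n_tail": n_tail, "seed": seed,
        })
    return ColonyAssayResult(
        results=results, replicate_means=means,
        reference_yfp50=reference_yfp50, ttest=ttest,
    )


# ---------------------------------------------------------------------------
# Flow timecourse


DEFAULT_PRODUCER_SCHEDULE = {0: 0.0, 3: 0.25, 6: 0.35, 12: 0.4, 24: 0.4, 48: 0.4}
DEFAULT_CONTROL_SCHEDULE = {0: 0.0, 3: 0.01, 6: 0.01, 12: 0.01, 24: 0.01, 48: 0.01}


def run_flow_timecourse(
    producer_schedule: Mapping[float, float] | None = None,
    control_schedule: Mapping[float, float] | None = None,
    n_events: int = 50_000,
    spec: sc.FlowPopulationSpec | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Percent-positive time series for a producer (pks+-like) and a
    control (pks--like) co-culture.

    Schedules map co-culture time (h) to the generator's responder
    fraction; the defaults ramp the producer series to a 0.4 plateau
    within 12 h and hold the control near 1%.  Each strain uses one
    cutoff computed at its own t = 0 h.  Gates derive from a clean
    reference sample (no debris/doublets), playing the role of the
    overlaid control populations used for visual gating.
    """
    if producer_schedule is None:
        producer_schedule = DEFAULT_PRODUCER_SCHEDULE
    if control_schedule is None:
        control_schedule = DEFAULT_CONTROL_SCHEDULE
    if 0 not in producer_schedule or 0 not in control_schedule:
        raise ValueError("schedules must include the t = 0 h point")
    if len(producer_schedule) < 2:
        raise ValueError("timecourse requires at least 2 time points")
    base = spec if spec is not None else sc.FlowPopulationSpec(n_events=n_events)
    base = dataclasses.replace(base, n_events=n_events)
    cfp_cut, mch_cut = sc.marker_cutoffs(base)

    n_tables = len(producer_schedule) + len(control_schedule) + 1
    seeds = iter(_child_seeds(seed, n_tables))
    reference = sc.sample_flow_events(
        dataclasses.replace(
            base, n_events=min(n_events, 20_000), responder_fraction=0.0,
            debris_fraction=0.0, doublet_fraction=0.0, lysed_fraction=0.0,
            producer_to_reporter_ratio=0.0, seed=next(seeds),
        )
    )
    gates = cy.default_gates(reference)

    frames = []
    for strain, schedule in (("pks+", producer_schedule), ("pks-", control_schedule)):
        tables = {
            t: sc.sample_flow_events(
                dataclasses.replace(base, responder_fraction=f, seed=next(seeds))
            )
            for t, f in schedule.items()
        }
        tc = cy.timecourse(tables, gates, cfp_cut, mch_cut)
        tc.insert(0, "strain", strain)
        frames.append(tc)
    out = pd.concat(frames, ignore_index=True)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out.to_csv(outdir / "flow_timecourse.csv", index=False)
        _write_manifest(outdir, "flow-timecourse", {
            "producer_schedule": dict(producer_schedule),
            "control_schedule": dict(control_schedule),
            "n_events": n_events, "seed": seed,
        })
    return out


# ---------------------------------------------------------------------------
# Lysis and contamination controls


@dataclass
class LysisResult:
    results: pd.DataFrame  # strain × replicate percent PI-positive
    ttest: st.TTestResult


def run_lysis(
    lysed_fractions: Mapping[str, float] | None = None,
    n_replicates: int = 3,
    n_events: int = 20_000,
    spec: sc.FlowPopulationSpec | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> LysisResult:
    """Propidium-iodide lysis fractions per strain, in triplicate, with a
    two-tailed unequal-variance t-test between the strains.  The default
    ground truth has the same low lysed fraction (1.3%, below 2%) in both
    genetic backgrounds — toxin production does not by itself lyse
    producers — so observed differences are pure sampling noise."""
    if lysed_fractions is None:
        lysed_fractions = {"pks+": 0.013, "pks-": 0.013}
    base = spec if spec is not None else sc.FlowPopulationSpec()
    base = dataclasses.replace(
        base, n_events=n_events, responder_fraction=0.0,
        producer_to_reporter_ratio=0.0, count_mode="multinomial",
    )
    pe_cutoff = float(
        np.exp(base.channel_log_means["PE_A"] + base.pe_shift / 2.0)
    )
    seeds = iter(_child_seeds(seed, len(lysed_fractions) * n_replicates + 1))
    reference = sc.sample_flow_events(
        dataclasses.replace(base, debris_fraction=0.0, doublet_fraction=0.0,
                            lysed_fraction=0.0, seed=next(seeds))
    )
    gates = cy.default_gates(reference)

    rows = []
    for strain, fraction in lysed_fractions.items():
        for rep in range(n_replicates):
            table = sc.sample_flow_events(
                dataclasses.replace(base, lysed_fraction=fraction, seed=next(seeds))
            )
            pct = cy.lysis_fraction(table, pe_cutoff, gates)
            rows.append({"strain": strain, "replicate": rep,
                         "percent_pi_positive": pct})
    results = pd.DataFrame(rows)
    strains = list(lysed_fractions)
    ttest = st.welch_ttest(
        results.loc[results["strain"] == strains[0], "percent_pi_positive"],
        results.loc[results["strain"] == strains[1], "percent_pi_positive"],
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        results.to_csv(outdir / "lysis_results.csv", index=False)
        _write_manifest(outdir, "lysis", {
            "lysed_fractions": dict(lysed_fractions),
            "n_replicates": n_replicates, "n_events": n_events, "seed": seed,
        })
    return LysisResult(results=results, ttest=ttest)


@dataclass
class ContaminationResult:
    counts: list[int]
    dilution_factors: list[float]
    cfu: st.CfuEstimate
    purity: st.PurityReport


def run_contamination(
    true_cfu_per_ml: float = 7.5e4,
    n_dilutions: int = 4,
    plated_volume_ml: float = 0.1,
    n_colonies_screened: int = 7_500,
    n_producer_colonies: int = 0,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> ContaminationResult:
    """Cross-contamination control: Poisson plate counts over a 1:1
    four-step serial dilution, CFU back-calculation, and the exact upper
    bound on the producer fraction among screened colonies (all CFP-only
    by default, as observed)."""
    factors = st.serial_dilution_factors(n_dilutions)
    rng = np.random.default_rng(seed)
    counts = [
        int(rng.poisson(true_cfu_per_ml * plated_volume_ml / f)) for f in factors
    ]
    series = st.DilutionSeries(
        counts=counts, dilution_factors=factors, plated_volume_ml=plated_volume_ml
    )
    cfu = st.cfu_per_ml(series)
    purity = st.contamination_check(n_colonies_screened, n_producer_colonies)
    result = ContaminationResult(
        counts=counts, dilution_factors=factors, cfu=cfu, purity=purity
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "dilution_factor": factors,
                "count": counts,
                "cfu_per_ml": cfu.per_plate,
                "below_detection": cfu.below_detection,
            }
        ).to_csv(outdir / "contamination_cfu.csv", index=False)
        with open(outdir / "contamination_report.txt", "w") as fh:
            fh.write(
                "Cross-contamination control\n"
                f"pooled CFU/mL: {cfu.pooled:.4g}\n"
                f"colonies screened: {purity.n_total}\n"
                f"producer colonies: {purity.n_producer}\n"
                f"producer fraction: {purity.producer_fraction:.4%}\n"
                f"{purity.confidence:.0%} one-sided upper bound: "
                f"{purity.upper_bound:.4%}\n"
            )
        _write_manifest(outdir, "contamination", {
            "true_cfu_per_ml": true_cfu_per_ml, "n_dilutions": n_dilutions,
            "plated_volume_ml": plated_volume_ml,
            "n_colonies_screened": n_colonies_screened,
            "n_producer_colonies": n_producer_colonies, "seed": seed,
        })
    return result


# ---------------------------------------------------------------------------
# Configuration plumbing


@dataclass
class RunConfig:
    """One assay run: which assay, its parameters, where output goes."""

    assay: str  # lawn | colonies | flow | lysis | contamination
    params: dict = field(default_factory=dict)
    outdir: str | Path | None = None
    seed: int = 0


_ASSAYS = {
    "lawn": run_lawn_assay,
    "colonies": run_colony_assay,
    "flow": run_flow_timecourse,
    "lysis": run_lysis,
    "contamination": run_contamination,
}


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "assay" not in raw:
        raise ValueError("config must name an assay")
    return RunConfig(
        assay=raw["assay"],
        params=raw.get("params", {}) or {},
        outdir=raw.get("outdir"),
        seed=int(raw.get("seed", 0)),
    )


def run_from_config(cfg: RunConfig):
    if cfg.assay not in _ASSAYS:
        raise ValueError(
            f"unknown assay {cfg.assay!r}; expected one of {sorted(_ASSAYS)}"
        )
    fn = _ASSAYS[cfg.assay]
    return fn(**cfg.params, seed=cfg.seed, outdir=cfg.outdir)
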