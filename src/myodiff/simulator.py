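"""Synthetic flow-cytometry experiments emulating a C2C12 differentiation assay.

The generator produces Guava-style 4-channel acquisitions (FSC-HLin,
SSC-HLin, GRN-B-HLin, RED-R-HLin, plus FSC-H) with:

* a debris population at low forward/side scatter,
* optional doublets (paired cells: scatter/fluorescence areas summed,
  height taken as the pair maximum),
* autofluorescent background in both fluorescence channels,
* a transfected subpopulation whose GFP dose follows a wide lognormal
  spanning roughly 10^1–10^4 RFU,
* a bimodal MyHC channel: background around 5 RFU versus a differentiated
  mode around 300 RFU.

Differentiation is assigned per cell *before* intensities are drawn, via a
dose-dependent probability (a GFP-dose Hill inhibition with a drug-rescue
parameter), so the true differentiated fraction of any GFP window is well
defined and recoverable from the per-event ground truth.  Ground truth is
kept in a sidecar table, never inside FCS keywords, so emitted files stay
standard.

Every draw goes through one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; identical configs produce identical event matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fcs_io import GUAVA_CHANNELS, ChannelInfo, Experiment, Sample, write_fcs

__all__ = [
    "ChannelModel",
    "PopulationSpec",
    "SimConfig",
    "GroundTruth",
    "dose_response",
    "simulate_sample",
    "inject_doublets",
    "simulate_experiment",
    "true_bin_fraction",
    "DEFAULT_TRUTH_BINS",
]

#: Canonical GFP windows used for the stored per-sample truth summary
#: (measured-GFP RFU, half-open).
DEFAULT_TRUTH_BINS: tuple[tuple[str, float, float], ...] = (
    ("GFP-low", 10.0, 100.0),
    ("GFP-medium", 100.0, 1000.0),
    ("GFP-high", 1000.0, 10000.0),
)

_AREA_CHANNELS = ("FSC-HLin", "SSC-HLin", "GRN-B-HLin", "RED-R-HLin")
_HEIGHT_CHANNEL = "FSC-H"


@dataclass(frozen=True)
class ChannelModel:
    """Lognormal intensity model: ``10**Normal(log10_loc, log10_sd)`` RFU."""

    log10_loc: float
    log10_sd: float

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.power(10.0, rng.normal(self.log10_loc, self.log10_sd, size=n))


@dataclass(frozen=True)
class PopulationSpec:
    """Per-channel intensity models for the base populations.

    Cells sit at FSC ~1000 / SSC ~500 RFU; debris sits two orders of
    magnitude lower on both scatter channels so the default debris gate
    (FSC >= 100, SSC >= 50) removes essentially all of it.  Background
    fluorescence is ~5 RFU in both color channels; the differentiated MyHC
    mode is ~300 RFU, well separated from background on a log scale.
    """

    cell_fsc: ChannelModel = ChannelModel(3.0, 0.15)
    cell_ssc: ChannelModel = ChannelModel(2.7, 0.15)
    debris_fsc: ChannelModel = ChannelModel(np.log10(30.0), 0.2)
    debris_ssc: ChannelModel = ChannelModel(np.log10(15.0), 0.2)
    gfp_background: ChannelModel = ChannelModel(np.log10(5.0), 0.15)
    myhc_background: ChannelModel = ChannelModel(np.log10(5.0), 0.15)
    myhc_positive: ChannelModel = ChannelModel(np.log10(300.0), 0.15)
    #: sd of the FSC height-vs-area mismatch for singlets (ratio ~ 1)
    height_jitter: float = 0.02


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated acquisition.

    Defaults mirror the assay this package quantifies: 30,000 events per
    well, a minority debris load, a transfected subpopulation whose GFP dose
    spans ~10^1–10^4 RFU, and a baseline differentiation probability ``p0``
    that GFP-dose-dependent oncogene expression suppresses via a Hill term —
    ``drug_effect`` in [0, 1] scales how much of that suppression a drug
    rescues (1 = full rescue).
    """

    n_events: int = 30_000
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.02
    transfection_fraction: float = 0.4
    gfp_dose: ChannelModel = ChannelModel(2.2, 0.8)
    p0: float = 0.4
    hill_k: float = 30.0  # RFU at which half the (unrescued) suppression acts
    hill_h: float = 1.5
    drug_effect: float = 0.15  # vehicle default: little rescue
    populations: PopulationSpec = field(default_factory=PopulationSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("debris_fraction", "doublet_fraction", "transfection_fraction",
                     "p0", "drug_effect"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {x}")
        if self.doublet_fraction > 0.5:
            raise ConfigurationError("doublet_fraction must be <= 0.5")
        if self.n_events <= 0:
            raise ConfigurationError("n_events must be > 0")
        if not self.hill_k > 0:
            raise ConfigurationError("hill_k must be > 0")


@dataclass
class GroundTruth:
    """Per-event truth plus a per-sample summary of true bin fractions.

    ``per_event`` columns: ``label`` (debris/neg/gfp_only/myhc_only/
    double_pos), ``is_doublet``, ``gfp_true`` (dose in RFU, 0 for
    untransfected), ``differentiated``.  ``bin_fractions`` holds the true
    differentiated fraction of each canonical GFP window, recomputable from
    the per-event records and the sample's measured GFP.
    """

    per_event: pd.DataFrame
    bin_fractions: dict[str, float]


def dose_response(gfp, p0: float, k: float, h: float, drug_effect: float) -> np.ndarray:
    """Differentiation probability as a function of true GFP dose.

    ``p(g) = p0 * (1 - (1 - E) * g**h / (g**h + k**h))`` — decreasing in the
    dose when the rescue ``E < 1``, identically ``p0`` at ``E = 1`` or at
    zero dose.
    """
    g = np.asarray(gfp, dtype=np.float64)
    if np.any(g < 0):
        raise ConfigurationError("GFP dose must be >= 0")
    with np.errstate(over="ignore"):
        gh = np.power(g, h)
        kh = k ** h
        hill = np.where(np.isinf(gh), 1.0, gh / (gh + kh))
    return p0 * (1.0 - (1.0 - drug_effect) * hill)


def inject_doublets(
    events: np.ndarray,
    fraction: float,
    rng: np.random.Generator,
    area_cols: tuple[int, ...],
    height_col: int,
    eligible: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert a random subset of singlet events into doublets.

    Each selected event is merged with a random partner drawn from the
    eligible (singlet, non-debris) pool: area channels are summed, the height
    channel becomes the pair maximum, so the area/height ratio of a doublet
    is roughly twice the singlet ratio.

    Returns ``(events, is_doublet, partner_index)`` with ``partner_index``
    -1 for singlets.  The event count is unchanged.
    """
    if not 0.0 <= fraction <= 0.5:
        raise ConfigurationError("doublet fraction must lie in [0, 0.5]")
    n = events.shape[0]
    events = events.copy()
    is_doublet = np.zeros(n, dtype=bool)
    partner = np.full(n, -1, dtype=np.int64)
    if fraction == 0.0 or n < 2:
        return events, is_doublet, partner
    pool = np.nonzero(eligible)[0] if eligible is not None else np.arange(n)
    if pool.size < 2:
        return events, is_doublet, partner
    take = rng.random(pool.size) < fraction
    flagged = pool[take]
    singlet_pool = pool[~take]  # partners stay true singlets
    if singlet_pool.size == 0:
        return events, is_doublet, partner
    for i in flagged:
        j = int(rng.choice(singlet_pool))
        for c in area_cols:
            events[i, c] = events[i, c] + events[j, c]
        events[i, height_col] = max(events[i, height_col], events[j, height_col])
        is_doublet[i] = True
        partner[i] = j
    return events, is_doublet, partner


def _guava_channels() -> list[ChannelInfo]:
    return [ChannelInfo(name=n, index=i + 1, range=1048576.0) for i, n in enumerate(GUAVA_CHANNELS)]


def simulate_sample(
    config: SimConfig,
    role: str,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
    well_id: str | None = None,
) -> Sample:
    """Simulate one acquisition for a given experimental role.

    Roles: ``double_negative`` (no transfection, no differentiation),
    ``gfp_positive`` (transfected fraction, no differentiation),
    ``myhc_positive`` (differentiated fraction at ``p0``, no transfection),
    ``target`` (both active, differentiation dose-dependent).
    """
    if role not in ("double_negative", "gfp_positive", "myhc_positive", "target"):
        raise ConfigurationError(f"unknown sample role {role!r}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pop = config.populations
    n = config.n_events

    is_debris = rng.random(n) < config.debris_fraction
    cells = ~is_debris

    transfected = np.zeros(n, dtype=bool)
    if role in ("gfp_positive", "target"):
        transfected = cells & (rng.random(n) < config.transfection_fraction)
    gfp_true = np.zeros(n)
    gfp_true[transfected] = config.gfp_dose.draw(rng, int(transfected.sum()))

    differentiated = np.zeros(n, dtype=bool)
    if role == "myhc_positive":
        differentiated = cells & (rng.random(n) < config.p0)
    elif role == "target":
        p = dose_response(gfp_true, config.p0, config.hill_k, config.hill_h, config.drug_effect)
        differentiated = cells & (rng.random(n) < p)

    fsc = np.where(is_debris, pop.debris_fsc.draw(rng, n), pop.cell_fsc.draw(rng, n))
    ssc = np.where(is_debris, pop.debris_ssc.draw(rng, n), pop.cell_ssc.draw(rng, n))
    gfp = pop.gfp_background.draw(rng, n) + gfp_true
    myhc = np.where(
        differentiated, pop.myhc_positive.draw(rng, n), pop.myhc_background.draw(rng, n)
    )
    height = fsc / np.maximum(rng.normal(1.0, pop.height_jitter, size=n), 0.5)

    events = np.column_stack([fsc, ssc, gfp, myhc, height])
    events, is_doublet, partner = inject_doublets(
        events,
        config.doublet_fraction,
        rng,
        area_cols=tuple(range(4)),
        height_col=4,
        eligible=cells,
    )
    # a doublet carries the marker content of both members
    merged = partner >= 0
    transfected = transfected | np.where(merged, transfected[np.maximum(partner, 0)], False)
    differentiated = differentiated | np.where(merged, differentiated[np.maximum(partner, 0)], False)
    gfp_true = gfp_true + np.where(merged, gfp_true[np.maximum(partner, 0)], 0.0)

    # float32 quantization up front so FCS round-trips are bit-exact
    events = events.astype(np.float32).astype(np.float64)

    label = np.full(n, "neg", dtype=object)
    label[transfected & ~differentiated] = "gfp_only"
    label[~transfected & differentiated] = "myhc_only"
    label[transfected & differentiated] = "double_pos"
    label[is_debris] = "debris"

    per_event = pd.DataFrame(
        {
            "label": label,
            "is_doublet": is_doublet,
            "gfp_true": gfp_true,
            "differentiated": differentiated,
        }
    )
    sample = Sample(
        sample_id=sample_id or f"sim_{role}",
        events=events,
        channels=_guava_channels(),
        keywords={"SIMROLE": role},
        well_id=well_id,
        truth=None,
    )
    sample.truth = GroundTruth(per_event=per_event, bin_fractions={})
    sample.truth.bin_fractions = {
        lab: true_bin_fraction(sample, low, high) for lab, low, high in DEFAULT_TRUTH_BINS
    }
    return sample


def true_bin_fraction(sample: Sample, low: float, high: float) -> float:
    """True differentiated fraction among non-debris events whose *measured*
    GFP lies in ``[low, high)``; NaN when the window is empty."""
    truth = sample.truth.per_event if isinstance(sample.truth, GroundTruth) else sample.truth
    gfp = sample.channel_data("GRN-B-HLin")
    in_bin = (gfp >= low) & (gfp < high) & (truth["label"].to_numpy() != "debris")
    if not in_bin.any():
        return float("nan")
    return float(truth["differentiated"].to_numpy()[in_bin].mean())


#: layout of the default simulated experiment: (sample_id, well, role, drug_effect)
_DEFAULT_LAYOUT = (
    ("01_DN", "A01", "double_negative", None),
    ("02_MyHC", "A02", "myhc_positive", None),
    ("03_GFPctrl", "A03", "gfp_positive", None),
    ("04_G12C_DMSO", "A04", "target", "vehicle"),
    ("05_G12C_AMG510", "A05", "target", "drug"),
)


def simulate_experiment(
    config: SimConfig | None = None,
    out_dir: str | Path | None = None,
    drug_effect_vehicle: float = 0.15,
    drug_effect_drug: float = 0.85,
) -> Experiment:
    """Simulate a full experiment: the three controls plus two oncogene
    targets (vehicle- vs drug-treated, ``E_vehicle < E_drug`` so the drug
    sample differentiates more).

    When ``out_dir`` is given, each sample is written as an FCS 3.0 file with
    a per-event truth sidecar CSV and a ``manifest.csv`` mapping filenames to
    wells and roles.
    """
    config = config or SimConfig()
    if not drug_effect_vehicle < drug_effect_drug:
        raise ConfigurationError("the drug target must have a larger rescue than vehicle")
    samples: list[Sample] = []
    roles: dict[str, list[str]] = {r: [] for r in ("double_negative", "myhc_positive", "gfp_positive", "target")}
    for idx, (sid, well, role, treatment) in enumerate(_DEFAULT_LAYOUT):
        rng = np.random.default_rng([config.seed, idx])
        cfg = config
        if treatment == "vehicle":
            cfg = replace(config, drug_effect=drug_effect_vehicle)
        elif treatment == "drug":
            cfg = replace(config, drug_effect=drug_effect_drug)
        samples.append(simulate_sample(cfg, role, rng=rng, sample_id=sid, well_id=well))
        roles[role].append(sid)
    experiment = Experiment(samples=samples, roles=roles)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for s in samples:
            fname = f"{s.sample_id}.fcs"
            write_fcs(s, out_dir / fname)
            s.truth.per_event.to_csv(out_dir / f"truth_{s.sample_id}.csv", index=True, index_label="event")
            role = next(r for r, ids in roles.items() if s.sample_id in ids)
            manifest.append({"filename": fname, "sample_id": s.sample_id, "well": s.well_id, "role": role})
        pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False)
    return experiment
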