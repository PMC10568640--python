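"""End-to-end differentiation analysis: curate → bin → split → count → export.

The workflow quantifies the fraction of differentiated (MyHC+) cells within
GFP-expression bins of each target sample:

1. **Curate** — a fixed rectangular gate removes debris; a GFP threshold,
   the mean of the 99%-quantile GFP levels of the double-negative and MyHC+
   control samples (computed on their non-debris events), selects GFP+
   cells and becomes the lower bound of the first GFP bin.
2. **Bin** — up to three GFP windows (low/medium/high) stratify GFP+ cells
   by transgene dose.
3. **Split peaks** — within each bin, the bimodal MyHC intensity
   distribution is cut at the density valley between its two modes
   (:func:`myodiff.gating.mindensity_cutpoint`); events at or above the
   cutpoint are MyHC+, i.e. differentiated.
4. **Count & export** — populations are reported per the hierarchical
   nomenclature ``root → /NonDebris → /NonDebris/GFP+ → .../<bin> →
   .../<bin>/MyHC+`` and differentiation fractions as
   ``100 * MyHC+ / bin total``.

A fixed-threshold quadrant analysis (the manual-analysis surrogate) is
provided as an independent comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .errors import ChannelResolutionError, ConfigurationError, InsufficientDataError
from .fcs_io import (
    Experiment,
    Sample,
    export_population_stats,
    read_fcs,
)
from .gating import (
    QuadrantScheme,
    RangeBin,
    RectGate,
    SplitConfig,
    SplitResult,
    apply_range_bin,
    apply_rect_gate,
    empirical_quantile,
    mindensity_cutpoint,
    singlet_mask,
)

__all__ = [
    "AnalysisConfig",
    "GatingTree",
    "CurationResult",
    "DifferentiationResult",
    "default_bins",
    "control_gfp_quantile",
    "fit_gfp_threshold",
    "curate",
    "assign_bins",
    "split_peaks",
    "population_stats",
    "differentiation_fractions",
    "qc_differentiation_control",
    "quadrant_analysis",
    "run_pipeline",
    "differentiation_table",
]

GFP_POS_PATH = "/NonDebris/GFP+"


def default_bins(gfp_channel: str = "GRN-B-HLin") -> list[RangeBin]:
    """The demo binning scheme: GFP-low from the fitted threshold to 100 RFU,
    then contiguous decade bins to 10^4 RFU."""
    return [
        RangeBin("GFP-low", gfp_channel, None, 100.0),
        RangeBin("GFP-medium", gfp_channel, 100.0, 1000.0),
        RangeBin("GFP-high", gfp_channel, 1000.0, 10000.0),
    ]


@dataclass
class AnalysisConfig:
    """Every tunable of the automated analysis, with its default."""

    gfp_channel: str = "GRN-B-HLin"
    myhc_channel: str = "RED-R-HLin"
    fsc_channel: str = "FSC-HLin"
    ssc_channel: str = "SSC-HLin"
    fsc_h_channel: str | None = "FSC-H"
    #: fixed debris gate: keep FSC >= 100 RFU and SSC >= 50 RFU
    debris_gate: RectGate | None = None
    quantile_level: float = 0.99
    bins: list[RangeBin] | None = None  # None -> default_bins()
    split: SplitConfig = field(default_factory=SplitConfig)
    singlet_gating: bool = False
    singlet_tolerance: float = 0.25
    #: QC: a differentiation control below this MyHC+ percentage is flagged
    qc_min_control_fraction: float = 5.0
    #: sample_id or well -> role, used by run_pipeline to build the Experiment
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.debris_gate is None:
            self.debris_gate = RectGate(
                channel_x=self.fsc_channel, channel_y=self.ssc_channel, x_min=100.0, y_min=50.0
            )
        if not 0.0 < self.quantile_level < 1.0:
            raise ConfigurationError("quantile_level must lie in (0, 1)")
        required = [self.gfp_channel, self.myhc_channel, self.fsc_channel, self.ssc_channel]
        if len({c.upper() for c in required}) != len(required):
            raise ConfigurationError("required channels must be distinct")

    def effective_bins(self, threshold: float) -> list[RangeBin]:
        """Resolve the configured bins, auto-setting the first bin's lower
        bound to the fitted GFP threshold when left open."""
        bins = self.bins if self.bins is not None else default_bins(self.gfp_channel)
        if not 1 <= len(bins) <= 3:
            raise ConfigurationError("between 1 and 3 GFP bins are supported")
        resolved = []
        for i, b in enumerate(bins):
            low = b.low
            if i == 0 and low is None:
                low = threshold
            resolved.append(RangeBin(b.label, b.channel, low, b.high))
        for a, b in zip(resolved, resolved[1:]):
            if b.low < a.high:
                raise ConfigurationError(
                    f"bins must be ordered and non-overlapping: {a.label} ends at {a.high}, "
                    f"{b.label} starts at {b.low}"
                )
        return resolved


@dataclass
class _Node:
    mask: np.ndarray
    parent: str | None

    @property
    def count(self) -> int:
        return int(self.mask.sum())


class GatingTree:
    """Population hierarchy for one sample: named masks with child ⊆ parent."""

    def __init__(self, sample: Sample):
        self.sample = sample
        self.nodes: dict[str, _Node] = {
            "root": _Node(np.ones(sample.n_events, dtype=bool), None)
        }

    def add(self, path: str, mask: np.ndarray, parent: str) -> None:
        if parent not in self.nodes:
            raise ConfigurationError(f"parent population {parent!r} does not exist")
        mask = np.asarray(mask, dtype=bool) & self.nodes[parent].mask
        self.nodes[path] = _Node(mask, parent)

    def mask(self, path: str) -> np.ndarray:
        return self.nodes[path].mask

    def count(self, path: str) -> int:
        return self.nodes[path].count

    def paths(self) -> list[str]:
        return list(self.nodes)


@dataclass
class CurationResult:
    """Output of the curation (and later) stages, keyed by sample id."""

    trees: dict[str, GatingTree]
    gfp_threshold: float
    config: AnalysisConfig
    effective_bins: list[RangeBin] | None = None
    #: per sample: GFP+ events falling in no bin (above the top bin or gaps)
    unbinned: dict[str, int] = field(default_factory=dict)
    splits: dict[tuple[str, str], SplitResult | None] = field(default_factory=dict)


def _nondebris_mask(sample: Sample, config: AnalysisConfig) -> np.ndarray:
    mask = apply_rect_gate(sample, config.debris_gate)
    if config.singlet_gating:
        if config.fsc_h_channel is None:
            return mask  # singlet gating unavailable without a height channel
        try:
            mask = mask & singlet_mask(sample, config.singlet_tolerance,
                                       config.fsc_channel, config.fsc_h_channel)
        except ChannelResolutionError:
            # height channel absent in this file: proceed on the debris gate alone
            pass
    return mask


def control_gfp_quantile(sample: Sample, config: AnalysisConfig) -> float:
    """The quantile-gate level of one control: the ``quantile_level`` sample
    quantile of the GFP channel over the control's non-debris events."""
    mask = _nondebris_mask(sample, config)
    n = int(mask.sum())
    if n < config.split.min_events:
        raise InsufficientDataError(
            f"control {sample.sample_id!r} has only {n} non-debris events"
        )
    return empirical_quantile(sample.channel_data(config.gfp_channel)[mask], config.quantile_level)


def fit_gfp_threshold(experiment: Experiment, config: AnalysisConfig) -> float:
    """GFP threshold: mean of the double-negative and MyHC+ controls'
    quantile-gate levels.  Cells at or above it are GFP+; it also becomes the
    lower bound of the first GFP bin."""
    dn = experiment.control("double_negative")
    mp = experiment.control("myhc_positive")
    return 0.5 * (control_gfp_quantile(dn, config) + control_gfp_quantile(mp, config))


def curate(
    experiment: Experiment,
    config: AnalysisConfig,
    threshold: float | None = None,
) -> CurationResult:
    """Build per-sample gating trees: root → /NonDebris → /NonDebris/GFP+."""
    if threshold is None:
        threshold = fit_gfp_threshold(experiment, config)
    trees: dict[str, GatingTree] = {}
    for sample in experiment.samples:
        tree = GatingTree(sample)
        tree.add("/NonDebris", _nondebris_mask(sample, config), "root")
        gfp_pos = sample.channel_data(config.gfp_channel) >= threshold
        tree.add(GFP_POS_PATH, gfp_pos, "/NonDebris")
        trees[sample.sample_id] = tree
    return CurationResult(trees=trees, gfp_threshold=float(threshold), config=config)


def assign_bins(curation: CurationResult, config: AnalysisConfig | None = None) -> CurationResult:
    """Add the GFP-bin populations under /NonDebris/GFP+.

    GFP+ events above the top bin or inside inter-bin gaps belong to no bin;
    they are counted per sample in ``curation.unbinned`` so totals stay
    auditable.
    """
    config = config or curation.config
    bins = config.effective_bins(curation.gfp_threshold)
    curation.effective_bins = bins
    for sid, tree in curation.trees.items():
        binned = np.zeros(tree.sample.n_events, dtype=bool)
        for b in bins:
            mask = apply_range_bin(tree.sample, b)
            tree.add(f"{GFP_POS_PATH}/{b.label}", mask, GFP_POS_PATH)
            binned |= tree.mask(f"{GFP_POS_PATH}/{b.label}")
        curation.unbinned[sid] = int((tree.mask(GFP_POS_PATH) & ~binned).sum())
    return curation


def split_peaks(curation: CurationResult, config: AnalysisConfig | None = None) -> CurationResult:
    """Split the MyHC distribution of every (sample, bin) with enough events;
    add the MyHC+ child population.  Bins below ``min_events`` are recorded
    as not analyzable (split result ``None``)."""
    config = config or curation.config
    if curation.effective_bins is None:
        raise ConfigurationError("assign_bins must run before split_peaks")
    for sid, tree in curation.trees.items():
        myhc = tree.sample.channel_data(config.myhc_channel)
        for b in curation.effective_bins:
            bin_path = f"{GFP_POS_PATH}/{b.label}"
            bin_mask = tree.mask(bin_path)
            values = myhc[bin_mask]
            if values.size < config.split.min_events:
                curation.splits[(sid, b.label)] = None
                continue
            result = mindensity_cutpoint(values, config.split)
            tree.add(f"{bin_path}/MyHC+", myhc >= result.cutpoint, bin_path)
            curation.splits[(sid, b.label)] = result
    return curation


def population_stats(curation: CurationResult) -> pd.DataFrame:
    """One ``(sample, pop, count)`` row per population per sample, paths per
    the hierarchical nomenclature."""
    rows = []
    for sid, tree in curation.trees.items():
        for path in tree.paths():
            rows.append({"sample": sid, "pop": path, "count": tree.count(path)})
    return pd.DataFrame(rows, columns=["sample", "pop", "count"])


@dataclass(frozen=True)
class DifferentiationResult:
    """Differentiated fraction of one GFP bin of one sample."""

    sample: str
    bin: str
    myhc_pos: int | None
    bin_total: int
    fraction: float | None  # percentage, absent when not analyzable
    split_method: str | None
    analyzable: bool


def differentiation_fractions(
    stats: pd.DataFrame,
    splits: dict[tuple[str, str], SplitResult | None] | None = None,
) -> list[DifferentiationResult]:
    """``fraction = 100 * MyHC+ / bin total`` per sample per bin.

    Derived from a population-stats table; ``splits`` (when available)
    annotates each row with the split method.  A bin with no MyHC+ child or
    zero total is reported as not analyzable rather than dividing by zero.
    """
    results: list[DifferentiationResult] = []
    for sid, grp in stats.groupby("sample", sort=False):
        counts = dict(zip(grp["pop"], grp["count"]))
        for path in grp["pop"]:
            parts = path.split("/")
            if len(parts) != 4 or parts[-1] == "MyHC+":  # bin nodes only
                continue
            label = parts[-1]
            bin_total = int(counts[path])
            myhc_path = f"{path}/MyHC+"
            split = splits.get((sid, label)) if splits else None
            if myhc_path not in counts or bin_total == 0:
                results.append(
                    DifferentiationResult(sid, label, None, bin_total, None,
                                          split.method if split else None, False)
                )
                continue
            myhc_pos = int(counts[myhc_path])
            results.append(
                DifferentiationResult(
                    sample=sid,
                    bin=label,
                    myhc_pos=myhc_pos,
                    bin_total=bin_total,
                    fraction=100.0 * myhc_pos / bin_total,
                    split_method=split.method if split else None,
                    analyzable=True,
                )
            )
    return results


def qc_differentiation_control(
    result: DifferentiationResult, min_fraction: float = 5.0
) -> str | None:
    """Flag a differentiation control whose MyHC+ fraction is strictly below
    the minimum (default 5%) — the signature of poorly differentiating cells."""
    if result.analyzable and result.fraction is not None and result.fraction < min_fraction:
        return "poor_differentiation"
    return None


def quadrant_analysis(
    experiment: Experiment,
    scheme: QuadrantScheme,
    bins: list[RangeBin],
    config: AnalysisConfig | None = None,
    sample_ids: list[str] | None = None,
) -> list[DifferentiationResult]:
    """Fixed-threshold (manual-style) comparator: within each GFP bin of each
    sample's non-debris events, MyHC+ iff MyHC >= the y threshold."""
    config = config or AnalysisConfig()
    results: list[DifferentiationResult] = []
    samples = [s for s in experiment.samples if sample_ids is None or s.sample_id in sample_ids]
    for sample in samples:
        nondebris = apply_rect_gate(sample, config.debris_gate)
        myhc_pos = sample.channel_data(config.myhc_channel) >= scheme.y_threshold
        gfp = sample.channel_data(config.gfp_channel)
        for b in bins:
            low = b.low if b.low is not None else scheme.x_threshold
            in_bin = nondebris & (gfp >= low) & (gfp < b.high)
            total = int(in_bin.sum())
            if total == 0:
                results.append(DifferentiationResult(sample.sample_id, b.label, None, 0, None, "quadrant", False))
                continue
            pos = int((in_bin & myhc_pos).sum())
            results.append(
                DifferentiationResult(sample.sample_id, b.label, pos, total,
                                      100.0 * pos / total, "quadrant", True)
            )
    return results


def differentiation_table(results: list[DifferentiationResult]) -> pd.DataFrame:
    """Tabular form of differentiation results, one row per sample per bin."""
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "bin": r.bin,
                "myhc_pos": r.myhc_pos if r.myhc_pos is not None else "",
                "bin_total": r.bin_total,
                "fraction_percent": f"{r.fraction:.6g}" if r.fraction is not None else "",
                "method": r.split_method or "",
                "analyzable": r.analyzable,
            }
            for r in results
        ],
        columns=["sample", "bin", "myhc_pos", "bin_total", "fraction_percent", "method", "analyzable"],
    )


def _load_experiment(input_path: Path, roles: dict[str, str]) -> Experiment:
    """Read one merged file or a folder of FCS files and assign roles by
    sample id or well id."""
    if input_path.is_dir():
        samples = []
        for f in sorted(input_path.glob("*.fcs")):
            samples.extend(read_fcs(f))
    else:
        samples = read_fcs(input_path)
    role_map: dict[str, list[str]] = {}
    for sample in samples:
        role = roles.get(sample.sample_id) or (roles.get(sample.well_id) if sample.well_id else None)
        if role is not None:
            role_map.setdefault(role, []).append(sample.sample_id)
    for sample in samples:  # unassigned samples default to targets
        assigned = any(sample.sample_id in ids for ids in role_map.values())
        if not assigned:
            role_map.setdefault("target", []).append(sample.sample_id)
    return Experiment(samples=samples, roles=role_map)


def run_pipeline(
    input_path: str | Path,
    config: AnalysisConfig,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, list[DifferentiationResult]]:
    """Deterministic end-to-end run.

    Reads the input (merged file or folder), fits the GFP threshold from the
    controls, curates, bins, splits peaks, and writes
    ``population_stats.csv``, ``differentiation.csv`` and ``run_log.txt``
    into ``out_dir``.  Returns the stats table and the per-bin results.
    """
    input_path = Path(input_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    experiment = _load_experiment(input_path, config.roles)
    curation = curate(experiment, config)
    assign_bins(curation)
    split_peaks(curation)
    stats = population_stats(curation)
    results = differentiation_fractions(stats, curation.splits)

    export_population_stats(stats, out_dir / "population_stats.csv")
    differentiation_table(results).to_csv(out_dir / "differentiation.csv", index=False)

    qc_lines = []
    myhc_ids = set(experiment.roles.get("myhc_positive", []))
    for r in results:
        if r.sample in myhc_ids:
            flag = qc_differentiation_control(r, config.qc_min_control_fraction)
            if flag:
                qc_lines.append(f"QC {flag}: {r.sample} {r.bin} fraction {r.fraction:.2f}% "
                                f"< {config.qc_min_control_fraction}%")

    log = [
        f"myodiff {_version}",
        f"input: {input_path}",
        f"samples: {[s.sample_id for s in experiment.samples]}",
        f"roles: {experiment.roles}",
        f"gfp_threshold_rfu: {curation.gfp_threshold:.6g}",
        f"quantile_level: {config.quantile_level}",
        f"debris_gate: FSC>={config.debris_gate.x_min}, SSC>={config.debris_gate.y_min}",
        f"singlet_gating: {config.singlet_gating}",
        f"bins: {[(b.label, round(b.low, 4), b.high) for b in curation.effective_bins]}",
        f"split: transform={config.split.transform.kind} cofactor={config.split.transform.cofactor} "
        f"min_events={config.split.min_events} prominence={config.split.min_prominence_fraction} "
        f"fallback_threshold_rfu={config.split.fallback_threshold} grid={config.split.grid_size}",
        f"unbinned GFP+ events per sample: {curation.unbinned}",
        f"qc_min_control_fraction_percent: {config.qc_min_control_fraction}",
    ] + (qc_lines or ["QC: no flags"])
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    return stats, results
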