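# myodiff

Automated flow-cytometry quantification of C2C12 myoblast differentiation.

C2C12 myoblasts differentiate into myotubes under low-serum conditions, and the
fraction of cells expressing the late differentiation marker myosin heavy chain
(MyHC, immunolabeled and read on a far-red channel) is a quantitative readout of
that process. When cells also transiently express a GFP-tagged gene of interest,
stratifying by GFP intensity turns the same readout into a gene-dose–dependent
assay — for example, how strongly an oncogenic construct suppresses
differentiation, and how much of it a drug rescues. `myodiff` is for
cell-biology labs running such assays on bench-top cytometers (Guava-style
acquisitions: FSC-HLin, SSC-HLin, GRN-B-HLin, RED-R-HLin) who want the analysis
automated, deterministic, and free of manual gating bias.

## Method

For each experiment containing a double-negative control (GFP−/MyHC−), a MyHC+
control, optionally a GFP+ control, and any number of target samples:

1. **Debris exclusion.** A fixed rectangular scatter gate keeps events with
   FSC ≥ 100 and SSC ≥ 50 RFU (`/NonDebris`).
2. **GFP threshold (quantile gate).** For each of the two calibration controls,
   the type-7 sample quantile `Q_0.99` of the GFP channel is computed over its
   non-debris events — the level below which 99% of that control's cells are
   found. The GFP threshold is their mean,

   `T = (Q_0.99(double-negative) + Q_0.99(MyHC+)) / 2`,

   and cells with GFP ≥ T are GFP+ (`/NonDebris/GFP+`). T also becomes the
   lower bound of the first GFP bin.
3. **Gene-dose bins.** Up to three half-open GFP windows — by default
   GFP-low `[T, 100)`, GFP-medium `[100, 1000)`, GFP-high `[1000, 10000)` RFU —
   stratify GFP+ cells by construct dose.
4. **Peak splitting.** Within each bin, MyHC intensities are mapped to
   arcsinh space (`t = asinh(v/5)/ln 10`), a Gaussian KDE with Silverman
   bandwidth `0.9·min(sd, IQR/1.34)·n^{−1/5}` is evaluated on a 512-point
   grid, and the cutpoint is placed at the density minimum strictly between
   the two tallest peaks, mapped back to RFU. Unimodal bins fall back to a
   fixed 10 RFU threshold (the instrument background level). Events at or
   above the cutpoint are MyHC+.
5. **Report.** Population counts are exported per the hierarchical
   nomenclature (`root`, `/NonDebris`, `/NonDebris/GFP+`,
   `/NonDebris/GFP+/GFP-low`, `/NonDebris/GFP+/GFP-low/MyHC+`, …) and the
   differentiated fraction of a bin is `100 · MyHC+ / bin total` percent.
   A differentiation control below 5% MyHC+ is flagged as poorly
   differentiating.

A fixed-threshold quadrant analysis (both thresholds at ~10 RFU, the
manual-software convention) is included as an independent comparator.

The package also ships a seeded simulator that generates complete synthetic
experiments — debris, doublets, autofluorescent background, a lognormal GFP
dose spanning ~10¹–10⁴ RFU, and dose-dependent differentiation with a drug
rescue — written as standard FCS 3.0 files with per-event ground truth in
sidecar CSVs, so the whole pipeline is testable without instrument data.

## Worked example

```sh
myodiff simulate --out sim --seed 5
cat > cfg.yaml <<'EOF'
roles:
  01_DN: double_negative
  02_MyHC: myhc_positive
  03_GFPctrl: gfp_positive
  04_G12C_DMSO: target
  05_G12C_AMG510: target
EOF
myodiff analyze --input sim --config cfg.yaml --out run
```

which prints (abridged):

```
04_G12C_DMSO  GFP-low: 23.73% MyHC+ (957/4033, density_valley)
04_G12C_DMSO  GFP-medium: 8.87% MyHC+ (466/5254, density_valley)
04_G12C_DMSO  GFP-high: 6.84% MyHC+ (119/1739, density_valley)
05_G12C_AMG510  GFP-low: 37.30% MyHC+ (1570/4209, density_valley)
05_G12C_AMG510  GFP-medium: 35.97% MyHC+ (1840/5115, density_valley)
05_G12C_AMG510  GFP-high: 34.37% MyHC+ (599/1743, density_valley)
```

Reading: in the vehicle-treated oncogene sample (`04_G12C_DMSO`)
differentiation drops from 23.7% at low construct dose to 6.8% at high dose,
while in the drug-treated sample (`05_G12C_AMG510`) it is restored to ~34–37%
across all doses — the dose-dependent suppression and its pharmacological
rescue that the assay is designed to measure. `run/` also contains
`population_stats.csv` (header `sample,pop,count`), `differentiation.csv`,
and `run_log.txt` recording every effective default. The GFP+ control's bins
use the `fallback_threshold` method because its MyHC channel is unimodal
background, and `myodiff report --stats run/population_stats.csv` re-derives
the fractions from the exported counts alone.

The same workflow is available as library calls: `simulate_experiment`,
`curate`, `assign_bins`, `split_peaks`, `population_stats`,
`differentiation_fractions` (see `docs/methods.md`).

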