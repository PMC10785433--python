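# meioflow

Detection of rare cell-population shifts in bi-fluorescent protoplast flow
cytometry — the computational side of a high-throughput screen for in vitro
meiosis-like induction in plants.

In this screen, diploid cells carry both a GFP and an RFP marker; cells that
have undergone a meiosis-like (reductional) division can carry only one.
A candidate induction factor is therefore judged by whether single-marker
(here RFP-only) cells appear in a large double-marker population.  The assay
is validated with *spike-ins*: known small proportions of haploid RFP
protoplasts mixed into diploid GFP/RFP protoplasts and run through a flow
cytometer.  `meioflow` implements the analysis that turns the raw per-cell
measurements into calibrated spike-in estimates:

1. **I/O** — read FCS 3.0/3.1 files (or per-event CSVs), convert to CSV with
   fluorescence-channel headers (`FITC.A` = GFP readout, `PE.CF594.A` = RFP
   readout).
2. **Threshold gating** — classify each event as RFP / GFP / GFP·RFP / WT
   using published min/max intensity cuts (GFP-positive: 560 < FITC.A <
   10 000; RFP-positive: 1 000 < PE.CF594.A < 10 000), in two variants: with
   and without a scatter/autofluorescence quality pre-filter.
3. **Misclassification-adjusted estimation** — gating is imperfect, so the
   three collapsed categories (RFP, GFP + GFP·RFP, WT) are modelled as a
   two-component multinomial mixture.  With `p_j` the probability that a
   truly-RFP cell is classified into category `j`, `q_j` the same for a
   background cell, and `s_l` the spike-in proportion of sample `l`, the
   combined log-likelihood over an experiment's samples is

   ```
   l(p, q, s) = Σ_l Σ_j y_lj · log( p_j s_l + q_j (1 − s_l) )
   ```

   with `s` fixed at 0 for the background control and at 1 for the pure-RFP
   reference.  Maximizing it jointly yields spike-in estimates `ŝ_l` with
   standard errors from the observed information, and a one-sided Wald test
   of detectability (`H0: s = 0`).
4. **Method comparison** — recovery-rate regression of thresholding-detected
   RFP proportions on the expert polygonal-gating reference, with Cook's-
   distance influential-point removal.
5. **Synthetic data** — a generator of event-level samples (bivariate
   log-normal fluorescence clusters per genotype, Gaussian scatter, a debris
   cluster, spike-in mixing) with analytically known gate-crossing
   probabilities, so the whole pipeline is testable end to end.

## Worked example

```bash
python examples/spike_in_estimation.py
```

```
sim-l1 (control_zero): RFP=13, GFP+GFP/RFP=9928, WT=59
sim-l2 (pure_one): RFP=9892, GFP+GFP/RFP=36, WT=72
sim-l3 (unknown): RFP=129, GFP+GFP/RFP=9820, WT=51

estimated spike-in: 1.173% (SE 0.120%), truth 1.2%
Wald z = 9.80, one-sided p = 5.58e-23
```

The control shows that ~0.13% of pure background cells are misclassified as
RFP; the model subtracts exactly this background (scaled by the fitted
classification probabilities) from the spiked sample's RFP fraction, so the
1.2% spike is recovered as 1.17% ± 0.12% rather than the raw 1.29%, and the
Wald test says the excess over background is far beyond chance.

Other examples: `examples/event_pipeline.py` (simulate raw events → gate →
fit, recovering the 0.28% / 1.18% / 3.89% default spike design),
`examples/recovery_rates.py` (86% and 78% recovery slopes of the two
thresholding variants against polygonal gating on the bundled six-sample
table), `examples/fcs_conversion.py` (FCS → CSV round trip).

A thin CLI wraps the same functions for shell use:

```bash
meioflow simulate --out-dir sim --n-events 20000 --seed 1
meioflow gate sim/*.csv --variant quality_rfp_gfp --out counts.csv
meioflow run config.yaml        # whole pipeline from one config file
```

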