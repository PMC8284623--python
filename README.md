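# myeloquant

Image cytometry for delineating **microglia** from **tumor-associated
macrophages (TAMs)** in multiplex immunofluorescence of human brain-tumor
tissue, with downstream survival analysis of the microglia:TAM ratio.

Microglia (brain-resident, yolk-sac-derived) and TAMs (peripherally
invading monocyte-derived macrophages) can together make up half the mass
of a glioblastoma, but they are hard to tell apart in tissue: both are
Iba1⁺. Microglial-specific markers (P2RY12, TMEM119) separate the two
populations cleanly at the protein level, whereas TAM-enriched markers
(CD14, CD163) form a continuum expressed by both. `myeloquant`
re-implements the single-cell image-analysis workflow that exploits this:

1. **Segmentation** — each marker channel is binarised (fixed / Otsu /
   quantile thresholds), the binary masks are unioned into a *master mask*
   of all myeloid cells, connected components are treated as cells, and
   each marker's mean intensity is measured per cell.
2. **Gating** — flow-cytometry-style: an Iba1 master gate excludes debris
   ("total cells"); a split gate on the microglial marker classifies
   Iba1⁺P2RY12⁺/TMEM119⁺ cells as microglia and Iba1⁺P2RY12⁻/TMEM119⁻
   cells as TAMs; CD14/CD163 high/low gates are calibrated from the
   negative-staining quantile of epilepsy control tissue. Epilepsy and
   tumor tissue carry separate gate sets.
3. **Population metrics** — per-case proportions of total gated cells,
   densities (cells/mm² of stained tissue), the microglia:TAM ratio,
   per-population mean single-cell intensities, a global expression index
   (integrated intensity normalised to myeloid density), and the standard
   comparisons (Mann–Whitney U, two-way ANOVA with Tukey/Sidak post-hocs,
   paired t, Shapiro–Wilk/F-test gating).
4. **Survival** — per-case metrics are median-split into high/low cohorts
   and analysed with Kaplan–Meier curves, the log-rank test, univariate
   Cox proportional-hazards screening, AIC-guided variable selection and
   multivariate Cox (Efron ties), with rule-based case exclusion (e.g. the
   IDH1-mutant case).
5. **Synthetic data** — because no tissue or clinical data ship with the
   method, a simulator renders multiplex images of disk-shaped cells with
   known population labels and intensities (including epilepsy/meningioma/
   glioblastoma tissue presets and perivascular CD⁺ cells on a vessel
   path), and a cohort simulator draws survival times from an exponential
   proportional-hazards model whose hazard depends on the high/low-ratio
   group and MGMT methylation status. Every stage is validated against
   this analytic ground truth.

## Worked example

```python
import numpy as np
import myeloquant as mq

# simulate a glioblastoma-like field: 80 microglia, 120 TAMs, 0.5 µm/px
spec = mq.ImageSimSpec(n_microglia=80, n_tam=120, seed=1, case_id="gbm01")
image, truth = mq.simulate_image(spec)

# segment: per-channel Otsu masks -> master mask -> cells -> intensity table
masks = [mq.make_channel_mask(image, m, "otsu") for m in image.markers]
labeled = mq.label_objects(mq.combine_masks(masks), min_area_px=20)
table = mq.measure_cells(labeled, image)

# gate: Iba1 master gate, microglia/TAM split on P2RY12
scheme = mq.GatingScheme.from_thresholds(
    master_iba1_min=9000.0, split_threshold=8250.0, split_marker="P2RY12")
calls = mq.classify_microglia_tam(table, scheme)
s = mq.summarize_case(table, calls)
print(s.microglia_count, s.tam_count, round(s.prop_microglia, 3),
      round(s.density_total, 1), round(s.ratio_mg_tam, 3))
# 80 120 0.4 762.9 0.667

# survival: protective ratio effect (true HR e^-1 ≈ 0.368 for the high group)
coh = mq.simulate_cohort(mq.CohortSimSpec(
    n_patients=2000, log_hr_ratio_high=-1.0, log_hr_mgmt=0.0, seed=3))
fit = mq.cox_univariate(mq.median_split(coh, "ratio"), "ratio_group")
print(round(fit.hr("ratio_group"), 3))
# 0.374
```

The printed summary says: all 200 simulated cells were recovered as
objects and gated correctly (80 microglia, 120 TAMs → 40% microglia), the
total myeloid density is 762.9 cells/mm² over the 0.26 mm² field, and the
microglia:TAM ratio is 0.667. The Cox fit recovers the generating hazard
ratio 0.368 to within sampling error.

A CLI mirrors the stages (`myeloquant simulate / measure / gate /
summarize / split / km / cox`); run `myeloquant --help`.

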