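# mrmpanel

A tested, reusable implementation of a plasma-proteomic biomarker-panel
development pipeline for the early detection of pancreatic ductal
adenocarcinoma (PDAC): targeted MRM-MS quantitation, marker verification
filters, an anchored combinatorial panel search with SVM classification,
and paired-ROC validation of the resulting panel against the established
clinical marker CA19-9.

CA19-9 is the only FDA-approved serum marker for pancreatic cancer, but
it misses the 10–15% of patients who lack the Lewis-A antigen and is
uninformative within its clinical normal range (< 37 U/mL).  The pipeline
implemented here builds multimarker panels anchored on CA19-9 — in the
reference application, adding leucine-rich alpha-2 glycoprotein (LRG1,
elevated in PDAC plasma) and transthyretin (TTR, decreased) — and asks
whether the panel beats the anchor by defined margins under properly
paired statistics.

It is written for computational proteomics / biostatistics practitioners
who want the full procedure as an auditable library: every stage is a
plain function over pandas tables, and a synthetic multi-center cohort
generator with ground-truth labels stands in for the (non-public)
clinical data so that every filter and selection step can be tested as a
recovery problem.

## What the pipeline does

1. **Quantitation** (`mrmpanel.quantitation`) — Skyline-style transition
   tables (sample, peptide, transition, light/heavy peak areas,
   replicate, batch) become per-sample relative peptide levels: the
   signature transition (highest total light intensity) is ratioed
   against the spiked stable-isotope standard (light:heavy), averaged
   over triplicates with a replicate CV.
2. **Verification filters** (`mrmpanel.qc`) — replicate CV ≤ 10%; median
   relative level inside (0.1, 10); transition-interference detection by
   light-vs-heavy relative-contribution discordance (paired t-test
   across replicates) plus ratio-CV; Kruskal–Wallis confounder screens
   against center and batch within controls (BH-corrected); and an
   orientation-free single-marker AUC screen (> 0.60).
3. **Statistics** (`mrmpanel.rocstats`) — Mann–Whitney AUC, DeLong's
   paired AUC test via placement values, decision cutoffs frozen at a
   fixed training specificity (default 90%) and transferred to test
   data, McNemar's paired test on discordant predictions, and PPV at a
   population prevalence

   `PPV = Se·P(D) / (Se·P(D) + (1−Sp)(1−P(D)))`, default `P(D) = 12.9e-5`.
4. **Panel search** (`mrmpanel.panels`) — every marker subset containing
   the anchor (default triples), scored by a linear-kernel SVM whose
   continuous decision value `f(x) = Σ αᵢyᵢ⟨x,xᵢ⟩ + b` feeds the ROC;
   stratified 5-fold cross-validation with per-fold standardization and
   fold-centered score pooling; two-stage selection: AUC gain ≥ 0.07
   with DeLong p < 0.05, then sensitivity gain at 90% specificity > 0.10
   with McNemar p < 0.05.
5. **Validation** (`mrmpanel.evaluation`) — deterministic stratified 4:1
   train/test split, frozen-model application, and the eight standard
   scenarios (overall, early-stage, vs other cancers, vs benign disease,
   each also restricted to subjects with CA19-9 in the normal range),
   with report tables, box plots and ROC overlays.
6. **Synthetic cohorts** (`mrmpanel.synthetic`) — a 1008-sample,
   five-center cohort generator calibrated to the study demographics
   (group sizes, per-center CA19-9 medians and dispersions, stage
   distributions, censoring, missingness, batch structure, triplicate
   noise, injectable transition interference) that emits ground-truth
   labels for every planted property.  See `docs/methods.md` for the
   model and its calibration.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from mrmpanel import synthetic, quantitation, qc, panels, evaluation, rocstats

cfg = synthetic.default_cohort_config(seed=7)
meta, truth = synthetic.generate_cohort(cfg)
records = synthetic.generate_transition_data(meta, cfg, truth)
quant = quantitation.quantify(records)

report, verdicts = qc.run_qc(records, quant, meta)
stable = sorted({v.peptide.split('.')[0] for v in verdicts
                 if not (v.failed_rules - {'auc_screen'})})

qmat = quantitation.quant_matrix(quant)
feats = panels.build_feature_matrix(qmat, meta, markers=stable)
train_ids, test_ids = evaluation.split_train_test(meta, seed=7)
y = meta.set_index("sample_id")["group"] == "PDAC"

results = panels.search_panels(feats.loc[train_ids], y.loc[train_ids],
                               seed=7, min_size=3, max_size=3)
top = results.iloc[0]

cols = top["markers"].split("+")
Xtr = feats.loc[train_ids, cols].dropna()
model = panels.freeze_cutoff(panels.train_panel(Xtr, y.loc[Xtr.index], seed=7),
                             Xtr, y.loc[Xtr.index], 0.90)
anchor_cut = rocstats.sensitivity_at_specificity(
    Xtr["CA19-9"].to_numpy(), y.loc[Xtr.index].to_numpy(), 0.90)
scen = evaluation.evaluate_scenarios(
    model, feats.loc[test_ids], meta[meta.sample_id.isin(test_ids)],
    anchor_cut.cutoff)
```

Output (seed 7):

```
cohort: 1008 samples, 22 markers, 199584 transition rows
assay-stable markers after QC: 22
searched 231 anchored triples; best: CA19-9+LRG1+TTR (cvAUC 0.925, anchor 0.822, DeLong p 7.13e-14)
                        scenario  n_case  n_control anchor_auc panel_auc delong_p
                 control_vs_pdac      80         69      0.809     0.934    0.000
         control_vs_pdac_stage12      51         69      0.886     0.955    0.032
             othercancer_vs_pdac      80        149      0.794     0.916    0.000
                  benign_vs_pdac      80         21      0.825     0.946    0.000
        control_vs_pdac_lowca199      32         69      0.523     0.845    0.000
control_vs_pdac_stage12_lowca199      12         69      0.514     0.837    0.003
    othercancer_vs_pdac_lowca199      32        138      0.543     0.839    0.000
         benign_vs_pdac_lowca199      32         20      0.597     0.897    0.000
```

Reading the table: the search recovers the planted CA19-9+LRG1+TTR
triple out of 231 candidates; on the held-out test set the frozen panel
improves the overall cancer-vs-control AUC from 0.81 (anchor alone) to
0.93, and where CA19-9 is blind by construction — subjects inside its
normal range, where the anchor's AUC sits near 0.5 — the panel still
discriminates at AUC ≈ 0.84, the qualitative signature of a useful
add-on marker pair.  All panel rows carry paired DeLong p-values against
the anchor on the same samples.

The same steps are available from the shell via the `mrm-panel` console
script (`simulate`, `quantify`, `qc`, `search`, `evaluate` subcommands);
each reads and writes plain TSV/CSV/JSON files.

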