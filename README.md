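# fluidert

A reusable analysis pipeline for **noninvasive, RNA-seq-based endometrial
receptivity testing** from uterine-fluid transcriptomes.

Successful embryo implantation requires transferring the embryo inside the
window of implantation (WOI), the short interval around LH+7 (natural cycle)
or P+5 (hormone replacement) when the endometrium is receptive. Uterine
fluid aspirated just before transfer can be sequenced without biopsying the
endometrium, and its transcriptome carries enough signal to stage the tissue
as pre-receptive (PR), receptive (RE) or post-receptive (PO). A PR or PO
call on the expected receptive day means the WOI is displaced (delayed or
advanced) and the transfer is likely to fail.

`fluidert` implements the full chain from an expression matrix to a clinical
readout, for computational biologists who want to build, audit or stress-test
such a classifier:

1. **I/O and normalisation** (`exprio`) — TSV count/FPKM matrices with
   sample metadata; FPKM$_{gs} = c_{gs}\cdot 10^9 / (N_s \ell_g)$;
   $\log_2(\mathrm{FPKM}+1)$; per-library QC gates.
2. **Differential expression** (`degstats`) — per-gene ANOVA on the additive
   decomposition $Y_{gij} = \mu_g + T_{gi} + S_{gj} + \varepsilon_{gij}$
   (treatment = cycle protocol, stage = PR/RE/PO), $F = MS_S / MS_\varepsilon$,
   Benjamini–Hochberg q-values, pairwise log2 fold changes, volcano classes
   (p < 0.05, fold change ≥ 2) and Tukey HSD on all three stage pairs.
3. **Co-expression modules** (`coexnet`) — soft-thresholded correlation
   network ($a_{ij} = |\mathrm{cor}|^\beta$, β = 6), topological overlap,
   average-linkage tree cutting, module eigengenes, module–stage correlation,
   and the max-$k_{\text{within}}$ hub gene per module.
4. **Marker selection** (`markers`) — genes significant in *all three*
   pairwise Tukey tests, ranked by random-forest mean decrease accuracy and
   mean decrease Gini; the panel (default 87 genes) is augmented with the
   non-grey module hubs.
5. **Classification** (`ertmodel`) — a random forest over the panel with a
   probability-threshold call rule (τ = 0.6; below it the test reports
   NO_CALL), patient-grouped 10-fold cross-validation, WOI interpretation,
   and an LDA projection for visualisation.
6. **Clinical association** (`clinstats`) — 2×2 WOI-by-pregnancy tables with
   two-sided Fisher exact tests, cohort rates, and a generic hypergeometric
   over-representation test.
7. **Synthetic cohorts** (`synthdata`) — a generator with a planted truth
   ledger (stage-associated genes, modules, hubs, hidden validation stages
   and outcomes) so every stage of the pipeline is testable without any
   sequencing data.

## Worked example

`examples/receptivity_test_workflow.py` trains on a simulated 48-patient
cohort, predicts a 22-sample transfer-day cohort and tests the outcome link:

```text
10-fold patient-grouped CV: accuracy 98.7%, sensitivity 98.7%, specificity 99.3%
validation libraries passing QC: 21/22
WOI calls: {'normal': 13, 'delayed': 5, 'indeterminate': 2, 'advanced': 1, 'detection_failed': 1}
pregnancy rate, normal WOI: 92.3%  displaced WOI: 0.0%  overall: 54.5%
Fisher exact p = 0.0003 (association of displaced WOI with implantation failure)
```

The CV block says the staging signal is learnable from the panel; the WOI
lines show the per-sample readout a clinic would receive (including the
no-call and failed-library paths); the Fisher p tests whether displaced-WOI
patients fail to conceive more often than normal-WOI patients.
`examples/simulate_and_detect_degs.py` and `examples/modules_and_markers.py`
walk the earlier stages (DEG recovery and FDR behaviour; modules, hubs and
the marker panel).

There is also a CLI for shell use: `fluidert run --config pipeline.yaml`
executes the whole workflow with one YAML config and writes per-stage TSV/JSON
artifacts plus a manifest of SHA-256 hashes (identical config + seed is
byte-identical); `fluidert simulate|normalize|deg|network|select-markers|
train|cv|predict|assoc|ora` expose single stages.

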