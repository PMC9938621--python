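"""The complete receptivity test: train, cross-validate, predict transfer-day
samples, interpret the window of implantation and test the outcome link.

Training uses patient-grouped 10-fold cross-validation (the three stage-timed
samples of one woman never straddle a fold).  Transfer-day predictions use
the 0.6 probability threshold: below it the test reports NO_CALL rather than
guessing.  RE = normal WOI, PR = delayed, PO = advanced; the 2x2 association
of WOI status with pregnancy is tested with Fisher's exact test.
"""

from fluidert import (RFConfig, SimulationConfig, cross_validate,
                      outcome_association, predict_with_threshold, qc_filter,
                      simulate_training_cohort, simulate_validation_cohort, train)

config = SimulationConfig(n_patients=48, n_genes=2000, n_deg=200,
                          module_sizes=(60, 50, 40, 30),
                          validation_n=22, validation_qc_fail=1, seed=1)
training, truth = simulate_training_cohort(config)
markers = truth.deg_gene_ids[:90]  # panel selection shown in modules_and_markers.py

cv = cross_validate(training, markers, k=10, rf_config=RFConfig(n_trees=300, seed=1))
print(f"10-fold patient-grouped CV: accuracy {100 * cv.mean['accuracy']:.1f}%, "
      f"sensitivity {100 * cv.mean['sensitivity']:.1f}%, "
      f"specificity {100 * cv.mean['specificity']:.1f}%")

model = train(training, markers, RFConfig(n_trees=300, seed=1), tau=0.6)
validation = simulate_validation_cohort(config, truth)
passed, qc = qc_filter(validation, min_genes_detected=int(0.5 * validation.n_genes),
                       min_total=0)
print(f"validation libraries passing QC: {len(qc.passed)}/{validation.n_samples}")

report = predict_with_threshold(model, passed, failed_samples=qc.failed)
print("WOI calls:", report["woi"].value_counts().to_dict())

table = outcome_association(report, validation.sample_meta["outcome"])
print(f"pregnancy rate, normal WOI: {100 * table.normal_rate:.1f}%  "
      f"displaced WOI: {100 * table.displaced_rate:.1f}%  "
      f"overall: {100 * table.overall_rate:.1f}%")
print(f"Fisher exact p = {table.fisher_p:.4f} "
      "(association of displaced WOI with implantation failure)")
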