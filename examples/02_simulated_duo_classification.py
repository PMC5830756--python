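"""Predicting coordination bouts on a small simulated duo corpus.

Simulates six phase-coupled duos with scheduled coordination bouts, builds
the frame-wise predictor table, screens the predictors, and compares the
1-predictor logistic model with the 8-predictor random forest on held-out
frames.
"""

from duetsync import (
    EIGHT_PREDICTOR_SET,
    ONE_PREDICTOR_SET,
    DuoRecording,
    build_table,
    fit_predict,
    screen_predictors,
    split_train_eval,
)
from duetsync.simulate import nonpulsed_config, simulate_dyad

duos = []
for seed in range(6):
    d = simulate_dyad(nonpulsed_config(duration_s=120.0, seed=seed))
    duos.append(
        DuoRecording(
            rho_a=d.rho_a, rho_b=d.rho_b, bouts=d.truth,
            qom_a=d.qom_a, qom_b=d.qom_b, recording_id=f"sim{seed}",
        )
    )

table = build_table(duos)
print(f"{len(table)} analysis frames, "
      f"{table.label.mean():.1%} inside coordination bouts\n")

train, eval_set = split_train_eval(table, seed=0)
screening = screen_predictors(train, cv_folds=5, cv_repeats=2, seed=0)
print("univariate screening (CV AUC):")
print(screening.to_string(index=False, float_format="%.3f"), "\n")

for kind, preds, label in [
    ("logistic", ONE_PREDICTOR_SET, "1-predictor logistic (broad CWT energy)"),
    ("random_forest", EIGHT_PREDICTOR_SET, "8-predictor random forest"),
]:
    rep = fit_predict(train, eval_set, kind, preds, cv=None, seed=0)
    print(f"{label}: held-out AUC {rep.auc:.3f} "
          f"(CI95 {rep.ci95[0]:.3f}-{rep.ci95[1]:.3f}), "
          f"FN {rep.fn_rate:.1%} / FP {rep.fp_rate:.1%} at the Youden cutoff")
print("\nThe broad cross-wavelet energy alone recovers most bouts; the")
print("forest adds the narrow-band and overall-motion structure.")
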