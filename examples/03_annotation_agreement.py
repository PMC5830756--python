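"""Inter-annotator agreement and consensus bouts on simulated annotations.

Three noisy annotators mark the true coordination bouts of a simulated duo;
their tiers are DTW-aligned pairwise, agreement is summarized with Cohen's
kappa, and the >= 2-rater consensus is compared against the ground truth.
"""

import numpy as np

from duetsync import aggregate_bouts, binarize, cohens_kappa, dtw_align
from duetsync.simulate import AnnotatorModel, nonpulsed_config, simulate_annotators, simulate_dyad

cfg = nonpulsed_config(duration_s=150.0, seed=11)
dyad = simulate_dyad(cfg)
model = AnnotatorModel(onset_jitter_sd_s=0.4, miss_prob=0.15,
                       false_alarm_rate_per_min=0.3, n_annotators=3)
tiers = simulate_annotators(dyad.truth, model, cfg.duration_s, seed=2)

rate = cfg.rate_hz
kappas = []
for i in range(3):
    for j in range(i + 1, 3):
        a = binarize(tiers[i], rate, cfg.duration_s)
        b = binarize(tiers[j], rate, cfg.duration_s)
        aligned = dtw_align(a, b, band_s=2.0)
        rep = cohens_kappa(a, aligned)
        raw = cohens_kappa(a, b)
        kappas.append(rep.kappa)
        print(f"pair ({tiers[i].annotator_id}, {tiers[j].annotator_id}): "
              f"kappa {rep.kappa:.3f} aligned vs {raw.kappa:.3f} raw "
              f"(z = {rep.z_stat:.1f})")
print(f"mean aligned kappa: {np.mean(kappas):.3f}\n")

consensus = aggregate_bouts(tiers, rate, min_raters=2, duration_s=cfg.duration_s)
print(f"true bouts: {len(dyad.truth.intervals)}, "
      f"consensus bouts (>= 2 raters): {len(consensus.intervals)}")
for iv in consensus.intervals:
    print(f"  consensus [{iv.onset_s:7.2f}, {iv.offset_s:7.2f}) s")
print("Jitter shrinks each pair's raw agreement; the band-constrained DTW")
print("alignment absorbs it, and 2-of-3 aggregation drops lone false alarms.")
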