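"""Detection power of the Bayes-factor criterion vs effect size.

For a stationary rate of 0.02 spikes per 2 ms bin and 3 pooled trials,
prints how often BF_ne >= 10 detects increasing motion-phase rates, and
the false-positive rate under the null.
"""

from cxcompass import power_analysis

r_s = 0.02
print("r_motion  detection  (95% CI)        [r_stationary = 0.02, 3 trials x 2500 bins]")
for r_m in (0.02, 0.03, 0.04, 0.05, 0.10):
    res = power_analysis(r_m, r_s, n_bins=2500, n_trials=3, n_reps=1000, seed=42)
    label = "  <- null (false-positive rate)" if r_m == r_s else ""
    print(f"  {r_m:.2f}     {res.detection_prob:5.3f}   "
          f"[{res.ci_low:.3f}, {res.ci_high:.3f}]{label}")
print("power rises steeply with effect size; the null stays near zero.")
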