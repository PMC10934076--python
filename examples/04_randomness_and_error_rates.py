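"""Evaluation metrics: error seed/bit rates, entropies and randomness tests.

Runs a small cohort evaluation and prints the same indicator families the
system is assessed with: seed reproduction error rates for the dynamic
quantizer vs the fixed-length baseline, per-key entropies, and the four
statistical randomness tests on the pooled key bits.
"""

import warnings

from ecgkey.cohort import build_cohort, evaluate_cohort

warnings.simplefilter("ignore")

print("simulating and evaluating a 8-subject x 5-session cohort...")
data = build_cohort(n_subjects=8, n_sessions=5, n_population=40, rng_seed=2)
ev = evaluate_cohort(data, criterion="pu", rng_seed=2)

print(f"\nseed widths (pre-padding): "
      f"{[len(s.enrolled) - s.pad_bits for s in ev.seeds]}")
print(f"error seed rate:  proposed {ev.esr:5.1f} %   "
      f"baseline(152-bit) {ev.esr_baseline:5.1f} %")
print(f"error bit rate:   proposed {ev.ebr:5.1f} %   "
      f"baseline(152-bit) {ev.ebr_baseline:5.1f} %")
# the personalized quantizer reproduces far more seeds exactly than a global
# fixed-width interval coder on the very same sessions.

print(f"\nkey entropy (per key, mean): Shannon "
      f"{ev.entropy['key_shannon_mean']:.3f}, min "
      f"{ev.entropy['key_min_mean']:.3f}")
print("randomness tests on pooled key bits (p >= 0.01 passes):")
for name, p in ev.nist.items():
    print(f"  {name:16s} p = {p:.3f}")

print("\nauthentication over the tau sweep:")
for tau, m in ev.per_tau.items():
    print(f"  tau={tau:.2f}: accuracy={m['accuracy']:.2f} "
          f"FAR={m['far']:.2f} FRR={m['frr']:.2f}")
# raising tau relaxes the fuzzy extractor: rejections of genuine users fall
# while false accepts of impostors rise.
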