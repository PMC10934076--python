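"""Denoise, delineate, normalize and extract the 29 fiducial features.

Runs the preprocessing chain on a noisy synthetic record, forms the ensemble
beat from the three most template-like beats, and prints a few features with
their units.
"""

from ecgkey import features, preprocess, synthecg

template = synthecg.make_subject(rng_seed=7)
record = synthecg.synth_record(template, 0, 20.0, noise_cfg="default",
                               rng_seed=7)

denoised = preprocess.denoise(record)
beats = preprocess.delineate(denoised)
hr = preprocess.observed_heart_rate(beats)
print(f"delineated {len(beats)} beats, observed HR {hr:.1f} bpm")

normalized = preprocess.normalize_beats(beats, hr)
clean = preprocess.remove_outliers(normalized)
print(f"{len(normalized)} beats normalized to the 70 bpm standard sections, "
      f"{len(clean)} kept after outlier removal")

ens = preprocess.ensemble(clean)
fs = features.extract_features(ens)
print("\nensemble-beat features (subset):")
for name in ("RS amplitude", "PT amplitude", "QS interval", "PR interval",
             "RT slop", "QRS area"):
    unit = ("mV" if "amplitude" in name else
            "ms" if "interval" in name else
            "mV/s" if "slop" in name else "mV*ms")
    print(f"  {name:14s} = {fs.by_name(name):8.2f} {unit}")
# amplitudes are peak-to-peak voltage differences; intervals are times between
# wave peaks after per-section normalization; the area integrates |QRS|.
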