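"""Generate a synthetic one-factor-at-a-time fermentation campaign.

The default design mirrors the study conditions: saturating dose-response
for casamino acid and GTP, rise-then-fall for glycine and sodium acetate,
3 µg/L Gaussian measurement noise, triplicates at the tested
concentrations. The printed means show each factor's dose-response shape.
"""

import numpy as np

import ribofis as rf

config = rf.default_config(seed=2023, noise_sd=3.0, replicates=3)
datasets = rf.generate_ofat(config)

for ds in datasets:
    shape = config.curves_dict[ds.factor].shape
    print(f"{ds.factor} ({shape}):")
    for level in ds.levels:
        responses = [o.response for o in ds.observations if o.level == level]
        print(f"  {level:>6g} g/L -> mean {np.mean(responses):6.1f} ug/L "
              f"(n={len(responses)}, sd {np.std(responses, ddof=1):.1f})")
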