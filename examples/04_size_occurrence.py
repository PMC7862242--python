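"""Size-dependent slick occurrence: do bigger larvae live in slicks?

Fish are binned into 5-mm length classes; per class the bootstrapped mean
densities give the proportion of the class found in slicks, and a beta
regression fits a logit-linear occurrence curve against length.
"""

import slicksurvey as ss

survey, truth = ss.simulate_survey(ss.default_config(seed=1))

table = ss.occurrence_proportions(survey, bin_mm=5, nboot=2000, seed=1)
print("length bin (mm)   share in slicks   n fish")
for _, row in table.head(8).iterrows():
    print(f"  [{row.bin_low_mm:2.0f},{row.bin_high_mm:2.0f})          "
          f"{row.p:6.3f}         {row.n_fish:6.0f}")

fit = ss.beta_regression(table)
print(f"\nbeta regression: slope {fit.slope:.4f} logit/mm "
      f"(Z = {fit.z_statistic:.2f}, pseudo-R2 = {fit.pseudo_r2:.2f})")
print(f"fitted occurrence at 5 mm: {fit.predict([5.0])[0]:.2f}; "
      f"at 30 mm: {fit.predict([30.0])[0]:.2f}")
print("A positive slope means larger larvae are increasingly concentrated "
      "in slicks —\nconsistent with active habitat selection by competent "
      "swimmers.")
print(f"(generator truth: slope {truth['size']['logit_slope']}, shifted "
      f"intercept {truth['size']['effective_intercept']:.2f})")
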