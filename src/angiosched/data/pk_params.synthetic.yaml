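# Synthetic, representative pharmacokinetic defaults (NOT fitted to animal
# data — replace with constants calibrated to your own study).
#
# Rates are in 1/day.  `scale` converts a unit dose (mg/kg) to concentration
# units; it is set to ke so a unit dose has unit area under the curve, and
# the pharmacodynamic potency coefficients absorb any residual constant.
#
# cytotoxic (paclitaxel): terminal half-life 3 h -> ke = ln2/0.125 per day;
#   fast first-order absorption after intraperitoneal injection.
# antiangiogenic (bevacizumab): effective half-life of 1 day.  This is the
#   decay of the normalization *stimulus* the dynamic model responds to,
#   shorter than the plasma persistence of the antibody itself; it sets the
#   width of the transient vascular normalization window (days, not weeks).
cytotoxic:
  ka_per_day: 40.0
  ke_per_day: 5.545177444479562
  scale: 5.545177444479562
antiangiogenic:
  ka_per_day: 1.3862943611198906
  ke_per_day: 0.6931471805599453
  scale: 0.6931471805599453
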