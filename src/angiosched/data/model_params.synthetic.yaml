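# Synthetic, representative pharmacodynamic defaults (NOT fitted to animal
# data — replace with values calibrated to your own experiment).
#
# Both sets reproduce the same stated world on the three-arm design
# (cycles D11/D21/D31, 20 mg/kg both drugs): an untreated arm near
# 190-fold burden at day 52, a concomitant arm at roughly 0.55x control
# and a 3-day sequential arm at roughly 0.27x control.  The model-2 set
# additionally exhibits a transient vascular normalization window: pairs
# with the antiangiogenic-driven ("literal") vascular kill term, under
# which the gap scan has an interior optimum of ~3 days and an 8-day gap
# is detrimental.
shared:
  k: 1.0           # kill-chain transit rate (1/day)
  tau: 0.0         # stable-vessel loss (pinned at 0 by calibration)
  t_I: 8.0         # first observation day
model1:
  a: 0.148         # Gompertz proliferation rate (1/day)
  b: 1.0           # angiogenesis stimulation (1/day)
  d: 0.0257        # angiogenesis inhibition (1/(day*fold^(2/3)))
  e_txl: 0.0111    # cytotoxic potency of paclitaxel
  e_beva: 0.00377  # antiangiogenic potency of bevacizumab
  K0: 1.85         # initial carrying capacity (fold units)
  qbar: 0.203      # constant quality of the concomitant arm
model2:
  a: 0.1
  b: 30.0          # strong neo-angiogenic flux into the unstable pool
  d: 0.15          # fast unstable-vessel turnover (closes the window)
  e_txl: 0.0013
  e_beva: 0.03
  chi: 0.003       # slow maturation: stable pool nearly frozen
  K0: 150.0        # initial (= stable) vasculature, fold units; U0 = 0
  U0: 0.0
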