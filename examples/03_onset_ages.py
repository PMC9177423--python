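"""Back-extrapolate clone ages with the two-phase Wright-Fisher model.

Given a fitted growth rate b and birth offset u, the deterministic
back-extrapolation t0 is corrected for the initial stochastic (drift)
phase; onsets before conception (age -1) are infeasible and define the
minimal lifelong growth a clone must have had.
"""

import clonekinetics as ck

# a clone growing at 20%/yr (logit scale), subdetectable at birth
est = ck.age_at_onset(b_total=0.2, u=-15.0, n_hsc=50_000, g=2.0)
print(f"deterministic back-extrapolation t0 = {est.t0:.2f} y")
print(f"stochastic-phase corrected onset    = {est.t0_adjusted:.2f} y "
      f"(feasible: {est.feasible})")

lat = ck.detection_latency(0.2, -15.0, threshold_vaf=0.002)
print(f"latency from foundation to VAF >= 0.2%: {lat:.1f} y")

# a slow clone seen at VAF 0.2 at age 70 cannot have grown at 5%/yr its
# whole life -- that onset would precede conception
hg = ck.minimal_historical_growth(latest_vaf=0.2, age_t=70.0, observed_b=0.05)
print(f"\nobserved rate 0.05/yr is infeasible (capped: {hg.capped})")
print(f"minimal historical growth: {hg.minimal_historical_rate:.4f}/yr; "
      f"observed/historical ratio = {hg.ratio:.2f}")
print("a ratio < 1 means the clone must have grown faster earlier in life")
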