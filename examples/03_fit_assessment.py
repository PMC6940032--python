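"""Scale-, item-, and person-level fit assessment for one fitted model.

Computes the limited-information M2 statistic with RMSEA (90% CI), SRMSR,
TLI and CFI against the independence null, the residual-correlation
screen, a rest-score item-fit statistic, and the Zh person-fit summary.
"""

import irtqol as q

spec = q.preset("eq5d", n_persons=2000, seed=3)
data = q.simulate(spec)
model = q.fit_em(data, spec.structure, seed=1)

rep = q.fit_report(data, model)
print(f"M2 = {rep.m2:.2f} on df = {rep.df_m2}, p = {rep.p_m2:.3f}")
print(f"RMSEA = {rep.rmsea:.3f} (90% CI {rep.rmsea_ci[0]:.3f}-{rep.rmsea_ci[1]:.3f})"
      f"  [<= 0.05 acceptable]")
print(f"SRMSR = {rep.srmsr:.3f}  [<= 0.05 acceptable]")
print(f"TLI = {rep.tli:.3f}, CFI = {rep.cfi:.3f}  [>= 0.90 acceptable]")

resid, summary = q.residual_correlations(data, model)
print(f"\nresidual correlations: mean |r| = {summary['mean_abs']:.3f}, "
      f"{summary['n_above_threshold']} pair(s) above 0.05, "
      f"max |r| = {summary['max_abs']:.3f}")

stat, df, p, table = q.item_fit_sx2(data, model, item=1)
print(f"\nS-X2 for item 2: {stat:.1f} on df = {df}, p = {p:.3f}")

scores = q.eap_scores(data, model)
pf = q.zh_person_fit(data, model, scores)
print(f"person fit: {pf.summary['pct_misfit']:.1f}% misfit (Zh < -2), "
      f"{pf.summary['pct_overfit']:.1f}% overfit (Zh > 2)")
# Because the data were simulated from the fitted model family, all
# indices should sit comfortably inside their acceptability thresholds.
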