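"""Collinearity screening with variance inflation factors.

The default generator engineers a strongly correlated covariate pair
(per-capita income and university-graduate share at r = 0.829), which pushes
both VIFs above the 2.5 concern threshold; the screen drops the worse one.
"""

import caremap as cm

cfg = cm.SimulationConfig(graph="irregular", n_areas=1896, seed=4)
table, _, _ = cm.simulate_dataset(cfg)

socio = ["unemployment", "income", "pop_density", "crime_rate",
         "divorce_rate", "univ_graduates"]
vifs = cm.vif(table.covariates[socio], socio)
print("VIFs before screening:")
for name, v in vifs.items():
    marker = "  <-- above 2.5" if v > 2.5 else ""
    print(f"  {name:16s} {v:5.2f}{marker}")

report, reduced = cm.screen(table.covariates[socio], socio, threshold=2.5)
r = report.pairwise_r.loc["income", "univ_graduates"]
print(f"\nincome vs univ_graduates correlation: r = {r:.3f}")
print(f"dropped: {[name for name, _ in report.dropped]}")
print(f"retained: {list(report.retained)} (all VIFs now <= 2.5)")
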