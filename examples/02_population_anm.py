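"""Population ANM distribution under supply and drift heterogeneity.

Simulates women whose starting supplies are log-normal (mu = 12.686,
sigma = 0.497), first with identical drift for every subject, then with a 3%
coefficient of variation in drift. The second source of heterogeneity
broadens the ANM distribution (wider IQR, heavier tails) without moving its
median.
"""

from pfwalk import simulate_population

for c, label in ((0.0, "identical drift  (c = 0)"),
                 (0.03, "variable drift   (c = 0.03)")):
    res = simulate_population(5000, c=c, seed=42,
                              keep_quantile_trajectories=False)
    s = res.summary()
    print(f"{label}: median ANM {s['median_anm']:.2f} yr, "
          f"IQR {s['iqr']:.2f} yr, "
          f"P(ANM <= 40) = {s['prop_anm_le_40']:.4f}, "
          f"P(ANM >= 62) = {s['prop_anm_ge_62']:.4f}")

print("\nmedian ANM ~51 yr in both cases; drift heterogeneity widens the "
      "spread, including rare menopause before 40 (POI-like timing)")
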