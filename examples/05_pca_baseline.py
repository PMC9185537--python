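"""Compare the day-factor series with the PCA first-component baseline.

PCA treats frequencies as observations and soaking days as variables,
column-centers, and keeps the first right singular vector — one coefficient
per day, normalized to the first day, directly comparable to the normalized
DF series. The two reductions give similar day-to-day shapes on drifting
data; DF is the cheaper, frequency-weightable summary.
"""

from dayfactor import (
    df_series,
    mean_over_channels,
    pca_first_component,
    scenario_preset,
    simulate_dataset,
)

scenario = scenario_preset("dip_then_rise", seed=1)
spectra = mean_over_channels(simulate_dataset(scenario))
df = df_series(spectra)
pca = pca_first_component(spectra)

print("day  normalized DF  normalized PCA coefficient")
for day, d, p in zip(df.days, df.normalized, pca.normalized_coefficients):
    print(f"{day:3d}  {d:13.4f}  {p:26.4f}")
# Both series start at 1 on the reference day. The PCA coefficients live on
# their own scale (centered-variance loadings), so compare shapes, not values.
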