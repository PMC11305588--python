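"""Mean-KDE demography: recovering a known occupation curve.

A bimodal occupation history over 4000-200 cal BP generates 1000 dated
samples (Gaussian age errors, preferential-attachment site oversampling).
The clustered-bootstrap mean KDE (200 iterations, bandwidth 50 yr,
within-site clustering cut h = 100 yr, 30-year bins, trimmed to
3700-300 cal BP) should rank-correlate strongly with the generating curve.
"""

import numpy as np
from scipy.stats import spearmanr

from ismpop import mean_kde, synthetic_dates
from ismpop.synthetic import ScenarioSpec, make_density_scenario

sc = make_density_scenario(ScenarioSpec("bimodal_occupation", seed=1))
dates = synthetic_dates(sc.series, n=1000, seed=2)
kde = mean_kde(dates, n_iter=200, bandwidth=50.0, bin_width=30.0, h=100.0, seed=3)

truth = np.interp(kde.bin_calBP, sc.series.bin_centers[::-1], sc.series.values[::-1])
rho = spearmanr(kde.mean, truth).statistic
peak = kde.bin_calBP[np.argmax(kde.mean)]

print(f"dated samples: {len(dates)} across {len({d.site for d in dates})} sites")
print(f"mean KDE bins: {len(kde.bin_calBP)} (30-yr, {kde.bin_calBP.max():.0f}"
      f"-{kde.bin_calBP.min():.0f} cal BP)")
print(f"Spearman rho vs generating curve: {rho:.3f}")
print(f"strongest occupation signal at ~{peak:.0f} cal BP (truth: 1200 cal BP mode)")
# rho near 1 means the binned mean KDE reproduces the occupation history's
# shape; absolute KDE units are arbitrary and only ranks are compared.
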