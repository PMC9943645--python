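"""Project the community under a drier climate vs. the past climate.

The climate scenario resamples observed rainfall with below-average
years drawn with probability 0.8; the baseline resamples all observed
values uniformly.  Both run 100 stochastic community projections over
50 years and report mean adult abundances; the difference per species
shows who loses directly, and who is released from competition.
"""

import numpy as np

import stagecast as sc
from stagecast.forecast import _historical_inter
from stagecast.metapop import build_dispersal_matrix
from stagecast.synth import DEFAULT_STD

truth = sc.make_truth(n_species=5, effect_scale=0.3, seed=1)
rain = sc.make_rainfall(8, seed=2, first_year=2007)
topo = sc.grid_topology(18, retention=0.9)
data, _ = sc.simulate_community(truth, topo, 8, rain, seed=3)

D = build_dispersal_matrix(topo)
init = np.nan_to_num(data.counts[:, :, -1, :])
common = dict(D=D, std=DEFAULT_STD, rain_series=rain, seed=9)

base = sc.run_scenario(truth, init,
                       sc.ScenarioSpec(kind="baseline", horizon=50, n_runs=100),
                       **common)
clim = sc.run_scenario(truth, init,
                       sc.ScenarioSpec(kind="climate_change", p_below=0.8,
                                       horizon=50, n_runs=100),
                       **common)
clim_nd = sc.run_scenario(truth, init,
                          sc.ScenarioSpec(kind="climate_change", p_below=0.8,
                                          horizon=50, n_runs=100,
                                          dynamic_interspecific=False),
                          inter_hist=_historical_inter(data), **common)

diff = sc.compare_scenarios(clim, base)
diff_nd = sc.compare_scenarios(clim_nd, base)
print("change in mean adults/plot under the drier climate (climate - baseline):")
for sp in base.species:
    d = diff.loc[diff.species == sp, "delta_adults"]
    dn = diff_nd.loc[diff_nd.species == sp, "delta_adults"]
    print(f"  {sp}: fully dynamic {d.mean():+6.2f}   "
          f"no-dynamic {dn.mean():+6.2f}   (rain slope on adult survival "
          f"{truth[base.species.index(sp)].phi_coefs[1]:+.2f})")
# Species whose adult survival tracks rainfall decline under the dry
# scenario; others can even gain when their competitors decline.  The
# no-dynamic column shows how the picture distorts when interspecific
# densities are frozen at historical values instead of projected.
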