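"""Population exposure metrics and the covariate-effect forest simulation.

Computes per-subject steady-state AUC0-tau/Cmax/Ctau by grid NCA for a
simulated 361-subject population, prints the geometric means, then reruns
the population 200 times with fresh random effects to place each covariate
category's AUC ratio against the 0.8-1.25 bioequivalence band.
"""

import numpy as np

from dlpk import forest_simulation, load_model
from dlpk.nca import exposure_table
from dlpk.population import PopulationSpec, draw_covariates

cov = draw_covariates(PopulationSpec(), seed=7)
gm = lambda x: float(np.exp(np.mean(np.log(x))))

for name in ("dolutegravir", "lamivudine"):
    model = load_model(name)
    tab = exposure_table(model, cov, seed=7)
    print(f"\n{name}: geometric means over {len(tab)} simulated subjects")
    print(f"  AUC0-24 = {gm(tab.auc_tau):5.1f} ug*h/mL, "
          f"Cmax = {gm(tab.cmax):4.2f} ug/mL, C24 = {gm(tab.ctau):.3f} ug/mL")
    fs = forest_simulation(model, cov, n_trials=200, seed=7)
    auc = fs[fs.metric == "auc_tau"].sort_values(["covariate", "category"])
    print("  AUC ratio vs overall population (median [2.5th-97.5th]):")
    for _, r in auc.iterrows():
        flag = "" if 0.8 < r["median"] < 1.25 else "  <-- outside band"
        print(f"    {r['category']:15s} {r['median']:5.2f} "
              f"[{r['p2.5']:.2f}-{r['p97.5']:.2f}]{flag}")
print("\nRatios inside 0.8-1.25 mean the covariate shifts exposure by less "
      "than a bioequivalence margin — no dose adjustment needed.")
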