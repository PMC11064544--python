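"""OFV-based covariate selection and the nonparametric bootstrap.

Simulates data that truly carry the ethnicity effect on dolutegravir CL/F
(ratio 0.844), starts from a base model without it, and lets the
forward (dOFV >= 6.63) / backward (dOFV >= 10.83) search rediscover the
term; then bootstraps a small fit to show resampling-based precision.
"""

from dataclasses import replace

from dlpk import bootstrap, covariate_search, load_model, simulate_population
from dlpk.models import CovariateTerm, RandomEffectsSpec
from dlpk.population import PopulationSpec
import dataclasses

dtg = load_model("dolutegravir")
base = dtg.with_fixed(replace(
    dtg.fixed,
    covariate_terms=tuple(t for t in dtg.fixed.covariate_terms if t.covariate != "ethnicity"),
))
data = simulate_population(dtg, PopulationSpec(n_subjects=250, n_intensive=30), seed=101)

cand = CovariateTerm(target="cl", covariate="ethnicity", form="categorical", value=1.0)
res = covariate_search(data, base, [cand], n_starts=1, maxiter=150)
for step in res.steps:
    print(f"{step['phase']:8s} {step['candidate']:15s} dOFV {step['delta_ofv']:7.2f} "
          f"accepted={step['accepted']}")
print(f"retained terms: {res.retained}")
if "cl:ethnicity" in res.retained:
    est = next(t.value for t in res.final_model.fixed.covariate_terms
               if t.covariate == "ethnicity")
    print(f"estimated ethnicity CL/F ratio: {est:.3f} (truth 0.844)\n")

small = dataclasses.replace(
    dtg, random=RandomEffectsSpec(eta_order=("cl", "ruv"), omega2={"cl": 0.0682, "ruv": 0.0})
)
ds = simulate_population(small, PopulationSpec(n_subjects=30, n_intensive=30), seed=12)
bs = bootstrap(ds, small, n_replicates=20, seed=1,
               free=["theta.cl", "omega2.cl", "sigma.prop"], maxiter=100)
print(f"bootstrap ({bs.n_replicates} replicates, "
      f"{100 * bs.fraction_converged:.0f}% converged):")
for k in bs.median:
    print(f"  {k:12s} median {bs.median[k]:.4f} "
          f"[{bs.ci_lower[k]:.4f}, {bs.ci_upper[k]:.4f}]")
print("\nThe forward step clears the 6.63-point threshold and survives the "
      "stricter 10.83-point backward test, mirroring how the published "
      "covariates earned their place in the final models.")
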