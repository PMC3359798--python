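# braincm

Physiological compartment modeling of brain DCE-MRI concentration data.

During a slow intravenous infusion of a Gd-based extracellular contrast
agent, the ¹H spins of water whose longitudinal relaxation the agent has
shortened move between physiological compartments of every image voxel.
`braincm` models this transport in three pools — blood, tissue and
cerebrospinal fluid (CSF) — fits the model parameters to measured
concentration–time curves, and computes a cohort-level statistic of CSF
flow imbalance.  It is aimed at quantitative-MRI researchers who want to
assess blood–brain-barrier (BBB) permeability, compartment volume
fractions, and disturbances of CSF filtration/evacuation (e.g. in
communicating hydrocephalus) from dynamic contrast-enhanced data, and at
methodologists who need a fully synthetic, seed-reproducible test bed
for such pipelines.

## The model

**Blood pool.** Spins enter at a constant concentration rate and are
eliminated first-order, giving the arterial input function

    AIF(t) = c_in · t · exp(−k_out · t)            [mM; t in min]

and a whole-blood concentration `C_BLOOD(t) = (1 − Hct) · AIF(t)`, since
only plasma carries the agent.

**Tissue voxel.** Four compartments — blood, extracellular extravascular
space (EES), intracellular space (IES), and a space not accessible to
water (NOW) — with volume fractions closing to one:
`v_BLOOD + v_EES + v_IES + v_NOW = 1`.  Blood↔EES exchange follows the
Kety–Schmidt rate law

    dC_EES/dt + k_EP·C_EES = k_TRANS·C_BLOOD(t),   C_EES(0) = 0,

EES↔IES exchange is `dC_IES/dt + k_IP·C_IES = k_PI·C_EES(t)`, and the
voxel signal is the volume-weighted mixture
`C_TISSUE = v_BLOOD·C_BLOOD + v_EES·C_EES + v_IES·C_IES` (NOW is
silent).  `k_TRANS = 0` is the signature of an intact BBB.  Both ODEs are
evaluated in closed form (cancellation-free), with an independent
adaptive Runge–Kutta integration as a cross-check oracle.

**CSF voxel.** Two compartments (blood, CSF).  Blood water filters into
the CSF space at overall rate `k_IN′` and evacuates at `k_OUT′`, giving a
CSF input function `CSFIF(t) = k_IN′ · t · exp(−k_OUT′ · t)` of the same
form as the AIF; the voxel mixes as
`v_BLOOD·C_BLOOD + v_CSF·CSFIF`.

**The IOF statistic.** For each CSF space and disease stage
(control / mild / severe), mean fitted rates over subjects are
normalized by the same-region control means and

    IOF = mean(k_IN′)|normalized / mean(k_OUT′)|normalized .

IOF = 1 in the control stage by construction; IOF > 1 means the *input*
(filtration) disturbance predominates, IOF < 1 the *output* (evacuation)
disturbance, with 1/IOF reported alongside in that case.

Fitting is two-stage bounded trust-region least squares with five
deterministic restarts: blood-pool parameters from a blood-ROI curve
first, then tissue/CSF voxel parameters conditional on them.  Volume
closure is structural, never penalized.

## Worked example

Generate a three-stage synthetic cohort whose mild stage has a doubled
CSF filtration rate, fit every subject (blood pool, then CSF voxels),
and compute the IOF table:

```python
import pandas as pd
from braincm import (default_cohort_spec, generate_cohort,
                     fit_blood, fit_csf, compute_iof)

spec = default_cohort_spec(n_per_stage=30, k_in_scale={"mild": 2.0},
                           regions=("aqueduct",))
data = generate_cohort(spec, seed=7)

stage = dict(zip(data.blood_truth["subject"], data.blood_truth["stage"]))
blood = {s: fit_blood(c, hct=0.45).params
         for s, r, c in data.curves if r == "blood"}
rows = [{"subject": s, "region": r, "stage": stage[s],
         "k_in_prime": (fit := fit_csf(c, blood[s])).params.k_in_prime,
         "k_out_prime": fit.params.k_out_prime}
        for s, r, c in data.curves if r != "blood"]
table = compute_iof(pd.DataFrame(rows), control_stage="control")
print(table.to_string(index=False, float_format="%.4g"))
```

Output:

```
  region   stage  normalized_in  normalized_out   iof  iof_reciprocal predominance  n_subjects
aqueduct control              1               1     1             NaN     balanced          30
aqueduct    mild          2.079          0.9642 2.157             NaN        input          30
aqueduct  severe          1.105          0.9585 1.153             NaN        input          30
```

The control stage self-normalizes to IOF = 1 exactly.  The mild stage's
fitted filtration means come out 2.08× control (truth: 2×), so its IOF
of 2.16 flags an input-predominant flow disturbance; at 30 subjects per
stage the estimate carries a few-percent Monte-Carlo error, which
shrinks with cohort size (within 5% of 2.0 at n = 200 in the test
suite).  The same loop runs from the shell:
`braincm simulate`, `braincm fit`, `braincm iof`, and `braincm recover`
(the full generate → fit → IOF loop with a recovery report).

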