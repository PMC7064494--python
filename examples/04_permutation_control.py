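"""Label-permutation over-fitting control.

Shuffling outcome labels destroys any real image->outcome association;
a sound evaluation pipeline must then score at chance. Comparing the
real and permuted cross-validated metrics of the same classifier is
the standard leakage check.
"""
import numpy as np

from blastomorph import (ClassifierSpec, PhantomSpec, cross_validate,
                         generate_cohort, permutation_control)
from blastomorph.feature_pipeline import table_from_phantoms

spec = PhantomSpec(outcome_coeffs={"zp_thickness": 2.0,
                                   "te_texture_sd": 1.5, "age": 1.0})
table = table_from_phantoms(generate_cohort(spec, n=120, seed=9))
cspec = ClassifierSpec("nu_svm", seed=0)

real = cross_validate(table, cspec, k=10, seed=0)
print(f"real labels:     F1 {real.averaged.f1:.3f}  "
      f"AUC {real.averaged.auc:.3f}")

perm = [permutation_control(table, cspec, k=10, seed=0,
                            permutation_seed=s).averaged
        for s in range(5)]
print(f"permuted labels: F1 {np.mean([m.f1 for m in perm]):.3f}  "
      f"AUC {np.mean([m.auc for m in perm]):.3f}  (mean of 5 shuffles)")

print("\nThe permuted scores collapse to ~0.5 while the real ones do not: "
      "the classifier's skill comes from the data, not from leakage.")
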