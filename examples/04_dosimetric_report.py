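"""Full dosimetric comparison of a perturbed plan against the ground truth.

Evaluates DVH metrics (D98/D95/D50/D2/Dmean), conformity and homogeneity
indices per PTV, D1/Dmean/Dmax per OAR, per-structure MAE and 3%/3mm gamma
pass rates — the complete per-case report table.
"""

import numpy as np

from desire import PhantomSpec, generate_phantom
from desire.dosimetry import evaluate_case

case = generate_phantom(PhantomSpec(grid_shape=(32, 48, 48), seed=3))
rng = np.random.default_rng(0)
# stand-in prediction: ground truth plus 1 Gy of smooth-ish noise
pred = case.dose.with_values(case.dose.values
                             + rng.normal(0, 1.0, case.dose.shape))

report = evaluate_case(pred, case.dose, case.structures, case.prescription)
with np.printoptions(precision=3):
    print(report.to_string(index=False, float_format=lambda v: f"{v:8.3f}"))

mae = report[report.metric == "MAE"]
print(f"\nmean per-structure MAE: {mae['diff'].mean():.3f} Gy "
      f"(1 Gy gaussian noise has E|err| = 0.798 Gy)")
gam = report[report.metric == "gamma_pass_rate"]
print(f"gamma pass rates: {dict(zip(gam.structure, gam['pred'].round(3)))}")
# with 1 Gy noise against a 2.1 Gy dose criterion, nearly all voxels pass
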