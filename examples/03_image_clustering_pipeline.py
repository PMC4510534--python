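"""Full pipeline: PNG cohort on disk -> FPCA -> selection -> k-means.

Writes a synthetic two-group cohort to disk as 8-bit PNGs, then runs the
end-to-end pipeline exactly as the CLI would, and prints the evaluation
against the known group labels.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from imgfpc import CohortSpec, RunConfig, generate_cohort, run_pipeline, write_cohort_png

K = 6
m0, m1 = np.zeros(K * K), np.zeros(K * K)
m0[0] = m1[0] = 0.5        # shared brightness keeps pixel values in [0, 1]
m0[2], m1[3] = 0.15, 0.15  # group-specific smooth structure
spec = CohortSpec(
    n_per_group=(15, 15), H=32, W=32, K=K,
    group_mean_coeffs=(m0, m1), score_sds=(0.03, 0.02),
    noise_sd=0.01, seed=5,
)
images, labels = generate_cohort(spec)

with tempfile.TemporaryDirectory() as tmp:
    cohort_dir = Path(tmp) / "cohort"
    paths = write_cohort_png(images, cohort_dir)
    pd.DataFrame(
        {"sample_id": [p.stem for p in paths], "group": labels}
    ).to_csv(cohort_dir / "truth.csv", index=False)

    report = run_pipeline(RunConfig(
        image_dir=str(cohort_dir), basis_K=K, k=2, epsilon=1 / 3, seed=0,
        truth_csv=str(cohort_dir / "truth.csv"),
        output_dir=str(Path(tmp) / "out"),
    ))

for key in ("accuracy", "sensitivity", "specificity",
            "n_features_clustered", "objective"):
    print(f"{key}: {report[key]}")
# Accuracy 1.0: the two smooth group means dominate the leading FPC scores,
# so k-means on a handful of selected score features separates the groups.
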