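"""Simulate the lesion cohort: parcellated brain, unilateral focal lesions,
ground-truth right-frontal substrate, deficit-bearing scores.

Writes masks, the damage matrix, the cohort table and the ground truth into
the run directory and prints the cohort composition.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import driver

run_dir = driver("simulate", __doc__)
cohort = pd.read_csv(run_dir / "cohort.tsv", sep="\t")
pat = cohort[cohort["role"] == "patient"]
print(f"cohort: {len(pat)} patients + {(cohort['role'] == 'control').sum()} controls")
print("group counts:", cohort["group"].value_counts().to_dict())
print(
    "lesion volume (vox): median "
    f"{pat['lesion_volume_vox'].median():.0f}, "
    f"range {pat['lesion_volume_vox'].min()}-{pat['lesion_volume_vox'].max()}"
)
print(
    "substrate load: mean "
    f"{pat['substrate_load'].mean():.3f}, max {pat['substrate_load'].max():.3f}"
)
print(f"score: mean {cohort['score'].mean():.1f}, sd {cohort['score'].std():.1f}")
print(f"artifacts in {run_dir}")
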