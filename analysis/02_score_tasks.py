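"""Administer the item banks to the simulated cohort and score them.

Generates item-level response logs for the analogical-reasoning, deductive-
reasoning and baseline banks, scores percent correct overall and by subtype,
and joins the scores onto the cohort table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import driver

run_dir = driver("score", __doc__)
scored = pd.read_csv(run_dir / "cohort_scored.tsv", sep="\t")
cols = [c for c in scored.columns if c.endswith("_total")]
by_group = scored.groupby("group")[cols].mean().round(2)
print("mean percent correct by group:")
print(by_group.to_string())
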