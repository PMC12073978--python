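"""Age-adjusted group comparisons of the task scores.

Runs the frontal / posterior / healthy-control ANCOVAs with Bonferroni-
corrected post hocs and prints the resulting behavioural table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import driver

run_dir = driver("stats", __doc__)
table = pd.read_csv(run_dir / "behavioural_table.tsv", sep="\t")
print(table.to_string(index=False))
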