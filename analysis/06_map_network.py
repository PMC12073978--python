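"""Backproject edge weights onto parcels, bootstrap the confidence
intervals, apply the retention rule and export the anatomical map.

Prints the retained parcels and, since this is a synthetic run with known
ground truth, the substrate-recovery metrics.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import driver

run_dir = driver("map", __doc__)
nmap = pd.read_csv(run_dir / "network_map.tsv", sep="\t", index_col=0)
retained = nmap[nmap["retained"].fillna(False)]
print(f"retained parcels ({len(retained)}):")
if len(retained):
    print(retained[["deficit_strength", "def_ci_low", "def_ci_high",
                    "perm_ci_high", "community"]].round(3).to_string())
with open(run_dir / "recovery.json") as fh:
    rec = json.load(fh)
print(f"recovery: jaccard {rec['jaccard']:.3f}, "
      f"sensitivity {rec['sensitivity']:.3f}, specificity {rec['specificity']:.3f}")
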