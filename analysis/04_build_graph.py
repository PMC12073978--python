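"""Build the layered lesion-deficit graph and its behaviour-permuted null.

Binarizes the damage matrix, computes healthy-control-anchored deficit
z-scores (age regressed out), and assembles the parcel graph whose edges
carry lesion co-occurrence and deficit weights.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import driver

run_dir = driver("graph", __doc__)
edges = pd.read_csv(run_dir / "graph_test.tsv", sep="\t")
print(f"test graph: {len(edges)} edges, "
      f"{len(set(edges['j']) | set(edges['k']))} connected parcels")
print(f"support: median {edges['support'].median():.0f}, "
      f"max {edges['support'].max()}")
print(f"w_les range: {edges['w_les'].min():.3f}-{edges['w_les'].max():.3f}")
print(f"w_def: mean {edges['w_def'].mean():.2f}, "
      f"95th pct {edges['w_def'].quantile(0.95):.2f}")
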