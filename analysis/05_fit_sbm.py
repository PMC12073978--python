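"""Infer community structure by minimum description length and compare the
test model against the behaviour-permuted null in nats.

Prints the block count, the entropies of both models and the log posterior
odds (delta) with its e-exponent label.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import driver

run_dir = driver("fit", __doc__)
with open(run_dir / "sbm_summary.json") as fh:
    s = json.load(fh)
comp = s["comparison"]
print(f"test model: B = {s['test']['B']}, S = {comp['s_test']:.1f} nats")
print(f"null model: B = {s['null']['B']}, S = {comp['s_null']:.1f} nats")
print(f"delta = {comp['delta']:.1f} nats -> odds {comp['odds_label']} in favour of test")
print(f"merge dendrogram: {s['dendrogram']}")
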