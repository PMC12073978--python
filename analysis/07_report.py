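"""Collate the run artifacts into the summary report."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import driver

run_dir = driver("report", __doc__)
print((run_dir / "report.md").read_text())
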