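"""Shared argument handling for the numbered analysis drivers."""

import argparse
from pathlib import Path

from gldm.config import RunConfig
from gldm.pipeline import run_pipeline


def driver(stage, description):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1, help="master seed")
    ap.add_argument("--out", type=str, default="results/run", help="run directory")
    ap.add_argument("--config", type=str, default=None, help="YAML config")
    args = ap.parse_args()
    cfg = RunConfig.from_yaml(args.config) if args.config else RunConfig()
    cfg.seed = args.seed
    run_dir = run_pipeline(cfg, stages=(stage,), run_dir=args.out)
    return Path(run_dir)
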