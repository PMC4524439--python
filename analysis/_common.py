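"""Shared argument handling for the numbered analysis drivers."""

import argparse
import warnings
from pathlib import Path

from gdmomics.pipeline import PipelineConfig


def setup(description):
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--run-dir", type=Path, default=Path("results/run"))
    ap.add_argument("--n-pairs", type=int, default=10)
    args = ap.parse_args()
    warnings.simplefilter("ignore")
    cfg = PipelineConfig(seed=args.seed, n_pairs=args.n_pairs,
                         n_perm=1000, n_resamples=1000)
    args.run_dir.mkdir(parents=True, exist_ok=True)
    return cfg, args.run_dir
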