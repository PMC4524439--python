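"""Intensities -> quantile-normalized, type-adjusted, filtered betas; probe-
level expression -> background-corrected median-polish gene values."""

from _common import setup
from gdmomics.pipeline import stage_preprocess
from gdmomics._util import read_tsv

cfg, run_dir = setup(__doc__)
stage_preprocess(cfg, run_dir)
rep = read_tsv(run_dir / "filter_report.tsv", index_col=None)
print(rep.to_string(index=False))
expr = read_tsv(run_dir / "expression_genes.tsv")
print(f"gene-level expression: {expr.shape[0]} genes x {expr.shape[1]} samples")
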