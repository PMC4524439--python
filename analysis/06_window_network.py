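"""Permutation Spearman networks and regional summaries in the coordinated
block (the MHC-analog window)."""

from _common import setup
from gdmomics.pipeline import stage_network
from gdmomics._util import read_tsv

cfg, run_dir = setup(__doc__)
stage_network(cfg, run_dir)
me = read_tsv(run_dir / "network_meth_expr.tsv", index_col=None)
ee = read_tsv(run_dir / "network_expr_expr.tsv", index_col=None)
print(f"methylation-expression edges at q<0.05: {len(me)}")
print(f"co-expression edges at q<0.05 (top 100 by |rho|): {len(ee)}")
if len(ee):
    print(f"  dominant co-expression sign: "
          f"{'positive' if (ee.rho > 0).mean() >= 0.5 else 'negative'} "
          f"({(ee.rho > 0).mean():.0%} positive)")
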