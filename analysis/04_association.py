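"""Sitewise EWAS and genewise TWAS with robust-SE Wald tests for GDM."""

from _common import setup
from gdmomics.pipeline import stage_ewas, stage_twas
from gdmomics._util import read_tsv

cfg, run_dir = setup(__doc__)
stage_ewas(cfg, run_dir)
stage_twas(cfg, run_dir)
ewas = read_tsv(run_dir / "ewas.tsv")
twas = read_tsv(run_dir / "twas.tsv")
print(f"EWAS: {int((ewas.p_value < cfg.alpha_meth).sum())} probes at "
      f"alpha={cfg.alpha_meth}; top hit {ewas.p_value.idxmin()} "
      f"(effect {ewas.effect[ewas.p_value.idxmin()]:+.3f})")
print(f"TWAS: {int((twas.p_value < cfg.alpha_expr).sum())} genes at "
      f"alpha={cfg.alpha_expr}; top hit {twas.p_value.idxmin()} "
      f"(effect {twas.effect[twas.p_value.idxmin()]:+.2f} log2)")
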