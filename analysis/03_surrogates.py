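"""Estimate latent batch/ethnicity surrogates from the residualized matrices."""

from _common import setup
from gdmomics.pipeline import stage_surrogates
from gdmomics._util import read_tsv

cfg, run_dir = setup(__doc__)
stage_surrogates(cfg, run_dir)
for tag in ("meth", "expr"):
    rep = read_tsv(run_dir / f"surrogate_report_{tag}.tsv", index_col=None)
    sel = read_tsv(run_dir / f"surrogates_{tag}.tsv")
    best = rep.nsmallest(1, "p_value").iloc[0]
    print(f"{tag}: {sel.shape[1]} surrogate(s) selected; strongest "
          f"association: component {best.component} vs {best.confounder} "
          f"(q={best.q_value:.3g})")
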