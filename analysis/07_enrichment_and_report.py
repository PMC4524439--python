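"""Design-bias-corrected GO enrichment and truth-ledger recovery report."""

from _common import setup
from gdmomics.pipeline import stage_enrich, stage_report
from gdmomics._util import read_tsv

cfg, run_dir = setup(__doc__)
stage_enrich(cfg, run_dir)
summary = stage_report(cfg, run_dir)
for tag in ("meth", "expr"):
    path = run_dir / f"enrichment_{tag}.tsv"
    if path.exists():
        tab = read_tsv(path, index_col=None)
        top = tab.iloc[0]
        print(f"{tag} enrichment: {len(tab)} terms tested; top term "
              f"{top.term_id} (OR {top.odds_ratio:.2f}, p {top.p_value:.3g}, "
              f"q {top.q_value:.3g})")
for rec in summary["recovery"]:
    print(f"recovery[{rec['stage']}]: sensitivity={rec['sensitivity']}, "
          f"fdr={rec['fdr']}")
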