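"""Bump-hunting DMR detection, candidate ranking, and mixed-model
pyrosequencing validation of the top regions."""

from _common import setup
from gdmomics.pipeline import stage_bumps, stage_pyro
from gdmomics._util import read_tsv

cfg, run_dir = setup(__doc__)
stage_bumps(cfg, run_dir)
stage_pyro(cfg, run_dir)
bumps = read_tsv(run_dir / "bumps.tsv", index_col=None)
print(f"{len(bumps)} DMRs above the {cfg.bump_quantile:.0%} |t| threshold")
pyro = read_tsv(run_dir / "pyro_regional.tsv", index_col=None)
for _, r in pyro.iterrows():
    print(f"  region {r.chrom}:{r.start}-{r.end}: regional effect "
          f"{r.coef:+.2f}% (95% CI {r.ci_low:+.2f}, {r.ci_high:+.2f}), "
          f"{r.method}")
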