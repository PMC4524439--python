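"""Generate the synthetic matched GDM study: cohort, 450K-like intensities,
transcriptome probes, term DAG and truth ledger."""

from _common import setup
from gdmomics.pipeline import stage_simulate
from gdmomics._util import read_tsv

cfg, run_dir = setup(__doc__)
stage_simulate(cfg, run_dir)
cov = read_tsv(run_dir / "covariates.tsv")
truth = read_tsv(run_dir / "truth_cpgs.tsv", index_col=None)
print(f"cohort: {len(cov)} samples ({int(cov.gdm.sum())} GDM cases), "
      f"{cov.chip.nunique()} chips")
print(f"injected CpG effects: {len(truth)}; regions: "
      f"{len(read_tsv(run_dir / 'truth_regions.tsv', index_col=None))}")
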