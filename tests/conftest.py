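"""Shared fixtures: one small synthetic study reused across module tests."""

import warnings

import numpy as np
import pytest

from gdmomics import synth


@pytest.fixture(scope="session")
def gene_annot():
    return synth.generate_gene_annotation(n_genes=200, seed=2)


@pytest.fixture(scope="session")
def probe_annot(gene_annot):
    return synth.generate_probe_annotation(gene_annot, n_probes=1200, seed=3)


@pytest.fixture(scope="session")
def cohort20():
    return synth.generate_cohort(20, seed=1)


@pytest.fixture(scope="session")
def meth_study(cohort20, probe_annot):
    """Intensities + truth with injected site/region effects, no batch."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        im, truth = synth.generate_methylation(
            cohort20, probe_annot,
            synth.MethylationEffects(batch_sd=0.0), seed=4)
    return im, truth


@pytest.fixture(scope="session")
def expr_study(cohort20, gene_annot):
    im, truth = synth.generate_expression(
        cohort20, gene_annot,
        synth.ExpressionEffects(probes_per_gene_mean=6.0), seed=5)
    return im, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
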