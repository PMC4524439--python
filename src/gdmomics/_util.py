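"""Shared plumbing: seed derivation, TSV I/O, file hashing."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd


def child_seeds(master_seed: int, labels: list[str]) -> dict[int, int]:
    """Derive one integer seed per named stage from a master seed.

    Uses ``numpy.random.SeedSequence.spawn`` so stages are statistically
    independent and a single stage can be rerun reproducibly without
    regenerating the rest.  Returned seeds are < 2**31.
    """
    ss = np.random.SeedSequence(int(master_seed))
    children = ss.spawn(len(labels))
    return {lab: int(c.generate_state(1)[0] % (2**31)) for lab, c in zip(labels, children)}


def rng_from(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
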