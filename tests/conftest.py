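import numpy as np
import pandas as pd
import pytest

from evoenrich.reference_panel import GenotypePanel


def make_panel(columns, chrom="1", spacing=1000, start=1):
    """Build a small panel from an ordered {id: 0/1 list} mapping; variants
    are placed on one chromosome at fixed spacing."""
    ids = list(columns)
    variants = pd.DataFrame(
        {
            "id": ids,
            "chrom": [chrom] * len(ids),
            "pos": [start + i * spacing for i in range(len(ids))],
        }
    )
    haps = np.column_stack([np.asarray(columns[i], dtype=np.uint8) for i in ids])
    return GenotypePanel(variants, haps)


def random_panel(rng, n_variants, n_haplotypes, chrom="1", spacing=1000):
    """Random polymorphic panel for brute-force comparisons."""
    cols = {}
    i = 0
    while len(cols) < n_variants:
        col = (rng.random(n_haplotypes) < rng.uniform(0.1, 0.9)).astype(np.uint8)
        if 0 < col.sum() < n_haplotypes:
            cols[f"v{i}"] = col
            i += 1
    return make_panel(cols, chrom=chrom, spacing=spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
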