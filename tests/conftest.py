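import numpy as np
import pandas as pd
import pytest

from equidiv.genotypes import GenotypeMatrix, MarkerMap
from equidiv.simulate import PanelSpec, make_panel


def uniform_map(n_chrom: int, n_snp: int, spacing_bp: int = 40_000,
                freq: float | None = 0.3) -> MarkerMap:
    """Deterministic map with exactly uniform inter-SNP spacing."""
    snp_id, chrom, pos = [], [], []
    for c in range(1, n_chrom + 1):
        for k in range(n_snp):
            snp_id.append(f"c{c}s{k}")
            chrom.append(c)
            pos.append((k + 1) * spacing_bp)
    kw = {"freq": [freq] * len(snp_id)} if freq is not None else {}
    return MarkerMap.from_arrays(snp_id, chrom, pos, **kw)


def matrix_from_rows(rows, markers: MarkerMap) -> GenotypeMatrix:
    """GenotypeMatrix from a list of per-sample dosage lists."""
    rows = np.asarray(rows, dtype=np.int8)
    samples = pd.DataFrame(
        {"sample_id": [f"ind{i}" for i in range(rows.shape[0])],
         "sex": pd.NA, "birth_year": pd.NA}
    )
    return GenotypeMatrix(samples, markers, rows)


@pytest.fixture(scope="session")
def small_panel() -> MarkerMap:
    return make_panel(PanelSpec(n_chromosomes=2, snps_per_chromosome=150, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
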