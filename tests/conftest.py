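import numpy as np
import pandas as pd
import pytest

from epimir.io import IntensityMatrix, SampleMeta
from epimir.loci import MirnaLocus, ProbeFeature


@pytest.fixture
def small_locus():
    return MirnaLocus(id="MIRX", chrom="chr1", start=100_000, end=100_080)


def make_matrix(values: np.ndarray, log2: bool = False) -> IntensityMatrix:
    """Wrap a plain (probes x samples) array, samples alternating PrEC/LNCaP."""
    n_probes, n_samples = values.shape
    probes = [
        ProbeFeature(f"p{i}", "MIRX", "chr1", 100_000 + 20 * i, 100_060 + 20 * i)
        for i in range(n_probes)
    ]
    cells = ["PrEC", "LNCaP"]
    samples = [
        SampleMeta(assay="RNA", cell=cells[j % 2], treatment="none",
                   replicate=j // 2 + 1)
        for j in range(n_samples)
    ]
    df = pd.DataFrame(
        values, index=[p.probe_id for p in probes],
        columns=[s.sample_id for s in samples],
    )
    return IntensityMatrix(probes=probes, samples=samples, values=df, log2=log2)
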