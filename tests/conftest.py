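import numpy as np
import pytest

from clonefit.inference import InferenceConfig
from clonefit.io import TimepointObs, Trajectory, VariantAnnotation


def make_trajectory(
    vafs, ages=None, depth=2000, participant="P1", variant="chr1:100:A:G",
    gene="DNMT3A", consequence="missense", recurrent=False,
):
    """Trajectory with alt counts alt = round(depth * vaf)."""
    vafs = np.asarray(vafs, dtype=float)
    if ages is None:
        ages = 70.0 + 3.0 * np.arange(len(vafs))
    ann = VariantAnnotation(gene=gene, protein_change="X1Y", consequence=consequence)
    pts = [
        TimepointObs(age=float(a), depth=int(depth), alt_reads=int(round(depth * v)),
                     unique_alt_reads=int(round(depth * v)))
        for a, v in zip(ages, vafs)
    ]
    t = Trajectory(participant, variant, ann, pts)
    t.recurrent = recurrent
    return t


@pytest.fixture(scope="session")
def coarse_config():
    return InferenceConfig.coarse()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
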