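import numpy as np
import pytest

from kmercn.indexer import ControlRegions, IndexerConfig, KmerCatalog, build_catalog
from kmercn.simulate import implant_duplication, make_reference


@pytest.fixture(scope="session")
def toy_genome():
    """12 kb random genome with one 4%-diverged duplication implanted."""
    base = make_reference(12_000, 0.5, seed=11)
    seq, report = implant_duplication(base, (2_000, 3_000), 8_000, divergence=0.04, seed=12)
    return {"chr1": seq}, report


@pytest.fixture(scope="session")
def toy_catalog(toy_genome):
    seqs, _ = toy_genome
    control = ControlRegions.from_intervals([("chr1", 0, len(seqs["chr1"]))])
    config = IndexerConfig(k=30, edit_distance=2, max_near=100)
    return build_catalog(seqs, control, config)


def manual_catalog(
    starts,
    gc,
    is_control=None,
    k=30,
    chrom_len=1_000_000,
    **params,
) -> KmerCatalog:
    """Hand-built catalog for estimator tests (values are synthetic but distinct)."""
    n = len(starts)
    if is_control is None:
        is_control = np.ones(n, dtype=bool)
    defaults = dict(edit_distance=2, max_near=100, gc_window_bp=400)
    defaults.update(params)
    return KmerCatalog(
        k=k,
        sequences=[("chr1", chrom_len)],
        chrom_id=np.zeros(n, dtype=np.uint32),
        start=np.asarray(starts, dtype=np.int64),
        value=np.arange(n, dtype=np.uint64),
        is_control=np.asarray(is_control, dtype=bool),
        gc_fraction=np.asarray(gc, dtype=np.float64),
        **defaults,
    )
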