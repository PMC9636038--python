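import numpy as np
import pandas as pd
import pytest

from clonechron import ccf_engine, dirichlet_clustering, sim_evolution
from clonechron.variant_io import CopyNumberSegment, SampleCounts, SampleMeta, VariantRecord


@pytest.fixture
def diploid_segment():
    return CopyNumberSegment("S1", "chr2", 1, 10_000_000, 1, 1)


@pytest.fixture
def gain_segment():
    return CopyNumberSegment("S1", "chr1", 1, 10_000_000, 2, 1)


@pytest.fixture
def loh_segment():
    return CopyNumberSegment("S1", "chr1", 10_000_001, 20_000_000, 2, 0)


def make_variant(chrom="chr2", pos=500, ref="A", alt="T", sample="S1",
                 depth=100, alt_reads=40, context=None):
    return VariantRecord(chrom, pos, ref, alt,
                         {sample: SampleCounts(depth=depth, alt_reads=alt_reads)},
                         context)


@pytest.fixture(scope="session")
def two_cluster_annotations():
    """Single-region annotations with truth clusters at CCF 1.0 and 0.2
    (120 mutations each, depth 100, purity 1, diploid)."""
    return synthetic_annotations([(1.0,)] * 120 + [(0.2,)] * 120, depth=100, seed=7)


def synthetic_annotations(ccfs_per_mutation, depth=100, purity=1.0, seed=0):
    """Directly build a diploid annotation table from per-mutation CCF vectors."""
    rng = np.random.default_rng(seed)
    rows = []
    n_samples = len(ccfs_per_mutation[0])
    for i, ccfs in enumerate(ccfs_per_mutation):
        for s, ccf in enumerate(ccfs):
            xi = ccf * ccf_engine.expected_vaf(1, 2, purity)
            d = int(depth)
            a = int(rng.binomial(d, xi))
            rows.append(
                {
                    "mutation_id": f"m{i}",
                    "sample": f"S{s + 1}",
                    "depth": d,
                    "alt_reads": a,
                    "purity": purity,
                    "vaf": a / d,
                    "adjusted_vaf": a / d / purity,
                    "cn_class": "diploid",
                    "multiplicity": 1,
                    "total_cn": 2,
                    "ccf": 2 * a / d / purity,
                    "excluded": False,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def five_region_run():
    """Simulated five-region tumor, annotated and clustered (shared across
    the topology and recovery tests because the sampler run is the
    expensive step)."""
    cfg = sim_evolution.SimConfig(
        seed=11, n_regions=5, clone_spec=sim_evolution.five_region_spec(),
        purity_per_region=(0.81,) * 5,
    )
    sim = sim_evolution.simulate_tumor(cfg)
    ann = ccf_engine.annotate(sim.variants, sim.segments, sim.meta)
    result = dirichlet_clustering.cluster_mutations(
        ann,
        dirichlet_clustering.ClusteringConfig(
            n_iter=900, burn_in=300, max_clusters=15, seed=2
        ),
    )
    return sim, ann, result
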