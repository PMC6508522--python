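import numpy as np
import pandas as pd
import pytest

from nightcontrast.simulate import SimConfig
from nightcontrast.variants import PileupSite, VariantCall


@pytest.fixture
def tiny_config():
    return SimConfig(seed=7, n_genes=30, gene_length_range=(300, 500), n_metabolites=30)


@pytest.fixture
def clean_config():
    """All artifact channels off; SNP signal only."""
    return SimConfig(
        seed=11,
        n_genes=200,
        snp_rate=1e-3,
        het_artifact_rate=0.0,
        lowfrac_artifact_rate=0.0,
        refdisc_artifact_rate=0.0,
        cluster_artifact_rate=0.0,
    )


def make_site(seq_id="t1", pos=10, ref="A", a1=None, a2=None, mapq=60):
    return PileupSite(seq_id, pos, ref, a1 or {}, a2 or {}, mapq)


def make_call(ref="A", alt="G", a1=(0, 0, 0, 0), a2=(0, 0, 0, 0), seq_id="t1", pos=10):
    c1, c2 = np.asarray(a1), np.asarray(a2)
    d1, d2 = int(c1.sum()), int(c2.sum())
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    alt_reads = int(c1[base_index[alt]] + c2[base_index[alt]])
    return VariantCall(
        seq_id=seq_id,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        depth_a1=d1,
        depth_a2=d2,
        alt_fraction=alt_reads / (d1 + d2) if d1 + d2 else 0.0,
        quality=100.0,
        counts_a1=tuple(int(x) for x in a1),
        counts_a2=tuple(int(x) for x in a2),
    )


def metab_frame(rows):
    """rows: (metabolite, cls, experiment, genotype, values)."""
    records = []
    for met, cls, experiment, genotype, values in rows:
        for i, v in enumerate(values, start=1):
            records.append((met, cls, experiment, genotype, i, float(v)))
    return pd.DataFrame(
        records,
        columns=["metabolite", "class", "experiment", "genotype", "replicate", "value"],
    )
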