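import numpy as np
import pandas as pd
import pytest

from replicore import GeneOrderMap, MappedReadTable


@pytest.fixture
def toy_gene_order() -> GeneOrderMap:
    """Three 900-bp genes on a 3000-bp circular genome."""
    genes = pd.DataFrame({
        "gene_id": ["g1", "g2", "g3"],
        "start": [0, 1000, 2000],
        "end": [900, 1900, 2900],
    })
    return GeneOrderMap(reference_id="toy", genome_length=3000, genes=genes)


@pytest.fixture
def toy_reads() -> MappedReadTable:
    records = pd.DataFrame({
        "gene_id": ["g1", "g1", "g2", "g3", "g3"],
        "read_length": [150, 300, 150, 150, 150],
    })
    return MappedReadTable(sample_id="s1", records=records)


def make_read_table(gene_ids, read_lengths, sample_id="s1", **kw) -> MappedReadTable:
    records = pd.DataFrame({
        "gene_id": list(gene_ids),
        "read_length": list(read_lengths),
    })
    return MappedReadTable(sample_id=sample_id, records=records, **kw)
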