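import numpy as np
import pytest

from melibiome.otu_table import OtuTable, TaxonomyLineage


def make_table(counts, sample_ids=None, otu_ids=None, lineages=None) -> OtuTable:
    counts = np.asarray(counts)
    n, k = counts.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    otu_ids = otu_ids or [f"otu{j}" for j in range(k)]
    if lineages is None:
        lineages = [
            f"k__Bacteria; p__Proteobacteria; c__Gammaproteobacteria; g__Taxon{j}"
            for j in range(k)
        ]
    taxonomy = [TaxonomyLineage.parse(s) for s in lineages]
    return OtuTable(counts=counts, sample_ids=sample_ids, otu_ids=otu_ids, taxonomy=taxonomy)


@pytest.fixture
def small_table() -> OtuTable:
    return make_table(
        [[5, 5, 0, 0], [2, 2, 3, 3], [10, 0, 0, 10]],
        sample_ids=["a", "b", "c"],
    )
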