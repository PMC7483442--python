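import pandas as pd
import pytest

from dwarfmap import splice_effect


@pytest.fixture(scope="session")
def example_gene():
    """The bundled two-exon gene model and its acceptor-disrupting SNP."""
    return splice_effect.build_example_gene()


@pytest.fixture()
def site_row():
    """Single-site SiteCounts builder."""
    def make(n_ref_D, n_alt_D, n_ref_V, n_alt_V, chrom="chr9", pos=1, kind="SNP"):
        return pd.DataFrame([{
            "chrom": chrom, "pos": pos,
            "n_ref_D": n_ref_D, "n_alt_D": n_alt_D,
            "n_ref_V": n_ref_V, "n_alt_V": n_alt_V,
            "variant_kind": kind,
        }])
    return make
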