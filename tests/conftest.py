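"""Shared fixtures: small enzyme catalogs built in memory."""

import pytest

from rflpkit.rebase_io import generate_fixture, make_record


@pytest.fixture(scope="session")
def anchor_catalog():
    """Two-enzyme catalog: TspGWI (ACGGA) and BspGI (CTGGAC)."""
    return list(generate_fixture(2, seed=0).records)


@pytest.fixture(scope="session")
def snp_catalog():
    """Catalog for the CTGG[A/G]CCC worked example: BspGI plus three
    degenerate-pattern enzymes whose sites span the variant position
    and discriminate the A allele (synthetic Zdg* names)."""
    return [
        make_record("TspGWI", "ACGGA(11/9)", suppliers="Q", index=0),
        make_record("BspGI", "CTGGAC", suppliers="I", index=1),
        make_record("ZdgAI", "TGGAYC", suppliers="N", index=2),
        make_record("ZdgBI", "GGACCY", index=3),
        make_record("ZdgCI", "CTGGAY", suppliers="BN", index=4),
    ]
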