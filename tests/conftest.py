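import pytest

import radscav as rs


@pytest.fixture(scope="session")
def refs():
    """Bundled default reference enthalpies (per-phase dict)."""
    return rs.default_reference_enthalpies()


@pytest.fixture(scope="session")
def table1():
    """Verbatim transcription of the published descriptor table."""
    return rs.load_table1()


@pytest.fixture()
def pt_species(refs):
    """Synthetic species set realising the published Pt-3-O-glc gas-phase block
    (BDE/IP/PA targets; PDE and ETE follow from the Hess identities)."""
    rows = [
        rs.TargetRow("Pt-3-O-glc", "3'-OH", "gas", bde=94.6, ip=239.6, pa=278.0),
        rs.TargetRow("Pt-3-O-glc", "4'-OH", "gas", bde=86.2, ip=239.6, pa=251.7),
        rs.TargetRow("Pt-3-O-glc", "5-OH", "gas", bde=94.0, ip=239.6, pa=247.7),
        rs.TargetRow("Pt-3-O-glc", "7-OH", "gas", bde=96.7, ip=239.6, pa=247.3),
    ]
    return rs.make_species_set(rs.DescriptorTargets(rows=rows, refs=refs))
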