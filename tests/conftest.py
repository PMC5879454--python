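import pytest

from focuspharm.io_tables import CompoundRecord
from focuspharm.synthdata import load_mzrw_fixtures


@pytest.fixture(scope="session")
def mzrw():
    """Packaged MZRW worked-example fixtures (parsed once per session)."""
    return load_mzrw_fixtures()


@pytest.fixture(scope="session")
def mzrw_members(mzrw):
    """Compound records annotated as component-group members."""
    member_ids = {c for cs in mzrw.group_members.values() for c in cs}
    return [r for r in mzrw.compounds if r.compound_id in member_ids]


def make_record(cid="c1", smiles="CCO", herb="DH", extract=True, plasma=False,
                feces=False, rank=None, available=None, pharm=None):
    return CompoundRecord(
        compound_id=cid, name=cid, smiles=smiles, herb=herb,
        in_extract=extract, in_plasma=plasma, in_feces=feces,
        abundance_rank=rank, available=available, pharmacology_use=pharm,
    )
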