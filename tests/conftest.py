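import pytest

from odb.msa import Alignment, progressive_align
from odb.seqdb import Database, SeqType
from odb.synthfix import FamilySpec, simulate_family


@pytest.fixture(scope="session")
def family():
    """Default 4-species x 2-paralog simulated family with 3 decoys."""
    return simulate_family(FamilySpec(seed=42, n_decoys=3))


@pytest.fixture(scope="session")
def family_db(family) -> Database:
    return family.as_database()


@pytest.fixture(scope="session")
def family_nt_alignment(family) -> Alignment:
    # no indels are simulated, so the raw CDSs are already aligned
    rows = [(mid, family.members[mid]) for mid in sorted(family.members)]
    return Alignment(rows=rows, kind="nucleotide")


@pytest.fixture(scope="session")
def family_protein_alignment(family_db):
    prots = sorted(
        (
            r
            for r in family_db.records.values()
            if r.seq_type is SeqType.PROTEIN and r.species != "decoy"
        ),
        key=lambda r: r.internal_id,
    )
    return progressive_align(prots, "protein")


@pytest.fixture(scope="session")
def family_cds_by_internal_id(family_db):
    out = {}
    for rec in family_db.records.values():
        if rec.seq_type is not SeqType.CDS or rec.species == "decoy":
            continue
        prot_id = family_db._internal_id(rec.species, SeqType.PROTEIN, rec.original_id)
        out[prot_id] = rec.sequence
    return out
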