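"""Shared synthetic fixtures covering the archive's numbering pathologies."""

import pytest

from unirenum.fixtures import ChainSpec, FixtureSpec, LigandSpec, make_fixture


@pytest.fixture
def fx_offset16():
    """Chain whose author numbering trails UniProt by 16 (author 18,19,20
    correspond to UniProt 2,3,4) with an unobserved 3-residue tag and a
    zinc ligand."""
    spec = FixtureSpec(pdb_id="9aa3", chains=(
        ChainSpec(label_chain="A", auth_chain="A", length=12,
                  numbering="offset", accession="Q9PRK9",
                  uniprot_start=2, offset=-16, tag_length=3,
                  tag_observed=False),
    ), ligands=(LigandSpec("ZN", 5, "A"),))
    return make_fixture(spec, seed=11)


@pytest.fixture
def fx_signal_peptide():
    """Mature-protein numbering: a 30-residue signal peptide was cleaved, so
    author numbers run 30 below UniProt (author 1123 is UniProt 1153)."""
    spec = FixtureSpec(pdb_id="9d94", chains=(
        ChainSpec(label_chain="A", auth_chain="A", length=15,
                  numbering="signal_peptide", accession="P08069",
                  uniprot_start=1150, offset=30),
    ))
    return make_fixture(spec, seed=12)


@pytest.fixture
def fx_negative_tag():
    """His tag numbered with negative author numbers (observed)."""
    spec = FixtureSpec(pdb_id="9d5t", chains=(
        ChainSpec(label_chain="A", auth_chain="A", length=10,
                  numbering="negative_tag", accession="P11111",
                  tag_length=3, tag_observed=True),
    ))
    return make_fixture(spec, seed=13)


@pytest.fixture
def fx_insertion_codes():
    """Antibody-style numbering with insertion codes at three positions."""
    spec = FixtureSpec(pdb_id="9ins", chains=(
        ChainSpec(label_chain="D", auth_chain="D", length=12,
                  numbering="insertion_codes", accession="P22222",
                  insertion_positions=(4, 5, 9)),
    ))
    return make_fixture(spec, seed=14)


@pytest.fixture
def fx_chimera_overlap():
    """Chimeric chain: two accessions with overlapping UniProt ranges,
    lengths 80 and 20; only the longer accession renumbers."""
    spec = FixtureSpec(pdb_id="9chi", chains=(
        ChainSpec(label_chain="A", auth_chain="A", length=100,
                  numbering="chimera", accession="P10000",
                  chimera=("P20000", 20, True)),
    ))
    return make_fixture(spec, seed=15)


@pytest.fixture
def fx_chimera_disjoint():
    """Chimeric chain whose two accessions have non-overlapping ranges; both
    segments keep their own UniProt numbering (flag '+')."""
    spec = FixtureSpec(pdb_id="9chj", chains=(
        ChainSpec(label_chain="A", auth_chain="A", length=60,
                  numbering="chimera", accession="P10000",
                  chimera=("P20000", 25, False)),
    ))
    return make_fixture(spec, seed=16)


@pytest.fixture
def fx_identity():
    """Author numbering already equals UniProt numbering."""
    spec = FixtureSpec(pdb_id="9idn", chains=(
        ChainSpec(label_chain="A", auth_chain="A", length=20,
                  numbering="identity", accession="P33333"),
    ))
    return make_fixture(spec, seed=17)


@pytest.fixture
def fx_no_uniprot():
    """One mapped chain, one chain with no UniProt content (left as is)."""
    spec = FixtureSpec(pdb_id="9nou", chains=(
        ChainSpec(label_chain="A", auth_chain="A", length=8,
                  numbering="offset", accession="P44444", offset=-7),
        ChainSpec(label_chain="B", auth_chain="B", length=6,
                  numbering="no_uniprot"),
    ))
    return make_fixture(spec, seed=18)


@pytest.fixture
def fx_ligand_reassign():
    """150-residue identity chain (numbers below 200) with one ligand, for
    the reverse-order non-polymer reassignment."""
    spec = FixtureSpec(pdb_id="9t6a", chains=(
        ChainSpec(label_chain="A", auth_chain="A", length=150,
                  numbering="identity", accession="P55555"),
    ), ligands=(LigandSpec("HEM", 201, "A"),))
    return make_fixture(spec, seed=19)
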