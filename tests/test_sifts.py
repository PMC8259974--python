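"""SIFTS parsing, accession resolution, and numbering-plan unit tests."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from unirenum.fixtures import ChainSpec, FixtureSpec, make_fixture
from unirenum.model import (
    DEFAULT_CHAPERONE_IDS,
    NumberingCollisionError,
    OffsetConfig,
    ResidueRecord,
    SiftsParseError,
    legacy_key,
)
from unirenum.sifts import (
    assign_target_numbers,
    build_replacement_map,
    parse_sifts,
    resolve_chain_accession,
)


def rec(chain="A", seq=1, name="ALA", auth=None, ins="", acc=None, uni=None,
        mut=False):
    return ResidueRecord(pdb_chain_id=chain, auth_chain_id=chain,
                         seq_res_num=seq, res_name=name, auth_res_num=auth,
                         ins_code=ins, accession=acc, uniprot_res_num=uni,
                         uniprot_res_name="A" if acc else None,
                         is_mutation=mut)


class TestParseSifts:
    def test_unobserved_tag_has_no_author_number_and_no_accession(self, fx_offset16):
        records = parse_sifts(fx_offset16.sifts_xml.encode(), "9aa3")
        tag = [r for r in records if r.seq_res_num <= 3]
        assert len(tag) == 3
        assert all(r.auth_res_num is None and r.accession is None for r in tag)

    def test_zero_protein_chains_yield_empty_collection(self):
        xml = b'<?xml version="1.0"?><entry><entity type="ligand" entityId="X"/></entry>'
        assert parse_sifts(xml, "0xxx") == []

    def test_partial_uniprot_coverage_counts(self):
        """5-residue chain with 3 UniProt rows: 5 records, 3 with accession."""
        spec = FixtureSpec(pdb_id="9cov", chains=(
            ChainSpec(label_chain="A", auth_chain="A", length=5,
                      numbering="identity", accession="P99999",
                      tag_length=2, tag_observed=True),
        ))
        records = parse_sifts(make_fixture(spec, seed=3).sifts_xml.encode())
        assert len(records) == 5
        assert sum(r.accession is not None for r in records) == 3

    def test_negative_author_numbers_parse_signed(self, fx_negative_tag):
        records = parse_sifts(fx_negative_tag.sifts_xml.encode())
        tag_nums = [r.auth_res_num for r in records if r.accession is None]
        assert tag_nums == [-2, -1, 0]

    def test_insertion_codes_split_from_author_number(self, fx_insertion_codes):
        records = parse_sifts(fx_insertion_codes.sifts_xml.encode())
        with_ins = [r for r in records if r.ins_code]
        assert len(with_ins) == 3
        assert all(r.ins_code in "AB" for r in with_ins)

    def test_mutation_annotation_sets_flag(self):
        spec = FixtureSpec(pdb_id="9mut", chains=(
            ChainSpec(label_chain="A", auth_chain="A", length=6,
                      numbering="identity", accession="P12121",
                      mutation_positions=(2, 4)),
        ))
        records = parse_sifts(make_fixture(spec, seed=4).sifts_xml.encode())
        assert [r.seq_res_num for r in records if r.is_mutation] == [2, 4]

    def test_malformed_xml_names_the_entry(self):
        with pytest.raises(SiftsParseError, match="9bad"):
            parse_sifts(b"<entry><unclosed>", "9bad")

    def test_round_trip_matches_generator_ground_truth(self, fx_offset16):
        records = parse_sifts(fx_offset16.sifts_xml.encode(), "9aa3")
        assert records == fx_offset16.records()


class TestRecordInvariants:
    def test_accession_requires_uniprot_number(self):
        with pytest.raises(ValueError):
            rec(acc="P1", uni=None)

    def test_invalid_insertion_code_rejected(self):
        with pytest.raises(ValueError):
            rec(auth=5, ins="ab")

    def test_offsets_must_be_positive(self):
        with pytest.raises(ValueError):
            OffsetConfig(mmcif_offset=0)

    def test_exception_list_from_plain_text(self, tmp_path):
        from unirenum.sifts import load_exception_list

        path = tmp_path / "chaperones.txt"
        path.write_text("GFP_AEQVI\n# comment\nMALE_ECOLI  # trailing\n\n")
        assert load_exception_list(path) == {"GFP_AEQVI", "MALE_ECOLI"}


def brute_force_resolve(records, exceptions=frozenset(), names=None):
    """Independent literal resolver: per chain, enumerate accession pairs,
    test interval overlap on explicit number sets, then apply the
    longest/exception rule by exhaustive sorting."""
    names = names or {}
    result = {}
    chains = sorted({r.auth_chain_id for r in records})
    for chain in chains:
        rows = [r for r in records if r.auth_chain_id == chain
                and r.accession is not None]
        accs = sorted({r.accession for r in rows})
        if not accs:
            result[chain] = ((), "")
            continue
        if len(accs) == 1:
            result[chain] = (tuple(accs), "")
            continue
        numbers = {a: {r.uniprot_res_num for r in rows if r.accession == a}
                   for a in accs}
        clash = False
        for a, b in itertools.combinations(accs, 2):
            lo = max(min(numbers[a]), min(numbers[b]))
            hi = min(max(numbers[a]), max(numbers[b]))
            if lo <= hi:
                clash = True
        if not clash:
            result[chain] = (tuple(accs), "+")
            continue
        ranked = sorted(accs, key=lambda a: (-len(numbers[a]), a))
        survivors = [a for a in ranked
                     if a not in exceptions and names.get(a) not in exceptions]
        winner = (survivors or ranked)[0]
        result[chain] = ((winner,), "*")
    return result


class TestResolveChainAccession:
    def test_longest_accession_wins_on_overlap(self):
        records = ([rec(seq=i, acc="PLONG", uni=i) for i in range(1, 121)]
                   + [rec(seq=120 + i, acc="PSHRT", uni=i) for i in range(1, 41)])
        cm = resolve_chain_accession(records)
        assert cm["A"].accessions == ("PLONG",)
        assert cm["A"].flag == "*"

    def test_single_accession_no_flag(self):
        cm = resolve_chain_accession([rec(seq=i, acc="P1", uni=i)
                                      for i in range(1, 6)])
        assert cm["A"].accessions == ("P1",)
        assert cm["A"].flag == ""

    def test_chaperone_exception_defers_to_shorter_partner(self):
        names = {"P42212": "GFP_AEQVI"}
        records = ([rec(seq=i, acc="P42212", uni=i) for i in range(1, 121)]
                   + [rec(seq=120 + i, acc="PTARG", uni=i) for i in range(1, 41)])
        cm = resolve_chain_accession(records, DEFAULT_CHAPERONE_IDS, names)
        assert cm["A"].accessions == ("PTARG",)
        assert cm["A"].flag == "*"
        oracle = brute_force_resolve(records, DEFAULT_CHAPERONE_IDS, names)
        assert oracle["A"][0] == ("PTARG",)

    def test_disjoint_ranges_keep_all_accessions(self):
        records = ([rec(seq=i, acc="P1", uni=i) for i in range(1, 31)]
                   + [rec(seq=30 + i, acc="P2", uni=500 + i) for i in range(1, 21)])
        cm = resolve_chain_accession(records)
        assert cm["A"].accessions == ("P1", "P2")
        assert cm["A"].flag == "+"

    def test_unmapped_chain_resolves_to_none(self):
        cm = resolve_chain_accession([rec(seq=i, auth=i) for i in range(1, 4)])
        assert cm["A"].accessions == ()

    def test_coverage_tie_broken_lexicographically(self):
        records = ([rec(seq=i, acc="PBBB", uni=i) for i in range(1, 11)]
                   + [rec(seq=10 + i, acc="PAAA", uni=i) for i in range(1, 11)])
        cm = resolve_chain_accession(records)
        assert cm["A"].accessions == ("PAAA",)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle_on_small_chains(self, data):
        """On chains of <= 50 residues split over 1-3 accessions, resolution
        equals an exhaustive literal application of the rule."""
        n_acc = data.draw(st.integers(1, 3))
        accs = [f"P{i:05d}" for i in range(n_acc)]
        records = []
        seq = 0
        for i, acc in enumerate(accs):
            length = data.draw(st.integers(1, 16))
            start = data.draw(st.integers(1, 60))
            for j in range(length):
                seq += 1
                records.append(rec(seq=seq, auth=seq, acc=acc, uni=start + j))
        try:
            cm = resolve_chain_accession(records)
        except Exception:
            pytest.skip("degenerate random draw")
        oracle = brute_force_resolve(records)
        assert cm["A"].accessions == oracle["A"][0]
        assert cm["A"].flag == oracle["A"][1]


class TestAssignTargetNumbers:
    def test_author_18_maps_to_uniprot_2(self, fx_offset16):
        records = parse_sifts(fx_offset16.sifts_xml.encode())
        cm = resolve_chain_accession(records)
        plan = assign_target_numbers(records, cm, fmt="mmcif")
        by_auth = {e.auth_res_num: e for e in plan.entries}
        assert by_auth[18].new_number == 2
        assert by_auth[18].source == "uniprot"

    def test_tag_residue_gets_50000_plus_seq(self, fx_offset16):
        records = parse_sifts(fx_offset16.sifts_xml.encode())
        cm = resolve_chain_accession(records)
        plan = assign_target_numbers(records, cm, fmt="mmcif")
        offsets = {e.seq_res_num: e for e in plan.entries if e.source == "offset"}
        assert offsets[1].new_number == 50001

    def test_identity_numbering_is_fixed_point(self, fx_identity):
        records = parse_sifts(fx_identity.sifts_xml.encode())
        cm = resolve_chain_accession(records)
        plan = assign_target_numbers(records, cm, fmt="mmcif")
        assert all(e.new_number == e.auth_res_num for e in plan.entries)
        assert plan.chain_stats["A"].count_changed == 0

    def test_unmapped_chain_excluded_from_plan(self, fx_no_uniprot):
        records = parse_sifts(fx_no_uniprot.sifts_xml.encode())
        cm = resolve_chain_accession(records)
        plan = assign_target_numbers(records, cm, fmt="mmcif")
        assert plan.chains() == ["A"]

    def test_uniprot_number_at_offset_raises_collision(self):
        records = [rec(seq=1, auth=1, acc="P1", uni=5001)]
        cm = resolve_chain_accession(records)
        with pytest.raises(NumberingCollisionError):
            assign_target_numbers(records, cm, OffsetConfig(), "legacy")

    def test_mutated_residue_keeps_structure_name_and_uniprot_number(self):
        records = [rec(seq=1, auth=10, name="TRP", acc="P1", uni=7, mut=True)]
        cm = resolve_chain_accession(records)
        plan = assign_target_numbers(records, cm, fmt="mmcif")
        entry = plan.entries[0]
        assert (entry.new_number, entry.res_name) == (7, "TRP")

    def test_per_chain_counts(self, fx_offset16):
        records = parse_sifts(fx_offset16.sifts_xml.encode())
        cm = resolve_chain_accession(records)
        plan = assign_target_numbers(records, cm, fmt="mmcif")
        stats = plan.chain_stats["A"]
        assert (stats.chain_len, stats.uni_len) == (12, 9)
        assert (stats.count_renumbered, stats.count_offset) == (9, 3)


@st.composite
def chain_specs(draw):
    numbering = draw(st.sampled_from(
        ["identity", "offset", "signal_peptide", "negative_tag",
         "insertion_codes"]))
    length = draw(st.integers(4, 40))
    kwargs = dict(length=length, accession="P00042",
                  uniprot_start=draw(st.integers(1, 300)))
    if numbering in ("offset", "signal_peptide"):
        kwargs["offset"] = draw(st.integers(-200, 200))
    if numbering == "negative_tag":
        kwargs["tag_length"] = draw(st.integers(1, min(3, length - 1)))
        kwargs["tag_observed"] = True
    if numbering == "insertion_codes":
        kwargs["insertion_positions"] = tuple(sorted(draw(
            st.sets(st.integers(2, length), max_size=3))))
    return ChainSpec(numbering=numbering, **kwargs)


class TestPlanProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(spec=chain_specs(), seed=st.integers(0, 10))
    def test_injectivity_and_range_separation(self, spec, seed):
        """For every generated chain the author->new mapping is injective
        and all UniProt-derived numbers lie below all offset-derived ones."""
        triple = make_fixture(FixtureSpec(chains=(spec,)), seed=seed)
        records = parse_sifts(triple.sifts_xml.encode())
        cm = resolve_chain_accession(records)
        for fmt in ("mmcif", "legacy"):
            plan = assign_target_numbers(records, cm, fmt=fmt)
            plan.validate()  # injectivity + separation assertions
            new_keys = {(e.new_number, e.ins_code) for e in plan.entries}
            assert len(new_keys) == len(plan.entries)
            uni = [e.new_number for e in plan.entries if e.source == "uniprot"]
            off = [e.new_number for e in plan.entries if e.source == "offset"]
            if uni and off:
                assert max(uni) < min(off)


class TestBuildReplacementMap:
    def test_legacy_key_widths(self):
        assert legacy_key(100, "", "ALA", "A") == " 100 ALAA"
        assert len(legacy_key(100, "", "ALA", "A")) == 9

    def test_insertion_code_sits_in_fifth_column(self):
        key = legacy_key(100, "A", "ALA", "A")
        assert key == " 100AALAA"
        assert key[4] == "A"

    def test_negative_number_key(self):
        assert legacy_key(-2, "", "HIS", "B") == "  -2 HISB"

    def test_empty_plan_gives_empty_map(self):
        from unirenum.model import RenumberPlan
        rmap = build_replacement_map(RenumberPlan(fmt="mmcif"))
        assert len(rmap) == 0

    def test_legacy_pairs_render_values_at_identical_width(self, fx_offset16):
        records = parse_sifts(fx_offset16.sifts_xml.encode())
        cm = resolve_chain_accession(records)
        plan = assign_target_numbers(records, cm, fmt="legacy")
        pairs = build_replacement_map(plan).legacy_pairs()
        assert pairs and all(len(k) == 9 and len(v) == 9
                             for k, v in pairs.items())

    def test_out_of_range_legacy_chain_dropped(self):
        """A chain whose offset-derived numbers exceed 9999 cannot be
        represented in 4 columns and is excluded with a warning."""
        offsets = OffsetConfig(legacy_offset=9900)
        records = ([rec(seq=i, auth=i, acc="P1", uni=i) for i in range(1, 101)]
                   + [rec(seq=i, auth=i) for i in range(101, 121)])
        cm = resolve_chain_accession(records)
        plan = assign_target_numbers(records, cm, offsets, "legacy")
        rmap = build_replacement_map(plan, offsets)
        assert rmap.dropped_chains == ["A"]
        assert len(rmap.by_author) == 0
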