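"""Hit filtering, CDCP identification, and strain-state classification."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domarch import profiles as prof
from domarch.profiles import (
    COMPETENCE,
    DUF4131,
    LACTAMASE_B,
    DomainHit,
    NucleotideHit,
    ProteinProfile,
    classify_protein,
    filter_domain_hits,
    rescue_filter,
    strain_state,
)


def make_hit(evalue=1e-10, model_start=1, model_end=100, model_length=100,
             accession=COMPETENCE, protein="s1|P1", env_start=1, env_end=100,
             length=500):
    return DomainHit(
        protein_id=protein, proteome_id=protein.split("|")[0],
        domain_accession=accession, domain_name="dom", evalue=evalue,
        model_start=model_start, model_end=model_end, model_length=model_length,
        env_start=env_start, env_end=env_end, protein_length=length,
    )


class TestFilter:
    def test_boundary_hit_retained(self):
        # coverage exactly 0.70 and e-value exactly 1e-5 are both kept
        hit = make_hit(evalue=1e-6, model_start=1, model_end=70, model_length=100)
        assert filter_domain_hits([hit]) == [hit]
        hit = make_hit(evalue=1e-5, model_start=1, model_end=70, model_length=100)
        assert filter_domain_hits([hit]) == [hit]

    def test_evalue_above_threshold_removed(self):
        hit = make_hit(evalue=2e-5, model_start=1, model_end=100, model_length=100)
        assert filter_domain_hits([hit]) == []

    def test_six_case_threshold_grid(self):
        # coverages {0.69, 0.70, 0.71} x e-values {1e-5, 1.0001e-5}: only the
        # two passing-coverage/passing-evalue combinations survive
        hits = [
            make_hit(evalue=e, model_start=1, model_end=int(cov * 100),
                     model_length=100)
            for cov in (0.69, 0.70, 0.71)
            for e in (1e-5, 1.0001e-5)
        ]
        kept = filter_domain_hits(hits)
        assert len(kept) == 2
        assert all(h.evalue == 1e-5 and h.model_coverage >= 0.70 for h in kept)

    def test_idempotent_and_order_preserving(self):
        hits = [make_hit(evalue=1e-7, env_start=50), make_hit(evalue=1e-3),
                make_hit(evalue=1e-9, env_start=10)]
        once = filter_domain_hits(hits)
        assert filter_domain_hits(once) == once
        assert once == [hits[0], hits[2]]
        assert len(hits) == 3  # input untouched


class TestParser:
    def test_roundtrip_via_synth(self):
        from domarch.synth import SimConfig, generate_hit_tables
        from domarch.profiles import StrainState

        strains = [
            StrainState("sp1.1", "sp1", "DCL", 1, has_duf4131=True,
                        has_lactamase_b=True),
            StrainState("sp2.1", "sp2", "NC", 0, genomic_fragment=True),
        ]
        dom, blast, meta = generate_hit_tables(
            strains, {"sp1": "T", "sp2": "T"},
            SimConfig(straddle_fraction=0.0), seed=1,
        )
        hits = prof.parse_domtblout(io.StringIO(dom))
        assert {h.proteome_id for h in hits} == {"sp1.1"}
        assert all(h.model_coverage >= 0.70 for h in hits)
        nuc = prof.parse_blast_tab(io.StringIO(blast))
        assert [h.subject_genome_id for h in nuc] == ["sp2.1"]

    def test_malformed_row_names_line(self):
        good = (
            "s1|P1 - 500 Competence PF03772.10 241 1e-9 90.0 0.1 1 1 "
            "1e-9 1e-9 90.0 0.1 1 241 10 250 10 250 0.95 -"
        )
        bad = good.replace("1 241 10", "400 241 10")  # model_start > model_end
        with pytest.raises(ValueError, match="line 2"):
            prof.parse_domtblout(io.StringIO(good + "\n" + bad))
        with pytest.raises(ValueError, match="line 1"):  # non-numeric length
            prof.parse_domtblout(io.StringIO(good.replace(" 500 ", " abc ")))


class TestClassify:
    @pytest.mark.parametrize(
        "domains, expected",
        [
            ((COMPETENCE,), "C"),
            ((DUF4131, COMPETENCE), "DC"),
            ((COMPETENCE, LACTAMASE_B), "CL"),
            ((DUF4131, COMPETENCE, LACTAMASE_B), "DCL"),
            ((COMPETENCE, "PF10531"), "OTHER"),
            ((DUF4131, COMPETENCE, LACTAMASE_B, "PF12706"), "OTHER"),
            ((DUF4131, LACTAMASE_B), None),  # no Competence: not a CDCP
        ],
    )
    def test_profile_states(self, domains, expected):
        profile = ProteinProfile(
            protein_id="p", proteome_id="s", domains=domains,
            is_cdcp=COMPETENCE in domains,
        )
        assert classify_protein(profile) == expected

    @given(st.permutations([DUF4131, COMPETENCE, LACTAMASE_B]),
           st.integers(1, 3))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_order_and_duplicates(self, order, copies):
        base = ProteinProfile("p", "s", tuple(order), True)
        dup = ProteinProfile("p", "s", tuple(order) * copies, True)
        assert classify_protein(base) == classify_protein(dup) == "DCL"


class TestRescueFilter:
    def test_all_boundaries_inclusive(self):
        assert rescue_filter(NucleotideHit("q", "g", 1e-6, 0.30, 0.60))

    def test_truth_table_exactly_one_passes(self):
        # 2^3 combinations of pass/fail per predicate: only all-pass is true
        passing = dict(evalue=1e-6, query_coverage=0.5, identity=0.8)
        failing = dict(evalue=1e-3, query_coverage=0.1, identity=0.3)
        n_true = 0
        for e in (passing["evalue"], failing["evalue"]):
            for q in (passing["query_coverage"], failing["query_coverage"]):
                for i in (passing["identity"], failing["identity"]):
                    n_true += rescue_filter(NucleotideHit("q", "g", e, q, i))
        assert n_true == 1


class TestStrainState:
    def test_longest_cdcp_defines_state(self):
        long_dc = ProteinProfile("pA", "s1", (DUF4131, COMPETENCE), True, length=1000)
        short_dc = ProteinProfile("pB", "s1", (DUF4131, COMPETENCE), True, length=670)
        state = strain_state([long_dc, short_dc])
        assert state.state == "DC" and state.cdcp_count == 2

    def test_tie_broken_by_protein_id(self):
        a = ProteinProfile("pA", "s1", (COMPETENCE,), True, length=500)
        b = ProteinProfile("pB", "s1", (DUF4131, COMPETENCE), True, length=500)
        assert strain_state([a, b]).state == "C"

    def test_no_cdcp_with_passing_hit_is_rescued_nc(self):
        hit = NucleotideHit("q", "s1", 1e-10, 0.9, 0.9)
        state = strain_state([], [hit], strain_id="s1")
        assert state.state == "NC" and state.genomic_fragment

    def test_no_cdcp_no_hits(self):
        state = strain_state([], [], strain_id="s1")
        assert state.state == "NC" and not state.genomic_fragment

    def test_empty_without_strain_id_errors(self):
        with pytest.raises(ValueError):
            strain_state([], [])

    def test_cdcp_count_equals_cdcp_proteins(self):
        proteins = [
            ProteinProfile("p1", "s", (COMPETENCE,), True, length=400),
            ProteinProfile("p2", "s", (DUF4131,), False, length=300),
            ProteinProfile("p3", "s", (COMPETENCE, LACTAMASE_B), True, length=600),
        ]
        state = strain_state(proteins)
        assert state.cdcp_count == sum(p.is_cdcp for p in proteins)


def test_state_table_roundtrips_through_tsv(tmp_path):
    """Writing then re-reading a strain-state table reproduces identical states."""
    from domarch.synth import SimConfig, ecoli_example_states, generate_hit_tables

    strains = ecoli_example_states()
    dom, blast, meta = generate_hit_tables(
        strains, {"Escherichia coli": "Gamma"}, SimConfig(), seed=7
    )
    hits = prof.filter_domain_hits(prof.parse_domtblout(io.StringIO(dom)))
    profiles = prof.build_profiles(hits)
    nuc = prof.parse_blast_tab(io.StringIO(blast))
    metadata = prof.read_metadata(io.StringIO(meta))
    states = prof.strain_state_table(profiles, nuc, metadata)

    path = tmp_path / "states.tsv"
    prof.states_to_frame(states).to_csv(path, sep="\t", index=False)
    import pandas as pd

    again = prof.frame_to_states(pd.read_csv(path, sep="\t"))
    assert again == states
    assert {s.state for s in states} == {"NC", "CL", "DCL"}
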