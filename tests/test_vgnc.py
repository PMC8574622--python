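import itertools
import random

import pytest

from orthoconsensus import (
    CompositeGeneKey,
    OrthologTable,
    classify,
    combine,
    one_to_one_status,
    transfer_nomenclature,
)
from orthoconsensus.vgnc import DEFAULT_VOTERS, default_extra_checks

from conftest import HUMAN, MOUSE, make_entry, make_record

VOTERS = sorted(DEFAULT_VOTERS)  # Ensembl, NCBI Gene, OMA, PANTHER


def coding_lookup(answer=True):
    return lambda key, taxon: "protein-coding gene" if answer else "pseudogene"


class TestOneToOne:
    def test_lone_pair_is_one_to_one(self):
        e = make_entry(q_ncbi=1, t_ncbi=101, sources=["OMA"])
        assert one_to_one_status(OrthologTable([e]), e) is True

    def test_two_voter_supported_targets_break_one_to_one(self):
        a = make_entry(q_ncbi=1, t_ncbi=101, sources=["OMA"])
        b = make_entry(q_ncbi=1, t_ncbi=102, sources=["PANTHER"])
        table = OrthologTable([a, b])
        assert one_to_one_status(table, a) is False
        assert one_to_one_status(table, b) is False

    def test_non_voter_competition_is_ignored(self):
        """A second target supported only by non-voting resources does not
        break one-to-one status for the voting resources' pair."""
        a = make_entry(q_ncbi=1, t_ncbi=101, sources=["OMA", "Ensembl"])
        b = make_entry(q_ncbi=1, t_ncbi=102, sources=["TreeFam"])
        table = OrthologTable([a, b])
        assert one_to_one_status(table, a) is True

    def test_other_species_pairs_do_not_interfere(self):
        a = make_entry(q_ncbi=1, t_ncbi=101, t_taxon=MOUSE, sources=["OMA"])
        b = make_entry(q_ncbi=1, t_ncbi=201, t_taxon=10116, sources=["OMA"])
        table = OrthologTable([a, b])
        assert one_to_one_status(table, a) is True

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_degree_counting_oracle(self, seed):
        rng = random.Random(seed)
        entries = []
        seen = set()
        for _ in range(120):
            q, t = rng.randrange(1, 15), rng.randrange(101, 115)
            if (q, t) in seen:
                continue
            seen.add((q, t))
            k = rng.randrange(1, 5)
            entries.append(make_entry(
                q_ncbi=q, t_ncbi=t,
                sources=rng.sample([*VOTERS, "TreeFam", "eggNOG"], k)))
        table = OrthologTable(entries)
        voters = frozenset(DEFAULT_VOTERS)
        voter_entries = [e for e in entries
                         if set(e.supporting_sources) & set(VOTERS)]
        for e in entries:
            qd = sum(1 for x in voter_entries if x.query_key == e.query_key)
            td = sum(1 for x in voter_entries if x.target_key == e.target_key)
            assert one_to_one_status(table, e, voters) == (qd == 1 and td == 1)


class TestClassifyTruthTable:
    @staticmethod
    def rule_oracle(n_voters, one_to_one, both_coding, checks_pass):
        """Hand-written restatement of the naming rule."""
        if not (one_to_one and both_coding and n_voters >= 3):
            return "rejected"
        if n_voters == 4 and checks_pass:
            return "auto_name"
        return "manual_curation"

    @pytest.mark.parametrize("checks_pass", [True, False])
    def test_exhaustive_voter_subsets(self, checks_pass):
        """All 16 voter subsets x {1:1, 1:many} x {coding, not} match the
        rule oracle (binary checks-pass axis doubles the 64 cases)."""
        for subset_bits, one_to_one, coding in itertools.product(
                range(16), [True, False], [True, False]):
            voters_in = [v for i, v in enumerate(VOTERS) if subset_bits >> i & 1]
            sources = voters_in + ["TreeFam"]  # a non-voter never counts
            entry = make_entry(q_ncbi=1, t_ncbi=101, sources=sources)
            entries = [entry]
            if not one_to_one:
                entries.append(make_entry(q_ncbi=1, t_ncbi=102,
                                          sources=["Ensembl"]))
            table = OrthologTable(entries)
            call = classify(
                table, entry, coding_lookup(coding),
                extra_checks=lambda e: (checks_pass,
                                        [] if checks_pass else ["check failed"]),
            )
            expected = self.rule_oracle(len(voters_in), one_to_one, coding,
                                        checks_pass)
            assert call.classification == expected, (
                subset_bits, one_to_one, coding, checks_pass)
            assert call.voter_support == frozenset(voters_in)

    def test_four_voters_clean_is_auto_name(self):
        entry = make_entry(q_ncbi=1, t_ncbi=101, sources=VOTERS)
        call = classify(OrthologTable([entry]), entry, coding_lookup(),
                        extra_checks=lambda e: (True, []))
        assert call.classification == "auto_name"
        assert call.reasons == ()

    def test_three_voters_is_manual_curation(self):
        entry = make_entry(q_ncbi=1, t_ncbi=101, sources=VOTERS[:3])
        call = classify(OrthologTable([entry]), entry, coding_lookup(),
                        extra_checks=lambda e: (True, []))
        assert call.classification == "manual_curation"
        assert any("fewer than four" in r for r in call.reasons)

    def test_failed_extra_check_demotes_to_manual(self):
        entry = make_entry(q_ncbi=1, t_ncbi=101, sources=VOTERS)
        call = classify(OrthologTable([entry]), entry, coding_lookup(),
                        extra_checks=lambda e: (False, ["bad symbol"]))
        assert call.classification == "manual_curation"
        assert "bad symbol" in call.reasons

    def test_reasons_list_every_failed_gate_condition(self):
        entry = make_entry(q_ncbi=1, t_ncbi=101, sources=["OMA"])
        other = make_entry(q_ncbi=1, t_ncbi=102, sources=["Ensembl"])
        call = classify(OrthologTable([entry, other]), entry,
                        coding_lookup(False), extra_checks=lambda e: (True, []))
        assert call.classification == "rejected"
        assert len(call.reasons) == 3  # voters, one-to-one, coding

    def test_partition_every_entry_classified_once(self):
        rng = random.Random(2)
        entries = []
        for q in range(1, 20):
            entries.append(make_entry(
                q_ncbi=q, t_ncbi=100 + q,
                sources=rng.sample([*VOTERS, "TreeFam"], rng.randrange(1, 5))))
        table = OrthologTable(entries)
        calls = [classify(table, e, coding_lookup(),
                          extra_checks=lambda e: (True, [])) for e in table]
        assert len(calls) == len(entries)
        assert all(c.classification in ("auto_name", "manual_curation", "rejected")
                   for c in calls)

    def test_adding_a_voter_never_demotes(self):
        """Support monotonicity: growing the voter set cannot move a call away
        from auto_name."""
        order = {"rejected": 0, "manual_curation": 1, "auto_name": 2}
        for bits in range(16):
            voters_in = [v for i, v in enumerate(VOTERS) if bits >> i & 1]
            if len(voters_in) == 4:
                continue
            entry = make_entry(q_ncbi=1, t_ncbi=101, sources=voters_in or ["TreeFam"])
            call = classify(OrthologTable([entry]), entry, coding_lookup(),
                            extra_checks=lambda e: (True, []))
            extra = next(v for v in VOTERS if v not in voters_in)
            bigger = make_entry(q_ncbi=1, t_ncbi=101,
                                sources=[*voters_in, extra])
            call2 = classify(OrthologTable([bigger]), bigger, coding_lookup(),
                             extra_checks=lambda e: (True, []))
            assert order[call2.classification] >= order[call.classification]


class TestTransferNomenclature:
    def test_human_approved_nomenclature_is_proposed(self):
        human = make_record(symbol="BRCA1", name="BRCA1 DNA repair associated",
                            mod_id="HGNC:1100", ncbi_id=672,
                            nomenclature_status="approved", provenance="mod")
        target = make_record(taxon=MOUSE, symbol="?", ncbi_id=12189)
        assert transfer_nomenclature(human, target) == (
            "BRCA1", "BRCA1 DNA repair associated")

    def test_unapproved_human_record_refused(self):
        human = make_record(symbol="LOC999", ncbi_id=999)
        target = make_record(taxon=MOUSE, symbol="?", ncbi_id=1)
        with pytest.raises(ValueError, match="not committee-approved"):
            transfer_nomenclature(human, target)

    def test_proposal_isolated_from_unrelated_entries(self):
        """The proposal depends only on the two records, not on anything else
        in the table."""
        human = make_record(symbol="TP53", name="tumor protein p53",
                            mod_id="HGNC:11998", ncbi_id=7157,
                            nomenclature_status="approved", provenance="mod")
        t1 = make_record(taxon=MOUSE, symbol="a", ncbi_id=1)
        t2 = make_record(taxon=10116, symbol="b", ncbi_id=2)
        assert transfer_nomenclature(human, t1) == transfer_nomenclature(human, t2)


class TestDefaultExtraChecks:
    def test_approved_symbol_passes(self):
        rec = make_record(symbol="TP53", mod_id="HGNC:11998", ncbi_id=7157,
                          nomenclature_status="approved", provenance="mod")
        ok, reasons = default_extra_checks(rec)
        assert ok and not reasons

    def test_orf_placeholder_fails(self):
        rec = make_record(symbol="C9orf72", mod_id="HGNC:28337", ncbi_id=203228,
                          nomenclature_status="approved", provenance="mod")
        ok, reasons = default_extra_checks(rec)
        assert not ok and any("orf" in r for r in reasons)

    def test_missing_record_fails(self):
        ok, reasons = default_extra_checks(None)
        assert not ok
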