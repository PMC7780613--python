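"""Tests for LU profiling (event replay and contig tiling), PCRtag screens,
compaction statistics, and the iterative-round ledger."""

import pytest

from sgc import (
    CompactionLedger,
    RecombinationEvent,
    RoundResult,
    apply_events,
    compaction_stats,
    default_pcrtags,
    emit_contig,
    insilico_pcrtag,
    profile_from_events,
    profile_from_sequence,
    profile_from_state,
    reference_state,
    update_ledger,
)
from sgc.lu_profiler import PcrTag, parent_lu


class TestProfiles:
    def test_single_lu_deletion(self, synxiil):
        p = profile_from_events(
            synxiil, [RecombinationEvent("deletion", 7, 8)], "Z294")
        assert p.deleted_lus() == ("LU-8",)
        u = synxiil.lu("LU-8")
        assert p.deleted_segments == ((u.start, u.end),)

    def test_multi_lu_deletion_is_one_segment(self, synxiil):
        # sites 17 and 28 flank LU-18..LU-28
        p = profile_from_events(
            synxiil, [RecombinationEvent("deletion", 17, 28)], "Z315")
        assert len(p.deleted_segments) == 1
        assert p.deleted_lus() == tuple(f"LU-{k}" for k in range(18, 29))

    def test_disjoint_deletions_give_two_segments(self, synxiil):
        evs = [RecombinationEvent("deletion", 2, 4, order=0),
               RecombinationEvent("deletion", 8, 10, order=1)]
        p = profile_from_events(synxiil, evs, "x")
        assert len(p.deleted_segments) == 2

    def test_reference_contig_profiles_clean(self, synxiil):
        p = profile_from_sequence(synxiil, emit_contig(
            synxiil, reference_state(synxiil)), "ref")
        assert all(st["copies"] == 1 and not st["inverted"]
                   for st in p.status.values())
        assert p.deleted_segments == ()

    def test_tandem_duplication_copy_number(self, synxiil):
        state = apply_events(reference_state(synxiil),
                             [RecombinationEvent("duplication", 2, 4)])
        p = profile_from_sequence(synxiil, emit_contig(synxiil, state), "d")
        assert p.status["LU-3"]["copies"] == 2
        assert p.status["LU-4"]["copies"] == 2
        assert p.status["LU-1"]["copies"] == 1

    def test_inversion_detected_in_sequence_mode(self, synxiil):
        state = apply_events(reference_state(synxiil),
                             [RecombinationEvent("inversion", 5, 7)])
        p = profile_from_sequence(synxiil, emit_contig(synxiil, state), "i")
        assert p.status["LU-6"]["inverted"] and p.status["LU-7"]["inverted"]

    def test_foreign_contig_rejected(self, synxiil):
        with pytest.raises(ValueError, match="unrecognized"):
            profile_from_sequence(synxiil, "ACGT" * 100)


class TestPcrTags:
    def test_deleted_lu_tags_negative(self, synxiil):
        tags = default_pcrtags(synxiil)
        p = profile_from_events(
            synxiil, [RecombinationEvent("deletion", 19, 20)], "x")
        table = insilico_pcrtag(p, tags)
        assert table["LU-20"] is False
        assert sum(not v for v in table.values()) == 1

    def test_inverted_lu_tags_remain_positive(self, synxiil):
        tags = default_pcrtags(synxiil)
        state = apply_events(reference_state(synxiil),
                             [RecombinationEvent("inversion", 19, 20)])
        assert insilico_pcrtag(profile_from_state(synxiil, state), tags)["LU-20"]
        assert insilico_pcrtag(emit_contig(synxiil, state), tags)["LU-20"]

    def test_unscrambled_strain_all_positive(self, synxiil):
        tags = default_pcrtags(synxiil)
        p = profile_from_state(synxiil, reference_state(synxiil))
        assert all(insilico_pcrtag(p, tags).values())

    def test_short_lus_have_no_tag(self, synxiil):
        tagged = {t.lu_id for t in default_pcrtags(synxiil)}
        assert "LU-3" not in tagged  # the 50 bp unit
        assert len(tagged) < 46

    def test_unknown_lu_rejected(self, synxiil):
        p = profile_from_state(synxiil, reference_state(synxiil))
        with pytest.raises(KeyError, match="LU-99"):
            insilico_pcrtag(p, [PcrTag(lu_id="LU-99")])


class TestCompactionStats:
    def test_empty_profile_is_zero(self, synxiil):
        p = profile_from_state(synxiil, reference_state(synxiil))
        assert compaction_stats(p, synxiil) == {
            "n_lus_deleted": 0, "bp_deleted": 0, "n_genes_deleted": 0}

    def test_whole_arm_deletion_equals_reference_totals(self, synxiil):
        state = apply_events(reference_state(synxiil),
                             [RecombinationEvent("deletion", 0, 46)])
        p = profile_from_state(synxiil, state)
        s = compaction_stats(p, synxiil)
        assert s == {"n_lus_deleted": 46, "bp_deleted": 170_000,
                     "n_genes_deleted": 81}

    def test_replaced_gene_counts_when_lu_lost(self, synxiil):
        from sgc import integrate_ura3

        arm = integrate_ura3(synxiil, "LU-8", "replace_gene",
                             gene_id="YLL054C")
        p = profile_from_events(
            arm, [RecombinationEvent("deletion", 7, 8)], "x")
        assert compaction_stats(p, arm)["n_genes_deleted"] == 1


class TestLedger:
    def _round(self, rid, n_lus, bp, genes):
        per_bp, rem = divmod(bp, n_lus)
        per_g = [genes // n_lus + (1 if k < genes % n_lus else 0)
                 for k in range(n_lus)]
        deleted = {f"{rid}-D{k:02d}": (per_bp + (rem if k == 0 else 0),
                                       per_g[k])
                   for k in range(n_lus)}
        return RoundResult(rid, f"strain-{rid}", deleted)

    def test_worked_example_three_rounds(self):
        """Rounds deleting 12/9/7 LUs and 45/26/29 kbp from a 46-LU, 170 kbp
        arm leave 25 LUs after two rounds and 18 LUs / 99 kbp after two."""
        led = CompactionLedger(total_lus=46, total_bp=170_000, total_genes=81)
        update_ledger(led, self._round("r1", 12, 45_000, 18))
        update_ledger(led, self._round("r2", 9, 26_000, 9))
        assert led.retained_lus == 25
        assert led.retained_bp == 99_000
        update_ledger(led, self._round("r3", 7, 29_000, 12))
        assert led.retained_lus == 18

    def test_conservation_every_round(self):
        led = CompactionLedger(total_lus=46, total_bp=170_000, total_genes=81)
        for r in (self._round("a", 5, 20_000, 8),
                  self._round("b", 3, 11_000, 4)):
            update_ledger(led, r)
            assert led.retained_bp + led.deleted_bp == 170_000

    def test_overlapping_rounds_rejected(self):
        led = CompactionLedger(total_lus=46, total_bp=170_000, total_genes=81)
        r = self._round("r1", 4, 8000, 4)
        update_ledger(led, r)
        with pytest.raises(ValueError, match="re-deletes"):
            update_ledger(led, RoundResult("r2", "s", dict(r.deleted)))

    def test_split_unit_counts_once_fully_gone(self, synxiil):
        led = CompactionLedger.from_chromosome(synxiil)
        L = synxiil.lu("LU-24").length_bp
        update_ledger(led, RoundResult("r1", "s1",
                                       {"LU-24-b": (400, 0)}))
        assert led.retained_lus == 46  # partial loss of LU-24
        update_ledger(led, RoundResult("r2", "s2",
                                       {"LU-24-a": (L - 1000, 1),
                                        "LU-24-c": (600, 0)}))
        assert led.retained_lus == 45

    def test_parent_id_collapse(self):
        assert parent_lu("LU-24-b") == "LU-24"
        assert parent_lu("LU-24") == "LU-24"
        assert parent_lu("LU-7~2") == "LU-7"
        assert parent_lu("LU-24-a~2") == "LU-24"

    def test_tsv_and_json_render(self):
        led = CompactionLedger(total_lus=46, total_bp=170_000, total_genes=81)
        update_ledger(led, self._round("r1", 2, 5000, 2))
        assert "r1" in led.to_tsv()
        assert led.to_dict()["cumulative"]["retained_bp"] == 165_000
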