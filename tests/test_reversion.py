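"""Reversion engine: candidate enumeration, mechanism classification against
a brute-force translation oracle, read-backed phasing and confidence tiers."""

from __future__ import annotations

import numpy as np
import pytest

from revertscan.errors import ContractError
from revertscan.refmodel import GeneModel
from revertscan.reversion import (
    BACK_MUTATION,
    FRAME_RESTORING_INDEL,
    NOT_REVERSION,
    SPANNING_DELETION,
    PrimaryLesion,
    assign_confidence,
    call_reversions,
    check_cis_phase,
    classify_mechanism,
    enumerate_candidates,
)
from revertscan.simulate import (
    ReversionSpec,
    SimPatientConfig,
    default_primary,
    simulate_patient,
    toy_gene_model,
)
from revertscan.variants import normalize_variant

from conftest import TOY60_CDS, brute_force_functional, make_read, surgery, sv

# fixed primary for the 60-bp toy: 5-bp deletion anchored at position 9
# (footprint 10-14, codon-aligned at codon 4)
P60 = sv(9, TOY60_CDS[8:14], TOY60_CDS[8])


@pytest.fixture(scope="module")
def lesion60(toy60):
    return PrimaryLesion(gene="TOY60", variant=normalize_variant(toy60, P60), origin="germline")


class TestEnumerate:
    def test_window_and_gene_filters(self, toy60, lesion60):
        near = sv(40, TOY60_CDS[39], "A" if TOY60_CDS[39] != "A" else "C")
        other_contig = sv(40, "A", "C", contig="chrX")
        out = enumerate_candidates(lesion60, [near, other_contig], window=100, model=toy60)
        assert out == [near]

    def test_far_variant_outside_window_excluded(self, lesion60):
        far = sv(5000, "A", "C")
        assert enumerate_candidates(lesion60, [far], window=100) == []

    def test_overlapping_deletion_included_regardless_of_distance(self, toy60, lesion60):
        # deletion footprint covering the lesion is a candidate by the
        # overlap clause even with a tiny window
        big = sv(2, TOY60_CDS[1:26], TOY60_CDS[1])
        out = enumerate_candidates(lesion60, [big], window=1, model=toy60)
        assert out == [big]

    def test_primary_itself_excluded(self, toy60, lesion60):
        assert enumerate_candidates(lesion60, [lesion60.variant], model=toy60) == []


class TestClassifyMechanism:
    def test_exact_restoring_insertion_is_back_mutation(self, toy60, lesion60):
        p = lesion60.variant
        inverse = sv(p.pos, p.alt, p.ref)
        assert classify_mechanism(lesion60, inverse, toy60) == BACK_MUTATION

    def test_frame_restoring_pair_agrees_with_surgery_oracle(self, toy60, lesion60):
        ins2 = normalize_variant(toy60, sv(16, TOY60_CDS[15], TOY60_CDS[15] + "CT"))
        mech = classify_mechanism(lesion60, ins2, toy60)
        edited = surgery(TOY60_CDS, [lesion60.variant, ins2])
        assert brute_force_functional(edited)
        assert mech == FRAME_RESTORING_INDEL

    def test_in_frame_net_with_new_stop_is_not_reversion(self):
        """Net -6 restores the frame but the sequence spanning the two
        deletions now reads a TAA codon: the translation oracle rejects it."""
        # codons: ATG AAA TAC GAT CAA CCC GGG TTT AAA CCC ... TAA
        cds = "ATG" + "AAATACGATCAACCCGGGTTTAAACCC" + "GGG" * 8 + "TAA"
        model = GeneModel("STOPTRAP", "chrT", "+", 1, cds, ((1, len(cds)),))
        primary = sv(4, cds[3:9], cds[3])          # 5-bp deletion, footprint 5-9
        secondary = sv(10, cds[9], cds[9] + "GTAAC")  # +5 insertion: net 0
        # net = -5 + 5 = 0: back in frame, but the insertion places TAA on a
        # codon boundary of the edited sequence
        lesion = PrimaryLesion("STOPTRAP", primary)
        edited = surgery(cds, [primary, secondary])
        assert len(edited) % 3 == 0
        assert not brute_force_functional(edited)
        assert classify_mechanism(lesion, secondary, model) == NOT_REVERSION

    def test_spanning_deletion_in_frame(self, toy60, lesion60):
        # remove codons 2-8 entirely (21 bases, containing the lesion)
        cand = normalize_variant(toy60, sv(3, TOY60_CDS[2:24], TOY60_CDS[2]))
        assert cand.net_length == -21
        assert classify_mechanism(lesion60, cand, toy60) == SPANNING_DELETION

    def test_spanning_deletion_out_of_frame_rejected(self, toy60, lesion60):
        cand = normalize_variant(toy60, sv(3, TOY60_CDS[2:23], TOY60_CDS[2]))
        assert cand.net_length == -20
        assert classify_mechanism(lesion60, cand, toy60) == NOT_REVERSION

    def test_overlapping_conflict_is_not_reversion(self, toy60, lesion60):
        conflict = sv(11, TOY60_CDS[10], "A" if TOY60_CDS[10] != "A" else "G")
        assert classify_mechanism(lesion60, conflict, toy60) == NOT_REVERSION

    def test_exhaustive_oracle_equivalence(self, toy60, lesion60):
        """Classifier agrees with brute-force haplotype translation for all
        single secondary indels of lengths 1-6 at every position of the
        60-bp toy CDS, given the fixed 5-bp primary deletion."""
        p = lesion60.variant
        n_cases = 0
        rng = np.random.default_rng(60)
        for pos in range(2, 61):
            for length in range(1, 7):
                cases = []
                if pos + length <= 60:  # deletion of `length` bases after anchor
                    ref = TOY60_CDS[pos - 1 : pos - 1 + length + 1]
                    cases.append(sv(pos, ref, ref[0]))
                ins = "".join(rng.choice(list("ACGT"), size=length))
                cases.append(sv(pos, TOY60_CDS[pos - 1], TOY60_CDS[pos - 1] + ins))
                for raw in cases:
                    cand = normalize_variant(toy60, raw)
                    if cand.key == p.key:
                        continue
                    got = classify_mechanism(lesion60, cand, toy60)
                    n_cases += 1
                    expected = _oracle_mechanism(p, cand)
                    assert got == expected, f"{cand}: got {got}, oracle {expected}"
        assert n_cases >= 650

    def test_primary_must_truncate_for_frame_restoration(self, toy60):
        # an in-frame (3-bp) primary deletion leaves the protein intact, so a
        # nearby passenger indel pair is never labelled a reversion
        p3 = normalize_variant(toy60, sv(9, TOY60_CDS[8:12], TOY60_CDS[8]))
        lesion = PrimaryLesion("TOY60", p3)
        passenger = normalize_variant(toy60, sv(30, TOY60_CDS[29], TOY60_CDS[29] + "GGG"))
        assert classify_mechanism(lesion, passenger, toy60) == NOT_REVERSION


def _oracle_mechanism(p, cand) -> str:
    """Independent decision by direct string surgery on the whole-slice CDS."""
    if (cand.pos, cand.ref, cand.alt) == (p.pos, p.alt, p.ref):
        return BACK_MUTATION
    contains = cand.pos <= p.pos and cand.end >= p.end
    overlap = cand.pos <= p.end and p.pos <= cand.end
    if cand.net_length < 0 and contains:
        if cand.net_length % 3 != 0:
            return NOT_REVERSION
        return SPANNING_DELETION if brute_force_functional(surgery(TOY60_CDS, [cand])) else NOT_REVERSION
    if overlap:
        return NOT_REVERSION
    if (p.net_length + cand.net_length) % 3 != 0:
        return NOT_REVERSION
    if brute_force_functional(surgery(TOY60_CDS, [p])):
        return NOT_REVERSION
    edited = surgery(TOY60_CDS, [p, cand])
    return FRAME_RESTORING_INDEL if brute_force_functional(edited) else NOT_REVERSION


class TestCisPhase:
    REF = "GATTACAGATTACAGATTACAGATTACA"  # 28 bp backdrop

    def _lesion(self):
        return PrimaryLesion("G", sv(5, self.REF[4], "G"))  # A>G SNV at pos 5

    def test_shared_read_counting(self):
        lesion = self._lesion()
        cand = sv(15, self.REF[14], "T")  # C>T at pos 15
        both = self.REF[:4] + "G" + self.REF[5:14] + "T" + self.REF[15:]
        p_only = self.REF[:4] + "G" + self.REF[5:]
        reads = [make_read(1, both, qname=f"b{i}") for i in range(6)]
        reads += [make_read(1, p_only, qname=f"p{i}") for i in range(2)]
        phase, shared = check_cis_phase(lesion, cand, reads, min_shared=2)
        assert (phase, shared) == ("cis_confirmed", 6)

    def test_trans_when_alleles_never_cooccur(self):
        lesion = self._lesion()
        cand = sv(15, self.REF[14], "T")
        p_only = self.REF[:4] + "G" + self.REF[5:]
        c_only = self.REF[:14] + "T" + self.REF[15:]
        reads = [make_read(1, p_only, qname=f"p{i}") for i in range(4)]
        reads += [make_read(1, c_only, qname=f"c{i}") for i in range(4)]
        phase, shared = check_cis_phase(lesion, cand, reads, min_shared=2)
        assert (phase, shared) == ("trans", 0)

    def test_unphaseable_loci_beyond_read_span(self):
        lesion = self._lesion()
        cand = sv(15, self.REF[14], "T")
        reads = [make_read(1, self.REF[:8], qname="short1"), make_read(12, self.REF[11:], qname="short2")]
        phase, shared = check_cis_phase(lesion, cand, reads, min_shared=2)
        assert (phase, shared) == ("unknown", 0)

    def test_spanning_deletion_implicitly_cis(self):
        lesion = self._lesion()
        # deletion removing positions 3-11 (9 bp, contains the lesion)
        cand = sv(2, self.REF[1:11], self.REF[1])
        del_seq = self.REF[:2] + self.REF[11:]
        reads = [make_read(1, del_seq, cigar="2M9D17M", qname=f"d{i}") for i in range(3)]
        reads += [make_read(1, self.REF, qname=f"r{i}") for i in range(5)]
        phase, shared = check_cis_phase(lesion, cand, reads, mechanism=SPANNING_DELETION)
        assert (phase, shared) == ("implicit_cis", 3)

    def test_back_mutation_uses_caller_support(self):
        lesion = self._lesion()
        inverse = sv(5, "G", self.REF[4], alt_count=17, depth=400)
        phase, shared = check_cis_phase(lesion, inverse, None, mechanism=BACK_MUTATION)
        assert (phase, shared) == ("implicit_cis", 17)


class TestAssignConfidence:
    def test_matches_independent_truth_table(self):
        """Exact agreement with a directly coded tier table over the full
        support x VAF grid, including the undefined-VAF column."""
        def oracle(support, vaf):
            if vaf is not None and vaf > 0.05:
                return "high"
            table = [(11, 10**9, "high"), (6, 10, "moderate"), (2, 5, "low"), (0, 1, "rejected")]
            for lo, hi, tier in table:
                if lo <= support <= hi:
                    return tier
            raise AssertionError(support)

        for support in range(0, 21):
            for vaf in (0.0, 0.01, 0.05, 0.0501, 0.051, 0.2, None):
                assert assign_confidence(support, vaf) == oracle(support, vaf), (support, vaf)

    @pytest.mark.parametrize(
        "support,vaf,tier",
        [
            (12, 0.02, "high"),    # > 10 reads
            (4, 0.06, "high"),     # > 5% VAF wins regardless of reads
            (7, 0.01, "moderate"),
            (5, 0.01, "low"),
            (1, 0.002, "rejected"),
            (11, 0.05, "high"),    # 5% exactly is NOT high by VAF; 11 reads is
            (10, 0.05, "moderate"),
        ],
    )
    def test_boundary_cases(self, support, vaf, tier):
        assert assign_confidence(support, vaf) == tier

    def test_negative_support_rejected(self):
        with pytest.raises(ContractError):
            assign_confidence(-1, 0.1)


class TestCallReversions:
    def test_high_vaf_back_mutation_end_to_end(self):
        model = toy_gene_model()
        primary = default_primary(model)
        cfg = SimPatientConfig(
            patient_id="E2E",
            primary_lesion=primary,
            primary_origin="germline",
            purity=0.85,
            depth=500,
            error_rate=0.001,
            reversion_events=(ReversionSpec(BACK_MUTATION, 0.4),),
            seed=21,
        )
        pat = simulate_patient(cfg, model)
        (ev,) = pat.truth.events
        lesion = PrimaryLesion(model.gene_symbol, primary, "germline")
        dp = 500
        inverse = ev.variant.replace(alt_count=int(round(ev.true_vaf * dp)), depth=dp)
        (call,) = call_reversions(lesion, [inverse], list(pat.reads), model)
        assert call.mechanism == BACK_MUTATION
        assert call.phase == "implicit_cis"
        assert call.tier == "high"

    def test_no_events_no_calls(self):
        model = toy_gene_model()
        primary = default_primary(model)
        cfg = SimPatientConfig(patient_id="N", primary_lesion=primary, purity=0.6,
                               depth=300, error_rate=0.0, seed=4)
        pat = simulate_patient(cfg, model)
        lesion = PrimaryLesion(model.gene_symbol, primary, "germline")
        assert call_reversions(lesion, [], list(pat.reads), model) == []

    def test_two_mechanisms_two_distinct_calls(self):
        model = toy_gene_model()
        primary = default_primary(model)
        cfg = SimPatientConfig(
            patient_id="D",
            primary_lesion=primary,
            primary_origin="germline",
            purity=0.8,
            depth=500,
            error_rate=0.001,
            reversion_events=(
                ReversionSpec(FRAME_RESTORING_INDEL, 0.25),
                ReversionSpec(SPANNING_DELETION, 0.25),
            ),
            seed=31,
        )
        pat = simulate_patient(cfg, model)
        lesion = PrimaryLesion(model.gene_symbol, primary, "germline")
        somatic = [e.variant for e in pat.truth.events]
        calls = call_reversions(lesion, somatic, list(pat.reads), model)
        assert sorted(c.mechanism for c in calls) == [FRAME_RESTORING_INDEL, SPANNING_DELETION]

    def test_rejected_tier_kept_in_audit_only(self):
        model = toy_gene_model()
        primary = default_primary(model)
        cfg = SimPatientConfig(patient_id="A", primary_lesion=primary, purity=0.6,
                               depth=400, error_rate=0.0, seed=8,
                               reversion_events=(ReversionSpec(FRAME_RESTORING_INDEL, 0.3),))
        pat = simulate_patient(cfg, model)
        lesion = PrimaryLesion(model.gene_symbol, primary, "germline")
        somatic = [e.variant for e in pat.truth.events]
        audit: list = []
        reported = call_reversions(lesion, somatic, list(pat.reads), model, audit_log=audit)
        assert len(audit) >= len(reported)
        assert all(c.reported for c in reported)
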