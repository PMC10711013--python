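"""Synthetic-cohort generator: mixture arithmetic, read sampling, truth I/O,
pseudo-callers and determinism."""

from __future__ import annotations

import numpy as np
import pytest

from revertscan.errors import ConfigError
from revertscan.simulate import (
    ReversionSpec,
    SimPatientConfig,
    build_haplotype_mixture,
    default_primary,
    make_reversion_variant,
    plan_events,
    read_truth,
    simulate_caller_vcfs,
    simulate_patient,
    simulate_reads,
    toy_gene_model,
    write_patient_bundle,
    write_truth,
)


@pytest.fixture(scope="module")
def model():
    return toy_gene_model()


@pytest.fixture(scope="module")
def primary(model):
    return default_primary(model)


def _cfg(primary, **kw):
    base = dict(
        patient_id="P",
        primary_lesion=primary,
        primary_origin="somatic",
        purity=1.0,
        depth=500.0,
        read_length=100,
        error_rate=0.0,
        reversion_events=(),
        seed=1,
    )
    base.update(kw)
    return SimPatientConfig(**base)


class TestMixtureWeights:
    def test_pure_tumour_somatic_het_is_half_half(self, model, primary):
        cfg = _cfg(primary, purity=1.0, primary_origin="somatic")
        comps = {c.label: c.weight for c in build_haplotype_mixture(cfg, model, [])}
        assert comps["ref"] == pytest.approx(0.5)
        assert comps["lesion"] == pytest.approx(0.5)

    def test_germline_lesion_dosage_independent_of_purity(self, model, primary):
        # germline het: normal cells carry it too, so allele dosage stays 0.5
        cfg = _cfg(primary, purity=0.5, primary_origin="germline")
        comps = {c.label: c.weight for c in build_haplotype_mixture(cfg, model, [])}
        assert comps["lesion"] == pytest.approx(0.5)

    def test_reversion_weight_is_purity_ccf_dosage(self, model, primary):
        cfg = _cfg(
            primary,
            purity=0.6,
            primary_origin="germline",
            reversion_events=(ReversionSpec("frame_restoring_indel", 0.2),),
        )
        rng = np.random.default_rng(0)
        events = plan_events(cfg, model, rng)
        comps = {c.label: c.weight for c in build_haplotype_mixture(cfg, model, events)}
        assert comps["event0"] == pytest.approx(0.6 * 0.2 * 0.5)
        assert events[0].true_vaf == pytest.approx(0.06)
        assert sum(comps.values()) == pytest.approx(1.0)

    def test_overfull_ccf_rejected(self, primary):
        with pytest.raises(ConfigError):
            _cfg(primary, reversion_events=(
                ReversionSpec("back_mutation", 0.7),
                ReversionSpec("frame_restoring_indel", 0.7),
            ))


class TestSimulateReads:
    def test_depth_near_target_in_interior(self, model, primary):
        cfg = _cfg(primary, depth=500, seed=3)
        pat = simulate_patient(cfg, model)
        cover = np.zeros(len(model.ref_seq) + 2)
        for r in pat.reads:
            cover[r.pos : r.reference_end + 1] += 1
        interior = cover[cfg.read_length : len(model.ref_seq) - cfg.read_length]
        assert abs(len(pat.reads) - cfg.depth * len(model.ref_seq) / cfg.read_length) <= 1
        assert np.all(interior > 500 * 0.8)
        assert np.all(interior < 500 * 1.2)

    def test_error_free_reads_substring_of_source_haplotypes(self, model, primary):
        cfg = _cfg(
            primary,
            error_rate=0.0,
            purity=0.8,
            reversion_events=(ReversionSpec("frame_restoring_indel", 0.5),),
            seed=5,
        )
        pat = simulate_patient(cfg, model)
        hap_seqs = [c.haplotype.sequence for c in pat.mixture]
        for r in pat.reads[:500]:
            assert any(r.seq in h for h in hap_seqs)

    def test_alt_read_count_matches_binomial_sampling(self, model, primary):
        """Implanted event at true VAF 0.06, depth 500: alt reads behave like
        Binomial(~500, 0.06); the mean over seeds sits within 3 SE of 30."""
        from revertscan.variants import recount_from_reads

        counts = []
        vafs = []
        for seed in range(40):
            cfg = _cfg(
                primary,
                purity=0.6,
                primary_origin="germline",
                error_rate=0.0,
                reversion_events=(ReversionSpec("frame_restoring_indel", 0.2),),
                seed=1000 + seed,
            )
            pat = simulate_patient(cfg, model)
            (ev,) = pat.truth.events
            out = recount_from_reads(ev.variant, pat.reads)
            counts.append(out.alt_count)
            vafs.append(out.vaf)
        n = len(counts)
        mean = float(np.mean(counts))
        se = float(np.std(counts, ddof=1)) / np.sqrt(n)
        assert abs(mean - 0.06 * 500) <= 3 * max(se, 1e-9) + 1.5
        vaf_err = np.array(vafs) - 0.06
        assert abs(vaf_err.mean()) <= 3 * vaf_err.std(ddof=1) / np.sqrt(n)


class TestEvents:
    def test_back_mutation_is_exact_inverse(self, model, primary):
        rng = np.random.default_rng(0)
        v = make_reversion_variant(model, primary, "back_mutation", rng)
        assert (v.pos, v.ref, v.alt) == (primary.pos, primary.alt, primary.ref)

    def test_spanning_deletion_contains_lesion_in_frame(self, model, primary):
        rng = np.random.default_rng(0)
        v = make_reversion_variant(model, primary, "spanning_deletion", rng)
        assert v.pos <= primary.pos and v.end >= primary.end
        assert v.net_length % 3 == 0

    def test_distinct_events_get_distinct_loci(self, model, primary):
        cfg = _cfg(
            primary,
            purity=0.8,
            reversion_events=(
                ReversionSpec("frame_restoring_indel", 0.2),
                ReversionSpec("frame_restoring_indel", 0.2),
            ),
        )
        events = plan_events(cfg, model, np.random.default_rng(1))
        assert events[0].variant.key != events[1].variant.key


class TestTruthIO:
    def test_round_trip(self, model, primary, tmp_path):
        cfg = _cfg(primary, purity=0.5, primary_origin="germline",
                   reversion_events=(ReversionSpec("back_mutation", 0.3),), seed=2)
        pat = simulate_patient(cfg, model)
        write_truth(pat.truth, tmp_path, model)
        loaded = read_truth(tmp_path / "P.truth.json")
        assert loaded == pat.truth

    def test_empty_event_list_header_only_vcf(self, model, primary, tmp_path):
        cfg = _cfg(primary)
        pat = simulate_patient(cfg, model)
        write_truth(pat.truth, tmp_path, model)
        lines = (tmp_path / "P.truth.vcf").read_text().splitlines()
        assert all(l.startswith("#") for l in lines)

    def test_mechanism_tag_in_truth_vcf(self, model, primary, tmp_path):
        cfg = _cfg(primary, purity=0.5, reversion_events=(ReversionSpec("back_mutation", 0.3),))
        pat = simulate_patient(cfg, model)
        write_truth(pat.truth, tmp_path, model)
        body = [l for l in (tmp_path / "P.truth.vcf").read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 1 and "MECH=back_mutation" in body[0]


class TestPseudoCallers:
    def test_perfect_sensitivity_no_fp_reproduces_truth(self, model, primary):
        cfg = _cfg(primary, purity=0.5, primary_origin="germline",
                   reversion_events=(ReversionSpec("frame_restoring_indel", 0.4),))
        pat = simulate_patient(cfg, model)
        callers = simulate_caller_vcfs(pat.truth, cfg, sensitivity=1.0, fp_rate=0.0, model=model)
        truth_keys = {pat.truth.primary.key} | {e.variant.key for e in pat.truth.events} | {("TP53", 1000, "C", "T")}
        for calls in callers.values():
            assert {v.key for v in calls} == truth_keys

    def test_zero_sensitivity_empty(self, model, primary):
        cfg = _cfg(primary)
        pat = simulate_patient(cfg, model)
        callers = simulate_caller_vcfs(pat.truth, cfg, sensitivity=0.0, fp_rate=0.0, model=model)
        assert all(calls == [] for calls in callers.values())

    def test_bad_sensitivity_rejected(self, model, primary):
        cfg = _cfg(primary)
        pat = simulate_patient(cfg, model)
        with pytest.raises(ConfigError):
            simulate_caller_vcfs(pat.truth, cfg, sensitivity=1.5)


class TestDeterminism:
    def test_same_seed_byte_identical_bundle(self, model, primary, tmp_path):
        cfg = _cfg(primary, purity=0.5, primary_origin="germline", depth=120,
                   reversion_events=(ReversionSpec("spanning_deletion", 0.3),), seed=11)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        for d in (d1, d2):
            write_patient_bundle(simulate_patient(cfg, model), d)
        files1 = sorted(p.name for p in d1.iterdir())
        assert files1 == sorted(p.name for p in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
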