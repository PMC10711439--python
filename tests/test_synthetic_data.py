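"""Generators: planted truth, self-consistency gates, determinism."""

import numpy as np
import pytest
from scipy import stats

import fanzorkit.synthetic_data as sd
from fanzorkit.fingerprint import classify


class TestProteinFamily:
    def test_zero_noise_recovery_all_classes(self):
        for rc, ep, expected in [
            ("DPG", "E_alt", "FANZOR_LIKE"),
            ("DPhiG", "E_alt", "E_ALT_DPHIG"),
            ("DPG", "E_can", "CANONICAL"),
            ("DPhiG", "E_can", "CANONICAL"),
        ]:
            recs = sd.gen_protein_family(
                sd.ProteinFamilyConfig(n_positives=10, n_decoys=0,
                                       ruvc1_class=rc, e_placement=ep, seed=5)
            )
            assert all(classify(r.sequence).category == expected for r in recs)

    def test_dphig_never_fanzor_like(self):
        recs = sd.gen_protein_family(
            sd.ProteinFamilyConfig(n_positives=20, n_decoys=0,
                                   ruvc1_class="DPhiG", e_placement="E_alt", seed=6)
        )
        assert all(classify(r.sequence).category != "FANZOR_LIKE" for r in recs)

    def test_decoys_are_incomplete(self):
        recs = sd.gen_protein_family(
            sd.ProteinFamilyConfig(n_positives=0, n_decoys=30, seed=7)
        )
        assert all(classify(r.sequence).category == "INCOMPLETE" for r in recs)

    def test_motif_residues_protected_under_mutation(self):
        cfg = sd.ProteinFamilyConfig(n_positives=15, n_decoys=0,
                                     mutation_rate=0.3, seed=8)
        for r in sd.gen_protein_family(cfg):
            # heavy mutation, labels still exact because motifs are protected
            assert classify(r.sequence).category == "FANZOR_LIKE"

    def test_determinism(self):
        cfg = dict(n_positives=5, n_decoys=5, mutation_rate=0.1, seed=9)
        a = sd.gen_protein_family(sd.ProteinFamilyConfig(**cfg))
        b = sd.gen_protein_family(sd.ProteinFamilyConfig(**cfg))
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            sd.ProteinFamilyConfig(n_positives=1, n_decoys=0, mutation_rate=1.0)
        with pytest.raises(ValueError):
            sd.ProteinFamilyConfig(n_positives=1, n_decoys=0, spacer_range=(0, 600))


class TestTransposonSim:
    def test_euk_allele_structure(self):
        cfg = sd.TransposonSimConfig(element_length=300, tsd_length=4,
                                     flank_length=100, seed=1)
        ins, emp, tr = sd.gen_transposon_locus(cfg)
        s, e = tr.element_interval
        assert len(ins) == len(emp) + (e - s) + cfg.tsd_length
        assert ins[s - 4:s] == tr.tsd == ins[e:e + 4]
        assert emp == ins[:s] + ins[e + 4:]

    def test_is607_gg_boundaries_and_no_tsd(self):
        cfg = sd.TransposonSimConfig(is_family="IS607", tsd_length=0,
                                     element_length=300, flank_length=100, seed=2)
        ins, emp, tr = sd.gen_transposon_locus(cfg)
        s, e = tr.element_interval
        assert ins[s:s + 2] == "GG" and ins[e - 2:e] == "GG"
        assert tr.tsd is None and tr.tir_intervals is None
        # single GG at the pre-insertion junction
        assert emp == ins[:s] + "GG" + ins[e:]

    def test_is607_config_rejects_tsd(self):
        with pytest.raises(ValueError):
            sd.TransposonSimConfig(is_family="IS607", tsd_length=4)

    def test_euk_config_requires_tsd_and_tir(self):
        with pytest.raises(ValueError):
            sd.TransposonSimConfig(is_family="eukaryotic_DNA_transposon", tsd_length=1)

    def test_planted_tir_mismatch_count(self):
        cfg = sd.TransposonSimConfig(element_length=300, tir_length=20,
                                     tir_mismatches=2, flank_length=100, seed=3)
        ins, _, tr = sd.gen_transposon_locus(cfg)
        s, e = tr.element_interval
        el = ins[s:e]
        left = el[:20]
        right_rc = sd.revcomp(el[-20:])
        assert sum(a != b for a, b in zip(left, right_rc)) == 2


class TestTamSim:
    def test_no_depletion_is_uniform(self):
        # factor 1: input and output differ only by sampling noise
        rejects = 0
        for seed in range(10):
            cfg = sd.TamSimConfig(depletion_factor=1.0, reads_per_sample=40_000,
                                  tam_length=3, seed=seed)
            _, _, truth = sd.gen_tam_reads(cfg)
            obs = np.array(list(truth.counts_output.values()))
            p = stats.chisquare(obs).pvalue
            rejects += p < 0.001
        assert rejects <= 1

    def test_truth_counts_sum_to_depth(self):
        cfg = sd.TamSimConfig(reads_per_sample=5000, seed=1)
        rin, rout, truth = sd.gen_tam_reads(cfg)
        assert sum(truth.counts_input.values()) == 5000 == len(rin)
        assert sum(truth.counts_output.values()) == 5000 == len(rout)

    def test_depleted_set_rule(self):
        cfg = sd.TamSimConfig(reads_per_sample=0, seed=2)
        _, _, truth = sd.gen_tam_reads(cfg)
        assert len(truth.depleted) == 64
        assert all(t.startswith("GGG") for t in truth.depleted)

    def test_zero_reads_degenerate(self):
        cfg = sd.TamSimConfig(reads_per_sample=0, seed=3)
        rin, rout, truth = sd.gen_tam_reads(cfg)
        assert rin == [] and rout == []

    def test_read_layout(self):
        cfg = sd.TamSimConfig(reads_per_sample=50, seed=4)
        rin, _, _ = sd.gen_tam_reads(cfg)
        read = rin[0]
        pos = read.find(cfg.anchor)
        assert pos == cfg.pad_length + cfg.tam_length
        assert len(read) == 2 * cfg.pad_length + cfg.tam_length + len(cfg.anchor)


class TestPairedFamilies:
    def test_coupled_clock_correlates(self):
        fams = sd.gen_paired_families(sd.PairedFamilyConfig(coupling=1.0, seed=0))
        assert np.corrcoef(list(fams.distances_a.values()),
                           list(fams.distances_b.values()))[0, 1] > 0.999

    def test_shuffle_permutes_tnpb_only(self):
        fams = sd.gen_paired_families(
            sd.PairedFamilyConfig(coupling=1.0, shuffle_control=True, seed=1)
        )
        a_rows = [ra for ra, _ in fams.shuffled_pairing.values()]
        assert a_rows == [ra for ra, _ in fams.pairing.values()]
        b_orig = [rb for _, rb in fams.pairing.values()]
        b_shuf = [rb for _, rb in fams.shuffled_pairing.values()]
        assert sorted(b_orig) == sorted(b_shuf) and b_orig != b_shuf

    def test_minimum_elements(self):
        with pytest.raises(ValueError):
            sd.PairedFamilyConfig(n_elements=2)


class TestSmallRna:
    def test_noise_free_reads_tile_exact_interval(self):
        locus = "".join(np.random.default_rng(0).choice(list("ACGT"), size=400))
        cfg = sd.SmallRnaSimConfig(locus=locus, rerna_start=100, rerna_end=250,
                                   n_reads=50, end_noise_sd=0.0, seed=1)
        reads, truth = sd.gen_smallrna_reads(cfg)
        assert all(r == locus[100:250] for r in reads)
        assert truth.interval == (100, 250)

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            sd.SmallRnaSimConfig(locus="ACGT" * 10, rerna_start=10, rerna_end=100)


def test_generators_byte_identical_across_runs():
    ins1, emp1, _ = sd.gen_transposon_locus(sd.TransposonSimConfig(seed=11))
    ins2, emp2, _ = sd.gen_transposon_locus(sd.TransposonSimConfig(seed=11))
    assert (ins1, emp1) == (ins2, emp2)
    r1, _, t1 = sd.gen_tam_reads(sd.TamSimConfig(reads_per_sample=2000, seed=11))
    r2, _, t2 = sd.gen_tam_reads(sd.TamSimConfig(reads_per_sample=2000, seed=11))
    assert r1 == r2 and t1.counts_input == t2.counts_input
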