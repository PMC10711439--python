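"""PSSM construction, local alignment, calibration, iterative augmentation."""

import math

import numpy as np
import pytest

from fanzorkit.fingerprint import AA_ALPHABET
from fanzorkit.profile_search import (
    build_profile,
    calibrate_threshold,
    iterative_search,
    multi_profile_filter,
    search,
    _score_matrix,
)
from fanzorkit.synthetic_data import gen_homolog_ladder
from oracles import oracle_local_alignment


def _random_rows(rng, n, length):
    return ["".join(rng.choice(list(AA_ALPHABET), size=length)) for _ in range(n)]


class TestBuildProfile:
    def test_identical_rows_closed_form(self):
        prof = build_profile(["ACD"] * 4, pseudocount_weight=0.0)
        for i, res in enumerate("ACD"):
            k = AA_ALPHABET.index(res)
            assert prof.log_odds[i, k] == pytest.approx(math.log2(20.0))

    def test_all_gap_column_masked(self):
        prof = build_profile(["A-C", "A-C", "A-C"])
        assert list(prof.kept_columns) == [0, 2]
        assert not prof.occupancy_mask[1]

    def test_occupancy_cutoff_boundary(self):
        # 1 gap in 2 rows = occupancy 0.5, kept at the default cutoff
        prof = build_profile(["AC", "A-"])
        assert list(prof.kept_columns) == [0, 1]

    def test_formula_matches_cell_by_cell_oracle(self):
        rng = np.random.default_rng(3)
        rows = _random_rows(rng, 5, 8)
        rows[2] = rows[2][:3] + "-" + rows[2][4:]
        beta, q = 1.5, 1.0 / 20
        prof = build_profile(rows, pseudocount_weight=beta)
        for col_idx, col in enumerate(prof.kept_columns):
            residues = [r[col] for r in rows if r[col] != "-"]
            for k, a in enumerate(AA_ALPHABET):
                c = residues.count(a)
                expected = math.log2(((c + beta * q) / (len(residues) + beta)) / q)
                assert prof.log_odds[col_idx, k] == pytest.approx(expected, abs=1e-12)

    def test_ragged_alignment_raises(self):
        with pytest.raises(ValueError, match="ragged"):
            build_profile(["ACD", "AC"])


class TestSearch:
    def test_consensus_reaches_perfect_match_bound(self):
        rng = np.random.default_rng(4)
        prof = build_profile(_random_rows(rng, 6, 12))
        hit = search(prof, prof.consensus())
        assert hit.score == pytest.approx(prof.max_score())
        assert hit.profile_interval == (0, prof.n_columns)
        assert hit.aligned_segment == prof.consensus()

    def test_no_hit_below_threshold(self):
        prof = build_profile(["ACDEF"] * 3)
        assert search(prof, "WWWWW", threshold=1.0) is None

    def test_scores_match_bounded_gap_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            prof = build_profile(_random_rows(rng, 4, int(rng.integers(4, 11))))
            seq = "".join(rng.choice(list(AA_ALPHABET), size=int(rng.integers(10, 31))))
            S = _score_matrix(prof, seq)
            expected = oracle_local_alignment(S, -8.0, -1.0)
            hit = search(prof, seq, threshold=-1e9)
            got = hit.score if hit else 0.0
            assert got == pytest.approx(expected, abs=1e-9)

    def test_gapped_homolog_traceback(self):
        rng = np.random.default_rng(6)
        rows = _random_rows(rng, 5, 20)
        prof = build_profile(rows)
        consensus = prof.consensus()
        # delete two consensus residues: alignment must gap two columns
        seq = consensus[:8] + consensus[10:]
        hit = search(prof, seq)
        assert hit is not None
        assert hit.aligned_segment.count("-") == 2
        assert len(hit.aligned_segment) == prof.n_columns

    def test_positive_gap_penalties_rejected(self):
        prof = build_profile(["ACD"] * 2)
        with pytest.raises(ValueError):
            search(prof, "ACD", gap_open=1.0)


class TestCalibration:
    def test_quantile_one_is_max_decoy_score(self):
        rng = np.random.default_rng(7)
        rows = _random_rows(rng, 5, 15)
        prof = build_profile(rows)
        scores = []
        check_rng = np.random.default_rng(123)
        for s in range(100):
            tpl = rows[s % len(rows)]
            decoy = "".join(check_rng.permutation(list(tpl)))
            h = search(prof, decoy, threshold=-np.inf)
            scores.append(h.score if h else 0.0)
        thr = calibrate_threshold(prof, rows, n_shuffles=100, quantile=1.0, seed=123)
        assert thr == pytest.approx(max(scores))

    def test_null_controls_decoy_pass_rate(self):
        rng = np.random.default_rng(8)
        rows = _random_rows(rng, 5, 20)
        prof = build_profile(rows)
        thr = calibrate_threshold(prof, rows, n_shuffles=200, quantile=0.999, seed=1)
        passes = 0
        decoy_rng = np.random.default_rng(2)
        for _ in range(200):
            decoy = "".join(decoy_rng.choice(list(AA_ALPHABET), size=20))
            h = search(prof, decoy, threshold=thr)
            passes += h is not None
        assert passes <= 2

    def test_too_few_shuffles_rejected(self):
        prof = build_profile(["ACDEF"] * 3)
        with pytest.raises(ValueError):
            calibrate_threshold(prof, ["ACDEF"], n_shuffles=10)


class TestMultiProfileFilter:
    def _three_domain_setup(self, rng):
        domains = {name: _random_rows(rng, 4, 15) for name in ("ZF", "RuvC2", "RuvC3")}
        profiles = {n: build_profile(rows) for n, rows in domains.items()}
        thresholds = {
            n: calibrate_threshold(p, domains[n], n_shuffles=100, quantile=1.0, seed=0)
            for n, p in profiles.items()
        }
        positive = "".join(profiles[n].consensus() for n in ("RuvC2", "ZF", "RuvC3"))
        return profiles, thresholds, positive

    def test_full_domain_positive_passes(self):
        rng = np.random.default_rng(9)
        profiles, thresholds, positive = self._three_domain_setup(rng)
        ok, hits = multi_profile_filter(positive, profiles, thresholds)
        assert ok
        starts = [h.seq_interval[0] for h in hits.values()]
        assert starts == sorted(starts)

    def test_scrambled_domain_fails(self):
        rng = np.random.default_rng(9)
        profiles, thresholds, positive = self._three_domain_setup(rng)
        scrambled = positive[:30] + "".join(
            np.random.default_rng(1).permutation(list(positive[30:45]))
        ) + positive[45:]
        ok, _ = multi_profile_filter(scrambled, profiles, thresholds)
        assert not ok


class TestIterativeSearch:
    def test_seed_database_is_fixed_point(self):
        rng = np.random.default_rng(10)
        rows = _random_rows(rng, 5, 30)
        aln = [(f"s{i}", r) for i, r in enumerate(rows)]
        history = iterative_search(aln, aln, rounds=5, seed=0)
        assert history[0].hit_ids == {f"s{i}" for i in range(5)}
        for st in history[1:]:
            assert st.hit_ids == history[0].hit_ids
        assert len(history[-1].alignment) == 5  # seed ids never re-added

    def test_hit_sets_monotone_and_recall_improves(self):
        seed_aln, db, truth = gen_homolog_ladder(seed=3)
        history = iterative_search(seed_aln, db, rounds=5, seed=3)
        for prev, cur in zip(history, history[1:]):
            assert prev.hit_ids <= cur.hit_ids
        rung40 = [i for i, l in truth.identity_of.items() if l == 0.4]
        recall = lambda st: sum(i in st.hit_ids for i in rung40) / len(rung40)
        assert recall(history[4]) >= recall(history[0])

    def test_row_cap_enforced(self):
        rng = np.random.default_rng(12)
        rows = _random_rows(rng, 5, 20)
        aln = [(f"s{i}", r) for i, r in enumerate(rows)]
        db = [(f"d{i}", rows[0]) for i in range(20)]
        with pytest.raises(RuntimeError, match="row cap"):
            iterative_search(aln, db, rounds=1, threshold=1.0, row_cap=10)
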