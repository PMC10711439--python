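"""Iterative position-specific scoring matrix (PSSM) homolog search.

Emulates the iterative profile-augmentation strategy used to pull
divergent homologs out of a database from a seed alignment of conserved
subdomains: build a profile from the alignment, search every database
sequence by local alignment, add the aligned segments of new hits back
into the alignment, rebuild, and repeat for a fixed number of rounds
(five by default).

The profile is a per-column log-odds matrix in bits,

    log_odds[i][a] = log2( ((c_ia + beta * q_a) / (N_i + beta)) / q_a )

with c_ia the count of residue a in column i over non-gap rows, N_i the
non-gap count, beta a pseudocount weight and q_a the background
frequency.  Columns with occupancy below a cutoff are masked out of the
search.  Local alignment uses affine gap penalties with deterministic
traceback (diagonal > up > left).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fingerprint import AA_ALPHABET

GAP_CHARS = frozenset("-.")
_NEG = -1e30


@dataclass
class Profile:
    """Log-odds profile over the retained (well-occupied) alignment columns."""

    length: int                       # columns in the source alignment
    log_odds: np.ndarray              # (n_kept, n_alphabet) bits
    kept_columns: np.ndarray          # alignment-column index per profile column
    occupancy_mask: np.ndarray        # bool per alignment column
    background: np.ndarray
    pseudocount_weight: float
    alphabet: str = AA_ALPHABET

    @property
    def n_columns(self) -> int:
        return int(self.log_odds.shape[0])

    def consensus(self) -> str:
        return "".join(self.alphabet[int(j)] for j in np.argmax(self.log_odds, axis=1))

    def max_score(self) -> float:
        """Perfect-match bound: sum of per-column maxima."""
        return float(np.max(self.log_odds, axis=1).sum())


@dataclass
class SearchHit:
    sequence_id: str
    score: float
    seq_interval: tuple[int, int]
    profile_interval: tuple[int, int]
    aligned_segment: str              # one char per profile column in the interval


@dataclass
class IterationState:
    round_index: int
    alignment: list[tuple[str, str]]
    hit_ids: frozenset[str]
    new_hits: tuple[str, ...] = ()


def build_profile(
    alignment: list[tuple[str, str]] | list[str],
    pseudocount_weight: float = 1.0,
    background: np.ndarray | None = None,
    occupancy_cutoff: float = 0.5,
    alphabet: str = AA_ALPHABET,
) -> Profile:
    """Column-wise log-odds profile from a gapped alignment.

    Raises on ragged alignments or fewer than two rows.  With
    ``pseudocount_weight`` 0 an unobserved residue scores -inf; the
    default Laplace-style weight of 1 keeps every score finite.
    """
    rows = [r[1] if isinstance(r, tuple) else r for r in alignment]
    if len(rows) < 2:
        raise ValueError("alignment needs at least two rows")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("ragged alignment")
    if background is None:
        background = np.full(len(alphabet), 1.0 / len(alphabet))
    background = np.asarray(background, dtype=float)
    if not np.isclose(background.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")

    aa_index = {a: k for k, a in enumerate(alphabet)}
    counts = np.zeros((length, len(alphabet)))
    nongap = np.zeros(length)
    for row in rows:
        for i, ch in enumerate(row):
            if ch in GAP_CHARS:
                continue
            nongap[i] += 1
            k = aa_index.get(ch)
            if k is not None:
                counts[i, k] += 1

    occupancy = nongap / len(rows)
    mask = occupancy >= occupancy_cutoff
    kept = np.flatnonzero(mask)
    if kept.size == 0:
        raise ValueError("no column passes the occupancy cutoff")
    beta = float(pseudocount_weight)
    with np.errstate(divide="ignore"):
        freq = (counts[kept] + beta * background) / (nongap[kept, None] + beta)
        log_odds = np.log2(freq / background)
    return Profile(
        length=length,
        log_odds=log_odds,
        kept_columns=kept,
        occupancy_mask=mask,
        background=background,
        pseudocount_weight=beta,
        alphabet=alphabet,
    )


def _score_matrix(profile: Profile, seq: str) -> np.ndarray:
    """(len(seq), n_columns) match scores; unknown residues score the
    expectation under the background (0 bits against any column)."""
    aa_index = {a: k for k, a in enumerate(profile.alphabet)}
    n, m = len(seq), profile.n_columns
    S = np.zeros((n, m))
    for i, ch in enumerate(seq):
        k = aa_index.get(ch)
        if k is not None:
            S[i] = profile.log_odds[:, k]
    return S


def _fill_dp(S: np.ndarray, gap_open: float, gap_extend: float):
    """Affine local alignment matrices (Gotoh, gap-to-gap allowed)."""
    n, m = S.shape
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), _NEG)   # gap in profile: consume sequence
    Iy = np.full((n + 1, m + 1), _NEG)   # gap in sequence: consume column
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        best_prev = np.maximum(M[i - 1], np.maximum(Ix[i - 1], Iy[i - 1]))
        M[i, 1:] = np.maximum(best_prev[:-1], 0.0) + S[i - 1]
        Ix[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:], Iy[i - 1, 1:]) + gap_open,
            Ix[i - 1, 1:] + gap_extend,
        )
        # Iy[i, j] = max over k < j of (max(M[i,k], Ix[i,k]) + open + (j-1-k)*ext)
        src = np.maximum(M[i], Ix[i]) + gap_open - gap_extend * js
        src[0] = _NEG  # a local alignment cannot start inside a gap
        run = np.maximum.accumulate(src)
        Iy[i, 1:] = run[:-1] + gap_extend * (js[1:] - 1)
    return M, Ix, Iy


def _traceback(
    S: np.ndarray,
    M: np.ndarray,
    Ix: np.ndarray,
    Iy: np.ndarray,
    gap_open: float,
    gap_extend: float,
    seq: str,
):
    """Deterministic traceback from the best M cell.

    Tie-break priority at every step is diagonal (M) > up (Ix, residue
    against a gap) > left (Iy, deleted profile column).  The first best M
    cell in row-major order is used when the maximum is not unique.
    """
    tol = 1e-6
    i, j = (int(x) for x in np.unravel_index(int(np.argmax(M)), M.shape))
    end_i, end_j = i, j
    state = "M"
    seg: list[tuple[int, str]] = []       # (profile col, char) for M/Iy steps
    while i > 0 and j > 0:
        if state == "M":
            seg.append((j - 1, seq[i - 1]))
            contribution = M[i, j] - S[i - 1, j - 1]
            i, j = i - 1, j - 1
            if contribution <= tol:
                break  # local alignment starts at this match
            if abs(M[i, j] - contribution) <= tol:
                state = "M"
            elif abs(Ix[i, j] - contribution) <= tol:
                state = "Ix"
            else:
                state = "Iy"
        elif state == "Ix":
            val = Ix[i, j]
            i -= 1
            if abs(M[i, j] + gap_open - val) <= tol:
                state = "M"
            elif abs(Ix[i, j] + gap_extend - val) <= tol:
                state = "Ix"
            else:
                state = "Iy"
        else:  # Iy
            seg.append((j - 1, "-"))
            val = Iy[i, j]
            j -= 1
            if abs(M[i, j] + gap_open - val) <= tol:
                state = "M"
            elif abs(Ix[i, j] + gap_open - val) <= tol:
                state = "Ix"
            else:
                state = "Iy"
    start_i, start_j = i, j
    seg.reverse()
    cols = [c for c, _ in seg]
    chars = [ch for _, ch in seg]
    return start_i, end_i, start_j, end_j, cols, chars


def search(
    profile: Profile,
    seq: str,
    sequence_id: str = "",
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
    threshold: float = 0.0,
) -> SearchHit | None:
    """Best local alignment of ``seq`` against the profile, or None.

    Scores are in bits; a score below ``threshold`` (or an empty optimal
    alignment) is reported as no hit.
    """
    if gap_open >= 0 or gap_extend >= 0:
        raise ValueError("gap penalties must be negative")
    if not seq:
        return None
    S = _score_matrix(profile, seq)
    M, Ix, Iy = _fill_dp(S, gap_open, gap_extend)
    best = float(M.max())
    if best <= 0.0 or best < threshold:
        return None
    si, ei, sj, ej, cols, chars = _traceback(S, M, Ix, Iy, gap_open, gap_extend, seq)
    return SearchHit(
        sequence_id=sequence_id,
        score=best,
        seq_interval=(si, ei),
        profile_interval=(sj, ej),
        aligned_segment="".join(chars),
    )


def calibrate_threshold(
    profile: Profile,
    template_seqs: list[str],
    n_shuffles: int = 1000,
    quantile: float = 0.999,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
    seed: int = 0,
) -> float:
    """Empirical-null inclusion threshold in bits.

    Shuffles the residues of the template sequences (cycling through
    them) ``n_shuffles`` times, records each decoy's best local-alignment
    score, and returns the requested quantile (1.0 gives the max decoy
    score).  Deterministic for a fixed seed.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles for a stable null")
    rng = np.random.default_rng(seed)
    scores = np.zeros(n_shuffles)
    for s in range(n_shuffles):
        tpl = template_seqs[s % len(template_seqs)]
        decoy = "".join(rng.permutation(list(tpl)))
        hit = search(profile, decoy, gap_open=gap_open, gap_extend=gap_extend,
                     threshold=-np.inf)
        scores[s] = hit.score if hit else 0.0
    return float(np.quantile(scores, quantile))


def multi_profile_filter(
    seq: str,
    profiles: dict[str, Profile],
    thresholds: dict[str, float],
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
) -> tuple[bool, dict[str, SearchHit | None]]:
    """True iff the sequence hits every profile above its threshold.

    Mirrors the multi-domain requirement for calling a putative homolog:
    hits against all conserved subdomains (e.g. ZF + RuvC2 + RuvC3) are
    required.  Per-profile hits come back ordered by position on the
    sequence.
    """
    hits: dict[str, SearchHit | None] = {}
    ok = True
    for name, prof in profiles.items():
        h = search(prof, seq, sequence_id=name, gap_open=gap_open,
                   gap_extend=gap_extend, threshold=thresholds[name])
        hits[name] = h
        if h is None:
            ok = False
    ordered = dict(
        sorted(hits.items(), key=lambda kv: kv[1].seq_interval[0] if kv[1] else 1 << 30)
    )
    return ok, ordered


def _segment_to_row(profile: Profile, hit: SearchHit) -> str:
    """Lift a hit's profile-coordinate segment into alignment coordinates.

    Residues land in the retained columns they aligned to; all other
    columns are gaps.  Insertions relative to the profile are dropped.
    """
    row = ["-"] * profile.length
    lo, hi = hit.profile_interval
    for offset, ch in enumerate(hit.aligned_segment):
        col = int(profile.kept_columns[lo + offset])
        if ch != "-":
            row[col] = ch
    return "".join(row)


def iterative_search(
    seed_alignment: list[tuple[str, str]],
    database: list[tuple[str, str]],
    rounds: int = 5,
    pseudocount_weight: float = 1.0,
    occupancy_cutoff: float = 0.5,
    gap_open: float = -8.0,
    gap_extend: float = -1.0,
    threshold: float | None = None,
    n_shuffles: int = 500,
    quantile: float = 0.999,
    row_cap: int = 10_000,
    seed: int = 0,
) -> list[IterationState]:
    """Round-based profile augmentation search.

    Per round: build a profile from the current alignment, search every
    database sequence, and append the aligned segment of each new hit as
    an alignment row.  The inclusion threshold is calibrated once on the
    seed profile (empirical null) unless given, and held fixed so the hit
    set can only grow.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    alignment = list(seed_alignment)
    seen = {rid for rid, _ in seed_alignment}
    hit_ids: set[str] = set()
    history: list[IterationState] = []

    for rnd in range(1, rounds + 1):
        profile = build_profile(alignment, pseudocount_weight,
                                occupancy_cutoff=occupancy_cutoff)
        if threshold is None:
            templates = [r.replace("-", "") for _, r in seed_alignment]
            threshold = calibrate_threshold(
                profile, templates, n_shuffles=n_shuffles, quantile=quantile,
                gap_open=gap_open, gap_extend=gap_extend, seed=seed,
            )
        new_ids = []
        for sid, s in database:
            hit = search(profile, s, sequence_id=sid, gap_open=gap_open,
                         gap_extend=gap_extend, threshold=threshold)
            if hit is None:
                continue
            hit_ids.add(sid)
            if sid not in seen:
                alignment.append((sid, _segment_to_row(profile, hit)))
                seen.add(sid)
                new_ids.append(sid)
                if len(alignment) > row_cap:
                    raise RuntimeError(f"alignment grew beyond row cap {row_cap}")
        history.append(
            IterationState(
                round_index=rnd,
                alignment=list(alignment),
                hit_ids=frozenset(hit_ids),
                new_hits=tuple(new_ids),
            )
        )
    return history
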