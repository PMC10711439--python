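"""Independent reference implementations used only to check the package.

These deliberately avoid the production code paths: the fingerprint
oracle walks regular expressions with explicit spacer enumeration, and
the alignment oracle enumerates local alignment paths recursively.
"""

from __future__ import annotations

import re

PHI = "ILFWYM"


def oracle_zf_starts(seq: str) -> list[tuple[int, int, int]]:
    """(c1, spacer1, spacer2) of every zinc-finger pattern match."""
    out = []
    for s1 in range(12, 19):
        for s2 in range(4, 9):
            pat = re.compile(rf"(?=C..C.{{{s1}}}C..C.{{{s2}}}D)")
            for m in pat.finditer(seq):
                out.append((m.start(), s1, s2))
    return sorted(set(out))


_P_FANZOR = re.compile(r"DPG.{120,160}E.{6}C..C.{12,18}C..C.{4,8}D")
_P_DPHIG = re.compile(rf"D[{PHI}]G.{{120,160}}E.{{6}}C..C.{{12,18}}C..C.{{4,8}}D")
_P_RUVC1 = re.compile(rf"(?=D[P{PHI}]G)")


def oracle_category(
    seq: str,
    ecan_window: tuple[int, int] = (35, 65),
) -> str:
    """Fingerprint category by direct regex enumeration."""
    if _P_FANZOR.search(seq):
        return "FANZOR_LIKE"
    if _P_DPHIG.search(seq):
        return "E_ALT_DPHIG"
    has_ruvc1 = bool(_P_RUVC1.search(seq))
    zf_c1s = sorted({c1 for c1, _, _ in oracle_zf_starts(seq)})
    alt = {c1 for c1 in zf_c1s if c1 >= 7 and seq[c1 - 7] == "E"}
    lo, hi = ecan_window
    can = {
        c1
        for c1 in zf_c1s
        if any(
            c1 - d >= 0 and c1 - d != c1 - 7 and seq[c1 - d] == "E"
            for d in range(lo, hi + 1)
        )
    }
    if has_ruvc1 and can:
        if not alt:
            return "CANONICAL"
        if any(c != a for c in can for a in alt):
            return "AMBIGUOUS"
    return "INCOMPLETE"


def oracle_local_alignment(S, gap_open: float, gap_extend: float,
                           max_gap_runs: int = 2) -> float:
    """Best local-alignment score over paths with at most ``max_gap_runs``
    gap openings (a gap-to-gap direction switch opens a new run).

    Enumerates partial paths by a memoized recursion over
    (cell, state, runs used) — a bounded-run state space distinct from
    an affine three-matrix formulation.  Only paths ending on a match
    count; the empty alignment scores 0.
    """
    from functools import cache

    n, m = S.shape
    NEG = float("-inf")

    @cache
    def g(i: int, j: int, state: str, runs: int) -> float:
        """Best score of a partial path ending at (i, j) in ``state``."""
        if state == "M":
            if i < 1 or j < 1:
                return NEG
            prev = [0.0,  # the path may start with this match
                    g(i - 1, j - 1, "M", runs),
                    g(i - 1, j - 1, "Ix", runs),
                    g(i - 1, j - 1, "Iy", runs)]
            return max(prev) + S[i - 1, j - 1]
        if state == "Ix":      # consumed sequence row i against a gap
            if i < 1 or runs < 1:
                return NEG
            cands = [g(i - 1, j, "Ix", runs) + gap_extend]
            cands.append(g(i - 1, j, "M", runs - 1) + gap_open)
            cands.append(g(i - 1, j, "Iy", runs - 1) + gap_open)
            return max(cands)
        if j < 1 or runs < 1:  # Iy: consumed profile column j against a gap
            return NEG
        cands = [g(i, j - 1, "Iy", runs) + gap_extend]
        cands.append(g(i, j - 1, "M", runs - 1) + gap_open)
        cands.append(g(i, j - 1, "Ix", runs - 1) + gap_open)
        return max(cands)

    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            for runs in range(max_gap_runs + 1):
                best = max(best, g(i, j, "M", runs))
    return best
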