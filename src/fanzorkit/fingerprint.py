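"""RuvC/Zinc-Finger motif fingerprinting of TnpB-family proteins.

TnpB-family nucleases (prokaryotic TnpBs and eukaryotic Fanzors) carry a
RuvC nuclease domain whose D-E-D catalytic triad is split over three
subdomains (RuvC1-3), plus a C-terminal zinc-finger (ZF) motif.  Two
sequence features separate the Fanzor lineage from ordinary TnpBs:

* RuvC1 is a ``DPG`` motif (catalytic aspartate, proline, glycine) rather
  than the typical ``DΦG`` where Φ is a bulky hydrophobic residue
  (Φ = I, L, F, W, Y, M).
* the RuvC2 catalytic glutamate sits six residues upstream of the first
  ZF cysteine ("alternative" placement, E_alt) instead of ~50 residues
  upstream ("canonical" placement, E_can).

This module finds the individual motifs with gap-constrained patterns
(``DPGx(120,160)ExxxxxxCxxCx(12,18)CxxCx(4,8)D``) and combines them into a
per-protein fingerprint category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

PHI = frozenset("ILFWYM")
"""Bulky hydrophobic residues accepted at the middle RuvC1 position (DΦG)."""

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# fingerprint categories, best first (used for multi-candidate resolution)
FANZOR_LIKE = "FANZOR_LIKE"
E_ALT_DPHIG = "E_ALT_DPHIG"
CANONICAL = "CANONICAL"
AMBIGUOUS = "AMBIGUOUS"
INCOMPLETE = "INCOMPLETE"
CATEGORIES = (FANZOR_LIKE, E_ALT_DPHIG, CANONICAL, AMBIGUOUS, INCOMPLETE)


@dataclass(frozen=True)
class ZincFingerMotif:
    """CxxCx(12,18)CxxCx(4,8)D match; all indices 0-based into the protein."""

    c1: int
    c2: int
    c3: int
    c4: int
    d_end: int

    @property
    def spacer1(self) -> int:
        """Residues strictly between the two CxxC blocks (c2..c3)."""
        return self.c3 - self.c2 - 1

    @property
    def spacer2(self) -> int:
        """Residues strictly between c4 and the terminal aspartate."""
        return self.d_end - self.c4 - 1


@dataclass(frozen=True)
class RuvC1Motif:
    """A D[P|Φ]G occurrence; ``motif_class`` is ``"DPG"`` or ``"DPhiG"``."""

    d_index: int
    middle: str

    @property
    def g_index(self) -> int:
        return self.d_index + 2

    @property
    def motif_class(self) -> str:
        return "DPG" if self.middle == "P" else "DPhiG"


@dataclass
class FingerprintCall:
    """Combined fingerprint for one protein.

    ``category`` follows the lineage logic: ``FANZOR_LIKE`` needs DPG +
    E_alt + ZF with a 120-160 residue RuvC1->E spacer; ``E_ALT_DPHIG`` is
    the same arrangement with a DΦG RuvC1; ``CANONICAL`` has an E in the
    canonical window upstream of the ZF and no alternative E; ``AMBIGUOUS``
    has both arrangements on different ZF motifs; anything missing a
    component is ``INCOMPLETE``.
    """

    category: str
    ruvc1: RuvC1Motif | None = None
    zf: ZincFingerMotif | None = None
    e_alt_index: int | None = None
    e_can_index: int | None = None
    spacer_ok: bool = False


def find_ruvc1(seq: str) -> list[RuvC1Motif]:
    """All D[P|Φ]G occurrences, ordered by position."""
    out = []
    for i in range(len(seq) - 2):
        if seq[i] == "D" and seq[i + 2] == "G":
            mid = seq[i + 1]
            if mid == "P" or mid in PHI:
                out.append(RuvC1Motif(d_index=i, middle=mid))
    return out


def find_zf_motifs(
    seq: str,
    spacer1_range: tuple[int, int] = (12, 18),
    spacer2_range: tuple[int, int] = (4, 8),
) -> list[ZincFingerMotif]:
    """All CxxCx(s1)CxxCx(s2)D matches, including overlapping ones.

    'X' (unknown residue) never satisfies the literal C/D positions; it is
    accepted at wildcard positions because those are unconstrained.
    """
    s1_lo, s1_hi = spacer1_range
    s2_lo, s2_hi = spacer2_range
    n = len(seq)
    cpos = [i for i, ch in enumerate(seq) if ch == "C"]
    cset = set(cpos)
    out = []
    for c1 in cpos:
        c2 = c1 + 3
        if c2 not in cset:
            continue
        for c3 in range(c2 + 1 + s1_lo, min(c2 + 1 + s1_hi, n - 4) + 1):
            if c3 not in cset or (c3 + 3) not in cset:
                continue
            c4 = c3 + 3
            for d_end in range(c4 + 1 + s2_lo, min(c4 + 1 + s2_hi, n - 1) + 1):
                if seq[d_end] == "D":
                    out.append(ZincFingerMotif(c1, c2, c3, c4, d_end))
    out.sort(key=lambda m: (m.c1, m.c3, m.d_end))
    return out


# offset of the alternative glutamate relative to the first ZF cysteine:
# E + six arbitrary residues + C  =>  E at c1 - 7
E_ALT_OFFSET = 7


def _e_alt_index(seq: str, zf: ZincFingerMotif) -> int | None:
    i = zf.c1 - E_ALT_OFFSET
    if i >= 0 and seq[i] == "E":
        return i
    return None


def _e_can_indices(
    seq: str, zf: ZincFingerMotif, window: tuple[int, int]
) -> list[int]:
    lo, hi = window
    alt = zf.c1 - E_ALT_OFFSET
    out = []
    for dist in range(lo, hi + 1):
        i = zf.c1 - dist
        if i >= 0 and i != alt and seq[i] == "E":
            out.append(i)
    return out


def _spacer_ok(ruvc1: RuvC1Motif, e_index: int, spacer_range: tuple[int, int]) -> bool:
    spacer = e_index - ruvc1.g_index - 1
    return spacer_range[0] <= spacer <= spacer_range[1]


def classify(
    seq: str,
    spacer_range: tuple[int, int] = (120, 160),
    ecan_window: tuple[int, int] = (35, 65),
    spacer1_range: tuple[int, int] = (12, 18),
    spacer2_range: tuple[int, int] = (4, 8),
) -> FingerprintCall:
    """Assign the fingerprint category for one protein sequence.

    All (RuvC1, E, ZF) combinations are evaluated and the best category
    under the order FANZOR_LIKE > E_ALT_DPHIG > CANONICAL > AMBIGUOUS >
    INCOMPLETE is reported, with the left-most combination breaking ties.
    """
    ruvc1s = find_ruvc1(seq)
    zfs = find_zf_motifs(seq, spacer1_range, spacer2_range)

    # full alternative-E arrangements, by RuvC1 class
    for wanted in ("DPG", "DPhiG"):
        for r in ruvc1s:
            if r.motif_class != wanted:
                continue
            for zf in zfs:
                e_alt = _e_alt_index(seq, zf)
                if e_alt is not None and e_alt > r.g_index and _spacer_ok(
                    r, e_alt, spacer_range
                ):
                    return FingerprintCall(
                        category=FANZOR_LIKE if wanted == "DPG" else E_ALT_DPHIG,
                        ruvc1=r,
                        zf=zf,
                        e_alt_index=e_alt,
                        spacer_ok=True,
                    )

    alt_zfs = [zf for zf in zfs if _e_alt_index(seq, zf) is not None]
    can_hits = [
        (zf, es[0]) for zf in zfs if (es := _e_can_indices(seq, zf, ecan_window))
    ]
    if ruvc1s and can_hits:
        if not alt_zfs:
            zf, e_can = can_hits[0]
            r = ruvc1s[0]
            return FingerprintCall(
                category=CANONICAL,
                ruvc1=r,
                zf=zf,
                e_can_index=e_can,
                spacer_ok=_spacer_ok(r, e_can, spacer_range),
            )
        for zf, e_can in can_hits:
            for alt_zf in alt_zfs:
                if alt_zf != zf:
                    return FingerprintCall(
                        category=AMBIGUOUS,
                        ruvc1=ruvc1s[0],
                        zf=zf,
                        e_alt_index=_e_alt_index(seq, alt_zf),
                        e_can_index=e_can,
                    )
    return FingerprintCall(
        category=INCOMPLETE,
        ruvc1=ruvc1s[0] if ruvc1s else None,
        zf=zfs[0] if zfs else None,
    )


def scan_database(
    seqs: Mapping[str, str] | Iterable[tuple[str, str]],
    **classify_kwargs,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify every sequence and report per-category fractions.

    Returns a table (one row per sequence) and a fraction dict covering
    *all* categories (empty ones reported as 0.0, summing to 1).
    Raises on duplicate sequence identifiers or empty input.
    """
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    if not items:
        raise ValueError("scan_database requires a non-empty input")
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence identifiers: {dupes}")

    rows = []
    for sid, seq in items:
        call = classify(seq, **classify_kwargs)
        rows.append(
            {
                "id": sid,
                "category": call.category,
                "ruvc1_d": call.ruvc1.d_index if call.ruvc1 else None,
                "ruvc1_class": call.ruvc1.motif_class if call.ruvc1 else None,
                "zf_c1": call.zf.c1 if call.zf else None,
                "zf_d_end": call.zf.d_end if call.zf else None,
                "e_alt": call.e_alt_index,
                "e_can": call.e_can_index,
                "spacer_ok": call.spacer_ok,
            }
        )
    table = pd.DataFrame(rows)
    n = len(table)
    fractions = {
        cat: float((table["category"] == cat).sum()) / n for cat in CATEGORIES
    }
    return table, fractions
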