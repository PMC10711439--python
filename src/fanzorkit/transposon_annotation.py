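"""Transposon locus curation and IS-family assignment.

Covers the boundary features that distinguish transposon families hosting
TnpB/Fanzor genes: target site duplications (TSDs) and terminal inverted
repeats (TIRs) of eukaryotic cut-and-paste DNA transposons, and the GG
crossover dinucleotides of IS607 elements (which insert by serine-
recombinase crossover between GG motifs and therefore leave no TSD).
IS family is called from domain annotations of the neighbouring TnpA gene.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


IS200_605 = "IS200_605"
IS607 = "IS607"
UNCLASSIFIED = "UNCLASSIFIED"
CONFLICT = "CONFLICT"

# domain labels (names and accessions) that mark each transposase family
_IS200_605_LABELS = {
    "y1_tnp", "pfam01797", "y1_tnp_superfamily", "cl00848",
    "transpos_is200", "nf033573",
}
_IS607_LABELS = {
    "transpos_is607", "nf033518", "transpos_is607_superfamily", "cl41297",
    "resolvase", "cl02788", "recombinase", "cl06512",
}


@dataclass
class ISFamilyCall:
    family: str
    evidence: frozenset[str]


@dataclass
class TirCall:
    left: tuple[int, int]       # element-relative, half-open
    right: tuple[int, int]
    mismatches: int
    length: int


@dataclass
class TransposonLocus:
    locus_id: str
    sequence: str
    element_interval: tuple[int, int]
    tsd: str | None = None
    tirs: TirCall | None = None
    gg_boundaries: tuple[bool, bool] | None = None

    @property
    def le(self) -> int:
        return self.element_interval[0]

    @property
    def re(self) -> int:
        return self.element_interval[1]

    @property
    def left_flank(self) -> str:
        return self.sequence[: self.le]

    @property
    def right_flank(self) -> str:
        return self.sequence[self.re:]


def _normalize_label(label: str) -> str:
    return label.strip().lower().replace(" ", "_")


def classify_is_family(neighbor_domain_labels: set[str] | list[str]) -> ISFamilyCall:
    """Assign IS200/605 vs IS607 from neighbour-gene domain labels.

    Labels are matched case-insensitively by name or accession.  A locus
    matching both family sets is a CONFLICT; matching neither leaves the
    element UNCLASSIFIED (no TnpA partner to categorize by).
    """
    norm = {_normalize_label(x) for x in neighbor_domain_labels}
    hit_200 = norm & _IS200_605_LABELS
    hit_607 = norm & _IS607_LABELS
    if hit_200 and hit_607:
        return ISFamilyCall(CONFLICT, frozenset(hit_200 | hit_607))
    if hit_200:
        return ISFamilyCall(IS200_605, frozenset(hit_200))
    if hit_607:
        return ISFamilyCall(IS607, frozenset(hit_607))
    return ISFamilyCall(UNCLASSIFIED, frozenset())


def detect_tsd(
    insertion_allele: str,
    element_interval: tuple[int, int],
    k_min: int = 2,
    k_max: int = 15,
) -> str | None:
    """Longest exact direct repeat flanking the element (k in [k_min, k_max]).

    Returns the duplicated k-mer immediately 5' of the element that equals
    the k-mer immediately 3' of it, or None if no length matches.
    """
    start, stop = element_interval
    if start < k_max or len(insertion_allele) - stop < k_max:
        raise ValueError(f"flanks shorter than k_max={k_max}")
    for k in range(k_max, k_min - 1, -1):
        if insertion_allele[start - k:start] == insertion_allele[stop:stop + k]:
            return insertion_allele[start - k:start]
    return None


def verify_empty_site(
    insertion_allele: str,
    element_interval: tuple[int, int],
    tsd: str,
    empty_allele: str,
) -> bool:
    """True iff excising the element plus one TSD copy reproduces the empty allele.

    Both excision choices (drop the left or the right TSD copy) are tested;
    either exact reconstruction counts.
    """
    start, stop = element_interval
    k = len(tsd)
    drop_right = insertion_allele[:start] + insertion_allele[stop + k:]
    drop_left = insertion_allele[: start - k] + insertion_allele[stop:]
    return empty_allele in (drop_right, drop_left)


def detect_tir(
    element_seq: str,
    window: int = 50,
    min_len: int = 8,
    max_mismatch_frac: float = 0.2,
) -> TirCall | None:
    """Best (possibly degenerate) terminal inverted repeat pair.

    Scans every segment pair of equal length >= min_len inside the first
    and last ``window`` nucleotides, comparing the left segment to the
    reverse complement of the right one.  Candidate pairs must satisfy the
    mismatch-fraction cap; among those the alignment-style score
    (matches - mismatches) is maximised so chance agreements in flanking
    sequence cannot over-extend a repeat.  Ties prefer longer repeats,
    then smaller offsets.
    """
    n = len(element_seq)
    if n < 2 * window:
        raise ValueError("element shorter than twice the terminal window")
    left_win = np.frombuffer(element_seq[:window].encode(), dtype=np.uint8)
    right_rc = _revcomp(element_seq[n - window:])
    right_win = np.frombuffer(right_rc.encode(), dtype=np.uint8)

    best = None  # ((score, length, -a, -b), a, b, length, mism)
    for length in range(window, min_len - 1, -1):
        for a in range(window - length + 1):
            seg_l = left_win[a:a + length]
            # position b (from the right end): right segment in rc coordinates
            for b in range(window - length + 1):
                matches = int(np.count_nonzero(seg_l == right_win[b:b + length]))
                mism = length - matches
                if mism / length > max_mismatch_frac:
                    continue
                key = (matches - mism, length, -a, -b)
                if best is None or key > best[0]:
                    best = (key, a, b, length, mism)
    if best is None:
        return None
    _, a, b, length, mism = best
    # b counts from the element's right end in reverse-complement space:
    # rc index b corresponds to element interval [n - window + (window-length-b), ...)
    right_start = n - b - length
    return TirCall(
        left=(a, a + length),
        right=(right_start, right_start + length),
        mismatches=mism,
        length=length,
    )


def check_is607_boundaries(locus: TransposonLocus) -> tuple[bool, bool]:
    """GG flags at LE and RE (element-terminal dinucleotides)."""
    element = locus.sequence[locus.le:locus.re]
    return element[:2] == "GG", element[-2:] == "GG"


def find_element_copies(
    genome: str,
    element_seq: str,
    min_identity: float = 0.9,
    seed_k: int = 16,
    flank: int = 2000,
) -> list[dict]:
    """Ungapped seed-and-extend search for additional element copies.

    Exact ``seed_k``-mers of the element anchor candidate placements; each
    candidate is scored by full-length ungapped identity and kept at
    >= min_identity.  Hits report element coordinates plus 2 kb flanking
    intervals clipped at the contig ends.
    """
    m = len(element_seq)
    if len(genome) < m:
        raise ValueError("genome shorter than the element")
    index: dict[str, list[int]] = {}
    for off in range(0, m - seed_k + 1, seed_k):
        index.setdefault(element_seq[off:off + seed_k], []).append(off)
    candidates = set()
    for p in range(len(genome) - seed_k + 1):
        kmer = genome[p:p + seed_k]
        for off in index.get(kmer, ()):
            start = p - off
            if 0 <= start <= len(genome) - m:
                candidates.add(start)
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    e = np.frombuffer(element_seq.encode(), dtype=np.uint8)
    hits = []
    for start in sorted(candidates):
        ident = float(np.count_nonzero(g[start:start + m] == e)) / m
        if ident >= min_identity:
            hits.append(
                {
                    "interval": (start, start + m),
                    "identity": ident,
                    "flanked_interval": (max(0, start - flank), min(len(genome), start + m + flank)),
                }
            )
    return hits


def infer_element_interval(
    insertion_allele: str, empty_allele: str, k_max: int = 15
) -> tuple[tuple[int, int], str | None]:
    """Locate the inserted element by comparing insertion and empty alleles.

    Left-aligns the insertion at the longest common prefix of the two
    alleles, then resolves the framing: a direct repeat of length k
    (3..k_max) flanking the candidate element marks a TSD; a shared GG at
    both candidate ends marks an IS607-style crossover junction (checked
    before the degenerate k=2 repeat, which a GG junction mimics).
    Returns (element_interval in the insertion allele, tsd or None).
    """
    L = len(insertion_allele) - len(empty_allele)
    if L <= 0:
        raise ValueError("insertion allele is not longer than the empty allele")
    p = 0
    while p < len(empty_allele) and insertion_allele[p] == empty_allele[p]:
        p += 1
    for k in range(min(k_max, p, L - 1), 2, -1):
        if insertion_allele[p - k:p] == insertion_allele[p + L - k:p + L]:
            return (p, p + L - k), insertion_allele[p - k:p]
    if p >= 2 and insertion_allele[p - 2:p] == "GG" == insertion_allele[p + L - 2:p + L]:
        return (p - 2, p + L), None
    if p >= 2 and L > 2 and insertion_allele[p - 2:p] == insertion_allele[p + L - 2:p + L]:
        return (p, p + L - 2), insertion_allele[p - 2:p]
    return (p, p + L), None


def annotate_locus(
    locus_id: str,
    insertion_allele: str,
    element_interval: tuple[int, int],
    empty_allele: str | None = None,
    tir_window: int = 50,
) -> TransposonLocus:
    """Full curation of one locus: TSD, TIRs, GG boundary flags."""
    locus = TransposonLocus(locus_id, insertion_allele, element_interval)
    locus.tsd = detect_tsd(insertion_allele, element_interval)
    element = insertion_allele[element_interval[0]:element_interval[1]]
    if len(element) >= 2 * tir_window:
        locus.tirs = detect_tir(element, window=tir_window)
    locus.gg_boundaries = check_is607_boundaries(locus)
    if empty_allele is not None and locus.tsd is not None:
        if not verify_empty_site(insertion_allele, element_interval, locus.tsd, empty_allele):
            locus.tsd = None  # repeat not supported by the empty site
    return locus
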