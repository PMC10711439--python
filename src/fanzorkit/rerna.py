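"""reRNA boundary mapping and pseudoknot complementarity checks.

TnpB/Fanzor loci transcribe a right-end RNA (reRNA) across the transposon
right end: a structured scaffold followed by a guide region read from the
flanking DNA.  Mapping merged small-RNA reads onto the locus gives a
coverage profile whose plateau delimits the expressed reRNA; the called
boundary is compared against transposon features (RE, TSD) to measure how
far the scaffold extends past them.  A separate check scores Watson-Crick
/ G:U complementarity between the nucleotides flanking the guide region
and an apical loop segment — the pseudoknot interaction required for
nuclease activity — including the compensatory-mutation logic used to
validate it (disrupt one partner, rescue with the other).

Coordinates are 0-based half-open; RNA (U) and DNA (T) spellings are both
accepted and the input alphabet is preserved in outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ReRNAProfile:
    locus_id: str
    coverage: np.ndarray
    n_mapped: int
    n_unmapped: int
    n_ambiguous: int                # discarded multi-placement reads
    called_interval: tuple[int, int] | None = None

    @property
    def plateau(self) -> float:
        nz = self.coverage[self.coverage > 0]
        if nz.size == 0:
            raise ValueError("all-zero coverage; nothing was mapped")
        return float(np.median(nz))


@dataclass
class BoundaryCall:
    interval: tuple[int, int]
    secondary: list[tuple[int, int]]
    threshold: float


@dataclass
class PKAnnotation:
    region_a: tuple[int, int]
    region_b: tuple[int, int]
    paired: list[tuple[int, int, str]]   # (posA, posB, "WC" | "GU" | "none")

    @property
    def n_wc(self) -> int:
        return sum(1 for _, _, c in self.paired if c == "WC")

    @property
    def n_gu(self) -> int:
        return sum(1 for _, _, c in self.paired if c == "GU")


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def map_reads(
    reads: list[str],
    locus: str,
    locus_id: str = "locus",
    seed_k: int = 12,
    max_mismatch: int = 2,
) -> ReRNAProfile:
    """Seed-and-extend placement of reads on the forward strand.

    Candidate placements come from any exact ``seed_k``-mer shared between
    read and locus; a placement is accepted with <= ``max_mismatch``
    substitutions over the full read.  A read with several equally good
    placements is discarded as ambiguous; coverage counts each mapped
    read once over its span.
    """
    loc = _norm(locus)
    if len(loc) < seed_k:
        raise ValueError("locus shorter than the seed length")
    index: dict[str, list[int]] = {}
    for p in range(len(loc) - seed_k + 1):
        index.setdefault(loc[p:p + seed_k], []).append(p)
    larr = np.frombuffer(loc.encode(), dtype=np.uint8)

    coverage = np.zeros(len(loc), dtype=np.int64)
    n_mapped = n_unmapped = n_ambiguous = 0
    for read in reads:
        r = _norm(read)
        if len(r) < seed_k or len(r) > len(loc):
            n_unmapped += 1
            continue
        rarr = np.frombuffer(r.encode(), dtype=np.uint8)
        candidates = set()
        for off in range(0, len(r) - seed_k + 1):
            for p in index.get(r[off:off + seed_k], ()):
                start = p - off
                if 0 <= start <= len(loc) - len(r):
                    candidates.add(start)
        best_mm, best_starts = None, []
        for start in sorted(candidates):
            mm = int(np.count_nonzero(larr[start:start + len(r)] != rarr))
            if mm > max_mismatch:
                continue
            if best_mm is None or mm < best_mm:
                best_mm, best_starts = mm, [start]
            elif mm == best_mm:
                best_starts.append(start)
        if best_mm is None:
            n_unmapped += 1
        elif len(best_starts) > 1:
            n_ambiguous += 1
        else:
            n_mapped += 1
            s = best_starts[0]
            coverage[s:s + len(r)] += 1
    return ReRNAProfile(
        locus_id=locus_id,
        coverage=coverage,
        n_mapped=n_mapped,
        n_unmapped=n_unmapped,
        n_ambiguous=n_ambiguous,
    )


def call_boundaries(profile: ReRNAProfile, frac: float = 0.5) -> BoundaryCall:
    """Boundary of the expressed interval from the coverage plateau.

    Threshold = ``frac`` x (median of non-zero coverage).  The called
    interval is the maximal contiguous run of positions at or above the
    threshold that contains the coverage maximum; other runs are reported
    as secondary.  The result is stored on the profile as well.
    """
    cov = profile.coverage
    if not np.any(cov > 0):
        raise ValueError("all-zero coverage; cannot call boundaries")
    threshold = frac * profile.plateau
    above = cov >= threshold
    # contiguous runs of True
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = [(int(edges[k]), int(edges[k + 1])) for k in range(0, len(edges), 2)]
    peak = int(np.argmax(cov))
    primary = next(r for r in runs if r[0] <= peak < r[1])
    secondary = [r for r in runs if r != primary]
    profile.called_interval = primary
    return BoundaryCall(interval=primary, secondary=secondary, threshold=threshold)


def extension_beyond(
    called_interval: tuple[int, int], feature_coord: int, side: str = "right"
) -> int:
    """Signed distance from a feature coordinate to the called boundary.

    Positive values mean the called interval extends past the feature,
    away from the element: on the right side this is
    ``called_end - feature_coord``; on the left, ``feature_coord -
    called_start``.
    """
    start, stop = called_interval
    if side == "right":
        return stop - feature_coord
    if side == "left":
        return feature_coord - start
    raise ValueError("side must be 'left' or 'right'")


_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def pk_check(
    seq: str, region_a: tuple[int, int], region_b: tuple[int, int]
) -> PKAnnotation:
    """Antiparallel pairing between two annotated regions.

    Region A (the nucleotides flanking the guide region) position i is
    paired with region B (the apical loop) position n-1-i; each pair is
    classed Watson-Crick (A:U, G:C), G:U wobble, or unpaired.  Regions
    must be equal length and non-overlapping.
    """
    (a0, a1), (b0, b1) = region_a, region_b
    if a1 - a0 != b1 - b0:
        raise ValueError("regions must have equal length")
    if max(a0, b0) < min(a1, b1):
        raise ValueError("regions overlap")
    s = _norm(seq)
    n = a1 - a0
    paired = []
    for i in range(n):
        pa = a0 + i
        pb = b0 + (n - 1 - i)
        duo = (s[pa], s[pb])
        if duo in _WC:
            cls = "WC"
        elif duo in _GU:
            cls = "GU"
        else:
            cls = "none"
        paired.append((pa, pb, cls))
    return PKAnnotation(region_a=region_a, region_b=region_b, paired=paired)


_MUT_RE = re.compile(r"^([ACGUT])(-?\d+)([ACGUT])$")


def apply_mutation(seq: str, spec: str, guide_start: int) -> str:
    """Apply a point mutation named like ``U-130A`` or ``A-3U``.

    The signed position is relative to the first guide nucleotide:
    position -k is ``guide_start - k`` (so -1 abuts the guide) and
    position +k is the k-th guide nucleotide.  The stated reference base
    is checked against the sequence (U/T equivalently) before
    substituting; the substituted base is written in the sequence's own
    alphabet (U for RNA input, T for DNA input).
    """
    m = _MUT_RE.match(spec.strip().upper())
    if not m:
        raise ValueError(f"cannot parse mutation spec {spec!r}")
    ref, pos, new = m.group(1), int(m.group(2)), m.group(3)
    if pos == 0:
        raise ValueError("position 0 is not defined; positions are signed")
    idx = guide_start - (-pos) if pos < 0 else guide_start + pos - 1
    if not (0 <= idx < len(seq)):
        raise ValueError(f"mutation {spec!r} falls outside the sequence")
    found = seq[idx]
    if _norm(found) != _norm(ref):
        raise ValueError(
            f"reference mismatch for {spec!r} at index {idx}: "
            f"expected {ref}, found {found}"
        )
    is_rna = "U" in seq.upper() and "T" not in seq.upper()
    new_base = new.replace("T", "U") if is_rna else new.replace("U", "T")
    return seq[:idx] + new_base + seq[idx + 1:]
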