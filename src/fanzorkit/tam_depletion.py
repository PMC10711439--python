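"""TAM depletion scoring from paired amplicon libraries.

In a TAM (transposon-associated motif) depletion assay, a plasmid library
carrying all 4^L randomized motifs next to a fixed target site is
challenged with the nuclease in vivo; motifs supporting cleavage are lost
from the surviving pool.  Comparing per-TAM frequencies between the input
library and the selected output gives a log2 depletion score per motif;
motifs at or above the selection threshold (default 5 bits, i.e. >= 32-fold
depletion) form the retained set summarised as a sequence-logo matrix.

Also provides the normalized-CFU readout of plasmid interference assays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _tam_index(tam_length: int) -> pd.Index:
    from itertools import product

    return pd.Index(["".join(p) for p in product(DNA, repeat=tam_length)])


@dataclass
class TamCounts:
    tam_length: int
    counts: pd.Series              # indexed by all 4^L TAM strings, zero-filled
    total_extracted: int
    n_discarded: int


@dataclass
class TamDepletionResult:
    freq_input: pd.Series
    freq_output: pd.Series
    depletion_score: pd.Series     # log2(f_in / f_out), positive = depleted
    retained_set: frozenset[str]
    threshold: float


@dataclass
class LogoMatrix:
    frequencies: pd.DataFrame      # position x base
    information: np.ndarray        # bits per position, I_j = 2 - H_j
    letter_heights: pd.DataFrame   # f_bj * I_j


@dataclass
class InterferenceResult:
    cfu_double: int
    cfu_single: int
    norm_cfu: float
    is_detection_limit: bool


def extract_tams(
    reads: Iterable[str],
    anchor: str,
    tam_length: int = 6,
    search_rc: bool = True,
    max_ambiguous_frac: float = 0.01,
) -> TamCounts:
    """Count the TAM immediately 5' of the anchor in every read.

    The anchor must match exactly; if absent on the forward strand and
    ``search_rc`` is set, the reverse complement of the read is searched.
    Reads lacking the anchor, lacking the full TAM context, containing N
    in the TAM, or containing the anchor more than once are discarded.
    Raises if more than ``max_ambiguous_frac`` of anchor-containing reads
    are ambiguous (multi-anchor), which indicates a bad amplicon design.
    """
    if len(anchor) < 10:
        raise ValueError("anchor must be at least 10 nt")
    counts: dict[str, int] = {}
    n_total = 0
    n_discarded = 0
    n_ambiguous = 0
    n_with_anchor = 0
    for read in reads:
        n_total += 1
        target = read
        pos = read.find(anchor)
        if pos < 0 and search_rc:
            target = _revcomp(read)
            pos = target.find(anchor)
        if pos < 0:
            n_discarded += 1
            continue
        n_with_anchor += 1
        if target.find(anchor, pos + 1) >= 0:
            n_ambiguous += 1
            n_discarded += 1
            continue
        if pos < tam_length:
            n_discarded += 1
            continue
        tam = target[pos - tam_length:pos]
        if "N" in tam:
            n_discarded += 1
            continue
        counts[tam] = counts.get(tam, 0) + 1
    if n_with_anchor and n_ambiguous / n_with_anchor > max_ambiguous_frac:
        raise ValueError(
            f"anchor occurs multiple times in {n_ambiguous}/{n_with_anchor} "
            "reads; ambiguous amplicon design"
        )
    idx = _tam_index(tam_length)
    series = pd.Series(0, index=idx, dtype=np.int64)
    extracted = pd.Series(counts, dtype=np.int64)
    series.loc[extracted.index] = extracted
    return TamCounts(
        tam_length=tam_length,
        counts=series,
        total_extracted=int(series.sum()),
        n_discarded=n_discarded,
    )


def depletion_scores(
    input_counts: TamCounts,
    output_counts: TamCounts,
    pseudocount: float = 1.0,
    threshold: float = 5.0,
) -> TamDepletionResult:
    """Per-TAM log2 depletion scores and the retained (depleted) set.

    Frequencies are pseudocounted, f(t) = (c_t + p) / (total + 4^L * p),
    so zero-count TAMs cannot produce infinite scores.  The score is
    log2(f_input / f_output): motifs lost from the output score positive,
    and the default threshold of 5 bits selects >= 32-fold depletion.
    """
    if input_counts.tam_length != output_counts.tam_length:
        raise ValueError("input and output TAM lengths differ")
    if input_counts.total_extracted == 0 or output_counts.total_extracted == 0:
        raise ValueError("cannot score depletion from an empty count table")
    n_tams = len(input_counts.counts)

    def _freq(tc: TamCounts) -> pd.Series:
        c = tc.counts.astype(float) + pseudocount
        return c / (tc.total_extracted + n_tams * pseudocount)

    f_in = _freq(input_counts)
    f_out = _freq(output_counts)
    score = np.log2(f_in / f_out)
    retained = frozenset(score.index[score >= threshold])
    return TamDepletionResult(
        freq_input=f_in,
        freq_output=f_out,
        depletion_score=score,
        retained_set=retained,
        threshold=threshold,
    )


def build_logo(retained_set: Iterable[str]) -> LogoMatrix:
    """Sequence-logo matrix of the retained TAM set.

    Unweighted per-position base frequencies, information content
    I_j = 2 - H_j bits, and letter heights f_bj * I_j.  Raises on an
    empty set (lower the depletion threshold to retain motifs).
    """
    tams = sorted(set(retained_set))
    if not tams:
        raise ValueError(
            "retained set is empty; no TAM met the depletion threshold "
            "(consider lowering it)"
        )
    length = len(tams[0])
    if any(len(t) != length for t in tams):
        raise ValueError("retained TAMs have unequal lengths")
    arr = np.array([list(t) for t in tams])
    freqs = np.zeros((length, 4))
    for k, base in enumerate(DNA):
        freqs[:, k] = (arr == base).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = 2.0 + plogp.sum(axis=1)          # I_j = 2 - H_j
    freq_df = pd.DataFrame(freqs, columns=list(DNA))
    heights = freq_df.mul(info, axis=0)
    return LogoMatrix(frequencies=freq_df, information=info, letter_heights=heights)


def norm_cfu(cfu_double: int, cfu_single: int) -> InterferenceResult:
    """Normalized colony-forming units of a plasmid-interference assay.

    norm_cfu = CFU(double antibiotic) / CFU(single antibiotic control).
    Zero colonies on the double plate are reported at the detection limit
    1 / cfu_single (an upper bound) and flagged.
    """
    if cfu_single <= 0:
        raise ValueError("single-antibiotic control CFU must be positive")
    if cfu_double < 0:
        raise ValueError("CFU counts cannot be negative")
    if cfu_double == 0:
        return InterferenceResult(cfu_double, cfu_single, 1.0 / cfu_single, True)
    return InterferenceResult(cfu_double, cfu_single, cfu_double / cfu_single, False)
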