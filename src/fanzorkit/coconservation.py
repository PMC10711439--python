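"""Co-conservation of paired transposase (TnpA) and nuclease (TnpB/Fanzor) genes.

If the two proteins encoded by a transposable element diverge together,
then for any two elements i1, i2 the TnpA-TnpA percent identity and the
TnpB-TnpB percent identity should be correlated across element pairs.
This module computes percent-identity matrices from alignments, the
per-pair (idA, idB) scatter, correlation statistics and a 2D histogram,
plus the occupancy-based column trimming used to restrict alignments to
well-conserved regions before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GAP_CHARS = ("-", ".")


def percent_identity(row_i: str, row_j: str) -> float:
    """Percent identity over columns where both rows are non-gap.

    One-sided and mutual gap columns are excluded from the denominator.
    Returns 0 (with a warning) when the rows share no columns.
    """
    if len(row_i) != len(row_j):
        raise ValueError("aligned rows must have equal gapped lengths")
    a = np.frombuffer(row_i.encode(), dtype=np.uint8)
    b = np.frombuffer(row_j.encode(), dtype=np.uint8)
    gap_codes = [ord(g) for g in GAP_CHARS]
    shared = ~(np.isin(a, gap_codes) | np.isin(b, gap_codes))
    n_shared = int(shared.sum())
    if n_shared == 0:
        warnings.warn("rows share no aligned columns; identity reported as 0")
        return 0.0
    return 100.0 * float(np.count_nonzero(a[shared] == b[shared])) / n_shared


def identity_matrix(msa: dict[str, str]) -> pd.DataFrame:
    """Symmetric percent-identity matrix (diagonal exactly 100)."""
    ids = list(msa)
    n = len(ids)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = percent_identity(msa[ids[i]], msa[ids[j]])
            vals[i, j] = vals[j, i] = v
    return pd.DataFrame(vals, index=ids, columns=ids)


def trim_columns(
    msa: dict[str, str], occupancy: float = 0.9
) -> tuple[dict[str, str], list[int]]:
    """Keep columns whose non-gap fraction is >= ``occupancy``.

    The stringent default (0.9) mirrors gap-threshold trimming used to
    retain only well-conserved alignment regions.  Returns the trimmed
    alignment and the kept-column map for coordinate lift-over; raises if
    no column survives.
    """
    rows = list(msa.values())
    if len(rows) < 2:
        raise ValueError("alignment needs at least two rows")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("ragged alignment")
    arr = np.array([list(r) for r in rows])
    nongap = ~np.isin(arr, list(GAP_CHARS))
    frac = nongap.sum(axis=0) / len(rows)
    kept = [int(c) for c in np.flatnonzero(frac >= occupancy)]
    if not kept:
        raise ValueError("no column passes the occupancy threshold")
    trimmed = {
        rid: "".join(row[c] for c in kept) for rid, row in msa.items()
    }
    return trimmed, kept


@dataclass
class CoconservationResult:
    pairs: pd.DataFrame          # columns: elem_1, elem_2, identity_a, identity_b
    pearson_r: float
    spearman_rho: float
    histogram2d: np.ndarray      # 20 x 20 counts over [0,100]^2


def paired_identities(
    msa_a: dict[str, str],
    msa_b: dict[str, str],
    pairing: dict[str, tuple[str, str]],
) -> CoconservationResult:
    """Per-element-pair identity couples and their correlation.

    ``pairing`` maps each element to its (row in msa_a, row in msa_b).
    Emits one (identity_a, identity_b) couple per unordered element pair
    (n(n-1)/2 couples), Pearson and Spearman correlations, and a fixed
    20x20 histogram over [0,100]^2.
    """
    for elem, (ra, rb) in pairing.items():
        if ra not in msa_a or rb not in msa_b:
            raise ValueError(f"element {elem!r} lacks a row in one alignment")
    elems = list(pairing)
    rows = []
    for i in range(len(elems)):
        for j in range(i + 1, len(elems)):
            e1, e2 = elems[i], elems[j]
            ida = percent_identity(msa_a[pairing[e1][0]], msa_a[pairing[e2][0]])
            idb = percent_identity(msa_b[pairing[e1][1]], msa_b[pairing[e2][1]])
            rows.append({"elem_1": e1, "elem_2": e2,
                         "identity_a": ida, "identity_b": idb})
    pairs = pd.DataFrame(rows)
    r = float(stats.pearsonr(pairs["identity_a"], pairs["identity_b"])[0])
    rho = float(stats.spearmanr(pairs["identity_a"], pairs["identity_b"])[0])
    hist, _, _ = np.histogram2d(
        pairs["identity_a"], pairs["identity_b"],
        bins=20, range=[[0, 100], [0, 100]],
    )
    return CoconservationResult(pairs=pairs, pearson_r=r,
                                spearman_rho=rho, histogram2d=hist)
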