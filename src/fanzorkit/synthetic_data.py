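"""Seeded generators for every input the pipeline consumes.

Each generator plants a known ground truth (motif coordinates, transposon
boundaries, depleted TAM sets, divergence clocks, reRNA intervals) and
returns it as a machine-readable truth record, so every downstream stage
can be scored without re-deriving the truth.

Seeding convention: a config carries one master seed; independent child
streams are derived as ``numpy.random.default_rng([master_seed, index])``
so that record *k* of a run is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np

from .fingerprint import (
    AA_ALPHABET,
    CANONICAL,
    E_ALT_DPHIG,
    E_ALT_OFFSET,
    FANZOR_LIKE,
    INCOMPLETE,
    PHI,
    classify,
)

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def child_rng(master_seed: int, index: int) -> np.random.Generator:
    """Derive the deterministic child stream (master, index) -> stream."""
    return np.random.default_rng([int(master_seed), int(index)])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    # uniform 1/20 background over the standard alphabet
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))


# ---------------------------------------------------------------------------
# protein families with planted RuvC/ZF fingerprints
# ---------------------------------------------------------------------------

@dataclass
class ProteinFamilyConfig:
    n_positives: int
    n_decoys: int
    ruvc1_class: str = "DPG"           # "DPG" or "DPhiG"
    e_placement: str = "E_alt"         # "E_alt" or "E_can"
    spacer_range: tuple[int, int] = (120, 160)
    zf_spacers: tuple[tuple[int, int], tuple[int, int]] = ((12, 18), (4, 8))
    mutation_rate: float = 0.0
    decoy_length: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ruvc1_class not in ("DPG", "DPhiG"):
            raise ValueError(f"unknown ruvc1_class {self.ruvc1_class!r}")
        if self.e_placement not in ("E_alt", "E_can"):
            raise ValueError(f"unknown e_placement {self.e_placement!r}")
        lo, hi = self.spacer_range
        if not (1 <= lo <= hi <= 500):
            raise ValueError("spacer_range must lie within [1, 500]")
        if not (0 <= self.mutation_rate < 1):
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.n_positives < 0 or self.n_decoys < 0:
            raise ValueError("counts must be non-negative")

    @property
    def expected_category(self) -> str:
        if self.e_placement == "E_can":
            return CANONICAL
        return FANZOR_LIKE if self.ruvc1_class == "DPG" else E_ALT_DPHIG


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    category: str                       # planted truth label
    protected: tuple[int, ...] = ()     # motif positions never mutated


def _build_positive(
    rng: np.random.Generator, cfg: ProteinFamilyConfig
) -> tuple[str, tuple[int, ...]]:
    mid = "P" if cfg.ruvc1_class == "DPG" else str(rng.choice(sorted(PHI)))
    spacer = int(rng.integers(cfg.spacer_range[0], cfg.spacer_range[1] + 1))
    (s1_lo, s1_hi), (s2_lo, s2_hi) = cfg.zf_spacers
    s1 = int(rng.integers(s1_lo, s1_hi + 1))
    s2 = int(rng.integers(s2_lo, s2_hi + 1))
    prefix = _random_protein(rng, int(rng.integers(30, 81)))
    suffix = _random_protein(rng, int(rng.integers(30, 81)))

    parts = [prefix, "D", mid, "G", _random_protein(rng, spacer), "E"]
    protected = [len(prefix), len(prefix) + 1, len(prefix) + 2]
    e_index = sum(len(p) for p in parts) - 1
    protected.append(e_index)

    if cfg.e_placement == "E_alt":
        gap = _random_protein(rng, E_ALT_OFFSET - 1)   # six arbitrary residues
        parts.append(gap)
    else:
        # canonical placement: E sits 36-64 residues upstream of the first ZF
        # cysteine; the residue at the alternative offset must not be E
        dist = int(rng.integers(36, 65))
        gap = list(_random_protein(rng, dist - 1))
        alt_pos_in_gap = (dist - 1) - E_ALT_OFFSET     # index of c1-7 in gap
        while gap[alt_pos_in_gap] == "E":
            gap[alt_pos_in_gap] = str(rng.choice(list(AA_ALPHABET)))
        parts.append("".join(gap))
        protected.append(e_index + 1 + alt_pos_in_gap)

    c1 = sum(len(p) for p in parts)
    zf = "".join(
        [
            "C", _random_protein(rng, 2), "C",
            _random_protein(rng, s1),
            "C", _random_protein(rng, 2), "C",
            _random_protein(rng, s2), "D",
        ]
    )
    parts.append(zf)
    parts.append(suffix)
    d_end = c1 + len(zf) - 1
    protected += [c1, c1 + 3, c1 + 4 + s1, c1 + 7 + s1, d_end]
    return "".join(parts), tuple(protected)


def _mutate_protein(
    seq: str, rate: float, protected: set[int], rng: np.random.Generator
) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        if int(i) in protected:
            continue
        choices = [a for a in AA_ALPHABET if a != chars[i]]
        chars[i] = str(rng.choice(choices))
    return "".join(chars)


def gen_protein_family(config: ProteinFamilyConfig) -> list[ProteinRecord]:
    """Planted positives plus decoys, self-checked against the classifier.

    Positives match the requested fingerprint class exactly before
    mutation; motif residues are never mutated so truth labels stay exact.
    Decoys are uniform random sequences verified to classify INCOMPLETE
    (regenerated up to 100 times, then an error is raised).
    """
    records: list[ProteinRecord] = []
    kwargs = dict(
        spacer_range=config.spacer_range,
        spacer1_range=config.zf_spacers[0],
        spacer2_range=config.zf_spacers[1],
    )
    for k in range(config.n_positives):
        rng = child_rng(config.seed, k)
        for _ in range(100):
            seq, protected = _build_positive(rng, config)
            if classify(seq, **kwargs).category == config.expected_category:
                break
        else:
            raise RuntimeError("failed to plant a clean positive in 100 attempts")
        seq = _mutate_protein(seq, config.mutation_rate, set(protected), rng)
        records.append(
            ProteinRecord(
                id=f"pos_{k:05d}",
                sequence=seq,
                category=config.expected_category,
                protected=protected,
            )
        )
    for k in range(config.n_decoys):
        rng = child_rng(config.seed, 10_000_000 + k)
        for _ in range(100):
            seq = _random_protein(rng, config.decoy_length)
            if classify(seq, **kwargs).category == INCOMPLETE:
                break
        else:
            raise RuntimeError("decoy kept matching the fingerprint after 100 attempts")
        records.append(ProteinRecord(id=f"neg_{k:05d}", sequence=seq, category=INCOMPLETE))
    return records


# ---------------------------------------------------------------------------
# transposon loci with planted TSD / TIR / GG boundaries
# ---------------------------------------------------------------------------

IS200_605 = "IS200_605"
IS607 = "IS607"
EUK_DNA = "eukaryotic_DNA_transposon"


@dataclass
class TransposonSimConfig:
    element_length: int = 1500
    tsd_length: int = 4
    tir_length: int = 20
    tir_mismatches: int = 0
    is_family: str = EUK_DNA
    flank_length: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.is_family not in (IS200_605, IS607, EUK_DNA):
            raise ValueError(f"unknown is_family {self.is_family!r}")
        if not (0 <= self.tsd_length <= 15):
            raise ValueError("tsd_length must be in [0, 15]")
        if self.is_family == IS607 and self.tsd_length != 0:
            raise ValueError("IS607 elements insert without target site duplication")
        if self.is_family == EUK_DNA:
            if self.tsd_length < 2:
                raise ValueError("eukaryotic DNA transposons need tsd_length >= 2")
            if self.tir_length < 1:
                raise ValueError("eukaryotic DNA transposons need terminal inverted repeats")
        if self.tir_mismatches and (
            self.tir_mismatches > max(0, (self.tir_length - 5) // 3 + 1)
        ):
            # degeneracy is planted away from the repeat tips (transposase
            # cleavage sites) and spaced >= 3 nt apart so the planted repeat
            # stays the unique best-scoring one
            raise ValueError("tir_mismatches too large for the requested tir_length")
        if self.element_length < 2 * self.tir_length + 4:
            raise ValueError("element too short for the requested TIRs")


@dataclass
class TransposonTruth:
    is_family: str
    element_interval: tuple[int, int]          # in the insertion allele
    tsd: str | None
    tir_intervals: tuple[tuple[int, int], tuple[int, int]] | None  # element-relative
    tir_mismatches: int
    flank_length: int


def _build_element(cfg: TransposonSimConfig, rng: np.random.Generator):
    if cfg.is_family == IS607:
        core = _random_dna(rng, cfg.element_length - 4)
        return "GG" + core + "GG", None
    if cfg.is_family == IS200_605:
        return _random_dna(rng, cfg.element_length), None
    tir = _random_dna(rng, cfg.tir_length)
    right = list(revcomp(tir))
    if cfg.tir_mismatches:
        # degenerate positions sit in the repeat interior, >= 2 nt from
        # either tip and >= 3 nt apart: then no trimmed sub-repeat can score
        # as well as the full planted repeat and its coordinates stay the
        # unique optimum
        for _ in range(200):
            interior = np.arange(2, cfg.tir_length - 2)
            pos = np.sort(rng.choice(interior, size=cfg.tir_mismatches, replace=False))
            if cfg.tir_mismatches == 1 or np.min(np.diff(pos)) >= 3:
                break
        else:
            raise RuntimeError("cannot space TIR mismatches for this tir_length")
        for p in pos:
            right[p] = str(rng.choice([b for b in DNA if b != right[p]]))
    # keep the planted repeat maximal: no inward extension of the inverted
    # repeat may reach the planted alignment score by chance complementarity,
    # otherwise the true TIR coordinates would be ill-defined
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    core_len = cfg.element_length - 2 * cfg.tir_length
    k_pairs = max(0, min(50, cfg.element_length // 2) - cfg.tir_length)
    for _ in range(200):
        core = _random_dna(rng, core_len)
        score = 0
        ok = True
        for i in range(min(k_pairs, core_len // 2)):
            score += 1 if core[i] == comp[core[-1 - i]] else -1
            if score >= 0:      # extension must be strictly score-losing
                ok = False
                break
        if ok:
            break
    else:
        raise RuntimeError("could not draw a core with a maximal planted TIR")
    element = tir + core + "".join(right)
    tirs = ((0, cfg.tir_length), (cfg.element_length - cfg.tir_length, cfg.element_length))
    return element, tirs


def gen_transposon_locus(
    config: TransposonSimConfig,
) -> tuple[str, str, TransposonTruth]:
    """(insertion allele, empty allele, truth record).

    Eukaryotic mode: insertion = flank + TSD + element + TSD + flank and the
    empty allele keeps a single TSD copy.  IS607 mode: GG dinucleotides at
    both element ends, a single GG at the pre-insertion junction, no TSD or
    TIR.  Assembly is re-drawn (up to 100 times) whenever the planted TSD
    would be ambiguous against the flanking sequence.
    """
    from . import transposon_annotation as ta  # self-consistency gate

    for attempt in range(100):
        rng = child_rng(config.seed, attempt)
        left = _random_dna(rng, config.flank_length)
        right = _random_dna(rng, config.flank_length)
        element, tirs = _build_element(config, rng)

        if config.is_family == EUK_DNA:
            tsd = _random_dna(rng, config.tsd_length)
            insertion = left + tsd + element + tsd + right
            empty = left + tsd + right
            start = config.flank_length + config.tsd_length
            interval = (start, start + config.element_length)
            found = ta.detect_tsd(insertion, interval)
            if found != tsd:
                continue  # ambiguous against flank context; redraw
        elif config.is_family == IS607:
            tsd = None
            insertion = left + element + right
            empty = left + "GG" + right
            interval = (config.flank_length, config.flank_length + config.element_length)
            if ta.detect_tsd(insertion, interval) is not None:
                continue  # chance direct repeat at the junction; redraw
        else:  # IS200/605-style: no duplication, no TIR
            tsd = None
            insertion = left + element + right
            empty = left + right
            interval = (config.flank_length, config.flank_length + config.element_length)
            if ta.detect_tsd(insertion, interval) is not None:
                continue

        truth = TransposonTruth(
            is_family=config.is_family,
            element_interval=interval,
            tsd=tsd,
            tir_intervals=tirs,
            tir_mismatches=config.tir_mismatches if tirs else 0,
            flank_length=config.flank_length,
        )
        return insertion, empty, truth
    raise RuntimeError("could not assemble an unambiguous locus in 100 attempts")


# ---------------------------------------------------------------------------
# TAM depletion amplicon reads
# ---------------------------------------------------------------------------

def prefix_rule(prefix: str) -> Callable[[str], bool]:
    """Depletion predicate: TAMs whose first bases equal ``prefix``."""
    return lambda tam: tam.startswith(prefix)


def all_tams(tam_length: int) -> list[str]:
    return ["".join(p) for p in product(DNA, repeat=tam_length)]


@dataclass
class TamSimConfig:
    depleted_set_rule: Callable[[str], bool] = field(default_factory=lambda: prefix_rule("GGG"))
    depletion_factor: float = 2.0 ** 6
    tam_length: int = 6
    reads_per_sample: int = 500_000
    anchor: str = "TCTAGAGTCGACCTGCAGGC"
    pad_length: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depletion_factor <= 0:
            raise ValueError("depletion_factor must be positive")
        if len(self.anchor) < 10:
            raise ValueError("anchor must be at least 10 nt")
        if self.tam_length < 1:
            raise ValueError("tam_length must be >= 1")
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be non-negative")


@dataclass
class TamTruth:
    depleted: frozenset[str]
    counts_input: dict[str, int]
    counts_output: dict[str, int]
    anchor: str
    tam_length: int


def _assemble_reads(
    tams: Sequence[str],
    counts: np.ndarray,
    anchor: str,
    pad: int,
    rng: np.random.Generator,
) -> list[str]:
    total = int(counts.sum())
    if total == 0:
        return []
    tam_len = len(tams[0])
    tam_bytes = np.frombuffer("".join(tams).encode(), dtype=np.uint8).reshape(-1, tam_len)
    per_read = np.repeat(tam_bytes, counts, axis=0)[rng.permutation(total)]
    base_bytes = np.frombuffer(DNA.encode(), dtype=np.uint8)
    width = 2 * pad + tam_len + len(anchor)
    arr = np.empty((total, width), dtype=np.uint8)
    arr[:, :pad] = base_bytes[rng.integers(0, 4, size=(total, pad))]
    arr[:, pad:pad + tam_len] = per_read
    arr[:, pad + tam_len:pad + tam_len + len(anchor)] = np.frombuffer(
        anchor.encode(), dtype=np.uint8
    )
    arr[:, -pad:] = base_bytes[rng.integers(0, 4, size=(total, pad))]
    flat = arr.reshape(-1).view(f"S{width}")
    return [b.decode() for b in flat]


def gen_tam_reads(config: TamSimConfig) -> tuple[list[str], list[str], TamTruth]:
    """(input reads, output reads, truth record).

    Input reads sample TAMs uniformly over all 4^L motifs; output reads
    down-weight depleted TAMs by ``depletion_factor`` before renormalising.
    Each read is pad + TAM + anchor + pad on the forward strand.
    """
    tams = all_tams(config.tam_length)
    n = len(tams)
    depleted = frozenset(t for t in tams if config.depleted_set_rule(t))
    p_in = np.full(n, 1.0 / n)
    w = np.array([1.0 / config.depletion_factor if t in depleted else 1.0 for t in tams])
    p_out = w / w.sum()

    rng_counts = child_rng(config.seed, 0)
    counts_in = rng_counts.multinomial(config.reads_per_sample, p_in)
    counts_out = rng_counts.multinomial(config.reads_per_sample, p_out)
    reads_in = _assemble_reads(tams, counts_in, config.anchor, config.pad_length, child_rng(config.seed, 1))
    reads_out = _assemble_reads(tams, counts_out, config.anchor, config.pad_length, child_rng(config.seed, 2))
    truth = TamTruth(
        depleted=depleted,
        counts_input=dict(zip(tams, counts_in.tolist())),
        counts_output=dict(zip(tams, counts_out.tolist())),
        anchor=config.anchor,
        tam_length=config.tam_length,
    )
    return reads_in, reads_out, truth


# ---------------------------------------------------------------------------
# co-diverging TnpA / TnpB pairs
# ---------------------------------------------------------------------------

@dataclass
class PairedFamilyConfig:
    n_elements: int = 30
    divergence_clock: tuple[float, float] = (0.1, 0.6)  # substitutions/site range
    coupling: float = 1.0
    shuffle_control: bool = False
    len_a: int = 200
    len_b: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_elements < 3:
            raise ValueError("need at least 3 elements")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must be in [0, 1]")
        lo, hi = self.divergence_clock
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("divergence_clock range must lie in [0, 1)")


@dataclass
class PairedFamilies:
    msa_a: dict[str, str]              # TnpA rows, element id -> aligned row
    msa_b: dict[str, str]              # TnpB rows
    pairing: dict[str, tuple[str, str]]
    shuffled_pairing: dict[str, tuple[str, str]] | None
    distances_a: dict[str, float]
    distances_b: dict[str, float]


def _diverge(seq: str, p_sub: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < p_sub)
    for i in hits:
        chars[i] = str(rng.choice([a for a in AA_ALPHABET if a != chars[i]]))
    return "".join(chars)


def gen_paired_families(config: PairedFamilyConfig) -> PairedFamilies:
    """Elements whose TnpA and TnpB diverge on correlated clocks.

    With coupling 1 both proteins of an element diverge by the same clock
    draw; with coupling 0 the clocks are independent.  Substitution-only
    evolution keeps the rows aligned without an aligner.  The shuffle
    control permutes the TnpB assignments only.
    """
    rng = child_rng(config.seed, 0)
    anc_a = _random_protein(rng, config.len_a)
    anc_b = _random_protein(rng, config.len_b)
    lo, hi = config.divergence_clock
    z = rng.uniform(lo, hi, size=config.n_elements)
    u = rng.uniform(lo, hi, size=config.n_elements)
    v = rng.uniform(lo, hi, size=config.n_elements)
    t_a = config.coupling * z + (1 - config.coupling) * u
    t_b = config.coupling * z + (1 - config.coupling) * v

    ids = [f"elem_{i:03d}" for i in range(config.n_elements)]
    msa_a, msa_b, dist_a, dist_b = {}, {}, {}, {}
    for i, eid in enumerate(ids):
        r = child_rng(config.seed, 1 + i)
        msa_a[f"{eid}_tnpa"] = _diverge(anc_a, float(t_a[i]), r)
        msa_b[f"{eid}_tnpb"] = _diverge(anc_b, float(t_b[i]), r)
        dist_a[eid] = float(t_a[i])
        dist_b[eid] = float(t_b[i])
    pairing = {eid: (f"{eid}_tnpa", f"{eid}_tnpb") for eid in ids}

    shuffled = None
    if config.shuffle_control:
        perm_rng = child_rng(config.seed, 10_000_000)
        perm = perm_rng.permutation(config.n_elements)
        shuffled = {
            ids[i]: (f"{ids[i]}_tnpa", f"{ids[int(j)]}_tnpb")
            for i, j in enumerate(perm)
        }
    return PairedFamilies(msa_a, msa_b, pairing, shuffled, dist_a, dist_b)


# ---------------------------------------------------------------------------
# small-RNA reads tiling a reRNA span
# ---------------------------------------------------------------------------

@dataclass
class SmallRnaSimConfig:
    locus: str
    rerna_start: int
    rerna_end: int
    n_reads: int = 1000
    read_length_range: tuple[int, int] = (20, 400)  # size-selection window
    end_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rerna_start < self.rerna_end <= len(self.locus)):
            raise ValueError("rerna interval must lie within the locus")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        lo, hi = self.read_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid read_length_range")


@dataclass
class SmallRnaTruth:
    interval: tuple[int, int]
    starts: list[int]
    ends: list[int]


def gen_smallrna_reads(config: SmallRnaSimConfig) -> tuple[list[str], SmallRnaTruth]:
    """Reads spanning the planted reRNA interval with jittered endpoints.

    Each read is the locus substring over [start + j1, end + j2) with
    Gaussian endpoint jitter of sd ``end_noise_sd`` (rounded to integer
    positions), emulating merged small-RNA-seq reads of one transcript.
    Reads outside the size-selection window are redrawn.
    """
    rng = child_rng(config.seed, 0)
    n_locus = len(config.locus)
    lo, hi = config.read_length_range
    reads, starts, ends = [], [], []
    for _ in range(config.n_reads):
        for _ in range(100):
            s = config.rerna_start + int(round(rng.normal(0, config.end_noise_sd)))
            e = config.rerna_end + int(round(rng.normal(0, config.end_noise_sd)))
            s = max(0, s)
            e = min(n_locus, e)
            if e > s and lo <= e - s <= hi:
                break
        else:
            raise RuntimeError("could not draw a read inside the size-selection window")
        reads.append(config.locus[s:e])
        starts.append(s)
        ends.append(e)
    return reads, SmallRnaTruth(
        interval=(config.rerna_start, config.rerna_end), starts=starts, ends=ends
    )


# ---------------------------------------------------------------------------
# homolog ladder for the iterative profile search study
# ---------------------------------------------------------------------------

@dataclass
class LadderTruth:
    identity_of: dict[str, float]      # database id -> planted identity to ancestor
    rungs: tuple[float, ...]


def gen_homolog_ladder(
    seed: int,
    domain_len: int = 100,
    n_seed_rows: int = 5,
    seed_divergence: float = 0.05,
    rung_identities: tuple[float, ...] = (0.8, 0.6, 0.4, 0.3),
    n_per_rung: int = 50,
    n_decoys: int = 50,
    flank_len: int = 40,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], LadderTruth]:
    """Seed alignment plus a database of progressively diverged homologs.

    Seed rows are light mutations of a common ancestor domain (aligned
    trivially, substitution-only).  Database entries embed a diverged copy
    of the domain between random flanks; decoys are random sequences of
    matched length.
    """
    rng = child_rng(seed, 0)
    ancestor = _random_protein(rng, domain_len)
    seed_aln = []
    for i in range(n_seed_rows):
        r = child_rng(seed, 1 + i)
        seed_aln.append((f"seedrow_{i:02d}", _diverge(ancestor, seed_divergence, r)))

    database, identity_of = [], {}
    idx = 0
    for level in rung_identities:
        for _ in range(n_per_rung):
            r = child_rng(seed, 1000 + idx)
            domain = _diverge(ancestor, 1.0 - level, r)
            seq = _random_protein(r, flank_len) + domain + _random_protein(r, flank_len)
            sid = f"rung{int(level * 100):02d}_{idx:04d}"
            database.append((sid, seq))
            identity_of[sid] = level
            idx += 1
    for d in range(n_decoys):
        r = child_rng(seed, 500_000 + d)
        sid = f"decoy_{d:04d}"
        database.append((sid, _random_protein(r, domain_len + 2 * flank_len)))
        identity_of[sid] = 0.0
    truth = LadderTruth(identity_of=identity_of, rungs=tuple(rung_identities))
    return seed_aln, database, truth
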