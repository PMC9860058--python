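"""Sequence-level computations for common-garden reporter design.

This module covers the DNA arithmetic underlying the experimental design:
measuring GC content, recoding a CDS to a target GC fraction through
synonymous substitutions only, scanning degenerate (IUPAC) insertion-site
motifs, detecting target-site duplications (TSDs) from reference/mutant
allele pairs, building position frequency matrices from aligned TSD windows,
and measuring the GC asymmetry of insertion-site flanks.

Coordinates are 1-based and intervals are closed throughout, matching how
positions are reported in insertion catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable, IUPACData
from Bio.Seq import Seq

_DNA = frozenset("ACGT")

#: IUPAC code -> frozenset of plain bases it matches.
IUPAC_SETS: dict[str, frozenset] = {
    code: frozenset(bases) for code, bases in IUPACData.ambiguous_dna_values.items()
}
#: frozenset of bases -> shortest IUPAC code (for consensus strings).
_SET_TO_IUPAC = {bases: code for code, bases in IUPAC_SETS.items()}


@dataclass(frozen=True)
class NucleotideSequence:
    """An upper-case A/C/G/T sequence with an identifier."""

    id: str
    residues: str
    origin_note: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _DNA
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-ACGT symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingSequence(NucleotideSequence):
    """A protein-coding sequence; length must be a whole number of codons.

    ``codon_table_id`` selects the NCBI translation table (default 11,
    bacterial/archaeal/plant-plastid). Internal stop codons are rejected.
    """

    codon_table_id: int = 11

    def __post_init__(self) -> None:
        super().__post_init__()
        if len(self.residues) % 3 != 0:
            raise ValueError(
                f"CDS {self.id!r} length {len(self.residues)} is not divisible by 3"
            )
        translate(self)  # raises on internal stop

    @property
    def codons(self) -> list[str]:
        r = self.residues
        return [r[i : i + 3] for i in range(0, len(r), 3)]


@dataclass(frozen=True)
class RecodedVariant:
    """Result of synonymous GC recoding of a parent CDS."""

    parent_id: str
    residues: str
    target_gc: float
    achieved_gc: float
    n_substitutions: int
    unreachable: bool = False

    def as_cds(self, id: str | None = None, codon_table_id: int = 11) -> CodingSequence:
        return CodingSequence(
            id=id or f"{self.parent_id}_gc{self.achieved_gc:.3f}",
            residues=self.residues,
            codon_table_id=codon_table_id,
        )


@dataclass(frozen=True)
class TargetMotif:
    """A degenerate insertion-site motif for one IS.

    ``tsd_length`` is the length of the direct repeat created on insertion;
    by convention it equals the motif length (the duplicated sequence *is*
    the target site).
    """

    is_id: str
    iupac: str
    tsd_length: int | None = None

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError(f"motif for {self.is_id!r} is empty")
        bad = [c for c in self.iupac if c not in IUPAC_SETS]
        if bad:
            raise ValueError(f"motif {self.iupac!r} has invalid IUPAC codes: {bad}")
        if self.tsd_length is None:
            object.__setattr__(self, "tsd_length", len(self.iupac))

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class TSD:
    """A target-site duplication; length 0 means no detectable duplication.

    ``left_pos``/``right_pos`` are the 1-based start positions of the two
    repeat copies on the mutant allele, when known.
    """

    sequence: str
    length: int
    left_pos: int | None = None
    right_pos: int | None = None

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValueError("TSD length disagrees with its sequence")


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over aligned windows, with information content.

    ``counts`` is a 4 x L array in A, C, G, T row order. Information content
    per position is ``2 + sum_b f_b log2 f_b`` bits, computed from
    pseudocounted frequencies, and lies in [0, 2].
    """

    counts: np.ndarray
    pseudocount: float = 0.0
    alphabet: str = "ACGT"
    n_windows: int = 0
    information_content: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        freqs = self.frequencies()
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
        self.information_content = 2.0 + plogp.sum(axis=0)

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        padded = self.counts + self.pseudocount
        return padded / padded.sum(axis=0, keepdims=True)

    def consensus(self, secondary_threshold: float = 0.25) -> str:
        """Degenerate consensus, one token per position joined by '-'.

        A position is written ``X/Y`` when the runner-up base exceeds
        ``secondary_threshold`` frequency; three or four qualifying bases
        collapse to the IUPAC code for the set (e.g. H, N).
        """
        tokens = []
        freqs = self.frequencies()
        for j in range(self.length):
            col = freqs[:, j]
            order = np.argsort(-col, kind="stable")
            keep = [order[0]] + [i for i in order[1:] if col[i] > secondary_threshold]
            bases = [self.alphabet[i] for i in keep]
            if len(bases) <= 2:
                tokens.append("/".join(bases))
            else:
                tokens.append(_SET_TO_IUPAC[frozenset(bases)])
        return "-".join(tokens)


# ---------------------------------------------------------------------------
# GC content


def gc_fraction(
    seq: NucleotideSequence | str, start: int | None = None, end: int | None = None
) -> float:
    """GC fraction of ``seq`` or of the 1-based closed interval [start, end]."""
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    if not residues:
        raise ValueError("empty sequence")
    bad = set(residues) - _DNA
    if bad:
        raise ValueError(f"non-ACGT symbols: {sorted(bad)}")
    if start is None and end is None:
        window = residues
    else:
        start = 1 if start is None else start
        end = len(residues) if end is None else end
        if not (1 <= start <= end <= len(residues)):
            raise ValueError(
                f"interval [{start}, {end}] invalid for length {len(residues)}"
            )
        window = residues[start - 1 : end]
    return (window.count("G") + window.count("C")) / len(window)


# ---------------------------------------------------------------------------
# Translation and synonymous recoding


def _codon_table(table_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


def translate(cds: CodingSequence | str, codon_table_id: int = 11) -> str:
    """Translate a CDS; a terminal stop is rendered '*'.

    Raises ``ValueError`` naming the codon index (1-based) on an internal
    stop codon.
    """
    if isinstance(cds, CodingSequence):
        residues, table_id = cds.residues, cds.codon_table_id
    else:
        residues, table_id = cds, codon_table_id
    if len(residues) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    table = _codon_table(table_id)
    stops = set(table.stop_codons)
    aa = []
    n_codons = len(residues) // 3
    for i in range(n_codons):
        codon = residues[3 * i : 3 * i + 3]
        if codon in stops:
            if i != n_codons - 1:
                raise ValueError(
                    f"internal stop codon {codon} at codon index {i + 1}"
                )
            aa.append("*")
        else:
            aa.append(table.forward_table[codon])
    return "".join(aa)


def _synonym_map(table_id: int) -> dict[str, list[str]]:
    """codon -> sorted list of synonymous codons (same amino acid or stop)."""
    table = _codon_table(table_id)
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa["*"] = list(table.stop_codons)
    out = {}
    for codons in by_aa.values():
        codons = sorted(codons)
        for c in codons:
            out[c] = codons
    return out


def _gc_count(s: str) -> int:
    return s.count("G") + s.count("C")


def recode_to_gc(
    cds: CodingSequence,
    target_gc: float | None = None,
    direction: str = "nearest",
    tolerance: float = 0.005,
) -> RecodedVariant:
    """Recode a CDS toward a target GC fraction by synonymous substitution.

    A deterministic greedy pass: at each step the synonymous codon swap
    giving the largest GC movement toward the target is applied (ties broken
    by leftmost codon, then lexicographic codon order); the pass stops when
    no swap reduces the distance to the target.  ``direction='maximize'``
    (or ``'minimize'``) pushes GC as far up (down) as synonymy permits;
    ``target_gc`` then defaults to 1 (0) and only informs the
    ``unreachable`` flag.

    The translation is preserved exactly.  If the achieved GC differs from
    the target by more than ``tolerance`` the variant is flagged
    ``unreachable`` rather than failing silently.
    """
    if direction not in ("nearest", "maximize", "minimize"):
        raise ValueError(f"unknown direction {direction!r}")
    if target_gc is None:
        if direction == "nearest":
            raise ValueError("direction='nearest' requires target_gc")
        target_gc = 1.0 if direction == "maximize" else 0.0
    if not 0.0 <= target_gc <= 1.0:
        raise ValueError("target_gc must lie in [0, 1]")

    synonyms = _synonym_map(cds.codon_table_id)
    codons = cds.codons
    n = len(cds.residues)
    goal = target_gc * n  # target GC count, real-valued
    gc = float(_gc_count(cds.residues))
    n_subs = 0

    while True:
        best = None  # (gain, codon_index, replacement)
        for i, codon in enumerate(codons):
            for alt in synonyms[codon]:
                if alt == codon:
                    continue
                delta = _gc_count(alt) - _gc_count(codon)
                gain = abs(gc - goal) - abs(gc + delta - goal)
                if gain > 1e-12 and (best is None or gain > best[0] + 1e-12):
                    best = (gain, i, alt)
        if best is None:
            break
        _, i, alt = best
        gc += _gc_count(alt) - _gc_count(codons[i])
        codons[i] = alt
        n_subs += 1

    residues = "".join(codons)
    achieved = _gc_count(residues) / n
    n_substitutions = sum(
        1 for a, b in zip(cds.codons, codons) if a != b
    )
    # n_subs counts greedy steps; a codon touched twice is one substitution
    del n_subs
    return RecodedVariant(
        parent_id=cds.id,
        residues=residues,
        target_gc=target_gc,
        achieved_gc=achieved,
        n_substitutions=n_substitutions,
        unreachable=abs(achieved - target_gc) > tolerance,
    )


# ---------------------------------------------------------------------------
# Motif scanning


def _matches_at(residues: str, motif: str, start0: int) -> bool:
    for k, code in enumerate(motif):
        if residues[start0 + k] not in IUPAC_SETS[code]:
            return False
    return True


def scan_motif(
    seq: NucleotideSequence | str, motif: TargetMotif | str, strand: str = "forward"
) -> list[int]:
    """1-based start positions of (overlapping) motif matches.

    ``strand='both'`` additionally scans the reverse-complement of the motif
    against the forward strand and reports deduplicated forward-strand
    coordinates — a match on either strand counts once.
    """
    if strand not in ("forward", "both"):
        raise ValueError(f"unknown strand policy {strand!r}")
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    iupac = motif.iupac if isinstance(motif, TargetMotif) else motif
    bad = [c for c in iupac if c not in IUPAC_SETS]
    if bad:
        raise ValueError(f"invalid IUPAC codes in motif {iupac!r}: {bad}")
    m, n = len(iupac), len(residues)
    if m > n:
        return []
    patterns = [iupac]
    if strand == "both":
        rc = str(Seq(iupac).reverse_complement())
        if rc != iupac:
            patterns.append(rc)
    hits: set[int] = set()
    for pat in patterns:
        for i in range(n - m + 1):
            if _matches_at(residues, pat, i):
                hits.add(i + 1)
    return sorted(hits)


def available_sites(
    variants: NucleotideSequence | list[NucleotideSequence],
    motifs: list[TargetMotif],
    strand: str = "forward",
):
    """Per-variant, per-motif available-target-site counts.

    Returns a pandas DataFrame with columns
    ``variant_id, motif, is_id, strand_policy, count``, one row per
    (variant, motif) pair; the counts feed the environment table of the
    niche analysis.
    """
    import pandas as pd

    if isinstance(variants, NucleotideSequence):
        variants = [variants]
    rows = []
    for v in variants:
        for motif in motifs:
            rows.append(
                {
                    "variant_id": v.id,
                    "motif": motif.iupac,
                    "is_id": motif.is_id,
                    "strand_policy": strand,
                    "count": len(scan_motif(v, motif, strand=strand)),
                }
            )
    return pd.DataFrame(
        rows, columns=["variant_id", "motif", "is_id", "strand_policy", "count"]
    )


# ---------------------------------------------------------------------------
# Target-site duplication detection


def find_tsd(
    reference: NucleotideSequence,
    mutant: NucleotideSequence,
    max_tsd: int = 20,
) -> tuple[TSD, str, int]:
    """Recover (TSD, inserted element, insertion position) from an allele pair.

    The mutant must be the reference with one contiguous segment inserted.
    Let ``p`` be the longest common prefix of the two alleles; the inserted
    segment is taken as ``mutant[p+1 .. p+L]`` (1-based, L = length
    difference) and the TSD is the longest ``k <= max_tsd`` for which the
    ``k`` nucleotides ending at ``p`` equal the tail of the inserted
    segment.  When homology makes the breakpoint ambiguous this places the
    duplication as far left as the common prefix allows; the returned
    insertion position is the 1-based reference position after which the
    element (with its duplicated repeat) sits.
    """
    ref, mut = reference.residues, mutant.residues
    n, m = len(ref), len(mut)
    if m <= n:
        raise ValueError("mutant is not longer than reference")
    L = m - n

    p = 0
    while p < n and ref[p] == mut[p]:
        p += 1
    s = 0
    while s < n and ref[n - 1 - s] == mut[m - 1 - s]:
        s += 1
    if p + s < n:
        raise ValueError(
            "alleles differ by more than a single contiguous insertion "
            f"(common prefix {p} + common suffix {s} < reference length {n})"
        )

    inserted = mut[p : p + L]
    # a duplication flanks an element; the element itself cannot be empty
    k_max = min(max_tsd, p, L - 1)
    tsd_len = 0
    for k in range(k_max, 0, -1):
        if mut[p - k : p] == inserted[L - k :]:
            tsd_len = k
            break
    tsd = TSD(
        sequence=mut[p - tsd_len : p],
        length=tsd_len,
        left_pos=(p - tsd_len + 1) if tsd_len else None,
        right_pos=(p + L - tsd_len + 1) if tsd_len else None,
    )
    core = inserted[: L - tsd_len] if tsd_len else inserted
    return tsd, core, p


# ---------------------------------------------------------------------------
# Position frequency matrices and flank asymmetry


def build_pfm(windows: list[str], pseudocount: float = 0.0) -> PositionFrequencyMatrix:
    """Tally aligned equal-length windows into a position frequency matrix."""
    if not windows:
        raise ValueError("no windows given")
    L = len(windows[0])
    ragged = [w for w in windows if len(w) != L]
    if ragged:
        raise ValueError(f"ragged window lengths (expected {L}): {ragged[:3]}")
    counts = np.zeros((4, L), dtype=float)
    index = {b: i for i, b in enumerate("ACGT")}
    for w in windows:
        for j, base in enumerate(w):
            try:
                counts[index[base], j] += 1
            except KeyError:
                raise ValueError(f"non-ACGT symbol {base!r} in window {w!r}") from None
    return PositionFrequencyMatrix(
        counts=counts, pseudocount=pseudocount, n_windows=len(windows)
    )


def flank_gc_asymmetry(
    seq: NucleotideSequence, pos: int, window: int = 10
) -> tuple[float, float, float]:
    """GC of the ``window`` nt up- and downstream of ``pos`` (1-based).

    Returns ``(gc_up, gc_down, |difference|)`` with the difference expressed
    in percentage points.  The nucleotide at ``pos`` itself is excluded.
    """
    n = len(seq)
    if not (1 <= pos <= n):
        raise ValueError(f"position {pos} outside sequence of length {n}")
    if pos - window < 1 or pos + window > n:
        raise ValueError(
            f"need {window} nt on both sides of position {pos} (length {n})"
        )
    gc_up = gc_fraction(seq, pos - window, pos - 1)
    gc_down = gc_fraction(seq, pos + 1, pos + window)
    return gc_up, gc_down, abs(gc_down - gc_up) * 100.0


def reverse_complement(residues: str) -> str:
    """Reverse complement of a plain or IUPAC-degenerate DNA string."""
    return str(Seq(residues).reverse_complement())
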