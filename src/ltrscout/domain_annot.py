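"""Protein-domain annotation of the element interior and the intactness filter.

The internal region between the two LTRs of an autonomous element codes for
the Gag-Pol polyprotein: GAG (capsid), AP (aspartic proteinase), INT
(integrase), RT (reverse transcriptase) and RH (RNase H). Each candidate's
internal region is translated in all six frames and locally aligned
(affine-gap Smith-Waterman, BLOSUM80 by default) against a labeled reference
library; an element is *intact* iff all five domain types have at least one
accepted hit.

Stop codons translate to '*' and are retained (scored -4 against everything,
so local alignments simply avoid them); codons containing N translate to X.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .formats_io import DOMAIN_TYPES, DomainLibraryRecord

FRAMES = (1, 2, 3, -1, -2, -3)
MIN_INTERNAL_NT = 300
STOP_SCORE = -4


class ConfigError(ValueError):
    """Raised for unusable annotation configuration (e.g. empty library)."""


@dataclass(frozen=True)
class DomainAnnotParams:
    """Translated-search parameters.

    ``min_score`` is a raw alignment score (default 80, the standard cutoff
    for this screen). Gap penalties are positive costs in the units of the
    chosen matrix; the defaults (22/2) are calibrated to the 1/3-bit-unit
    BLOSUM80 distributed with Biopython, keeping random-alignment noise well
    below ``min_score`` while true domains score an order of magnitude higher.
    """

    matrix: str = "BLOSUM80"
    gap_open: int = 22
    gap_extend: int = 2
    min_score: int = 80
    max_type_overlap: int = 10  # amino acids
    #: accepted hits must align over at least this fraction of the library
    #: peptide; random near-threshold alignments span <40% of a domain,
    #: genuine domains align nearly full length.
    min_ref_coverage: float = 0.8

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive costs")
        if self.min_score <= 0:
            raise ValueError("min_score must be positive")
        if not (0.0 <= self.min_ref_coverage <= 1.0):
            raise ValueError("min_ref_coverage must be a fraction")


@dataclass(frozen=True)
class DomainHit:
    """One accepted translated-alignment hit on the internal region.

    ``nt_start``/``nt_end`` are 0-based half-open offsets on the *internal
    region* (forward strand), regardless of the hit's own strand.
    """

    domain_type: str
    nt_start: int
    nt_end: int
    frame: int
    strand: str
    score: float
    library_id: str
    superfamily_label: str
    lineage_label: str

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.nt_start + self.nt_end)


@dataclass(frozen=True)
class IntactnessReport:
    is_intact: bool
    present_types: frozenset[str]
    multi_cassette: bool
    cassette_count: int


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_AMINO = ("FFLLSSSSYY**CC*W"
          "LLLLPPPPHHQQRRRR"
          "IIIMTTTTNNKKSSRR"
          "VVVVAAAADDEEGGGG")
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def _translate(dna: str) -> str:
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i:i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def translate_six_frames(dna: str) -> list[tuple[int, str]]:
    """Standard-code translation in frames +1,+2,+3 (forward) and -1,-2,-3
    (reverse complement). Codons containing N give X; stops give '*'.

    Returns ``[(frame, peptide), ...]`` in frame order; sequences shorter
    than 3 nt give six empty peptides.
    """
    rc = reverse_complement(dna)
    peps = []
    for f in FRAMES:
        src = dna if f > 0 else rc
        off = abs(f) - 1
        peps.append((f, _translate(src[off:])))
    return peps


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4)
def load_matrix(name: str):
    """Substitution matrix with the '*' row/column forced to STOP_SCORE."""
    m = substitution_matrices.load(name).copy()
    if "*" in m.alphabet:
        for c in m.alphabet:
            m[c, "*"] = STOP_SCORE
            m["*", c] = STOP_SCORE
    return m


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        substitution_matrix=load_matrix(matrix),
        open_gap_score=-float(gap_open),
        extend_gap_score=-float(gap_extend),
    )


def smith_waterman(pep: str, ref: str, params: Optional[DomainAnnotParams] = None
                   ) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Optimal affine-gap local alignment score and spans.

    Returns ``(score, (pep_start, pep_end), (ref_start, ref_end))`` with
    half-open spans of the optimal alignment (the aligner's first optimal
    traceback; deterministic). Either sequence empty gives score 0.
    """
    params = params or DomainAnnotParams()
    if not pep or not ref:
        return 0.0, (0, 0), (0, 0)
    al = _aligner(params.matrix, params.gap_open, params.gap_extend)
    if al.score(pep, ref) <= 0.0:
        return 0.0, (0, 0), (0, 0)
    aln = al.align(pep, ref)[0]
    bp, br = aln.aligned
    if len(bp) == 0:
        return 0.0, (0, 0), (0, 0)
    return float(aln.score), (int(bp[0][0]), int(bp[-1][1])), (int(br[0][0]), int(br[-1][1]))


def _sw_score(pep: str, ref: str, params: DomainAnnotParams) -> float:
    if not pep or not ref:
        return 0.0
    return float(_aligner(params.matrix, params.gap_open, params.gap_extend).score(pep, ref))


def _pep_to_nt(frame: int, pep_span: tuple[int, int], n: int) -> tuple[int, int]:
    """Map a half-open peptide span in the given frame to internal-region
    nucleotide offsets (forward-strand coordinates)."""
    ps, pe = pep_span
    off = abs(frame) - 1
    if frame > 0:
        return off + 3 * ps, off + 3 * pe
    return n - (off + 3 * pe), n - (off + 3 * ps)


def _repeated_local_hits(pep: str, ref: str, params: DomainAnnotParams
                         ) -> list[tuple[float, tuple[int, int], tuple[int, int]]]:
    """All non-overlapping local alignments scoring >= min_score, found by
    repeated Smith-Waterman with segment splitting (so tandem copies of a
    domain in one frame are all reported)."""
    out: list[tuple[float, tuple[int, int], tuple[int, int]]] = []

    def rec(lo: int, hi: int) -> None:
        if hi - lo < 20:
            return
        sub = pep[lo:hi]
        if _sw_score(sub, ref, params) < params.min_score:
            return
        score, (ps, pe), rspan = smith_waterman(sub, ref, params)
        if pe <= ps or score < params.min_score:
            return
        out.append((score, (lo + ps, lo + pe), rspan))
        rec(lo, lo + ps)
        rec(lo + pe, hi)

    rec(0, len(pep))
    return out


def annotate_domains(internal: str, library: Sequence[DomainLibraryRecord],
                     params: Optional[DomainAnnotParams] = None) -> list[DomainHit]:
    """Six-frame translated search of the internal region against the library.

    Hits scoring >= ``min_score`` are kept; per domain type a maximal set is
    accepted greedily by descending score with pairwise nucleotide overlap of
    at most ``3 * max_type_overlap``. Output is sorted by nt_start.
    """
    params = params or DomainAnnotParams()
    if not library:
        raise ConfigError("domain library is empty")
    if len(internal) < MIN_INTERNAL_NT:
        return []
    frames = translate_six_frames(internal)
    n = len(internal)
    raw: list[DomainHit] = []
    for rec in library:
        for f, pep in frames:
            for score, pspan, rspan in _repeated_local_hits(pep, rec.peptide, params):
                if rspan[1] - rspan[0] < params.min_ref_coverage * len(rec.peptide):
                    continue
                nt_start, nt_end = _pep_to_nt(f, pspan, n)
                raw.append(DomainHit(
                    domain_type=rec.domain_type, nt_start=nt_start, nt_end=nt_end,
                    frame=f, strand="+" if f > 0 else "-", score=score,
                    library_id=rec.id, superfamily_label=rec.superfamily,
                    lineage_label=rec.lineage,
                ))
    accepted: list[DomainHit] = []
    max_overlap_nt = 3 * params.max_type_overlap
    for dtype in DOMAIN_TYPES:
        pool = sorted((h for h in raw if h.domain_type == dtype),
                      key=lambda h: (-h.score, h.nt_start, h.library_id, h.frame))
        chosen: list[DomainHit] = []
        for h in pool:
            if all(_overlap_nt(h, o) <= max_overlap_nt for o in chosen):
                chosen.append(h)
        accepted.extend(chosen)
    accepted.sort(key=lambda h: (h.nt_start, h.nt_end, h.domain_type))
    return accepted


def _overlap_nt(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.nt_end, b.nt_end) - max(a.nt_start, b.nt_start))


def assess_intactness(hits: Sequence[DomainHit]) -> IntactnessReport:
    """Intact iff every one of the five Gag-Pol domain types has >= 1 accepted
    hit; multi-cassette iff some type has >= 2."""
    counts = {t: 0 for t in DOMAIN_TYPES}
    for h in hits:
        counts[h.domain_type] += 1
    present = frozenset(t for t, c in counts.items() if c > 0)
    cassette_count = max(counts.values()) if counts else 0
    return IntactnessReport(
        is_intact=present == frozenset(DOMAIN_TYPES),
        present_types=present,
        multi_cassette=cassette_count >= 2,
        cassette_count=max(cassette_count, 1),
    )
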