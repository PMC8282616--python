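"""De novo detection of candidate LTR pairs.

An LTR retrotransposon leaves two near-identical direct repeats (the LTRs)
whose start positions are 1-15 kb apart. Detection proceeds in four stages:

1. exact k-mer seeding (``find_seed_matches``): maximal exact matches between
   positions i < j on the same strand with j - i in the allowed distance
   window, merged into maximal runs along each diagonal;
2. chaining + banded X-drop extension (``chain_and_extend``): nearby seeds
   are chained and extended outward by banded affine-gap alignment; the pair
   is re-aligned globally to measure column identity, and candidates failing
   the structural constraints (LTR length 100-3000 bp, start separation
   1-15 kb, identity strictly > 0.80) are discarded;
3. greedy overlap resolution (``resolve_overlaps``), nesting allowed;
4. boundary refinement to the terminal TG...CA motif (``refine_motif``) and
   target-site-duplication search (``detect_tsd``).

TSD presence is annotation only; it never filters an element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .formats_io import GenomeSequence

logger = logging.getLogger(__name__)

_NEG = -1.0e9

# Extension / identity-alignment scoring (favors high-identity repeats with a
# sharp score drop-off at the repeat boundary).
MATCH = 2.0
MISMATCH = -3.0
GAP_OPEN = -5.0
GAP_EXTEND = -2.0
XDROP = 20.0


@dataclass(frozen=True)
class DetectionParams:
    """Structural constraints and tuning knobs of the LTR-pair search.

    Defaults encode the standard screen: LTR length 100-3,000 bp, LTR start
    separation 1-15 kb, pairwise identity strictly greater than 80%, and a
    4-6 bp TSD search.
    """

    k: int = 20
    ltr_min: int = 100
    ltr_max: int = 3000
    min_identity: float = 0.80
    dist_min: int = 1000
    dist_max: int = 15000
    motif_window: int = 10
    boundary_window: int = 45
    tsd_lengths: tuple[int, ...] = (4, 5, 6)
    chain_gap: int = 50
    band: int = 30

    def __post_init__(self):
        if not (0 < self.ltr_min < self.ltr_max):
            raise ValueError("require 0 < ltr_min < ltr_max")
        if not (0 < self.dist_min < self.dist_max):
            raise ValueError("require 0 < dist_min < dist_max")
        if not (0.0 < self.min_identity < 1.0):
            raise ValueError("require 0 < min_identity < 1")
        if self.k > self.ltr_min:
            raise ValueError("require k <= ltr_min")


@dataclass(frozen=True)
class SeedMatch:
    """A maximal exact repeat: seq[pos5:pos5+length] == seq[pos3:pos3+length]."""

    pos5: int
    pos3: int
    length: int

    @property
    def diag(self) -> int:
        return self.pos3 - self.pos5


@dataclass
class CandidateElement:
    """A detected LTR pair, before functional annotation.

    Coordinates are 0-based half-open on the forward strand of ``chrom``.
    ``tg_ca`` flags whether the 5' LTR starts with TG / the 3' LTR ends with
    CA after boundary refinement; ``tsd`` is the exact 4-6 bp target-site
    duplication if one flanks the element.
    """

    chrom: str
    ltr5_start: int
    ltr5_end: int
    ltr3_start: int
    ltr3_end: int
    identity: float
    tg_ca: tuple[bool, bool] = (False, False)
    tsd: Optional[str] = None
    score: float = 0.0

    @property
    def ltr5_len(self) -> int:
        return self.ltr5_end - self.ltr5_start

    @property
    def ltr3_len(self) -> int:
        return self.ltr3_end - self.ltr3_start

    @property
    def span(self) -> tuple[int, int]:
        return self.ltr5_start, self.ltr3_end

    def violations(self, params: DetectionParams) -> list[str]:
        """Structural-invariant violations (empty when valid)."""
        out = []
        if not (self.ltr5_start < self.ltr5_end <= self.ltr3_start < self.ltr3_end):
            out.append("coordinate order")
        for n, ln in (("5'", self.ltr5_len), ("3'", self.ltr3_len)):
            if not (params.ltr_min <= ln <= params.ltr_max):
                out.append(f"{n} LTR length {ln}")
        d = self.ltr3_start - self.ltr5_start
        if not (params.dist_min <= d <= params.dist_max):
            out.append(f"LTR start separation {d}")
        if not (self.identity > params.min_identity):
            out.append(f"identity {self.identity:.3f}")
        return out


# ---------------------------------------------------------------------------
# Stage 1: seeding
# ---------------------------------------------------------------------------

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i


def _encode(s: str) -> np.ndarray:
    return _ENC[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def find_seed_matches(seq: GenomeSequence | str,
                      params: DetectionParams) -> list[SeedMatch]:
    """All maximal exact k-mer matches (i, j), i < j, with j - i in the
    distance window; direct orientation only (LTRs are direct repeats).

    K-mers containing N never seed. Matches sharing a diagonal are merged
    into maximal runs.
    """
    s = seq.residues if isinstance(seq, GenomeSequence) else seq
    n = len(s)
    k = params.k
    if n < params.dist_min + k:
        return []
    codes = _encode(s)
    m = n - k + 1
    # exact 2k-bit integer code per window (k <= 32 fits in uint64)
    kint = np.zeros(m, dtype=np.uint64)
    for t in range(k):
        kint = (kint << np.uint64(2)) | codes[t:t + m].astype(np.uint64)
    bad = (codes == 4).astype(np.int64)
    badc = np.concatenate([[0], np.cumsum(bad)])
    has_n = (badc[k:] - badc[:-k]) > 0
    valid_pos = np.nonzero(~has_n)[0]
    vals = kint[valid_pos]
    order = np.argsort(vals, kind="stable")
    sv = vals[order]
    sp = valid_pos[order]

    by_diag: dict[int, list[int]] = {}
    gstart = 0
    bounds = np.nonzero(np.diff(sv))[0] + 1
    for gend in list(bounds) + [len(sv)]:
        size = gend - gstart
        if size >= 2:
            pos = np.sort(sp[gstart:gend])
            for a in range(size):
                for b in range(a + 1, size):
                    d = int(pos[b] - pos[a])
                    if d > params.dist_max:
                        break
                    if d < params.dist_min:
                        continue
                    by_diag.setdefault(d, []).append(int(pos[a]))
        gstart = gend

    seeds: list[SeedMatch] = []
    for d in sorted(by_diag):
        poss = sorted(set(by_diag[d]))
        run_start = prev = poss[0]
        for p in poss[1:]:
            if p == prev + 1:
                prev = p
                continue
            seeds.append(SeedMatch(run_start, run_start + d, prev - run_start + k))
            run_start = prev = p
        seeds.append(SeedMatch(run_start, run_start + d, prev - run_start + k))
    seeds.sort(key=lambda sd: (sd.pos5, sd.pos3))
    return seeds


# ---------------------------------------------------------------------------
# Stage 2: chaining + banded X-drop extension
# ---------------------------------------------------------------------------

@dataclass
class _Chain:
    diag: int
    a_start: int
    a_end: int
    cover: int
    anchor: SeedMatch = field(default=None)  # longest seed


def _cluster_seeds(seeds: Sequence[SeedMatch], params: DetectionParams) -> list[_Chain]:
    chains: list[_Chain] = []
    for sd in sorted(seeds, key=lambda s: (s.diag, s.pos5)):
        placed = False
        for ch in chains:
            if abs(sd.diag - ch.diag) <= params.band and \
                    sd.pos5 <= ch.a_end + params.chain_gap and sd.pos5 >= ch.a_start:
                ch.a_end = max(ch.a_end, sd.pos5 + sd.length)
                ch.cover += sd.length
                if sd.length > ch.anchor.length:
                    ch.anchor = sd
                placed = True
                break
        if not placed:
            chains.append(_Chain(diag=sd.diag, a_start=sd.pos5,
                                 a_end=sd.pos5 + sd.length, cover=sd.length,
                                 anchor=sd))
    return chains


def _xdrop_extend(a: str, b: str, params: DetectionParams) -> tuple[int, int, float]:
    """Banded affine-gap extension of prefixes of ``a`` vs ``b`` with X-drop.

    Returns (la, lb, score): the prefix lengths at the best-scoring cell.
    Extension stops once the best score in a row falls more than XDROP below
    the running maximum. N compares as a mismatch.
    """
    la_max, lb_max = len(a), len(b)
    if la_max == 0 or lb_max == 0:
        return 0, 0, 0.0
    band = params.band
    W = 2 * band + 1
    ea, eb = _encode(a), _encode(b)
    offs = np.arange(W)

    M = np.full(W, _NEG)
    Ix = np.full(W, _NEG)
    Iy = np.full(W, _NEG)
    M[band] = 0.0
    jmax0 = min(band, lb_max)
    for j in range(1, jmax0 + 1):
        Ix[band + j] = GAP_OPEN + (j - 1) * GAP_EXTEND
    best = 0.0
    best_la, best_lb = 0, 0
    imax = min(la_max, lb_max + band)
    for i in range(1, imax + 1):
        prev_state = np.maximum(M, np.maximum(Ix, Iy))
        jvals = i + offs - band
        valid = (jvals >= 1) & (jvals <= lb_max)
        bj = np.where(valid, jvals - 1, 0)
        ai = ea[i - 1]
        s = np.where((eb[bj] == ai) & (ai != 4) & (eb[bj] != 4), MATCH, MISMATCH)
        newM = prev_state + s
        newM[~valid] = _NEG
        # vertical (consume a): same j = previous row offset o+1
        prevM_up = np.concatenate([M[1:], [_NEG]])
        prevIy_up = np.concatenate([Iy[1:], [_NEG]])
        newIy = np.maximum(prevM_up + GAP_OPEN, prevIy_up + GAP_EXTEND)
        jy_valid = (jvals >= 0) & (jvals <= lb_max)
        newIy[~jy_valid] = _NEG
        # horizontal (consume b): within-row prefix max trick
        cand = newM - offs * GAP_EXTEND
        run = np.maximum.accumulate(cand)
        newIx = np.full(W, _NEG)
        newIx[1:] = GAP_OPEN + (offs[1:] - 1) * GAP_EXTEND + run[:-1]
        newIx[~valid] = _NEG
        newIx = np.maximum(newIx, _NEG)
        M, Ix, Iy = newM, newIx, newIy
        row_best_o = int(np.argmax(M))
        if M[row_best_o] > best:
            best = float(M[row_best_o])
            best_la, best_lb = i, int(i + row_best_o - band)
        state_max = max(float(M.max()), float(Ix.max()), float(Iy.max()))
        if state_max < best - XDROP:
            break
    return best_la, best_lb, best


_identity_aligner = Align.PairwiseAligner(
    mode="global", match_score=MATCH, mismatch_score=MISMATCH,
    open_gap_score=GAP_OPEN, extend_gap_score=GAP_EXTEND,
)


def alignment_identity(a: str, b: str) -> float:
    """Column identity of the optimal global alignment of a vs b
    (gap columns count in the denominator)."""
    aln = _identity_aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    matches = 0
    aligned_cols = 0
    for (as_, ae), (bs, be) in zip(blocks_a, blocks_b):
        aligned_cols += ae - as_
        for x, y in zip(a[as_:ae], b[bs:be]):
            if x == y and x != "N":
                matches += 1
    total_cols = aln.length
    return matches / total_cols if total_cols else 0.0


def chain_and_extend(seq: GenomeSequence | str, seeds: Sequence[SeedMatch],
                     params: DetectionParams) -> list[CandidateElement]:
    """Chain seeds and extend each chain into a candidate LTR pair.

    Candidates violating any structural invariant are silently discarded
    (counts are logged); duplicates arising from split chains collapse.
    """
    s = seq.residues if isinstance(seq, GenomeSequence) else seq
    chrom = seq.id if isinstance(seq, GenomeSequence) else "seq"
    n = len(s)
    chains = _cluster_seeds(seeds, params)
    chains.sort(key=lambda c: (-c.cover, c.a_start, c.diag))

    candidates: list[CandidateElement] = []
    attempted: list[tuple[int, int, int]] = []  # (diag, a_lo, a_hi) regions tried
    n_raw = n_filtered = 0
    for ch in chains:
        covered = False
        for diag, lo, hi in attempted:
            if abs(ch.diag - diag) <= params.band and \
                    ch.a_start >= lo - params.band and ch.a_end <= hi + params.band:
                covered = True
                break
        if covered:
            continue
        a_start, a_end = ch.a_start, ch.a_end
        b_start, b_end = a_start + ch.diag, a_end + ch.diag
        # leftward extension (reversed prefixes)
        capA = min(a_start, params.ltr_max)
        capB = min(max(b_start - a_end, 0), params.ltr_max)
        laL, lbL, _ = _xdrop_extend(s[a_start - capA:a_start][::-1],
                                    s[b_start - capB:b_start][::-1], params)
        new_b_start = b_start - lbL
        # rightward extension
        capA = min(max(new_b_start - a_end, 0), params.ltr_max)
        capB = min(n - b_end, params.ltr_max)
        laR, lbR, _ = _xdrop_extend(s[a_end:a_end + capA],
                                    s[b_end:b_end + capB], params)
        ltr5_start, ltr5_end = a_start - laL, a_end + laR
        ltr3_start, ltr3_end = new_b_start, b_end + lbR
        attempted.append((ch.diag, ltr5_start, ltr5_end))
        n_raw += 1
        if ltr5_end <= ltr5_start or ltr3_end <= ltr3_start:
            n_filtered += 1
            continue
        identity = alignment_identity(s[ltr5_start:ltr5_end], s[ltr3_start:ltr3_end])
        cand = CandidateElement(
            chrom=chrom, ltr5_start=ltr5_start, ltr5_end=ltr5_end,
            ltr3_start=ltr3_start, ltr3_end=ltr3_end, identity=identity,
        )
        if cand.violations(params):
            n_filtered += 1
            continue
        cand.score = identity * 0.5 * (cand.ltr5_len + cand.ltr3_len)
        candidates.append(cand)

    # collapse duplicates from split chains
    seen = set()
    unique: list[CandidateElement] = []
    for cand in sorted(candidates, key=lambda c: (c.ltr5_start, c.ltr3_start,
                                                  c.ltr5_end, c.ltr3_end)):
        key = (cand.ltr5_start, cand.ltr5_end, cand.ltr3_start, cand.ltr3_end)
        if key not in seen:
            seen.add(key)
            unique.append(cand)
    logger.info("stage=extend chrom=%s chains=%d extended=%d filtered=%d candidates=%d",
                chrom, len(chains), n_raw, n_filtered, len(unique))
    return unique


# ---------------------------------------------------------------------------
# Stage 3: overlap resolution
# ---------------------------------------------------------------------------

def _intervals_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def resolve_overlaps(candidates: Sequence[CandidateElement]) -> list[CandidateElement]:
    """Greedy selection by descending score.

    A candidate is kept iff its full span overlaps no kept candidate's LTRs;
    a candidate strictly inside another's internal region therefore survives
    (nested insertions). Ties break toward the lower ltr5_start.
    """
    kept: list[CandidateElement] = []
    for cand in sorted(candidates, key=lambda c: (-c.score, c.ltr5_start, c.ltr3_start)):
        span = cand.span
        ok = True
        for other in kept:
            if _intervals_overlap(span, (other.ltr5_start, other.ltr5_end)) or \
                    _intervals_overlap(span, (other.ltr3_start, other.ltr3_end)):
                ok = False
                break
        if ok:
            kept.append(cand)
    kept.sort(key=lambda c: (c.ltr5_start, c.ltr3_start))
    logger.info("stage=overlap in=%d kept=%d", len(candidates), len(kept))
    return kept


# ---------------------------------------------------------------------------
# Stage 4: motif refinement and TSD search
# ---------------------------------------------------------------------------

def _nearest_motif(s: str, motif: str, anchor: int, window: int,
                   is_start: bool) -> Optional[int]:
    """Position of the occurrence of ``motif`` nearest to ``anchor``.

    For a start boundary the motif begins at the returned position; for an
    end boundary it ends (exclusively) there. Equidistant ties prefer the
    interior side of the element (right for starts, left for ends).
    """
    n = len(s)
    best = None
    for p in range(anchor - window, anchor + window + 1):
        if is_start:
            if p < 0 or p + 2 > n or s[p:p + 2] != motif:
                continue
        else:
            if p - 2 < 0 or p > n or s[p - 2:p] != motif:
                continue
        dist = abs(p - anchor)
        if best is None:
            best = p
        else:
            bdist = abs(best - anchor)
            if dist < bdist or (dist == bdist and
                                ((is_start and p > best) or (not is_start and p < best))):
                best = p
    return best


def _joint_boundary_anchor(s: str, cand: CandidateElement,
                           params: DetectionParams
                           ) -> Optional[tuple[int, int]]:
    """Element boundary pair anchored by TG + CA + an exact 4-6 bp TSD.

    Searches +-boundary_window around the detected element start/end for a
    (start, end) pair where the start sits on TG, the end on CA, and the
    flanks carry an exact target-site duplication. The joint requirement is
    specific enough (~1e-5 per position pair by chance) to correct extension
    overshoot well beyond the plain motif window. Returns the closest such
    pair, or None.
    """
    n = len(s)
    W = params.boundary_window
    a0, e0 = cand.ltr5_start, cand.ltr3_end
    tg_pos = [p for p in range(max(0, a0 - W), min(n - 1, a0 + W) + 1)
              if s[p:p + 2] == "TG"]
    ca_pos = [q for q in range(max(2, e0 - W), min(n, e0 + W) + 1)
              if s[q - 2:q] == "CA"]
    best = None  # (dist, -L, -p, q, p)
    for p in tg_pos:
        for q in ca_pos:
            for L in sorted(params.tsd_lengths, reverse=True):
                if p - L < 0 or q + L > n:
                    continue
                up = s[p - L:p]
                if "N" in up or up != s[q:q + L]:
                    continue
                key = (abs(p - a0) + abs(q - e0), -L, -p, q)
                if best is None or key < best[0]:
                    best = (key, (p, q))
                break
    return None if best is None else best[1]


def refine_motif(seq: GenomeSequence | str, cand: CandidateElement,
                 params: DetectionParams) -> CandidateElement:
    """Snap boundaries to the terminal TG...CA dinucleotides.

    A jointly TSD-anchored boundary pair (TG start + CA end + exact flanking
    duplication, within +-boundary_window) takes precedence; otherwise the 5'
    start of the 5' LTR is moved to the nearest TG within +-motif_window,
    shifting the 3' LTR start by the same offset (the two LTRs are copies of
    the same repeat), and symmetrically the 3' end of the 3' LTR is moved to
    the nearest CA, shifting the 5' LTR end. A shift that would break a
    structural invariant is reverted and the flag left false.
    """
    s = seq.residues if isinstance(seq, GenomeSequence) else seq
    c = replace(cand)
    tg = ca = False
    anchor = _joint_boundary_anchor(s, c, params)
    if anchor is not None:
        p, q = anchor
        off5 = p - c.ltr5_start
        off3 = q - c.ltr3_end
        trial = replace(c, ltr5_start=p, ltr3_start=c.ltr3_start + off5,
                        ltr3_end=q, ltr5_end=c.ltr5_end + off3)
        if not trial.violations(params) and trial.ltr5_start >= 0 and \
                trial.ltr3_end <= len(s):
            trial.tg_ca = (True, True)
            return trial
    p = _nearest_motif(s, "TG", c.ltr5_start, params.motif_window, is_start=True)
    if p is not None:
        off = p - c.ltr5_start
        trial = replace(c, ltr5_start=c.ltr5_start + off, ltr3_start=c.ltr3_start + off)
        if not trial.violations(params) and trial.ltr5_start >= 0:
            c = trial
            tg = True
    q = _nearest_motif(s, "CA", c.ltr3_end, params.motif_window, is_start=False)
    if q is not None:
        off = q - c.ltr3_end
        trial = replace(c, ltr3_end=c.ltr3_end + off, ltr5_end=c.ltr5_end + off)
        if not trial.violations(params) and trial.ltr3_end <= len(s):
            c = trial
            ca = True
    c.tg_ca = (tg, ca)
    return c


def detect_tsd(seq: GenomeSequence | str, cand: CandidateElement,
               params: DetectionParams) -> Optional[str]:
    """Exact target-site duplication flanking the element, longest first.

    Compares the L bp immediately upstream of the 5' LTR with the L bp
    immediately downstream of the 3' LTR for L = 6, 5, 4 (configurable).
    A flank containing N never matches; flanks beyond the contig edge are
    unavailable.
    """
    s = seq.residues if isinstance(seq, GenomeSequence) else seq
    for L in sorted(params.tsd_lengths, reverse=True):
        lo = cand.ltr5_start - L
        hi = cand.ltr3_end + L
        if lo < 0 or hi > len(s):
            continue
        up = s[lo:cand.ltr5_start]
        down = s[cand.ltr3_end:hi]
        if "N" in up:
            continue
        if up == down:
            return up
    return None


def detect_elements(seq: GenomeSequence, params: DetectionParams
                    ) -> tuple[list[CandidateElement], dict[str, int]]:
    """Full detection pass on one contig; returns refined candidates and
    per-stage counts."""
    seeds = find_seed_matches(seq, params)
    cands = chain_and_extend(seq, seeds, params)
    kept = resolve_overlaps(cands)
    refined: list[CandidateElement] = []
    for cand in kept:
        c = refine_motif(seq, cand, params)
        c.tsd = detect_tsd(seq, c, params)
        refined.append(c)
    counts = {
        "n_seeds": len(seeds),
        "n_candidates": len(cands),
        "n_after_overlap": len(kept),
        "n_with_tg_ca": sum(1 for c in refined if c.tg_ca[0] and c.tg_ca[1]),
        "n_with_tsd": sum(1 for c in refined if c.tsd is not None),
    }
    logger.info("stage=detect chrom=%s %s", seq.id,
                " ".join(f"{k}={v}" for k, v in counts.items()))
    return refined, counts
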