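"""Synthetic genomes with LTR retrotransposons of known structure.

The generator builds elements the way the detection pipeline expects to find
them: a random LTR beginning TG and ending CA, an internal region obtained by
reverse-translating labeled library peptides (uniform random synonymous
codons) joined by 30-bp random linkers, a mutated copy of the LTR at the 3'
end, and an exact 4-6 bp target-site duplication on both flanks. Mutations
are applied to the 3' LTR copy only — the detector and the K2P estimator see
pair divergence, not per-branch history — with independent per-site
transition/transversion draws, so realized counts are exactly binomial and
recountable from the emitted sequences. The terminal TG/CA dinucleotides are
exempt from mutation so that motif-built elements keep their motif.

Negative features probe false positives: solo LTRs (recombination leftovers),
truncated elements (one or more domains deleted), and tandem decoys (short
close repeats below the structural thresholds).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .age_estimate import k2p_distance
from .classify import UNCLASSIFIED
from .domain_annot import reverse_complement
from .formats_io import DomainLibraryRecord, GenomeSequence, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# codons per amino acid (standard code), for reverse translation
_CODONS: dict[str, list[str]] = {}
from .domain_annot import CODON_TABLE as _CT  # noqa: E402

for _codon, _aa in _CT.items():
    _CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class ElementSpec:
    """Blueprint for one inserted element."""

    ltr_length: int = 500
    internal_order: tuple[tuple[str, str], ...] = ()  # (domain_type, library_id)
    superfamily: str = "Gypsy"
    lineage: str = "unresolved"
    strand: str = "+"
    tsd: Optional[str] = None
    P_target: float = 0.0
    Q_target: float = 0.0
    indel_rate: float = 0.0

    def __post_init__(self):
        if not (100 <= self.ltr_length <= 3000):
            raise ValueError("ltr_length must be in [100, 3000]")
        if self.P_target + self.Q_target >= 1.0 or \
                1.0 - 2.0 * self.P_target - self.Q_target <= 0.0:
            raise ValueError("mutation targets too large (K2P would saturate)")


@dataclass
class TruthRecord:
    """Ground truth for one placed feature (0-based half-open coordinates)."""

    feature_kind: str  # intact | solo_ltr | truncated | tandem_decoy
    chrom: str
    start: int
    end: int
    ltr5_start: int = -1
    ltr5_end: int = -1
    ltr3_start: int = -1
    ltr3_end: int = -1
    strand: str = "+"
    superfamily: str = UNCLASSIFIED
    lineage: str = "unresolved"
    tsd: Optional[str] = None
    true_P: float = float("nan")
    true_Q: float = float("nan")
    true_d: float = float("nan")


@dataclass
class SimulationConfig:
    """Background composition plus the feature roster."""

    background_length: int = 200_000
    gc: float = 0.42
    elements: list[ElementSpec] = field(default_factory=list)
    n_solo: int = 0
    n_truncated: int = 0
    n_tandem: int = 0
    min_spacing: int = 2000


def canonical_order(superfamily: str,
                    library: Sequence[DomainLibraryRecord]) -> tuple[tuple[str, str], ...]:
    """Canonical single-cassette domain order for a superfamily, using the
    first library record of each (type, superfamily)."""
    order = ("GAG", "AP", "INT", "RT", "RH") if superfamily == "Copia" \
        else ("GAG", "AP", "RT", "RH", "INT")
    ids = {}
    for rec in library:
        if rec.superfamily == superfamily and rec.domain_type not in ids:
            ids[rec.domain_type] = rec.id
    missing = [t for t in order if t not in ids]
    if missing:
        raise ValueError(f"library lacks {superfamily} records for {missing}")
    return tuple((t, ids[t]) for t in order)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(_BASES[rng.choice(4, size=n, p=p)]).decode("ascii")


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    """Uniform random synonymous codon for each residue."""
    out = []
    for aa in peptide:
        codons = _CODONS.get(aa)
        if not codons:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def mutate_ltr_copy(ltr: str, P_target: float, Q_target: float,
                    rng: np.random.Generator,
                    protect: Optional[set[int]] = None) -> tuple[str, int, int]:
    """Independent per-site mutation of one LTR copy.

    Each site receives a transition with probability ``P_target``, else a
    transversion with probability ``Q_target`` (mutually exclusive draws).
    Returns ``(mutated, n_transitions, n_transversions)``.
    """
    protect = protect or set()
    u = rng.random(len(ltr))
    tv_pick = rng.integers(2, size=len(ltr))
    out = list(ltr)
    n_ti = n_tv = 0
    for i, base in enumerate(ltr):
        if i in protect or base not in _TRANSITION:
            continue
        if u[i] < P_target:
            out[i] = _TRANSITION[base]
            n_ti += 1
        elif u[i] < P_target + Q_target:
            out[i] = _TRANSVERSIONS[base][tv_pick[i]]
            n_tv += 1
    return "".join(out), n_ti, n_tv


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Geometric-length (mean 3 bp) insertions/deletions at the given per-site
    rate; robustness-test mode only."""
    out = []
    i = 0
    while i < len(seq):
        if rng.random() < rate:
            length = int(rng.geometric(1.0 / 3.0))
            if rng.random() < 0.5:
                i += length  # deletion
                continue
            out.append(random_dna(rng, length))
        out.append(seq[i])
        i += 1
    return "".join(out)


def build_element(spec: ElementSpec, library: Sequence[DomainLibraryRecord],
                  rng: np.random.Generator) -> tuple[str, TruthRecord]:
    """Assemble one element; truth coordinates are relative to the returned
    sequence (chrom unset)."""
    lib = {rec.id: rec for rec in library}
    for _, lid in spec.internal_order:
        if lid not in lib:
            raise ValueError(f"library id {lid!r} not found")
    L = spec.ltr_length
    ltr = random_dna(rng, L)
    ltr = "TG" + ltr[2:L - 2] + "CA"
    parts = []
    for idx, (_, lid) in enumerate(spec.internal_order):
        if idx:
            parts.append(random_dna(rng, 30))
        parts.append(reverse_translate(lib[lid].peptide, rng))
    internal = "".join(parts)
    protect = {0, 1, L - 2, L - 1}
    ltr3, n_ti, n_tv = mutate_ltr_copy(ltr, spec.P_target, spec.Q_target, rng,
                                       protect=protect)
    if spec.indel_rate > 0.0:
        ltr3 = _apply_indels(ltr3, spec.indel_rate, rng)
    element = ltr + internal + ltr3
    if spec.strand == "-":
        element = reverse_complement(element)
    true_P = n_ti / L
    true_Q = n_tv / L
    truth = TruthRecord(
        feature_kind="intact", chrom="", start=0, end=len(element),
        ltr5_start=0, ltr5_end=L,
        ltr3_start=len(element) - len(ltr3), ltr3_end=len(element),
        strand=spec.strand, superfamily=spec.superfamily, lineage=spec.lineage,
        tsd=spec.tsd, true_P=true_P, true_Q=true_Q,
        true_d=k2p_distance(true_P, true_Q),
    )
    return element, truth


def simulate_genome(config: SimulationConfig, rng_seed: int,
                    library: Sequence[DomainLibraryRecord],
                    chrom: str = "chr1") -> tuple[GenomeSequence, list[TruthRecord]]:
    """Place elements and negatives at non-overlapping positions (>= min
    spacing apart) on an i.i.d. background; fully reproducible from the seed."""
    rng = np.random.default_rng(rng_seed)
    inserts: list[tuple[str, TruthRecord]] = []

    for spec in config.elements:
        element, truth = build_element(spec, library, rng)
        if spec.tsd:
            seq = spec.tsd + element + spec.tsd
            off = len(spec.tsd)
        else:
            seq, off = element, 0
        truth.start += off
        truth.end += off
        truth.ltr5_start += off
        truth.ltr5_end += off
        truth.ltr3_start += off
        truth.ltr3_end += off
        inserts.append((seq, truth))

    for _ in range(config.n_solo):
        L = int(rng.integers(300, 1501))
        ltr = random_dna(rng, L)
        ltr = "TG" + ltr[2:L - 2] + "CA"
        tsd = random_dna(rng, int(rng.integers(4, 7)))
        seq = tsd + ltr + tsd
        inserts.append((seq, TruthRecord(
            feature_kind="solo_ltr", chrom=chrom, start=len(tsd),
            end=len(tsd) + L, tsd=tsd)))

    for _ in range(config.n_truncated):
        base = config.elements[int(rng.integers(len(config.elements)))] \
            if config.elements else ElementSpec()
        order = list(base.internal_order)
        if order:
            n_drop = int(rng.integers(1, min(3, len(order)) + 1))
            for _ in range(n_drop):
                order.pop(int(rng.integers(len(order))))
        spec = dataclasses.replace(base, internal_order=tuple(order), tsd=None)
        element, truth = build_element(spec, library, rng)
        truth.feature_kind = "truncated"
        inserts.append((element, truth))

    for _ in range(config.n_tandem):
        rep = random_dna(rng, 80)
        seq = rep + random_dna(rng, 500) + rep
        inserts.append((seq, TruthRecord(feature_kind="tandem_decoy", chrom=chrom,
                                         start=0, end=len(seq))))

    order = rng.permutation(len(inserts))
    inserts = [inserts[i] for i in order]

    background = random_dna(rng, config.background_length, config.gc)
    positions = _place(rng, config.background_length,
                       [len(s) for s, _ in inserts], config.min_spacing)

    pieces = []
    truths: list[TruthRecord] = []
    cursor = 0
    genome_offset = 0
    for (seq, truth), pos in sorted(zip(inserts, positions), key=lambda t: t[1]):
        pieces.append(background[cursor:pos])
        genome_offset += pos - cursor
        shift = genome_offset
        truth.chrom = chrom
        truth.start += shift
        truth.end += shift
        if truth.ltr5_start >= 0:
            truth.ltr5_start += shift
            truth.ltr5_end += shift
            truth.ltr3_start += shift
            truth.ltr3_end += shift
        pieces.append(seq)
        genome_offset += len(seq)
        truths.append(truth)
        cursor = pos
    pieces.append(background[cursor:])
    genome = GenomeSequence(id=chrom, residues="".join(pieces))
    return genome, truths


def _place(rng: np.random.Generator, background_len: int,
           sizes: list[int], spacing: int) -> list[int]:
    """Feature start offsets in background coordinates, pairwise >= spacing
    apart (features are inserted, so spacing in background coordinates keeps
    them non-overlapping in the final genome)."""
    n = len(sizes)
    if n == 0:
        return []
    lo, hi = spacing, background_len - spacing
    avail = (hi - lo) - n * spacing
    if avail <= 0:
        raise ValueError("features cannot be placed without overlap; "
                         "use a larger background or fewer features")
    raw = np.sort(rng.integers(0, avail, size=n))
    pos = lo + raw + np.arange(n) * spacing
    return [int(p) for p in pos]


# ---------------------------------------------------------------------------
# Manifest I/O and evaluation
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["feature_kind", "chrom", "start", "end", "ltr5_start",
                    "ltr5_end", "ltr3_start", "ltr3_end", "strand",
                    "superfamily", "lineage", "tsd", "true_P", "true_Q", "true_d"]


def manifest_frame(truths: Sequence[TruthRecord]) -> pd.DataFrame:
    """Truth records as a DataFrame (still 0-based half-open)."""
    return pd.DataFrame([dataclasses.asdict(t) for t in truths],
                        columns=MANIFEST_COLUMNS)


def write_manifest(truths: Sequence[TruthRecord], path: str | os.PathLike) -> None:
    """Manifest TSV; coordinate columns serialized 1-based inclusive."""
    df = manifest_frame(truths).copy()
    for col in ("start", "ltr5_start", "ltr3_start"):
        df[col] = df[col].where(df[col] < 0, df[col] + 1)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a manifest TSV back to 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t", dtype={"tsd": "string"})
    for col in ("start", "ltr5_start", "ltr3_start"):
        df[col] = df[col].where(df[col] < 0, df[col] - 1)
    df["tsd"] = df["tsd"].where(df["tsd"].notna(), None)
    return df


def simulate_to_files(config: SimulationConfig, rng_seed: int,
                      library: Sequence[DomainLibraryRecord],
                      out_dir: str | os.PathLike) -> tuple[str, str]:
    """Write genome FASTA + manifest TSV; returns their paths."""
    os.makedirs(out_dir, exist_ok=True)
    genome, truths = simulate_genome(config, rng_seed, library)
    fasta = os.path.join(out_dir, "genome.fa")
    manifest = os.path.join(out_dir, "manifest.tsv")
    write_fasta([genome], fasta)
    write_manifest(truths, manifest)
    return fasta, manifest


def _reciprocal_overlap(a0: int, a1: int, b0: int, b1: int) -> float:
    inter = max(0, min(a1, b1) - max(a0, b0))
    if inter == 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


@dataclass
class EvaluationResult:
    n_truth: int
    n_pred: int
    n_matched: int
    recall: float
    precision: float
    boundary_mae: float
    superfamily_accuracy: float
    lineage_accuracy: float
    tsd_exact_rate: float
    divergence_errors: list[float]
    negatives_hit: int

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        errs = d.pop("divergence_errors")
        d["divergence_mean_abs_error"] = float(np.mean(np.abs(errs))) if errs else float("nan")
        return d


def evaluate_against_truth(predictions: pd.DataFrame, manifest: pd.DataFrame,
                           slop: int = 20) -> EvaluationResult:
    """Match intact predictions against the truth manifest.

    A prediction matches a truth element when both LTR intervals reciprocally
    overlap >= 50% and every boundary agrees within ``slop`` bp. Matching is
    1-1, greedy by total boundary error. Precision is NaN when there are no
    predictions. ``negatives_hit`` counts matches of predictions to solo/
    truncated/tandem features by >= 50% span overlap (should be 0).
    """
    if predictions["ltr_id"].duplicated().any():
        raise ValueError("duplicate LTR_IDs in predictions")
    truth_intact = manifest[manifest["feature_kind"] == "intact"].reset_index()
    pairs = []
    for pi, p in predictions.iterrows():
        for ti, t in truth_intact.iterrows():
            if p["chrom"] != t["chrom"]:
                continue
            r5 = _reciprocal_overlap(p["ltr5_start"], p["ltr5_end"],
                                     t["ltr5_start"], t["ltr5_end"])
            r3 = _reciprocal_overlap(p["ltr3_start"], p["ltr3_end"],
                                     t["ltr3_start"], t["ltr3_end"])
            if r5 < 0.5 or r3 < 0.5:
                continue
            devs = [abs(int(p[c]) - int(t[c])) for c in
                    ("ltr5_start", "ltr5_end", "ltr3_start", "ltr3_end")]
            if max(devs) > slop:
                continue
            pairs.append((sum(devs), pi, ti, devs))
    pairs.sort(key=lambda x: (x[0], x[1], x[2]))
    used_p: set = set()
    used_t: set = set()
    matches = []
    for total, pi, ti, devs in pairs:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
        matches.append((pi, ti, devs))

    n_truth = len(truth_intact)
    n_pred = len(predictions)
    n_matched = len(matches)
    recall = n_matched / n_truth if n_truth else float("nan")
    precision = n_matched / n_pred if n_pred else float("nan")

    boundary_devs: list[int] = []
    sf_ok = lin_ok = 0
    tsd_ok = tsd_n = 0
    div_errors: list[float] = []
    for pi, ti, devs in matches:
        p = predictions.loc[pi]
        t = truth_intact.loc[ti]
        boundary_devs.extend(devs)
        if p["superfamily"] == t["superfamily"]:
            sf_ok += 1
        if p["lineage"] == t["lineage"]:
            lin_ok += 1
        if t["tsd"] is not None and not (isinstance(t["tsd"], float) and np.isnan(t["tsd"])):
            tsd_n += 1
            if p["tsd"] == t["tsd"]:
                tsd_ok += 1
        if np.isfinite(p["divergence"]) and np.isfinite(t["true_d"]):
            div_errors.append(float(p["divergence"]) - float(t["true_d"]))

    negatives = manifest[manifest["feature_kind"] != "intact"]
    negatives_hit = 0
    for _, t in negatives.iterrows():
        for _, p in predictions.iterrows():
            if p["chrom"] != t["chrom"]:
                continue
            if _reciprocal_overlap(p["ltr5_start"], p["ltr3_end"],
                                   t["start"], t["end"]) >= 0.5:
                negatives_hit += 1
                break

    return EvaluationResult(
        n_truth=n_truth, n_pred=n_pred, n_matched=n_matched,
        recall=recall, precision=precision,
        boundary_mae=float(np.mean(boundary_devs)) if boundary_devs else float("nan"),
        superfamily_accuracy=sf_ok / n_matched if n_matched else float("nan"),
        lineage_accuracy=lin_ok / n_matched if n_matched else float("nan"),
        tsd_exact_rate=tsd_ok / tsd_n if tsd_n else float("nan"),
        divergence_errors=div_errors,
        negatives_hit=negatives_hit,
    )


# ---------------------------------------------------------------------------
# Standard benchmark roster
# ---------------------------------------------------------------------------

def benchmark_config(rng_seed: int, library: Sequence[DomainLibraryRecord],
                     n_intact: int = 50, n_solo: int = 7, n_truncated: int = 7,
                     n_tandem: int = 6, background_length: int = 2_000_000,
                     zero_divergence: bool = False) -> SimulationConfig:
    """The standard validation roster: ``n_intact`` canonical elements (LTR
    300-1500 bp, K2P divergence <= 0.05, random strand, 4-6 bp TSD, alternating
    Copia/Gypsy) plus negative features, on a 2 Mb background."""
    rng = np.random.default_rng(rng_seed)
    lineages = {}
    for rec in library:
        lineages.setdefault(rec.superfamily, rec.lineage)
    specs = []
    for i in range(n_intact):
        superfamily = "Copia" if i % 2 == 0 else "Gypsy"
        P = 0.0 if zero_divergence else float(rng.uniform(0.004, 0.032))
        specs.append(ElementSpec(
            ltr_length=int(rng.integers(300, 1501)),
            internal_order=canonical_order(superfamily, library),
            superfamily=superfamily,
            lineage=lineages.get(superfamily, "unresolved"),
            strand="+" if rng.random() < 0.5 else "-",
            tsd=random_dna(rng, int(rng.integers(4, 7))),
            P_target=P, Q_target=P / 2.0,
        ))
    return SimulationConfig(
        background_length=background_length, gc=0.42, elements=specs,
        n_solo=n_solo, n_truncated=n_truncated, n_tandem=n_tandem,
    )
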