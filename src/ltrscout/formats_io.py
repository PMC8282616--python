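"""Readers and writers for the on-disk formats of the toolkit.

Genome assemblies and protein libraries come in as FASTA; annotations go out
as GFF3, as element FASTA, and as a ten-column tab-separated annotation table
(one row per LTR and per protein-domain hit of each intact element).

Coordinate convention: everything in memory is 0-based half-open; everything
serialized (GFF3, annotation table, manifest) is 1-based inclusive.
"""

from __future__ import annotations

import math
import os
import tempfile
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .elements import AnnotatedElement

DOMAIN_TYPES = ("GAG", "AP", "INT", "RT", "RH")
SUPERFAMILIES = ("Copia", "Gypsy")

#: The exact column set (and order) of the annotation table.
TABLE_COLUMNS = (
    "Species",
    "LTR_ID",
    "Chromosome",
    "Start",
    "End",
    "Domain",
    "Length(bp)",
    "Superfamilies",
    "Lineages",
    "Divergence",
)

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


class LibraryFormatError(ValueError):
    """Raised for malformed domain-library headers."""


class GffConsistencyError(ValueError):
    """Raised when a GFF3 child feature would fall outside its parent."""


def _normalize_residues(raw: str, header: str) -> str:
    # Uppercase; IUPAC ambiguity codes (and gap/stop symbols) become N.
    up = raw.upper()
    out = []
    for ch in up:
        if ch in "ACGTN":
            out.append(ch)
        elif ch.isalpha() or ch in "-.*":
            out.append("N")
        else:
            raise FastaFormatError(
                f"illegal character {ch!r} in sequence of record {header!r}"
            )
    return "".join(out)


@dataclass(frozen=True)
class GenomeSequence:
    """One FASTA record: uppercase residues over {A,C,G,T,N}."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainLibraryRecord:
    """A labeled reference peptide from the domain library.

    Header dialect: ``>id|domain|superfamily|lineage`` (exactly four
    pipe-delimited fields; REXdb-style labels).
    """

    id: str
    domain_type: str
    superfamily: str
    lineage: str
    peptide: str


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    """Read a nucleotide FASTA into normalized :class:`GenomeSequence` records."""
    records: list[GenomeSequence] = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            records.append(
                GenomeSequence(id=header.split()[0] if header.split() else "",
                               residues=_normalize_residues(seq, header))
            )
    # SimpleFastaParser silently skips leading junk; enforce the format.
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaFormatError("sequence line before any FASTA header")
            break
    if not records:
        raise FastaFormatError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[GenomeSequence | tuple[str, str]],
                path: str | os.PathLike, width: int = 60) -> None:
    """Write records (GenomeSequence or ``(id, seq)`` pairs) as FASTA."""
    with _atomic_open(path) as fh:
        for rec in records:
            if isinstance(rec, GenomeSequence):
                rid, seq = rec.id, rec.residues
            else:
                rid, seq = rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_domain_library(path: str | os.PathLike) -> list[DomainLibraryRecord]:
    """Read the labeled protein-domain library.

    Each header must be ``id|domain|superfamily|lineage`` with
    domain in {GAG,AP,INT,RT,RH} and superfamily in {Copia,Gypsy}.
    """
    records: list[DomainLibraryRecord] = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            token = header.split()[0] if header.split() else ""
            fields = token.split("|")
            if len(fields) != 4:
                raise LibraryFormatError(
                    f"header {header!r}: expected 4 pipe-delimited fields, got {len(fields)}"
                )
            rid, domain, superfamily, lineage = fields
            if domain not in DOMAIN_TYPES:
                raise LibraryFormatError(
                    f"header {header!r}: unknown domain type {domain!r}"
                )
            if superfamily not in SUPERFAMILIES:
                raise LibraryFormatError(
                    f"header {header!r}: unknown superfamily {superfamily!r}"
                )
            if not lineage:
                raise LibraryFormatError(f"header {header!r}: empty lineage")
            pep = seq.upper().replace(" ", "")
            if len(pep) < 20:
                raise LibraryFormatError(
                    f"header {header!r}: peptide shorter than 20 residues"
                )
            if not set(pep) <= _AA_LETTERS:
                bad = sorted(set(pep) - _AA_LETTERS)
                raise LibraryFormatError(
                    f"header {header!r}: illegal peptide characters {bad}"
                )
            records.append(DomainLibraryRecord(rid, domain, superfamily, lineage, pep))
    if not records:
        raise LibraryFormatError(f"no records in library {path}")
    return records


def _format_divergence(element: "AnnotatedElement") -> str:
    age = element.age
    if age is None:
        raise ValueError(
            f"element {element.ltr_id} lacks divergence; run the age stage first"
        )
    if age.saturated or math.isnan(age.d):
        return "NA"
    return f"{age.d:.6f}"


def write_annotation_table(elements: Sequence["AnnotatedElement"], species: str,
                           path: str | os.PathLike) -> None:
    """Write the ten-column annotation table (tab-separated, 1-based inclusive).

    One row per LTR (Domain = LTR5/LTR3) plus one row per accepted domain hit,
    all sharing the element's LTR_ID, length, classification and divergence.
    Only intact elements may be tabulated.
    """
    with _atomic_open(path) as fh:
        fh.write("\t".join(TABLE_COLUMNS) + "\n")
        for el in elements:
            if not el.report.is_intact:
                raise ValueError(
                    f"element {el.ltr_id} is not intact; only intact elements are tabulated"
                )
            div = _format_divergence(el)
            length = el.ltr3_end - el.ltr5_start
            rows: list[tuple[int, int, str]] = [
                (el.ltr5_start, el.ltr5_end, "LTR5"),
                (el.ltr3_start, el.ltr3_end, "LTR3"),
            ]
            for hit in el.hits:
                gs, ge = el.hit_genomic_span(hit)
                rows.append((gs, ge, hit.domain_type))
            rows.sort(key=lambda r: (r[0], r[1]))
            for start, end, domain in rows:
                fh.write("\t".join([
                    species,
                    el.ltr_id,
                    el.chrom,
                    str(start + 1),
                    str(end),
                    domain,
                    str(length),
                    el.classification.superfamily,
                    el.classification.lineage,
                    div,
                ]) + "\n")


def _gff_attrs(pairs: list[tuple[str, str]]) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs)


def write_gff3(elements: Sequence["AnnotatedElement"], path: str | os.PathLike) -> None:
    """Write one LTR_retrotransposon feature per element with children
    long_terminal_repeat (x2), target_site_duplication (0-2) and one
    protein_match per domain hit.

    The parent span covers all children (it is widened to include TSDs,
    which flank the element).
    """
    lines = ["##gff-version 3"]
    for el in elements:
        div = "NA" if el.age is None or el.age.saturated else f"{el.age.d:.6f}"
        tsd = el.candidate.tsd or "none"
        tg, ca = el.candidate.tg_ca
        children: list[tuple[int, int, str, str]] = []  # start, end, type, attrs
        eid = el.ltr_id
        children.append((el.ltr5_start, el.ltr5_end, "long_terminal_repeat",
                         _gff_attrs([("ID", f"{eid}:LTR5"), ("Parent", eid)])))
        children.append((el.ltr3_start, el.ltr3_end, "long_terminal_repeat",
                         _gff_attrs([("ID", f"{eid}:LTR3"), ("Parent", eid)])))
        if el.candidate.tsd:
            tlen = len(el.candidate.tsd)
            children.append((el.ltr5_start - tlen, el.ltr5_start,
                             "target_site_duplication",
                             _gff_attrs([("ID", f"{eid}:TSD5"), ("Parent", eid)])))
            children.append((el.ltr3_end, el.ltr3_end + tlen,
                             "target_site_duplication",
                             _gff_attrs([("ID", f"{eid}:TSD3"), ("Parent", eid)])))
        for i, hit in enumerate(el.hits, 1):
            gs, ge = el.hit_genomic_span(hit)
            children.append((gs, ge, "protein_match",
                             _gff_attrs([
                                 ("ID", f"{eid}:{hit.domain_type}{i}"),
                                 ("Parent", eid),
                                 ("Name", hit.domain_type),
                                 ("library_id", hit.library_id),
                                 ("frame", str(hit.frame)),
                                 ("score", f"{hit.score:.1f}"),
                             ])))
        pstart = min(c[0] for c in children)
        pend = max(c[1] for c in children)
        for cs, ce, ctype, _ in children:
            if cs < pstart or ce > pend:
                raise GffConsistencyError(
                    f"{ctype} child [{cs},{ce}) outside parent span of {eid}"
                )
        strand = el.strand if el.strand in "+-" else "."
        parent_attrs = _gff_attrs([
            ("ID", eid),
            ("identity", f"{el.candidate.identity:.4f}"),
            ("superfamily", el.classification.superfamily),
            ("lineage", el.classification.lineage),
            ("divergence", div),
            ("tsd_motif", tsd),
            ("tg_ca", f"{str(tg).lower()},{str(ca).lower()}"),
        ])
        lines.append("\t".join([
            el.chrom, "ltrscout", "LTR_retrotransposon",
            str(pstart + 1), str(pend), f"{el.candidate.score:.2f}",
            strand, ".", parent_attrs,
        ]))
        for cs, ce, ctype, attrs in children:
            lines.append("\t".join([
                el.chrom, "ltrscout", ctype, str(cs + 1), str(ce),
                ".", strand, ".", attrs,
            ]))
    with _atomic_open(path) as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3_elements(path: str | os.PathLike):
    """Re-read a GFF3 written by :func:`write_gff3` into a prediction table.

    Returns a pandas DataFrame with 0-based half-open LTR coordinates,
    suitable for :func:`ltrscout.simulate.evaluate_against_truth`.
    """
    import gffutils
    import pandas as pd

    with open(path) as fh:
        data = fh.read()
    db = gffutils.create_db(data, ":memory:", from_string=True,
                            merge_strategy="error", keep_order=True)
    rows = []
    for feat in db.features_of_type("LTR_retrotransposon"):
        ltrs = sorted(
            ((c.start - 1, c.end) for c in db.children(feat, featuretype="long_terminal_repeat")),
        )
        if len(ltrs) != 2:
            raise GffConsistencyError(
                f"element {feat.id} has {len(ltrs)} long_terminal_repeat children"
            )
        tsd = feat.attributes.get("tsd_motif", ["none"])[0]
        div = feat.attributes.get("divergence", ["NA"])[0]
        rows.append({
            "ltr_id": feat.id,
            "chrom": feat.seqid,
            "ltr5_start": ltrs[0][0],
            "ltr5_end": ltrs[0][1],
            "ltr3_start": ltrs[1][0],
            "ltr3_end": ltrs[1][1],
            "superfamily": feat.attributes.get("superfamily", ["unclassified"])[0],
            "lineage": feat.attributes.get("lineage", ["unresolved"])[0],
            "tsd": None if tsd == "none" else tsd,
            "divergence": float("nan") if div == "NA" else float(div),
        })
    return pd.DataFrame(
        rows,
        columns=["ltr_id", "chrom", "ltr5_start", "ltr5_end", "ltr3_start",
                 "ltr3_end", "superfamily", "lineage", "tsd", "divergence"],
    )


def write_elements_fasta(genome: dict[str, str],
                         elements: Sequence["AnnotatedElement"],
                         path: str | os.PathLike) -> None:
    """Write the full genomic span of each element as FASTA (id = LTR_ID)."""
    recs = [(el.ltr_id, genome[el.chrom][el.ltr5_start:el.ltr3_end]) for el in elements]
    write_fasta(recs, path)


class _atomic_open:
    """Write to a temp file in the target directory, rename on success."""

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self._fh = None
        self._tmp = None

    def __enter__(self):
        d = os.path.dirname(os.path.abspath(self.path))
        fd, self._tmp = tempfile.mkstemp(dir=d, prefix=".tmp_ltrscout_")
        self._fh = os.fdopen(fd, "w")
        return self._fh

    def __exit__(self, exc_type, exc, tb):
        self._fh.close()
        if exc_type is None:
            os.replace(self._tmp, self.path)
        else:
            os.unlink(self._tmp)
        return False
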