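"""Scan orchestration: detect -> refine -> annotate -> classify -> age -> write.

Contigs are processed one at a time in input order and results concatenated,
so memory stays bounded and output order is fixed; the whole scan path is
deterministic (no unseeded randomness anywhere).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import formats_io
from .age_estimate import estimate_ltr_divergence
from .classify import Classification, classify_element, element_strand
from .domain_annot import DomainAnnotParams, annotate_domains, assess_intactness
from .elements import AnnotatedElement
from .formats_io import read_domain_library, read_fasta
from .ltr_detect import DetectionParams, detect_elements

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome_path: str
    library_path: str
    species: str
    output_prefix: str
    detect: DetectionParams = field(default_factory=DetectionParams)
    annotate: DomainAnnotParams = field(default_factory=DomainAnnotParams)
    rate: Optional[float] = None       # substitutions / site / year
    report_mya: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        for p in (self.genome_path, self.library_path):
            if not os.path.isfile(p) or not os.access(p, os.R_OK):
                raise FileNotFoundError(f"input not readable: {p}")


@dataclass
class RunSummary:
    """Per-stage accounting of one scan; the inequalities are invariants."""

    n_candidates: int = 0
    n_after_overlap: int = 0
    n_with_tg_ca: int = 0
    n_with_tsd: int = 0
    n_intact: int = 0
    n_copia: int = 0
    n_gypsy: int = 0
    n_unclassified: int = 0
    n_saturated_divergence: int = 0

    def check(self) -> None:
        if self.n_copia + self.n_gypsy + self.n_unclassified != self.n_intact:
            raise AssertionError("classification counts do not sum to n_intact")
        if not (self.n_intact <= self.n_after_overlap <= self.n_candidates):
            raise AssertionError("stage counts are not monotone")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | os.PathLike, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file with blocks detect/annotate/age."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    detect = DetectionParams(**{k: (tuple(v) if isinstance(v, list) else v)
                                for k, v in (doc.get("detect") or {}).items()})
    annotate = DomainAnnotParams(**(doc.get("annotate") or {}))
    age = doc.get("age") or {}
    kwargs = dict(
        genome_path=doc.get("genome_path", ""),
        library_path=doc.get("library_path", ""),
        species=doc.get("species", "species"),
        output_prefix=doc.get("output_prefix", "ltrscout_out"),
        detect=detect, annotate=annotate,
        rate=age.get("rate"), report_mya=bool(age.get("report_mya", False)),
        log_level=doc.get("log_level", "INFO"),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def scan_contig(seq: formats_io.GenomeSequence, library, config: RunConfig
                ) -> tuple[list[AnnotatedElement], dict[str, int]]:
    """Run every stage on one contig; returns intact elements + counts."""
    candidates, counts = detect_elements(seq, config.detect)
    elements: list[AnnotatedElement] = []
    n_saturated = 0
    for cand in candidates:
        internal = seq.residues[cand.ltr5_end:cand.ltr3_start]
        hits = annotate_domains(internal, library, config.annotate)
        report = assess_intactness(hits)
        if not report.is_intact:
            continue
        classification = classify_element(hits, report)
        strand = element_strand(hits)
        age = estimate_ltr_divergence(
            seq.residues[cand.ltr5_start:cand.ltr5_end],
            seq.residues[cand.ltr3_start:cand.ltr3_end],
            rate=config.rate,
        )
        if age.saturated:
            n_saturated += 1
        elements.append(AnnotatedElement(
            species=config.species, chrom=seq.id, candidate=cand, hits=hits,
            report=report, classification=classification, strand=strand, age=age,
        ))
    counts["n_intact"] = len(elements)
    counts["n_saturated_divergence"] = n_saturated
    return elements, counts


def run_scan(config: RunConfig) -> tuple[list[AnnotatedElement], RunSummary]:
    """Scan the genome and write PREFIX.gff3 / PREFIX.txt / PREFIX.elements.fa
    / PREFIX.summary.json (atomically). Returns the elements and the summary."""
    config.validate()
    genome = read_fasta(config.genome_path)
    library = read_domain_library(config.library_path)
    summary = RunSummary()
    elements: list[AnnotatedElement] = []
    for seq in genome:
        contig_elements, counts = scan_contig(seq, library, config)
        elements.extend(contig_elements)
        summary.n_candidates += counts["n_candidates"]
        summary.n_after_overlap += counts["n_after_overlap"]
        summary.n_with_tg_ca += counts["n_with_tg_ca"]
        summary.n_with_tsd += counts["n_with_tsd"]
        summary.n_intact += counts["n_intact"]
        summary.n_saturated_divergence += counts["n_saturated_divergence"]
    for el in elements:
        sf = el.classification.superfamily
        if sf == "Copia":
            summary.n_copia += 1
        elif sf == "Gypsy":
            summary.n_gypsy += 1
        else:
            summary.n_unclassified += 1
    summary.check()

    prefix = config.output_prefix
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)
    formats_io.write_gff3(elements, prefix + ".gff3")
    formats_io.write_annotation_table(elements, config.species, prefix + ".txt")
    formats_io.write_elements_fasta({s.id: s.residues for s in genome},
                                    elements, prefix + ".elements.fa")
    with formats_io._atomic_open(prefix + ".summary.json") as fh:
        json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("stage=summary %s",
                " ".join(f"{k}={v}" for k, v in summary.as_dict().items()))
    return elements, summary


def summarize_ages(tsv_path: str | os.PathLike, bin_width: float) -> pd.DataFrame:
    """Counts of elements per divergence bin, by superfamily and lineage.

    Bins are left-closed ``[i*bin_width, (i+1)*bin_width)``. Each element
    (LTR_ID) counts once; divergence is constant across its rows.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    df = pd.read_csv(tsv_path, sep="\t")
    if "Divergence" not in df.columns:
        raise ValueError("annotation table lacks a Divergence column")
    if df.empty:
        return pd.DataFrame(columns=["Superfamilies", "Lineages", "bin_start", "count"])
    per_el = df.drop_duplicates("LTR_ID")[["Superfamilies", "Lineages", "Divergence"]]
    per_el = per_el[pd.to_numeric(per_el["Divergence"], errors="coerce").notna()].copy()
    per_el["Divergence"] = per_el["Divergence"].astype(float)
    per_el["bin_start"] = (per_el["Divergence"] / bin_width).apply(math.floor) * bin_width
    out = (per_el.groupby(["Superfamilies", "Lineages", "bin_start"])
           .size().reset_index(name="count")
           .sort_values(["Superfamilies", "Lineages", "bin_start"])
           .reset_index(drop=True))
    return out
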