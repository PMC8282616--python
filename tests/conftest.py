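"""Shared fixtures: the bundled domain library, element factories, and a
small simulated genome reused across integration tests."""

from __future__ import annotations

import numpy as np
import pytest

from ltrscout.age_estimate import AgeResult, estimate_ltr_divergence
from ltrscout.classify import Classification
from ltrscout.cli import fixture_library_path
from ltrscout.domain_annot import DomainHit, IntactnessReport
from ltrscout.formats_io import read_domain_library
from ltrscout.elements import AnnotatedElement
from ltrscout.ltr_detect import CandidateElement


@pytest.fixture(scope="session")
def library():
    return read_domain_library(fixture_library_path())


@pytest.fixture(scope="session")
def library_by_key(library):
    return {(r.domain_type, r.superfamily): r for r in library}


def make_hit(domain_type="GAG", nt_start=0, nt_end=300, frame=1, strand="+",
             score=500.0, library_id="x", superfamily_label="Gypsy",
             lineage_label="Tekay") -> DomainHit:
    return DomainHit(domain_type=domain_type, nt_start=nt_start, nt_end=nt_end,
                     frame=frame, strand=strand, score=score,
                     library_id=library_id, superfamily_label=superfamily_label,
                     lineage_label=lineage_label)


def make_cassette_hits(order=("GAG", "AP", "RT", "RH", "INT"), strand="+",
                       superfamily_label="Gypsy", lineage_label="Tekay",
                       scores=None, start=0, length=300, gap=30):
    """Hits laid out left-to-right in the given nt order."""
    hits = []
    pos = start
    for i, t in enumerate(order):
        hits.append(make_hit(domain_type=t, nt_start=pos, nt_end=pos + length,
                             strand=strand, frame=1 if strand == "+" else -1,
                             score=(scores[i] if scores else 500.0),
                             superfamily_label=superfamily_label,
                             lineage_label=lineage_label))
        pos += length + gap
    return hits


def make_annotated_element(species="testus", chrom="chr1", ltr5_start=1000,
                           ltr_len=300, internal_len=1700, identity=0.99,
                           hits=None, superfamily="Gypsy", lineage="Tekay",
                           tsd="ACGTA", d=0.0123) -> AnnotatedElement:
    ltr5_end = ltr5_start + ltr_len
    ltr3_start = ltr5_end + internal_len
    ltr3_end = ltr3_start + ltr_len
    cand = CandidateElement(chrom=chrom, ltr5_start=ltr5_start, ltr5_end=ltr5_end,
                            ltr3_start=ltr3_start, ltr3_end=ltr3_end,
                            identity=identity, tg_ca=(True, True), tsd=tsd,
                            score=identity * ltr_len)
    if hits is None:
        hits = make_cassette_hits(superfamily_label=superfamily,
                                  lineage_label=lineage)
    report = IntactnessReport(is_intact=True,
                              present_types=frozenset(h.domain_type for h in hits),
                              multi_cassette=False, cassette_count=1)
    return AnnotatedElement(
        species=species, chrom=chrom, candidate=cand, hits=hits, report=report,
        classification=Classification(superfamily, lineage, "order+labels", False),
        strand="+", age=AgeResult(d=d, saturated=False),
    )


@pytest.fixture(scope="session")
def small_sim(library, tmp_path_factory):
    """A 300 kb genome with 6 intact elements and 6 negatives (session-wide)."""
    from ltrscout.simulate import benchmark_config, simulate_to_files

    out = tmp_path_factory.mktemp("smallsim")
    cfg = benchmark_config(7, library, n_intact=6, n_solo=2, n_truncated=2,
                           n_tandem=2, background_length=300_000)
    fasta, manifest = simulate_to_files(cfg, 7, library, out)
    return {"fasta": fasta, "manifest": manifest, "dir": out, "config": cfg}
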