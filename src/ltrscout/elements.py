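"""The fully annotated element record shared by the pipeline and the writers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .age_estimate import AgeResult
from .classify import Classification
from .domain_annot import DomainHit, IntactnessReport
from .ltr_detect import CandidateElement


@dataclass
class AnnotatedElement:
    """A candidate that survived the intactness filter, with its domain hits,
    classification and divergence. Coordinates 0-based half-open, genomic."""

    species: str
    chrom: str
    candidate: CandidateElement
    hits: Sequence[DomainHit]
    report: IntactnessReport
    classification: Classification
    strand: str
    age: Optional[AgeResult] = None

    @property
    def ltr5_start(self) -> int:
        return self.candidate.ltr5_start

    @property
    def ltr5_end(self) -> int:
        return self.candidate.ltr5_end

    @property
    def ltr3_start(self) -> int:
        return self.candidate.ltr3_start

    @property
    def ltr3_end(self) -> int:
        return self.candidate.ltr3_end

    @property
    def internal_span(self) -> tuple[int, int]:
        return self.candidate.ltr5_end, self.candidate.ltr3_start

    @property
    def length(self) -> int:
        return self.ltr3_end - self.ltr5_start

    @property
    def ltr_id(self) -> str:
        # 1-based, collision-free within a run by construction
        return f"{self.species}_{self.chrom}_{self.ltr5_start + 1}_{self.ltr3_end}"

    def hit_genomic_span(self, hit: DomainHit) -> tuple[int, int]:
        """Domain-hit offsets on the internal region mapped to the genome."""
        base = self.candidate.ltr5_end
        return base + hit.nt_start, base + hit.nt_end


def elements_frame(elements: Sequence[AnnotatedElement]) -> pd.DataFrame:
    """Prediction table for evaluation against a simulator manifest."""
    rows = []
    for el in elements:
        rows.append({
            "ltr_id": el.ltr_id,
            "chrom": el.chrom,
            "ltr5_start": el.ltr5_start,
            "ltr5_end": el.ltr5_end,
            "ltr3_start": el.ltr3_start,
            "ltr3_end": el.ltr3_end,
            "superfamily": el.classification.superfamily,
            "lineage": el.classification.lineage,
            "tsd": el.candidate.tsd,
            "divergence": float("nan") if el.age is None or el.age.saturated else el.age.d,
        })
    return pd.DataFrame(rows, columns=["ltr_id", "chrom", "ltr5_start", "ltr5_end",
                                       "ltr3_start", "ltr3_end", "superfamily",
                                       "lineage", "tsd", "divergence"])
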