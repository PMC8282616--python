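"""Superfamily and lineage assignment for intact elements.

Superfamily follows the order of the integrase domain in the polyprotein:
Copia elements carry INT *before* RT (canonical order GAG-AP-INT-RT-RH),
Gypsy elements carry INT *after* RH (GAG-AP-RT-RH-INT). Elements with
multiple Gag-Pol cassettes, mixed-strand domain hits, or an order matching
neither pattern are left unclassified.

Lineage is a score-weighted vote over the library labels of the hits whose
superfamily label agrees with the order-based call; when the label vote and
the domain order disagree, the order wins and the conflict is flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .domain_annot import DomainHit, IntactnessReport

UNCLASSIFIED = "unclassified"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class Classification:
    superfamily: str  # Copia | Gypsy | unclassified
    lineage: str      # library lineage or "unresolved"
    basis: str        # order | order+labels | none
    conflict: bool    # order-based and label-based superfamily disagree


def element_strand(hits: Sequence[DomainHit]) -> str:
    """Score-weighted majority strand over accepted hits ('.' if empty/tied)."""
    w = {"+": 0.0, "-": 0.0}
    for h in hits:
        w[h.strand] += h.score
    if w["+"] == w["-"]:
        return "."
    return "+" if w["+"] > w["-"] else "-"


def superfamily_from_order(hits: Sequence[DomainHit],
                           report: IntactnessReport) -> str:
    """Order-based superfamily of an intact element.

    Hits are oriented 5'->3' in element orientation (majority strand);
    midpoints are compared so slightly overlapping spans stay robust.
    """
    if not report.is_intact:
        raise ValueError("superfamily_from_order requires an intact element")
    if report.multi_cassette:
        return UNCLASSIFIED
    if len({h.strand for h in hits}) > 1:
        return UNCLASSIFIED
    strand = hits[0].strand
    mids = {h.domain_type: h.midpoint for h in hits}
    sign = 1.0 if strand == "+" else -1.0
    int_m, rt_m, rh_m = (sign * mids[t] for t in ("INT", "RT", "RH"))
    if int_m < rt_m:
        return "Copia"
    if int_m > rh_m:
        return "Gypsy"
    return UNCLASSIFIED


def assign_lineage(hits: Sequence[DomainHit], superfamily: str) -> tuple[str, bool]:
    """Score-weighted lineage vote among label-matching hits.

    Returns ``(lineage, conflict)`` where ``conflict`` is true when the
    score-weighted majority *superfamily label* differs from the order-based
    superfamily. Ties go to the lineage of the single highest-scoring hit;
    a residual tie (or no label-matching hit) gives "unresolved".
    """
    if superfamily not in ("Copia", "Gypsy"):
        raise ValueError("assign_lineage requires a Copia/Gypsy superfamily")
    label_w: dict[str, float] = {}
    for h in hits:
        label_w[h.superfamily_label] = label_w.get(h.superfamily_label, 0.0) + h.score
    majority_label = max(sorted(label_w), key=lambda k: label_w[k]) if label_w else None
    conflict = majority_label is not None and majority_label != superfamily

    matching = [h for h in hits if h.superfamily_label == superfamily]
    if not matching:
        return UNRESOLVED, conflict
    votes: dict[str, float] = {}
    for h in matching:
        votes[h.lineage_label] = votes.get(h.lineage_label, 0.0) + h.score
    top = max(votes.values())
    winners = sorted(lin for lin, v in votes.items() if v == top)
    if len(winners) == 1:
        return winners[0], conflict
    best_hit_score = max(h.score for h in matching)
    best_lineages = sorted({h.lineage_label for h in matching if h.score == best_hit_score})
    if len(best_lineages) == 1:
        return best_lineages[0], conflict
    return UNRESOLVED, conflict


def classify_element(hits: Sequence[DomainHit],
                     report: IntactnessReport) -> Classification:
    """Full classification of an intact element (order first, labels second)."""
    superfamily = superfamily_from_order(hits, report)
    if superfamily == UNCLASSIFIED:
        return Classification(UNCLASSIFIED, UNRESOLVED, "none", False)
    lineage, conflict = assign_lineage(hits, superfamily)
    basis = "order" if conflict or lineage == UNRESOLVED else "order+labels"
    return Classification(superfamily, lineage, basis, conflict)
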