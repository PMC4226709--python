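"""Genomic-context classification of lncRNAs relative to protein-coding genes.

Each lncRNA receives exactly one of six subtype labels, decided in a fixed
priority order against all mRNAs on its chromosome:

1. ``exon_sense_overlapping``   — overlaps >= 1 exon of a same-strand gene
2. ``intron_sense_overlapping`` — fully inside an intron of a same-strand gene
3. ``natural_antisense``        — overlaps exon(s) of an opposite-strand gene
4. ``intronic_antisense``       — fully inside an intron of an opposite-strand gene
5. ``bidirectional``            — no overlap, divergent head-to-head orientation,
                                  TSS-to-TSS gap <= ``bidir_window``
6. ``intergenic``               — none of the above

Sense relationships outrank antisense ones, exonic outrank intronic, and any
overlap outranks mere promoter proximity; the order is a convention (multi-
relationship lncRNAs are not given a precedence by the subtype names alone)
and is applied deterministically. Non-intergenic labels carry the single cis
partner gene chosen by the tie rule: largest overlap, then smallest TSS gap,
then lexicographically smallest gene id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .formats import ContractError, TranscriptRecord

SUBTYPES = (
    "intergenic",
    "intronic_antisense",
    "natural_antisense",
    "exon_sense_overlapping",
    "bidirectional",
    "intron_sense_overlapping",
)

#: subtypes whose partner gene counts as the lncRNA's cis mRNA
CIS_SUBTYPES = (
    "intronic_antisense",
    "natural_antisense",
    "bidirectional",
    "intron_sense_overlapping",
)

DEFAULT_BIDIR_WINDOW = 1000


@dataclass(frozen=True)
class SubtypeLabel:
    """Classification outcome for one lncRNA."""

    lnc_id: str
    subtype: str
    partner: str | None
    evidence: str

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ContractError(f"unknown subtype {self.subtype!r}")
        if (self.partner is None) != (self.subtype == "intergenic"):
            raise ContractError(
                f"{self.lnc_id}: partner must be absent iff intergenic"
            )


def _overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _overlaps_exon(lnc: TranscriptRecord, gene: TranscriptRecord) -> int:
    """Total overlap (bp) between the lncRNA span and the gene's exons."""
    exons = gene.exons or ((gene.start, gene.end),)
    return sum(_overlap_len(lnc.start, lnc.end, es, ee) for es, ee in exons)


def _containing_intron(lnc: TranscriptRecord, gene: TranscriptRecord) -> tuple[int, int] | None:
    for (is_, ie) in gene.introns:
        if is_ <= lnc.start and lnc.end <= ie:
            return (is_, ie)
    return None


def _divergent_gap(lnc: TranscriptRecord, gene: TranscriptRecord) -> int | None:
    """TSS-to-TSS gap if the pair is head-to-head divergent and disjoint, else None.

    Head-to-head: the minus-strand feature lies upstream (left) of the
    plus-strand feature, so each transcribes away from the shared gap. The gap
    is the distance between the facing TSSs (start for +, end for -).
    """
    if lnc.strand == gene.strand:
        return None
    if _overlap_len(lnc.start, lnc.end, gene.start, gene.end) > 0:
        return None
    minus, plus = (lnc, gene) if lnc.strand == "-" else (gene, lnc)
    if minus.end > plus.start:
        return None
    return plus.start - minus.end


def classify(
    lnc: TranscriptRecord,
    genes: Sequence[TranscriptRecord],
    bidir_window: int = DEFAULT_BIDIR_WINDOW,
) -> SubtypeLabel:
    """Classify one lncRNA against the protein-coding genes of its chromosome.

    ``genes`` may span several chromosomes; only same-chromosome genes are
    considered. An lncRNA on a chromosome with no genes is intergenic (a
    warning is emitted). Candidate genes at the winning priority level are
    disambiguated by largest overlap, then smallest TSS gap, then gene id.
    """
    cands = [g for g in genes if g.chrom == lnc.chrom and g.biotype == "mRNA"]
    if not any(g.chrom == lnc.chrom for g in genes if g.biotype == "mRNA"):
        warnings.warn(
            f"{lnc.id}: chromosome {lnc.chrom} has no annotated genes; "
            "classified intergenic",
            stacklevel=2,
        )

    def pick(scored: list[tuple[int, int, str, TranscriptRecord]]) -> TranscriptRecord:
        # sort key: largest overlap, smallest TSS gap, lexicographic id
        scored.sort(key=lambda t: (-t[0], t[1], t[2]))
        return scored[0][3]

    def tss_gap(g: TranscriptRecord) -> int:
        return abs(lnc.tss - g.tss)

    exo_sense = [
        (ov, tss_gap(g), g.id, g)
        for g in cands
        if g.strand == lnc.strand and (ov := _overlaps_exon(lnc, g)) > 0
    ]
    if exo_sense:
        g = pick(exo_sense)
        return SubtypeLabel(lnc.id, "exon_sense_overlapping", g.id,
                            f"exon_overlap={_overlaps_exon(lnc, g)}bp")

    intron_sense = [
        (lnc.end - lnc.start, tss_gap(g), g.id, g)
        for g in cands
        if g.strand == lnc.strand and _containing_intron(lnc, g) is not None
    ]
    if intron_sense:
        g = pick(intron_sense)
        intron = _containing_intron(lnc, g)
        return SubtypeLabel(lnc.id, "intron_sense_overlapping", g.id,
                            f"intron={intron[0]}-{intron[1]}")

    exo_anti = [
        (ov, tss_gap(g), g.id, g)
        for g in cands
        if g.strand != lnc.strand and (ov := _overlaps_exon(lnc, g)) > 0
    ]
    if exo_anti:
        g = pick(exo_anti)
        return SubtypeLabel(lnc.id, "natural_antisense", g.id,
                            f"exon_overlap={_overlaps_exon(lnc, g)}bp")

    intron_anti = [
        (lnc.end - lnc.start, tss_gap(g), g.id, g)
        for g in cands
        if g.strand != lnc.strand and _containing_intron(lnc, g) is not None
    ]
    if intron_anti:
        g = pick(intron_anti)
        intron = _containing_intron(lnc, g)
        return SubtypeLabel(lnc.id, "intronic_antisense", g.id,
                            f"intron={intron[0]}-{intron[1]}")

    bidir = []
    for g in cands:
        gap = _divergent_gap(lnc, g)
        if gap is not None and gap <= bidir_window:
            bidir.append((0, gap, g.id, g))
    if bidir:
        g = pick(bidir)
        return SubtypeLabel(lnc.id, "bidirectional", g.id,
                            f"tss_gap={_divergent_gap(lnc, g)}bp")

    return SubtypeLabel(lnc.id, "intergenic", None, "no_relationship")


def classify_all(
    records: Sequence[TranscriptRecord],
    bidir_window: int = DEFAULT_BIDIR_WINDOW,
) -> list[SubtypeLabel]:
    """Classify every lncRNA in an annotation against its chromosome's mRNAs.

    Uses a per-chromosome interval index widened by ``bidir_window`` so only
    plausibly related genes are tested; each candidate set is then run through
    the same rule cascade as :func:`classify`.
    """
    genes = [r for r in records if r.biotype == "mRNA"]
    lncs = [r for r in records if r.biotype == "lncRNA"]
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
    labels = []
    for lnc in lncs:
        tree = trees.get(lnc.chrom)
        if tree is None:
            labels.append(SubtypeLabel(lnc.id, "intergenic", None,
                                       "no_genes_on_chromosome"))
            continue
        nearby = [iv.data for iv in
                  tree.overlap(lnc.start - bidir_window, lnc.end + bidir_window)]
        # chromosome is in the index, so an empty neighbourhood is an ordinary
        # intergenic call, not the missing-chromosome condition
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels.append(classify(lnc, nearby, bidir_window=bidir_window))
    return labels


def subtype_fractions(
    labels: Sequence[SubtypeLabel],
    subset: set[str] | None = None,
) -> dict[str, float]:
    """Proportion of each subtype among ``subset`` (default: all labelled lncRNAs)."""
    if subset is not None:
        known = {l.lnc_id for l in labels}
        unknown = subset - known
        if unknown:
            raise ContractError(f"subset ids not labelled: {sorted(unknown)}")
        labels = [l for l in labels if l.lnc_id in subset]
    if not labels:
        raise ContractError("empty lncRNA subset")
    n = len(labels)
    return {s: sum(l.subtype == s for l in labels) / n for s in SUBTYPES}


def cis_partner_pairs(labels: Sequence[SubtypeLabel]) -> list[tuple[str, str, str]]:
    """(lncRNA, mRNA, subtype) for subtypes with a meaningful cis partner.

    Intergenic lncRNAs (no partner) and exon sense-overlapping ones (likely
    probe cross-hybridization with the host transcript rather than regulation)
    are excluded.
    """
    return [
        (l.lnc_id, l.partner, l.subtype)
        for l in labels
        if l.subtype in CIS_SUBTYPES
    ]
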