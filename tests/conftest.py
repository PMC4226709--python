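"""Shared fixtures and the independent brute-force classifier oracle."""

from __future__ import annotations

import numpy as np
import pytest

from lncomat import SimParams, TranscriptRecord, simulate


@pytest.fixture(scope="session")
def default_study():
    """One default-parameter synthetic study (annotation, matrix, truth, sets)."""
    annotation, matrix, sheet, truth, genesets = simulate(SimParams(seed=101))
    return {
        "annotation": annotation,
        "matrix": matrix,
        "sheet": sheet,
        "truth": truth,
        "genesets": genesets,
    }


def random_genome(rng: np.random.Generator,
                  max_genes: int = 50,
                  max_lncs: int = 30,
                  chrom_length: int = 50_000) -> list[TranscriptRecord]:
    """A small random annotation with dense, adversarial overlaps.

    Genes get 1-3 exons (single-exon genes exercise the no-intron path);
    lncRNAs land anywhere, so exon straddles, containments, divergent
    promoters and multi-relationship cases all occur.
    """
    records = []
    n_genes = int(rng.integers(1, max_genes + 1))
    n_lncs = int(rng.integers(1, max_lncs + 1))
    chroms = ["chr1", "chr2"]
    for i in range(n_genes):
        start = int(rng.integers(0, chrom_length - 4000))
        length = int(rng.integers(500, 4000))
        n_exons = int(rng.integers(1, 4))
        bounds = np.sort(rng.choice(
            np.arange(1, length), size=2 * (n_exons - 1), replace=False)
        ) if n_exons > 1 else np.array([], dtype=int)
        edges = np.concatenate([[0], bounds, [length]])
        exons = tuple(
            (start + int(edges[2 * k]), start + int(edges[2 * k + 1]))
            for k in range(n_exons)
        )
        records.append(TranscriptRecord(
            id=f"G{i:03d}", chrom=str(rng.choice(chroms)), start=start,
            end=start + length, strand=str(rng.choice(["+", "-"])),
            biotype="mRNA", exons=exons))
    for j in range(n_lncs):
        start = int(rng.integers(0, chrom_length - 2000))
        length = int(rng.integers(100, 2000))
        records.append(TranscriptRecord(
            id=f"X{j:03d}", chrom=str(rng.choice(chroms)), start=start,
            end=start + length, strand=str(rng.choice(["+", "-"])),
            biotype="lncRNA"))
    return records


def brute_force_classify(lnc: TranscriptRecord,
                         genes: list[TranscriptRecord],
                         bidir_window: int = 1000) -> tuple[str, str | None]:
    """Naive O(n*m) reference for the six-way subtype decision.

    Re-states the rules from scratch (interval arithmetic only) so it stays
    independent of the implementation under test. Returns (subtype, partner).
    """
    def span_overlap(a, b, c, d):
        return max(0, min(b, d) - max(a, c))

    same = [g for g in genes
            if g.chrom == lnc.chrom and g.biotype == "mRNA"
            and g.strand == lnc.strand]
    anti = [g for g in genes
            if g.chrom == lnc.chrom and g.biotype == "mRNA"
            and g.strand != lnc.strand]

    def exonic(gs):
        hits = []
        for g in gs:
            exons = g.exons or ((g.start, g.end),)
            ov = sum(span_overlap(lnc.start, lnc.end, a, b) for a, b in exons)
            if ov > 0:
                hits.append((ov, g))
        return hits

    def intronic(gs):
        hits = []
        for g in gs:
            for k in range(len(g.exons) - 1):
                a, b = g.exons[k][1], g.exons[k + 1][0]
                if a <= lnc.start and lnc.end <= b:
                    hits.append((lnc.end - lnc.start, g))
                    break
        return hits

    def tss(t):
        return t.start if t.strand == "+" else t.end

    def choose(hits):
        best = min(hits, key=lambda h: (-h[0], abs(tss(lnc) - tss(h[1])), h[1].id))
        return best[1].id

    for label, hits in (
        ("exon_sense_overlapping", exonic(same)),
        ("intron_sense_overlapping", intronic(same)),
        ("natural_antisense", exonic(anti)),
        ("intronic_antisense", intronic(anti)),
    ):
        if hits:
            return label, choose(hits)

    bidir = []
    for g in anti:
        if span_overlap(lnc.start, lnc.end, g.start, g.end) > 0:
            continue
        minus, plus = (lnc, g) if lnc.strand == "-" else (g, lnc)
        if minus.end <= plus.start and plus.start - minus.end <= bidir_window:
            bidir.append((0, g))
    if bidir:
        return "bidirectional", choose(bidir)
    return "intergenic", None
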