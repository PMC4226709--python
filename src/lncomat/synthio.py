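"""Synthetic annotated genomes and matched tumor/normal expression data.

The generator emulates the statistical structure of a paired tumor-size
expression study on log2 microarray intensities:

* matched normal / small-tumor / large-tumor samples (default five
  patients, each contributing all three tissues);
* planted differential expression with direction bias (mRNAs mostly down,
  lncRNAs mostly up) and a larger mean effect in large tumors;
* lncRNAs placed so that each satisfies exactly one genomic-context subtype
  under the classifier's rules, with no accidental second relationship;
* planted cis lncRNA-mRNA correlations through shared latent factors whose
  loading is solved so the population Pearson r equals the signed target;
* optionally, a block of mRNAs and lncRNAs sharing one latent factor (a
  co-expression module) for relevance-ranking recovery experiments;
* gene sets in GMT form with one set enriched among the down-regulated mRNAs.

All randomness flows from one seed, forked into named substreams so adding a
feature class never perturbs earlier draws. Every planted quantity is
recorded in a :class:`TruthManifest` for recovery testing.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .formats import (
    ContractError,
    ExpressionMatrix,
    GeneSetCollection,
    TranscriptRecord,
)
from .lncclass import CIS_SUBTYPES, SUBTYPES

# fixed toy-genome geometry (bp): one gene per slot, with room for a
# bidirectional lncRNA upstream and several intergenic lncRNAs downstream
_SLOT = 20_000
_GENE_OFFSET = 5_000      # gene start within its slot
_GENE_SPAN = 3_000
_EXON_LEN = 600           # two terminal exons; intron spans the middle 1800 bp
_LNC_LEN = 400
_INTERGENIC_GAP = 6_000   # first intergenic lncRNA this far past the gene end
_INTERGENIC_STEP = 600
_MAX_INTERGENIC_PER_SLOT = 14
_BIDIR_GAP = 300          # TSS-to-TSS gap of planted bidirectional pairs


class CapacityError(ContractError):
    """The requested features do not fit on the requested chromosomes."""


@dataclass
class SimParams:
    """Design of one synthetic study; defaults mirror the emulated design.

    Five patients per group with ~2-fold mean effects in small tumors and
    stronger effects in large tumors, mRNAs biased down and lncRNAs biased
    up, all six lncRNA subtypes represented, and strong planted cis
    correlations whose sign depends on subtype.
    """

    n_patients_per_group: int = 5
    n_mrna: int = 300
    n_lncrna: int = 120
    n_chromosomes: int = 4
    chrom_length: int = 2_000_000
    frac_de_mrna_small: float = 0.10
    frac_de_mrna_large: float = 0.20
    frac_de_lncrna_small: float = 0.10
    frac_de_lncrna_large: float = 0.20
    down_bias_mrna: float = 0.70
    up_bias_lncrna: float = 0.70
    effect_small: float = 1.5
    effect_large: float = 2.5
    noise_sd: float = 0.4
    patient_sd: float = 0.3
    subtype_mix: dict = field(default_factory=lambda: {s: 1 / 6 for s in SUBTYPES})
    cis_rho: float = 0.9
    subtype_sign_profile: dict = field(default_factory=lambda: {
        "intronic_antisense": 0.30,       # negative correlations dominate
        "natural_antisense": 0.50,
        "bidirectional": 0.70,
        "intron_sense_overlapping": 0.95,  # overwhelmingly positive
    })
    n_genesets: int = 10
    geneset_size: int = 25
    enriched_fraction: float = 0.8
    design: str = "triplet"   # or "disjoint": separate small/large patients
    module_n_mrna: int = 0
    module_n_lncrna: int = 0
    module_rho: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        props = [
            self.frac_de_mrna_small, self.frac_de_mrna_large,
            self.frac_de_lncrna_small, self.frac_de_lncrna_large,
            self.down_bias_mrna, self.up_bias_lncrna, self.enriched_fraction,
            *self.subtype_mix.values(), *self.subtype_sign_profile.values(),
        ]
        if any(not 0 <= p <= 1 for p in props):
            raise ContractError("all proportions must lie in [0, 1]")
        if abs(sum(self.subtype_mix.values()) - 1) > 1e-9:
            raise ContractError("subtype_mix must sum to 1")
        if unknown := set(self.subtype_mix) - set(SUBTYPES):
            raise ContractError(f"unknown subtypes in mix: {sorted(unknown)}")
        if not (self.effect_large > self.effect_small > 0):
            raise ContractError("need effect_large > effect_small > 0")
        if not 0 < self.cis_rho < 1:
            raise ContractError("cis_rho must lie in (0, 1)")
        if self.module_n_mrna and not 0 < self.module_rho < 1:
            raise ContractError("module_rho must lie in (0, 1)")
        for name in ("n_patients_per_group", "n_mrna", "n_lncrna",
                     "n_chromosomes", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be positive")
        if self.design not in ("triplet", "disjoint"):
            raise ContractError("design must be 'triplet' or 'disjoint'")

    def rng(self, substream: str) -> np.random.Generator:
        """Named substream forked from the master seed (stable across runs)."""
        key = zlib.crc32(substream.encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, key]))


@dataclass
class TruthManifest:
    """Planted ground truth of one synthetic run.

    * ``de_calls``: feature -> {direction, log2fc_small, log2fc_large}
      (zero log2fc means not planted in that contrast);
    * ``intended_subtype``: lncRNA -> subtype label the placement satisfies;
    * ``cis_pairs``: (lncRNA, mRNA, subtype, signed target r);
    * ``module_mrna``/``module_lnc``: members of the planted co-expression
      module (empty when none was requested);
    * ``enriched_sets``: gene-set names planted as enriched.
    """

    seed: int
    de_calls: dict = field(default_factory=dict)
    intended_subtype: dict = field(default_factory=dict)
    cis_pairs: list = field(default_factory=list)
    module_mrna: list = field(default_factory=list)
    module_lnc: list = field(default_factory=list)
    module_rho: float = 0.0
    enriched_sets: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cis_pairs"] = [list(p) for p in self.cis_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthManifest":
        d = dict(d)
        d["cis_pairs"] = [tuple(p) for p in d.get("cis_pairs", [])]
        return cls(**d)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(params: SimParams) -> tuple[list[TranscriptRecord], TruthManifest]:
    """Lay out genes and lncRNAs so each lncRNA has exactly one relationship.

    Genes occupy well-separated fixed slots (two exons flanking one intron).
    Each lncRNA draws an intended subtype from ``subtype_mix`` and is placed
    in the geometry that realises that subtype and nothing else; the intended
    label, cis partner, and the signed cis correlation target go into the
    truth manifest.
    """
    slots_per_chrom = (params.chrom_length - _SLOT) // _SLOT
    if slots_per_chrom < 1:
        raise CapacityError("chrom_length too short for a single gene slot")
    total_slots = params.n_chromosomes * slots_per_chrom
    if params.n_mrna > total_slots:
        raise CapacityError(
            f"{params.n_mrna} genes need {params.n_mrna} slots; only "
            f"{total_slots} fit on {params.n_chromosomes} chromosomes")

    rng_sub = params.rng("subtypes")
    rng_strand = params.rng("strands")
    rng_sign = params.rng("cis_signs")

    genes: list[TranscriptRecord] = []
    gene_slot: list[tuple[str, int]] = []
    for i in range(params.n_mrna):
        chrom = f"chr{i % params.n_chromosomes + 1}"
        slot = i // params.n_chromosomes
        base = slot * _SLOT
        gs = base + _GENE_OFFSET
        strand = "+" if rng_strand.random() < 0.5 else "-"
        genes.append(TranscriptRecord(
            id=f"M{i+1:05d}", chrom=chrom, start=gs, end=gs + _GENE_SPAN,
            strand=strand, biotype="mRNA",
            exons=((gs, gs + _EXON_LEN),
                   (gs + _GENE_SPAN - _EXON_LEN, gs + _GENE_SPAN)),
        ))
        gene_slot.append((chrom, slot))

    mix_names = list(params.subtype_mix)
    mix_probs = np.array([params.subtype_mix[s] for s in mix_names], dtype=float)
    intended = rng_sub.choice(mix_names, size=params.n_lncrna, p=mix_probs)

    n_hosted = int(np.sum(intended != "intergenic"))
    if n_hosted > params.n_mrna:
        raise CapacityError(
            f"{n_hosted} gene-associated lncRNAs but only {params.n_mrna} genes "
            "(one hosted lncRNA per gene)")

    truth = TruthManifest(seed=params.seed)
    lncs: list[TranscriptRecord] = []
    host_iter = iter(range(params.n_mrna))
    intergenic_count: dict[int, int] = {}
    next_intergenic_gene = 0

    other = {"+": "-", "-": "+"}
    for j, subtype in enumerate(intended):
        lid = f"L{j+1:05d}"
        truth.intended_subtype[lid] = str(subtype)
        if subtype == "intergenic":
            gi = next_intergenic_gene % params.n_mrna
            next_intergenic_gene += 1
            c = intergenic_count.get(gi, 0)
            if c >= _MAX_INTERGENIC_PER_SLOT:
                raise CapacityError(
                    "too many intergenic lncRNAs per gene slot; add genes or "
                    "chromosomes")
            intergenic_count[gi] = c + 1
            g = genes[gi]
            start = g.end + _INTERGENIC_GAP + c * _INTERGENIC_STEP
            strand = "+" if rng_strand.random() < 0.5 else "-"
            lncs.append(TranscriptRecord(
                id=lid, chrom=g.chrom, start=start, end=start + _LNC_LEN,
                strand=strand, biotype="lncRNA"))
            continue
        try:
            gi = next(host_iter)
        except StopIteration:  # pragma: no cover - guarded by capacity check
            raise CapacityError("ran out of host genes for lncRNA placement")
        g = genes[gi]
        gs = g.start
        if subtype == "exon_sense_overlapping":
            start, strand = gs + _EXON_LEN - 300, g.strand
        elif subtype == "natural_antisense":
            start, strand = gs + _EXON_LEN - 300, other[g.strand]
        elif subtype == "intron_sense_overlapping":
            start, strand = gs + _EXON_LEN + 300, g.strand
        elif subtype == "intronic_antisense":
            start, strand = gs + _EXON_LEN + 300, other[g.strand]
        elif subtype == "bidirectional":
            if g.strand == "+":
                start, strand = gs - _BIDIR_GAP - _LNC_LEN, "-"
            else:
                start, strand = g.end + _BIDIR_GAP, "+"
        else:  # pragma: no cover
            raise ContractError(f"unhandled subtype {subtype!r}")
        lncs.append(TranscriptRecord(
            id=lid, chrom=g.chrom, start=start, end=start + _LNC_LEN,
            strand=strand, biotype="lncRNA"))
        if subtype in CIS_SUBTYPES:
            p_pos = params.subtype_sign_profile.get(str(subtype), 0.5)
            sign = 1.0 if rng_sign.random() < p_pos else -1.0
            truth.cis_pairs.append((lid, g.id, str(subtype),
                                    float(sign * params.cis_rho)))
    return genes + lncs, truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _sample_sheet(params: SimParams) -> pd.DataFrame:
    rows = []
    n = params.n_patients_per_group
    if params.design == "triplet":
        for i in range(1, n + 1):
            pid = f"P{i:03d}"
            rows += [
                {"sample": f"{pid}_N", "patient": pid, "tissue": "N", "size": "NA"},
                {"sample": f"{pid}_S", "patient": pid, "tissue": "T", "size": "S"},
                {"sample": f"{pid}_L", "patient": pid, "tissue": "T", "size": "L"},
            ]
    else:
        for size in ("S", "L"):
            for i in range(1, n + 1):
                pid = f"P{size}{i:03d}"
                rows += [
                    {"sample": f"{pid}_N", "patient": pid, "tissue": "N",
                     "size": "NA"},
                    {"sample": f"{pid}_T", "patient": pid, "tissue": "T",
                     "size": size},
                ]
    return pd.DataFrame(rows).set_index("sample")


def _plant_de(params: SimParams, ids: list[str], frac_small: float,
              frac_large: float, down_bias: float, stream: str,
              truth: TruthManifest) -> None:
    rng = params.rng(stream)
    n = len(ids)
    large = list(rng.choice(ids, size=round(frac_large * n), replace=False))
    small = list(rng.choice(ids, size=round(frac_small * n), replace=False))
    for fid in sorted(set(large) | set(small)):
        direction = "down" if rng.random() < down_bias else "up"
        sign = -1.0 if direction == "down" else 1.0
        mag_s = rng.gamma(shape=6.0, scale=params.effect_small / 6.0)
        mag_l = rng.gamma(shape=6.0, scale=params.effect_large / 6.0)
        truth.de_calls[fid] = {
            "direction": direction,
            "log2fc_small": float(sign * mag_s) if fid in small else 0.0,
            "log2fc_large": float(sign * mag_l) if fid in large else 0.0,
        }


def simulate_expression(
    annotation: list[TranscriptRecord],
    truth: TruthManifest,
    params: SimParams,
) -> tuple[ExpressionMatrix, pd.DataFrame, TruthManifest, GeneSetCollection]:
    """Expression model on top of a simulated annotation.

    Per feature g and sample s:

        x_gs = baseline_g + patientEffect_gp(s) + delta_g(size(s)) * I[tumor]
               + sum_f gamma_gf * factor_fs + eps_gs

    with eps ~ N(0, noise_sd^2) and a feature-specific patient effect shared
    between a patient's samples, N(0, patient_sd^2). Shared latent factors
    realise planted cis pairs and the optional co-expression module; each
    factor is iid standard normal per sample. The loading gamma solves
    gamma^2 / (gamma^2 + sigma^2) = rho with sigma^2 = patient_sd^2 +
    noise_sd^2, so the population Pearson r between two features with equal
    |loading| on one factor is exactly the signed rho. Note the factor is
    honest sample-level biological variation: for factor-loaded features it
    also inflates the paired-difference variance, so their planted mean
    shifts are harder to call than those of factor-free features — by design,
    not by accident.

    Returns the log2 matrix, the sample sheet, the completed truth manifest,
    and the GMT-ready gene-set collection.
    """
    feature_ids = [r.id for r in annotation]
    known = set(feature_ids)
    for (lid, mid, _s, _r) in truth.cis_pairs:
        if lid not in known or mid not in known:
            raise ContractError(f"cis pair ({lid}, {mid}) references unknown features")
    for lid in truth.intended_subtype:
        if lid not in known:
            raise ContractError(f"truth subtype for unknown feature {lid}")

    mrna_ids = [r.id for r in annotation if r.biotype == "mRNA"]
    lnc_ids = [r.id for r in annotation if r.biotype == "lncRNA"]
    sheet = _sample_sheet(params)
    n_samples = len(sheet)
    idx = {fid: i for i, fid in enumerate(feature_ids)}

    # --- planted differential expression -----------------------------------
    _plant_de(params, mrna_ids, params.frac_de_mrna_small,
              params.frac_de_mrna_large, params.down_bias_mrna, "de_mrna", truth)
    _plant_de(params, lnc_ids, params.frac_de_lncrna_small,
              params.frac_de_lncrna_large, 1.0 - params.up_bias_lncrna,
              "de_lncrna", truth)

    # --- gene sets, one enriched among down-regulated large-tumor mRNAs -----
    genesets = _plant_genesets(params, mrna_ids, truth)

    # --- co-expression module ----------------------------------------------
    rng_mod = params.rng("module")
    truth.module_rho = float(params.module_rho) if params.module_n_mrna else 0.0
    if params.module_n_mrna or params.module_n_lncrna:
        cis_members = {x for p in truth.cis_pairs for x in p[:2]}
        free_m = [m for m in mrna_ids if m not in cis_members]
        free_l = [l for l in lnc_ids if l not in cis_members]
        if (len(free_m) < params.module_n_mrna
                or len(free_l) < params.module_n_lncrna):
            raise CapacityError("not enough cis-free features for the module")
        truth.module_mrna = sorted(
            rng_mod.choice(free_m, size=params.module_n_mrna, replace=False))
        truth.module_lnc = sorted(
            rng_mod.choice(free_l, size=params.module_n_lncrna, replace=False))
        # module members carry the shared factor only: planting mean shifts on
        # top would entangle group structure with the factor correlation and
        # make the planted rho no longer the population correlation
        for fid in [*truth.module_mrna, *truth.module_lnc]:
            truth.de_calls.pop(fid, None)

    # --- assemble the matrix ------------------------------------------------
    sigma2 = params.patient_sd ** 2 + params.noise_sd ** 2

    def loading(rho: float) -> float:
        return float(np.sqrt(sigma2 * rho / (1.0 - rho))) if sigma2 > 0 else 0.0

    rng_base = params.rng("baseline")
    rng_pat = params.rng("patient")
    rng_eps = params.rng("noise")
    rng_fac = params.rng("factors")

    x = np.zeros((len(feature_ids), n_samples))
    x += rng_base.uniform(6.0, 12.0, size=len(feature_ids))[:, None]

    patients = sheet["patient"].to_numpy()
    uniq_pat = list(dict.fromkeys(patients))
    pat_col = np.array([uniq_pat.index(p) for p in patients])
    pat_eff = rng_pat.normal(0.0, params.patient_sd,
                             size=(len(feature_ids), len(uniq_pat)))
    x += pat_eff[:, pat_col]

    is_tumor = (sheet["tissue"] == "T").to_numpy()
    size_col = sheet["size"].to_numpy()
    for fid, call in truth.de_calls.items():
        row = idx[fid]
        x[row, is_tumor & (size_col == "S")] += call["log2fc_small"]
        x[row, is_tumor & (size_col == "L")] += call["log2fc_large"]

    for (lid, mid, _subtype, signed_r) in truth.cis_pairs:
        f = rng_fac.normal(0.0, 1.0, size=n_samples)
        g = loading(abs(signed_r))
        x[idx[lid]] += g * f
        x[idx[mid]] += np.sign(signed_r) * g * f

    if truth.module_mrna or truth.module_lnc:
        f = rng_fac.normal(0.0, 1.0, size=n_samples)
        g = loading(params.module_rho)
        for fid in [*truth.module_mrna, *truth.module_lnc]:
            x[idx[fid]] += g * f

    x += rng_eps.normal(0.0, params.noise_sd, size=x.shape)

    values = pd.DataFrame(x, index=feature_ids, columns=list(sheet.index))
    biotype = pd.Series(
        ["mRNA" if f in set(mrna_ids) else "lncRNA" for f in feature_ids],
        index=feature_ids)
    matrix = ExpressionMatrix(values=values, samples=sheet, biotype=biotype)
    return matrix, sheet, truth, genesets


def _plant_genesets(params: SimParams, mrna_ids: list[str],
                    truth: TruthManifest) -> GeneSetCollection:
    rng = params.rng("genesets")
    if params.n_genesets == 0:
        return GeneSetCollection({})
    if params.geneset_size > len(mrna_ids):
        raise CapacityError("geneset_size exceeds the number of mRNAs")
    sets = {}
    down_pool = [m for m, c in truth.de_calls.items()
                 if m.startswith("M") and c["direction"] == "down"
                 and c["log2fc_large"] != 0.0]
    for i in range(1, params.n_genesets + 1):
        name = f"SET{i:02d}"
        members = sorted(rng.choice(mrna_ids, size=params.geneset_size,
                                    replace=False))
        sets[name] = (f"synthetic set {i}", tuple(members))
    # plant enrichment: swap a fraction of the first set's members for
    # down-regulated large-tumor mRNAs
    if down_pool and params.enriched_fraction > 0:
        name = "SET01"
        n_forced = min(round(params.enriched_fraction * params.geneset_size),
                       len(down_pool))
        forced = sorted(rng.choice(down_pool, size=n_forced, replace=False))
        rest_pool = [m for m in mrna_ids
                     if m not in set(forced) and m not in set(down_pool)]
        rest = sorted(rng.choice(rest_pool,
                                 size=params.geneset_size - n_forced,
                                 replace=False))
        sets[name] = (sets[name][0], tuple(sorted(set(forced + rest))))
        truth.enriched_sets = [name]
    return GeneSetCollection(sets)


def simulate(params: SimParams):
    """Full simulation: annotation, expression, sample sheet, truth, gene sets."""
    annotation, truth = simulate_annotation(params)
    matrix, sheet, truth, genesets = simulate_expression(annotation, truth, params)
    return annotation, matrix, sheet, truth, genesets
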