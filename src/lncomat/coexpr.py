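"""Pearson co-expression machinery: cis-pair profiles, the dysregulated
mRNA x lncRNA correlation matrix, its trichotomized twin, and relevance
scoring of mRNAs against an lncRNA set.

The rectangular correlation matrix holds the Pearson coefficient between
every dysregulated mRNA (rows) and every dysregulated lncRNA (columns),
computed across the chosen sample span (all samples pooled by default).
Cells are trichotomized at a symmetric cutoff: r > cutoff maps to +1,
r < -cutoff to -1, anything else (including exactly +/-cutoff) to 0. The
relevance score of an mRNA against an lncRNA set is the sum of |r| over the
cutoff-passing cells of that set's columns; genes ranked by descending score
give the "relevant genes" list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import ContractError, ExpressionMatrix

DEFAULT_CUTOFF = 0.8


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN sentinel when either vector is constant.

    Undefined correlations are excluded downstream and tallied, never raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ContractError("pearson needs two equal-length vectors of size >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rowwise-standardized cross-correlation of two feature x sample blocks."""
    def standardize(m: np.ndarray) -> np.ndarray:
        mc = m - m.mean(axis=1, keepdims=True)
        sd = np.sqrt((mc ** 2).sum(axis=1, keepdims=True))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = mc / sd
        out[sd[:, 0] == 0] = np.nan  # constant feature -> undefined everywhere
        return out

    r = standardize(a) @ standardize(b).T
    return np.clip(r, -1.0, 1.0)


@dataclass
class CoMatrix:
    """Rectangular mRNA x lncRNA Pearson matrix with its {-1,0,+1} twin."""

    r: pd.DataFrame
    cutoff: float
    tri: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rv = self.r.to_numpy(dtype=float)
        tri = np.zeros_like(rv)
        tri[rv > self.cutoff] = 1
        tri[rv < -self.cutoff] = -1
        tri[np.isnan(rv)] = np.nan
        self.tri = pd.DataFrame(tri, index=self.r.index, columns=self.r.columns)

    @property
    def mrna_ids(self) -> list[str]:
        return list(self.r.index)

    @property
    def lnc_ids(self) -> list[str]:
        return list(self.r.columns)

    def tri_counts(self) -> dict[str, int]:
        t = self.tri.to_numpy()
        return {
            "positive": int((t == 1).sum()),
            "negative": int((t == -1).sum()),
            "none": int((t == 0).sum()),
            "undefined": int(np.isnan(t).sum()),
        }


def build_comatrix_from_ids(
    matrix: ExpressionMatrix,
    mrna_ids: list[str],
    lnc_ids: list[str],
    cutoff: float = DEFAULT_CUTOFF,
    span: str = "all",
) -> CoMatrix:
    """Correlation matrix for explicit row/column feature lists.

    ``span='all'`` pools every sample; ``span='tumor'`` restricts to tumor
    columns. At least 3 samples are required in the chosen span.
    """
    if not mrna_ids or not lnc_ids:
        raise ContractError("empty mRNA row set or lncRNA column set")
    if span == "all":
        samples = matrix.sample_ids
    elif span == "tumor":
        samples = [s for s in matrix.sample_ids
                   if matrix.samples.loc[s, "tissue"] == "T"]
    else:
        raise ContractError(f"unknown sample span {span!r}")
    if len(samples) < 3:
        raise ContractError("correlation needs >= 3 samples in the chosen span")
    a = matrix.values.loc[mrna_ids, samples].to_numpy(dtype=float)
    b = matrix.values.loc[lnc_ids, samples].to_numpy(dtype=float)
    r = pd.DataFrame(_cross_correlation(a, b), index=mrna_ids, columns=lnc_ids)
    return CoMatrix(r=r, cutoff=cutoff)


def build_comatrix(de, matrix: ExpressionMatrix, cutoff: float = DEFAULT_CUTOFF,
                   span: str = "all") -> CoMatrix:
    """Matrix over features dysregulated in either contrast (rows: mRNAs,
    columns: lncRNAs), the default construction for the relevance analysis."""
    rows = list(de.called_any(biotype="mRNA"))
    cols = list(de.called_any(biotype="lncRNA"))
    return build_comatrix_from_ids(matrix, rows, cols, cutoff=cutoff, span=span)


# ---------------------------------------------------------------------------
# Cis-pair correlation profiles by subtype
# ---------------------------------------------------------------------------

def cis_correlation_profile(
    pairs: list[tuple[str, str, str]],
    matrix: ExpressionMatrix,
    bins: int = 20,
) -> dict[str, dict]:
    """Per-subtype distribution of Pearson r between lncRNAs and cis mRNAs.

    Returns, per subtype present in ``pairs``: the r values, the fractions of
    positive/negative/undefined correlations, and a normalized histogram over
    [-1, 1]. Subtypes with zero defined correlations are flagged empty.
    """
    values = matrix.values
    by_subtype: dict[str, list[float]] = {}
    undefined: dict[str, int] = {}
    for lnc_id, mrna_id, subtype in pairs:
        r = pearson(values.loc[lnc_id].to_numpy(), values.loc[mrna_id].to_numpy())
        if np.isnan(r):
            undefined[subtype] = undefined.get(subtype, 0) + 1
        else:
            by_subtype.setdefault(subtype, []).append(r)
    out = {}
    for subtype in set(by_subtype) | set(undefined):
        rs = np.array(by_subtype.get(subtype, []), dtype=float)
        entry = {"r": rs, "n_undefined": undefined.get(subtype, 0),
                 "empty": rs.size == 0}
        if rs.size:
            entry["frac_positive"] = float((rs > 0).mean())
            entry["frac_negative"] = float((rs < 0).mean())
            density, edges = np.histogram(rs, bins=bins, range=(-1, 1),
                                          density=True)
            entry["density"] = density
            entry["bin_edges"] = edges
        out[subtype] = entry
    return out


# ---------------------------------------------------------------------------
# Relevance scoring
# ---------------------------------------------------------------------------

@dataclass
class RelevanceRanking:
    """Per-mRNA relevance scores against a named lncRNA set, ranked descending.

    ``table`` is indexed by mRNA id with columns ``score`` and ``rank``
    (1-based; ties broken by id).
    """

    table: pd.DataFrame
    lnc_set: tuple[str, ...]
    cutoff: float

    def top(self, k: int) -> list[str]:
        return list(self.table.index[:k])


def relevance_scores(
    comat: CoMatrix,
    lnc_set: list[str] | set[str],
    filtered: bool = True,
) -> RelevanceRanking:
    """Sum of |r| over cutoff-passing cells of the set's columns, per mRNA.

    With ``filtered=False`` the sum runs over all defined cells regardless of
    the cutoff (diagnostic variant).
    """
    lnc_set = sorted(set(lnc_set))
    unknown = [l for l in lnc_set if l not in comat.r.columns]
    if unknown:
        raise ContractError(f"lncRNA ids not in matrix columns: {unknown}")
    r = comat.r[lnc_set].to_numpy(dtype=float)
    keep = comat.tri[lnc_set].to_numpy() != 0 if filtered else ~np.isnan(r)
    score = np.where(keep & ~np.isnan(r), np.abs(r), 0.0).sum(axis=1)
    table = pd.DataFrame({"score": score},
                         index=comat.r.index.rename(None))
    table = table.sort_values(["score"], ascending=False, kind="mergesort")
    # stable sort on descending score; secondary deterministic order by id
    table = (table.reset_index()
                  .sort_values(["score", "index"], ascending=[False, True],
                               kind="mergesort")
                  .set_index("index").rename_axis(None))
    table["rank"] = np.arange(1, len(table) + 1)
    return RelevanceRanking(table=table, lnc_set=tuple(lnc_set), cutoff=comat.cutoff)


def select_top(
    ranking: RelevanceRanking,
    mode: str = "score_min",
    value: float = 0.0,
) -> list[str]:
    """Pick the relevant genes: top-k by rank or all with score >= value.

    With ``mode='score_min'`` and the default value 0.0, genes with strictly
    positive score are selected (the default relevant-gene rule).
    """
    t = ranking.table
    if mode == "k":
        k = int(value)
        if k <= 0:
            raise ContractError("top-k selection needs k > 0")
        if k > len(t):
            import warnings
            warnings.warn(f"k={k} exceeds {len(t)} genes; returning all",
                          stacklevel=2)
        return list(t.index[:k])
    if mode == "score_min":
        if value <= 0:
            return list(t.index[t["score"] > 0])
        return list(t.index[t["score"] >= value])
    raise ContractError(f"unknown selection mode {mode!r}")
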