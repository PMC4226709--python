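"""Quantile normalization, paired differential expression, and signature sets.

The differential analysis mirrors a matched tumor/normal microarray design
with two contrasts: small tumors vs matched normal tissue (S) and large
tumors vs matched normal tissue (L). A feature is called dysregulated when its mean
paired log2 fold change passes the fold-change threshold (|log2FC| >= 1 for
a 2-fold cut, inclusive) and its paired t-test p-value is below alpha
(strict). Calls in the two contrasts are combined into Venn partitions and
into the four large-tumor signature sets:

* set 1 (mRNA) / set 3 (lncRNA): called in L but not in S;
* set 2 (mRNA) / set 4 (lncRNA): called in L, not discordant with S, and with
  an L-over-S fold change above a second threshold (|log2FC_L - log2FC_S| >= 1
  for the default 2-fold cut) — "more dramatically changed in large tumors".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .formats import ContractError, ExpressionMatrix

#: smallest positive double: the "0-adjacent" sentinel p-value for a
#: zero-variance, nonzero-mean paired difference
P_DEGENERATE_LOW = 5e-324

CALLS = ("up", "down", "none")


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the common rank-mean distribution.

    Rank r of each column is replaced by the mean over columns of each
    column's r-th smallest value. Ties within a column receive the mean of
    their tied ranks' reference values (average-rank convention), so tied
    inputs stay tied.
    """
    v = matrix.values
    if v.shape[1] < 2:
        raise ContractError("quantile normalization needs >= 2 samples")
    x = v.to_numpy(dtype=float)
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = st.rankdata(x[:, j], method="average")  # 1-based, .5 on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=v.index, columns=v.columns),
        samples=matrix.samples,
        biotype=matrix.biotype,
    )


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def contrast_pairs(samples: pd.DataFrame, contrast: str) -> list[tuple[str, str]]:
    """(tumor sample, matched normal sample) pairs for contrast 'S' or 'L'.

    Every tumor sample of the requested size class must have exactly one
    normal sample from the same patient.
    """
    if contrast not in ("S", "L"):
        raise ContractError(f"contrast must be 'S' or 'L', got {contrast!r}")
    tumors = samples[(samples["tissue"] == "T") & (samples["size"] == contrast)]
    normals = samples[samples["tissue"] == "N"]
    by_patient = normals.groupby("patient").groups
    pairs = []
    for sid, row in tumors.iterrows():
        match = by_patient.get(row["patient"], [])
        if len(match) != 1:
            raise ContractError(
                f"tumor sample {sid!r} (patient {row['patient']!r}) has "
                f"{len(match)} matched normals; exactly one required"
            )
        pairs.append((sid, match[0]))
    if not pairs:
        raise ContractError(f"no tumor samples found for contrast {contrast!r}")
    return pairs


def _paired_diffs(matrix: ExpressionMatrix, contrast: str) -> np.ndarray:
    pairs = contrast_pairs(matrix.samples, contrast)
    v = matrix.values
    t = v[[p[0] for p in pairs]].to_numpy(dtype=float)
    n = v[[p[1] for p in pairs]].to_numpy(dtype=float)
    return t - n  # features x pairs, log2 scale


def paired_log2fc(matrix: ExpressionMatrix, contrast: str) -> pd.Series:
    """Mean over pairs of (tumor - normal) on the log2 scale, per feature."""
    d = _paired_diffs(matrix, contrast)
    return pd.Series(d.mean(axis=1), index=matrix.values.index, name=f"log2FC_{contrast}")


def paired_t_test(matrix: ExpressionMatrix, contrast: str) -> pd.DataFrame:
    """Two-sided paired t-test per feature: t = mean(d) / (sd(d)/sqrt(n)), df = n-1.

    Zero-variance differences do not raise: a nonzero mean with no variance
    gets the smallest positive double as p (flagged degenerate), a zero mean
    with no variance gets p = 1 (flagged).
    """
    d = _paired_diffs(matrix, contrast)
    n = d.shape[1]
    if n < 2:
        raise ContractError("paired t-test needs >= 2 pairs")
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2 * st.t.sf(np.abs(t), df=n - 1)
    sentinel_t = np.where(mean > 0, np.inf, np.where(mean < 0, -np.inf, 0.0))
    t = np.where(degenerate, sentinel_t, t)
    p = np.where(degenerate, np.where(mean != 0, P_DEGENERATE_LOW, 1.0), p)
    return pd.DataFrame(
        {"t": t, "p": p, "degenerate": degenerate},
        index=matrix.values.index,
    )


# ---------------------------------------------------------------------------
# Calls, Venn partitions, signature sets
# ---------------------------------------------------------------------------

def call_dysregulated(
    log2fc: pd.Series,
    pvals: pd.Series,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> pd.Series:
    """up / down / none calls: |log2FC| >= log2(threshold) inclusive, p < alpha strict."""
    if fc_threshold <= 0:
        raise ContractError("fc_threshold must be positive")
    cut = np.log2(fc_threshold)
    sig = pvals < alpha
    call = np.where(sig & (log2fc >= cut), "up",
                    np.where(sig & (log2fc <= -cut), "down", "none"))
    return pd.Series(call, index=log2fc.index, name="call")


@dataclass
class DiffExprTable:
    """Per-feature differential-expression results for both contrasts.

    ``table`` columns: log2FC_S, log2FC_L, p_S, p_L, call_S, call_L plus the
    set-membership flags set1m/set2m/set3l/set4l and the Venn partition.
    """

    table: pd.DataFrame
    fc_threshold: float
    alpha: float
    ls_fc_threshold: float

    def called(self, contrast: str, biotype: str | None = None) -> pd.Index:
        mask = self.table[f"call_{contrast}"] != "none"
        if biotype is not None:
            mask &= self.table["biotype"] == biotype
        return self.table.index[mask]

    def called_any(self, biotype: str | None = None) -> pd.Index:
        mask = (self.table["call_S"] != "none") | (self.table["call_L"] != "none")
        if biotype is not None:
            mask &= self.table["biotype"] == biotype
        return self.table.index[mask]

    def set_members(self, name: str) -> pd.Index:
        return self.table.index[self.table[name]]


def venn_partition(calls_S: pd.Series, calls_L: pd.Series) -> pd.Series:
    """Disjoint partitions over called features.

    Values: ``S_only_up``, ``S_only_down``, ``L_only_up``, ``L_only_down``,
    ``both_up``, ``both_down``, ``discordant`` (opposite directions in S and
    L, reported separately rather than merged), or ``uncalled``.
    """
    if not calls_S.index.equals(calls_L.index):
        raise ContractError("calls_S and calls_L cover different feature universes")
    out = pd.Series("uncalled", index=calls_S.index, name="venn")
    for direction in ("up", "down"):
        s = calls_S == direction
        l = calls_L == direction
        out[s & l] = f"both_{direction}"
        out[s & (calls_L == "none")] = f"S_only_{direction}"
        out[(calls_S == "none") & l] = f"L_only_{direction}"
    discordant = ((calls_S == "up") & (calls_L == "down")) | (
        (calls_S == "down") & (calls_L == "up"))
    out[discordant] = "discordant"
    return out


def signature_sets(
    table: pd.DataFrame,
    ls_fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Large-tumor signature flags set1m/set2m (mRNA) and set3l/set4l (lncRNA).

    Sets 1/3: called in L and not in S. Sets 2/4: called in L, S call absent
    or same-signed, and the L-vs-S change |log2FC_L - log2FC_S| at least
    log2(ls_fc_threshold).
    """
    if ls_fc_threshold <= 0:
        raise ContractError("ls_fc_threshold must be positive")
    cut = np.log2(ls_fc_threshold)
    called_L = table["call_L"] != "none"
    called_S = table["call_S"] != "none"
    concordant = ~called_S | (table["call_S"] == table["call_L"])
    large_only = called_L & ~called_S
    dramatic = called_L & concordant & (
        (table["log2FC_L"] - table["log2FC_S"]).abs() >= cut)
    is_m = table["biotype"] == "mRNA"
    is_l = table["biotype"] == "lncRNA"
    return pd.DataFrame({
        "set1m": large_only & is_m,
        "set2m": dramatic & is_m,
        "set3l": large_only & is_l,
        "set4l": dramatic & is_l,
    }, index=table.index)


def differential_expression(
    matrix: ExpressionMatrix,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    ls_fc_threshold: float = 2.0,
    adjust: str = "none",
) -> DiffExprTable:
    """Run both contrasts on a (normalized) matrix and assemble the full table.

    ``adjust='bh'`` applies Benjamini-Hochberg to each contrast's p-values
    before calling; the default keeps raw p-values.
    """
    cols = {}
    for contrast in ("S", "L"):
        cols[f"log2FC_{contrast}"] = paired_log2fc(matrix, contrast)
        tt = paired_t_test(matrix, contrast)
        p = tt["p"]
        if adjust == "bh":
            p = pd.Series(multipletests(p, method="fdr_bh")[1], index=p.index)
        elif adjust != "none":
            raise ContractError(f"unknown adjust mode {adjust!r}")
        cols[f"p_{contrast}"] = p
        cols[f"t_{contrast}"] = tt["t"]
    table = pd.DataFrame(cols)
    table["biotype"] = matrix.biotype
    for contrast in ("S", "L"):
        table[f"call_{contrast}"] = call_dysregulated(
            table[f"log2FC_{contrast}"], table[f"p_{contrast}"],
            fc_threshold=fc_threshold, alpha=alpha)
    table["venn"] = venn_partition(table["call_S"], table["call_L"])
    table = table.join(signature_sets(table, ls_fc_threshold))
    return DiffExprTable(table=table, fc_threshold=fc_threshold, alpha=alpha,
                         ls_fc_threshold=ls_fc_threshold)


# ---------------------------------------------------------------------------
# Density summaries and heatmap ordering
# ---------------------------------------------------------------------------

def fc_density_summary(
    log2fc: pd.Series,
    calls: pd.Series | None = None,
    bins: int = 50,
) -> dict:
    """Normalized log2FC histogram plus the up/down mass among called features."""
    x = np.asarray(log2fc, dtype=float)
    if x.size == 0:
        raise ContractError("empty log2FC input")
    if not np.isfinite(x).all():
        raise ContractError("non-finite log2FC values")
    if np.ptp(x) == 0:
        edges = np.linspace(x[0] - 0.5, x[0] + 0.5, bins + 1)
    else:
        edges = np.linspace(x.min(), x.max(), bins + 1)
    density, edges = np.histogram(x, bins=edges, density=True)
    summary = {"bin_edges": edges, "density": density}
    if calls is not None:
        called = calls[calls != "none"]
        n = max(len(called), 1)
        summary["frac_up"] = float((called == "up").sum()) / n
        summary["frac_down"] = float((called == "down").sum()) / n
    return summary


def cluster_order(values: pd.DataFrame) -> list[str]:
    """Row ordering for heatmaps: average linkage on 1 - Pearson distance.

    Constant rows (undefined correlation) are placed last, by id; ties in the
    dendrogram are broken deterministically by scipy's leaf ordering of the
    id-sorted input.
    """
    df = values.sort_index()
    sd = df.std(axis=1, ddof=0)
    ok = df[sd > 0]
    flat = sorted(df.index[sd == 0])
    if len(ok) < 2:
        return list(ok.index) + flat
    corr = np.corrcoef(ok.to_numpy(dtype=float))
    dist = 1.0 - corr[np.triu_indices(len(ok), k=1)]
    link = hierarchy.linkage(np.clip(dist, 0, 2), method="average")
    leaves = hierarchy.leaves_list(link)
    return [ok.index[i] for i in leaves] + flat
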