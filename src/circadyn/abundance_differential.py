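"""Gene-level eccDNA abundance and differential eccGene statistics.

An eccGene is a gene whose body contains the junction coordinate (start
by default, end as a cross-check) of at least one distinct eccDNA.
"eccDNA types" are distinct (chrom, start, end) coordinates; duplicates
collapse before counting.  Abundance of gene g in a sample is the
length-normalized count rescaled to a per-million composition:

    a_g = (n_g / L_g) / sum_i (n_i / L_i) * 1e6

so every column with at least one assigned eccDNA sums to 1e6.

Differential eccGenes: two-sided Wilcoxon rank-sum per gene across
samples, significant iff p < 0.05 and |log2FC| >= 1 (log2FC uses a
pseudo-count of 1 abundance unit; BH q-values are reported alongside but
do not gate significance).  Uniquely-present genes use the two-sided
Fisher exact test on the 2x2 sample-presence table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, fisher_exact, mannwhitneyu
from scipy.stats import pearsonr as _scipy_pearsonr
from scipy.stats import rankdata

from .io_formats import AnnotationSet, Catalog

LOG2FC_EPS = 1.0   # pseudo-count, in units of the 1e6 abundance scale
EXACT_MAX_COMB = 20_000


def gene_spans(annot: AnnotationSet) -> pd.DataFrame:
    """Gene id, chrom, start, end, length from the gene track."""
    g = annot.subset("gene").copy()
    g = g.rename(columns={"parent": "gene"})
    g["length"] = g["end"] - g["start"]
    return g[["gene", "chrom", "start", "end", "length"]]


def gene_counts(catalog: Catalog, annot: AnnotationSet,
                junction: str = "start") -> pd.Series:
    """Distinct-eccDNA count per gene, assigned by junction containment.

    ``junction`` selects the start coordinate or the end-junction base
    (end - 1, the last covered base of the half-open record).  A record
    spanning several genes counts once per containing gene.
    """
    if junction not in ("start", "end"):
        raise ValueError("junction must be 'start' or 'end'")
    uniq = catalog.df.drop_duplicates(subset=["chrom", "start", "end"])
    pos = uniq[junction].to_numpy()
    if junction == "end":
        pos = pos - 1
    chroms = uniq["chrom"].to_numpy()
    genes = gene_spans(annot)
    counts: dict[str, int] = {}
    for chrom, sub in genes.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        p = pos[sel]
        # genes may overlap in principle: check each gene's span
        for g, s, e in zip(sub["gene"], sub["start"], sub["end"]):
            n = int(((p >= s) & (p < e)).sum())
            if n:
                counts[g] = counts.get(g, 0) + n
    return pd.Series(counts, dtype=np.int64).sort_index()


def abundance(counts: pd.Series, gene_lengths: pd.Series) -> pd.Series:
    """One abundance column: length-normalized rates scaled to 1e6 total."""
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every counted gene needs a positive length")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        import warnings
        warnings.warn("all gene counts are zero; abundance column is zero",
                      stacklevel=2)
        return rate * 0.0
    return rate / total * 1e6


@dataclass
class AbundanceMatrix:
    """genes x samples abundance with the raw counts and gene lengths."""

    values: pd.DataFrame       # genes x samples, columns sum to 1e6
    counts: pd.DataFrame       # raw distinct-eccDNA counts
    gene_lengths: pd.Series


def abundance_matrix(catalogs: dict[str, Catalog], annot: AnnotationSet,
                     junction: str = "start") -> AbundanceMatrix:
    """Assemble the gene x sample abundance matrix.

    The gene universe is genes with a nonzero count in at least one
    sample (all-zero genes are excluded from the normalization).
    """
    lengths = gene_spans(annot).set_index("gene")["length"]
    counts = {}
    for sid, cat in catalogs.items():
        counts[sid] = gene_counts(cat, annot, junction)
    cmat = pd.DataFrame(counts).fillna(0).astype(np.int64).sort_index()
    cmat = cmat[cmat.sum(axis=1) > 0]
    vals = pd.DataFrame(
        {sid: abundance(cmat[sid], lengths) for sid in cmat.columns})
    return AbundanceMatrix(values=vals, counts=cmat,
                           gene_lengths=lengths.reindex(cmat.index))


# ---------------------------------------------------------------------------
# exact Wilcoxon rank-sum (two-sided permutation p, midranks for ties)

def rank_sum_exact_p(x, y) -> float:
    """Two-sided exact permutation p for the Wilcoxon rank-sum statistic.

    Enumerates all C(n1+n2, n1) group labelings; ties get midranks;
    p = Pr(|W - E[W]| >= |W_obs - E[W]|) with W the rank sum of ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    center = n1 * (n + 1) / 2.0
    d_obs = abs(w_obs - center)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - center) >= d_obs - 1e-9:
            hits += 1
    return hits / total


def rank_sum_p(x, y) -> float:
    """Two-sided rank-sum p: exact enumeration when feasible, otherwise the
    tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0
    if comb(len(x) + len(y), len(x)) <= EXACT_MAX_COMB:
        return rank_sum_exact_p(x, y)
    return float(mannwhitneyu(x, y, alternative="two-sided",
                              method="asymptotic").pvalue)


def differential(matrix: AbundanceMatrix, groups: dict[str, str],
                 paired: bool = False) -> pd.DataFrame:
    """Per-gene differential table (post vs pre).

    Unpaired two-sided Wilcoxon rank-sum by default; ``paired`` switches
    to the signed-rank test on per-patient differences (sample ids must
    then align pre/post by sorted order within group).
    """
    pre_ids = [s for s in matrix.values.columns if groups[s] == "pre"]
    post_ids = [s for s in matrix.values.columns if groups[s] == "post"]
    if len(pre_ids) < 2 or len(post_ids) < 2:
        raise ValueError("need at least two samples per group")
    rows = []
    for gene, vals in matrix.values.iterrows():
        a_pre = vals[pre_ids].to_numpy(dtype=float)
        a_post = vals[post_ids].to_numpy(dtype=float)
        if paired:
            from scipy.stats import wilcoxon as _signed_rank
            d = a_post - a_pre
            p = 1.0 if np.all(d == 0) else float(
                _signed_rank(d, alternative="two-sided").pvalue)
        else:
            p = rank_sum_p(a_pre, a_post)
        log2fc = float(np.log2((a_post.mean() + LOG2FC_EPS)
                               / (a_pre.mean() + LOG2FC_EPS)))
        constant = np.ptp(vals.to_numpy(dtype=float)) == 0
        rows.append((gene, a_pre.mean(), a_post.mean(), log2fc, p, constant))
    out = pd.DataFrame(rows, columns=["gene", "mean_pre", "mean_post",
                                      "log2FC", "p", "constant"])
    out["q"] = false_discovery_control(out["p"], method="bh")
    out["significant"] = (out["p"] < 0.05) & (out["log2FC"].abs() >= 1.0)
    return out


def unique_genes(presence: pd.DataFrame, groups: dict[str, str],
                 min_samples: int = 3) -> pd.DataFrame:
    """Genes forming eccDNAs in one group only, by Fisher's exact test.

    ``presence`` is a gene x sample boolean frame (count > 0).  A gene is
    unique to a group iff it is present in at least ``min_samples``
    samples of that group, absent from every sample of the other, and the
    two-sided Fisher p on the 2x2 presence table is < 0.05.
    """
    pre_ids = [s for s in presence.columns if groups[s] == "pre"]
    post_ids = [s for s in presence.columns if groups[s] == "post"]
    rows = []
    for gene, vals in presence.iterrows():
        n_pre = int(vals[pre_ids].sum())
        n_post = int(vals[post_ids].sum())
        table = [[n_pre, len(pre_ids) - n_pre],
                 [n_post, len(post_ids) - n_post]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
        unique_to = "none"
        if n_pre >= min_samples and n_post == 0 and p < 0.05:
            unique_to = "pre"
        elif n_post >= min_samples and n_pre == 0 and p < 0.05:
            unique_to = "post"
        rows.append((gene, n_pre, n_post, p, unique_to))
    return pd.DataFrame(rows, columns=["gene", "n_pre", "n_post",
                                       "fisher_p", "unique_to"])


def junction_concordance(counts_by_start: pd.Series,
                         counts_by_end: pd.Series) -> tuple[float, float]:
    """Pearson correlation across genes of start- vs end-derived counts."""
    genes = counts_by_start.index.union(counts_by_end.index)
    x = counts_by_start.reindex(genes, fill_value=0).to_numpy(dtype=float)
    y = counts_by_end.reindex(genes, fill_value=0).to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: concordance undefined")
    r, p = _scipy_pearsonr(x, y)
    return float(r), float(p)
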