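"""Element-class observed/expected ratios and repeat-class ratios.

A record is assigned to a class if its START position falls inside an
interval of that class (half-open); tracks and classes are evaluated
independently, so one start can count toward exon and CpG at once.  For
the intron/exon proportion analysis a mutually exclusive "partition" mode
exists with precedence exon > UTR > intron > Gene2kbU > Gene2kbD >
intergenic.

The observed/expected ratio of a class c is

    O/E = (fraction of records starting in c)
            / (bp of c / genome bp)

so uniform placement drives every ratio to 1.  Group (pre vs post)
comparisons use the two-sided Wilcoxon rank-sum across per-sample values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .io_formats import (AnnotationSet, Catalog, ELEMENT_LABELS,
                         REPEAT_LABELS)

PARTITION_PRECEDENCE = ("exon", "5UTR", "3UTR", "intron",
                        "Gene2kbU", "Gene2kbD")


def _start_hits(catalog: Catalog, annot: AnnotationSet, track: str,
                coordinate: str = "start") -> pd.DataFrame:
    """Boolean record x class matrix of start-containment hits.

    Vectorized per class with searchsorted over the class's merged,
    sorted intervals (intervals of one class rarely overlap in practice;
    merging makes containment well defined regardless).
    """
    sub = annot.subset(track)
    labels = sorted(sub["label"].unique())
    pos_all = catalog.df[coordinate].to_numpy()
    if coordinate == "end":
        pos_all = pos_all - 1  # junction base of a half-open record
    chrom_all = catalog.df["chrom"].to_numpy()
    out = np.zeros((len(catalog.df), len(labels)), dtype=bool)
    for j, lab in enumerate(labels):
        lsub = sub[sub["label"] == lab]
        for chrom, csub in lsub.groupby("chrom"):
            sel = np.flatnonzero(chrom_all == chrom)
            if sel.size == 0:
                continue
            iv = csub[["start", "end"]].sort_values("start").to_numpy()
            # merge overlapping intervals of the same class
            merged_s, merged_e = [iv[0, 0]], [iv[0, 1]]
            for s, e in iv[1:]:
                if s > merged_e[-1]:
                    merged_s.append(s)
                    merged_e.append(e)
                else:
                    merged_e[-1] = max(merged_e[-1], e)
            ms = np.asarray(merged_s)
            me = np.asarray(merged_e)
            pos = pos_all[sel]
            k = np.searchsorted(ms, pos, side="right") - 1
            hit = (k >= 0) & (pos < me[np.maximum(k, 0)])
            out[sel[hit], j] = True
    return pd.DataFrame(out, columns=labels, index=catalog.df.index)


def assign_starts(catalog: Catalog, annot: AnnotationSet,
                  track: str) -> list[set]:
    """Per-record set of class labels whose intervals contain the start."""
    hits = _start_hits(catalog, annot, track)
    cols = np.array(hits.columns)
    return [set(cols[row]) for row in hits.to_numpy()]


def element_oe(catalog: Catalog, annot: AnnotationSet, genome,
               labels=ELEMENT_LABELS) -> pd.DataFrame:
    """Per-class observed fraction, expected genome fraction and O/E ratio."""
    genome_bp = genome.total_bp if hasattr(genome, "total_bp") \
        else sum(len(s) for s in genome.values())
    span = annot.class_span("element")
    hits = _start_hits(catalog, annot, "element")
    n = len(catalog.df)
    rows = []
    for lab in labels:
        expected = span.get(lab, 0) / genome_bp
        observed = float(hits[lab].mean()) if (lab in hits.columns and n) else 0.0
        undefined = expected == 0.0
        ratio = np.nan if undefined else observed / expected
        rows.append((lab, observed, expected, ratio, undefined))
    return pd.DataFrame(rows, columns=["label", "observed", "expected",
                                       "ratio", "undefined"])


def repeat_ratio(catalog_or_reads, annot: AnnotationSet, genome,
                 labels=REPEAT_LABELS) -> pd.DataFrame:
    """Normalized mapping ratio per repeat class.

    Input is either a Catalog (record starts, the default unit here) or a
    DataFrame of read intervals with columns chrom/start/end (read-level
    weighting, matching upstream read-counting conventions; read starts
    are the assignment coordinate).
    """
    if isinstance(catalog_or_reads, Catalog):
        catalog = catalog_or_reads
    else:
        df = catalog_or_reads.copy()
        catalog = Catalog.__new__(Catalog)  # lightweight wrapper, no checks
        catalog.sample_id = "reads"
        catalog.df = df
        catalog.total_mapped_reads = max(len(df), 1)
        catalog.timepoint = "pre"
        catalog.patient_id = ""
    genome_bp = genome.total_bp if hasattr(genome, "total_bp") \
        else sum(len(s) for s in genome.values())
    span = annot.class_span("repeat")
    present = [lab for lab in labels if lab in span]
    if not present:
        return pd.DataFrame(columns=["label", "observed", "expected",
                                     "ratio", "undefined"])
    hits = _start_hits(catalog, annot, "repeat")
    n = len(catalog.df)
    rows = []
    for lab in present:
        expected = span[lab] / genome_bp
        observed = float(hits[lab].mean()) if (lab in hits.columns and n) else 0.0
        rows.append((lab, observed, expected, observed / expected, False))
    return pd.DataFrame(rows, columns=["label", "observed", "expected",
                                       "ratio", "undefined"])


def partition_labels(catalog: Catalog, annot: AnnotationSet) -> np.ndarray:
    """Mutually exclusive per-record class with the fixed precedence order;
    records hitting nothing are 'intergenic'."""
    hits = _start_hits(catalog, annot, "element")
    out = np.full(len(catalog.df), "intergenic", dtype=object)
    for lab in reversed(PARTITION_PRECEDENCE):
        if lab in hits.columns:
            out[hits[lab].to_numpy()] = lab
    return out


def intron_exon_proportions(catalog: Catalog, annot: AnnotationSet,
                            mode: str = "independent"
                            ) -> tuple[float, float]:
    """(exon fraction, intron fraction) of record starts.

    ``independent`` counts a start once per class it hits (a start in a
    UTR that is also labeled exon counts as exon once — set semantics);
    ``partition`` applies the exclusive precedence so that exon + intron
    + other fractions sum to 1.
    """
    if len(catalog.df) == 0:
        return 0.0, 0.0
    if mode == "partition":
        lab = partition_labels(catalog, annot)
        return (float((lab == "exon").mean()),
                float((lab == "intron").mean()))
    hits = _start_hits(catalog, annot, "element")
    exon = float(hits["exon"].mean()) if "exon" in hits.columns else 0.0
    intron = float(hits["intron"].mean()) if "intron" in hits.columns else 0.0
    return exon, intron


def group_ratio_comparison(catalogs, groups: dict[str, str],
                           annot: AnnotationSet, genome,
                           kind: str = "element") -> pd.DataFrame:
    """Per-class group means (pre vs post) with Wilcoxon rank-sum p.

    ``catalogs`` maps sample_id -> Catalog; ``groups`` maps sample_id ->
    'pre'/'post'.
    """
    fn = element_oe if kind == "element" else repeat_ratio
    per_sample = {}
    for sid, cat in catalogs.items():
        tab = fn(cat, annot, genome)
        per_sample[sid] = tab.set_index("label")["ratio"]
    wide = pd.DataFrame(per_sample)
    rows = []
    for lab, vals in wide.iterrows():
        pre = vals[[s for s in vals.index if groups[s] == "pre"]].dropna()
        post = vals[[s for s in vals.index if groups[s] == "post"]].dropna()
        if len(pre) and len(post):
            stat, p = mannwhitneyu(pre, post, alternative="two-sided")
        else:
            p = np.nan
        rows.append((lab, pre.mean(), post.mean(), p))
    return pd.DataFrame(rows, columns=["label", "mean_pre", "mean_post",
                                       "wilcoxon_p"])
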