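"""Exon-spanning eccDNA cluster analysis.

Catalogs from both groups are merged; eccDNAs intersecting exons of the
same gene form one cluster per gene; from each cluster the members whose
interval fully contains at least one exon ("spanning") are selected, and
per-exon group presence is compared by Fisher's exact test.  "Spanning"
is full containment: record.start <= exon.start and exon.end <=
record.end (a record equal to the exon interval spans it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .io_formats import AnnotationSet, Catalog


@dataclass
class ClusterMember:
    sample_id: str
    group: str
    chrom: str
    start: int
    end: int
    #: exon ids of the gene that the record fully contains
    spanned_exons: tuple[str, ...] = ()


@dataclass
class ExonCluster:
    """All eccDNAs intersecting exons of one gene."""

    gene: str
    members: list[ClusterMember] = field(default_factory=list)

    @property
    def spanned_exon_ids(self) -> set[str]:
        return {e for m in self.members for e in m.spanned_exons}


def build_clusters(catalogs: dict[str, Catalog], annot: AnnotationSet,
                   groups: dict[str, str] | None = None) -> list[ExonCluster]:
    """One cluster per gene with >= 1 eccDNA intersecting one of its exons.

    Intersection is any overlap between the half-open record and exon
    intervals.  A record overlapping exons of two genes joins both
    clusters.  ``groups`` maps sample_id -> group label (defaults to each
    catalog's timepoint).
    """
    ex = annot.subset("exon")
    clusters: dict[str, ExonCluster] = {}
    for sid, cat in catalogs.items():
        group = groups[sid] if groups else cat.timepoint
        df = cat.df.drop_duplicates(subset=["chrom", "start", "end"])
        for chrom, esub in ex.groupby("chrom"):
            rsub = df[df["chrom"] == chrom]
            if rsub.empty:
                continue
            es = esub["start"].to_numpy()
            ee = esub["end"].to_numpy()
            eids = esub["parent"].to_numpy()   # exon id
            # parent gene: exon id is "<gene>_e<k>"
            egenes = np.array([e.rsplit("_e", 1)[0] for e in eids])
            rs = rsub["start"].to_numpy()
            re = rsub["end"].to_numpy()
            # any-overlap matrix via broadcasting (toy-scale exon counts)
            ov = (rs[:, None] < ee[None, :]) & (es[None, :] < re[:, None])
            sp = (rs[:, None] <= es[None, :]) & (ee[None, :] <= re[:, None])
            for i in range(len(rsub)):
                hit = np.flatnonzero(ov[i])
                if hit.size == 0:
                    continue
                for gene in np.unique(egenes[hit]):
                    gmask = hit[egenes[hit] == gene]
                    spanned = tuple(eids[j] for j in gmask if sp[i, j])
                    clusters.setdefault(gene, ExonCluster(gene=gene)) \
                        .members.append(ClusterMember(
                            sample_id=sid, group=group, chrom=chrom,
                            start=int(rs[i]), end=int(re[i]),
                            spanned_exons=spanned))
    return sorted(clusters.values(), key=lambda c: c.gene)


def select_spanning(clusters: list[ExonCluster]) -> list[ExonCluster]:
    """Retain only members that fully contain >= 1 exon of their gene."""
    out = []
    for c in clusters:
        members = [m for m in c.members if m.spanned_exons]
        if members:
            out.append(ExonCluster(gene=c.gene, members=members))
    return out


def group_exon_stats(spanning: list[ExonCluster],
                     group_sizes: dict[str, int],
                     top_n: int = 30) -> pd.DataFrame:
    """Per spanned exon: sample presence per group, Fisher p, uniqueness.

    Presence is at sample level (a sample counts once per exon however
    many of its records span it).  ``group_sizes`` gives the number of
    samples per group ('pre'/'post') for the 2x2 tables.  Rows are ranked
    by total presence (ties: total spanning-record count, then exon id);
    ``rank`` <= top_n marks the top table.
    """
    n_pre = group_sizes.get("pre", 0)
    n_post = group_sizes.get("post", 0)
    presence: dict[str, dict[str, set]] = {}
    rec_count: dict[str, int] = {}
    gene_of: dict[str, str] = {}
    for c in spanning:
        for m in c.members:
            for eid in m.spanned_exons:
                presence.setdefault(eid, {"pre": set(), "post": set()})
                presence[eid].setdefault(m.group, set()).add(m.sample_id)
                rec_count[eid] = rec_count.get(eid, 0) + 1
                gene_of[eid] = c.gene
    rows = []
    for eid, pres in presence.items():
        k_pre = len(pres.get("pre", ()))
        k_post = len(pres.get("post", ()))
        table = [[k_pre, n_pre - k_pre], [k_post, n_post - k_post]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
        if k_pre > 0 and k_post == 0:
            unique_to = "pre"
        elif k_post > 0 and k_pre == 0:
            unique_to = "post"
        else:
            unique_to = "none"
        rows.append((eid, gene_of[eid], k_pre, k_post, rec_count[eid], p,
                     unique_to))
    out = pd.DataFrame(rows, columns=["exon", "gene", "n_pre_samples",
                                      "n_post_samples", "n_records",
                                      "fisher_p", "unique_to"])
    out["total_samples"] = out["n_pre_samples"] + out["n_post_samples"]
    out = out.sort_values(by=["total_samples", "n_records", "exon"],
                          ascending=[False, False, True]).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out["top"] = out["rank"] <= top_n
    return out
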