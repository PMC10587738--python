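"""End-to-end analysis: simulate (or load) a cohort, filter, characterize,
and write one TSV per analysis table."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import (abundance_differential as ad, annotation_metrics as am,
               association as assoc, catalog_metrics as cm, clinical as cl)
from .circle_filter import FilterCriteria, apply_filters
from .io_formats import Catalog, write_annotation, write_catalog, \
    write_clinical, write_fasta, write_sample_sheet
from .exon_clusters import build_clusters, group_exon_stats, select_spanning
from .synthetic_data import CohortSim, SimConfig, simulate_cohort

log = logging.getLogger(__name__)


def write_simulation(sim: CohortSim, out_dir) -> None:
    """Write genome FASTA, annotation BED, catalogs, clinical and sample
    sheet plus truth labels for a simulated cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.genome.contigs, out / "genome.fa")
    write_annotation(sim.annot, out / "annotation.bed")
    cat_dir = out / "catalogs"
    cat_dir.mkdir(exist_ok=True)
    truth = {}
    for sid, cat in sim.catalogs.items():
        write_catalog(cat, cat_dir / f"{sid}.tsv")
        if "truth" in cat.df.columns:
            truth[sid] = cat.df["truth"].astype(int).tolist()
    write_clinical(sim.meals, out / "clinical.tsv")
    sheet = sim.sheet.df.copy()
    sheet["catalog_path"] = ["catalogs/" + s + ".tsv" for s in sheet["sample_id"]]
    sheet["clinical_path"] = "clinical.tsv"
    write_sample_sheet(type(sim.sheet)(df=sheet), out / "samples.tsv")
    sim.followup.to_csv(out / "followup.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh)


def run_pipeline(config: SimConfig = SimConfig(), seed: int | None = None,
                 out_dir=None, criteria: FilterCriteria = FilterCriteria()
                 ) -> dict[str, pd.DataFrame]:
    """Simulate a cohort and run every analysis stage; return (and
    optionally write) the report tables."""
    sim = simulate_cohort(config, seed)
    return analyze_cohort(sim, out_dir=out_dir, criteria=criteria)


def analyze_cohort(sim: CohortSim, out_dir=None,
                   criteria: FilterCriteria = FilterCriteria()
                   ) -> dict[str, pd.DataFrame]:
    groups = dict(zip(sim.sheet.df["sample_id"], sim.sheet.df["timepoint"]))

    filtered: dict[str, Catalog] = {}
    filter_rows = []
    for sid, cat in sim.catalogs.items():
        fcat, rep = apply_filters(cat, criteria)
        filtered[sid] = fcat
        filter_rows.append((sid, rep.n_input, rep.n_passed,
                            *[rep.fail_counts[k] for k in range(1, 6)]))
    filter_table = pd.DataFrame(filter_rows, columns=[
        "sample_id", "n_input", "n_passed",
        "fail_split", "fail_score", "fail_cov_sd", "fail_edge", "fail_uncov"])

    # per-sample EPM and element-start fractions
    epm_rows = []
    frac_rows = []
    for sid, cat in filtered.items():
        exon_f, intron_f = am.intron_exon_proportions(cat, sim.annot)
        epm_rows.append((sid, cat.patient_id, cat.timepoint, cm.epm(cat),
                         cat.total_mapped_reads))
        frac_rows.append((sid, exon_f, intron_f))
    epm_table = pd.DataFrame(epm_rows, columns=[
        "sample_id", "patient_id", "timepoint", "EPM", "total_mapped_reads"])
    fractions = pd.DataFrame(frac_rows, columns=[
        "sample_id", "exon_fraction", "intron_fraction"]).set_index("sample_id")

    # pooled length / GC characterization per group
    char_rows = []
    for tp in ("pre", "post"):
        lengths = np.concatenate([c.lengths for s, c in filtered.items()
                                  if groups[s] == tp])
        peaks = cm.length_peaks(lengths)
        bands = cm.length_bands(lengths)
        char_rows.append((tp, peaks.centers[0] if peaks.centers else np.nan,
                          peaks.centers[1] if len(peaks.centers) > 1 else np.nan,
                          peaks.mean_spacing, *bands.values()))
    char_table = pd.DataFrame(char_rows, columns=[
        "group", "peak1_bp", "peak2_bp", "sub_peak_spacing",
        *cm.BAND_NAMES])

    element_table = am.group_ratio_comparison(filtered, groups, sim.annot,
                                              sim.genome, kind="element")
    repeat_table = am.group_ratio_comparison(filtered, groups, sim.annot,
                                             sim.genome, kind="repeat")

    # gene-level abundance + differential + unique genes
    mat = ad.abundance_matrix(filtered, sim.annot)
    diff_table = ad.differential(mat, groups)
    uniq_table = ad.unique_genes(mat.counts > 0, groups)

    # exon clusters
    clusters = build_clusters(filtered, sim.annot, groups)
    spanning = select_spanning(clusters)
    sizes = {"pre": sum(v == "pre" for v in groups.values()),
             "post": sum(v == "post" for v in groups.values())}
    exon_table = group_exon_stats(spanning, sizes)

    # clinical indices, deltas, associations
    indices = cl.indices_table(sim.meals)
    deltas = cl.delta_frame(indices)
    epm_by = epm_table.pivot(index="patient_id", columns="timepoint",
                             values="EPM")
    dtab = assoc.delta_table(epm_by["pre"], epm_by["post"], deltas)
    corr = assoc.correlate_deltas(dtab)

    fpg = indices.set_index(["patient_id", "timepoint"])["FPG"]
    sid_fpg = pd.Series(
        {sid: fpg.get((filtered[sid].patient_id, groups[sid]), np.nan)
         for sid in fractions.index})
    fpg_corr = assoc.fpg_element_corr(fractions, sid_fpg)

    traj = assoc.trajectory_summary(sim.followup)
    traj_counts = assoc.trajectory_group_counts(traj)

    tables = {
        "filter_report": filter_table,
        "epm_per_sample": epm_table,
        "length_characterization": char_table,
        "element_oe": element_table,
        "repeat_ratio": repeat_table,
        "abundance": mat.values.reset_index(names="gene"),
        "differential_genes": diff_table,
        "unique_genes": uniq_table,
        "exon_clusters": exon_table,
        "clinical_indices": indices,
        "delta_table": dtab,
        "delta_correlations": corr.long,
        "fpg_element_corr": fpg_corr,
        "trajectory": traj,
        "trajectory_counts": traj_counts,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in tables.items():
            tab.to_csv(out / f"{name}.tsv", sep="\t", index=False)
        log.info("wrote %d report tables to %s", len(tables), out)
    return tables
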