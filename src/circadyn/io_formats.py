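"""Readers and writers for on-disk artifacts.

Everything genomic is BED-style 0-based half-open; a record's length is
always ``end - start``.  Catalogs are TSV with an explicit header (the
detection statistics are first-class columns, not BED extras) preceded by
``#key=value`` metadata lines.  Contigs named ``chrM``/``MT`` are treated as
mitochondrial and dropped from catalogs at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

MITO_NAMES = frozenset({"chrM", "chrMT", "MT", "M"})

#: column order of a catalog TSV (after chrom/start/end come the
#: detection statistics emitted by the upstream circle caller)
CATALOG_COLUMNS = [
    "chrom", "start", "end", "n_discordant", "n_split", "score",
    "mean_cov", "sd_cov", "start_inc", "end_inc", "uncovered_frac",
]

_INT_COLS = ["start", "end", "n_discordant", "n_split"]
_FLOAT_COLS = ["score", "mean_cov", "sd_cov", "start_inc", "end_inc", "uncovered_frac"]

ELEMENT_LABELS = ("3UTR", "5UTR", "CpG", "exon", "intron", "Gene2kbU", "Gene2kbD")
REPEAT_LABELS = ("SINE", "LINE", "LTR", "satellite", "srpDNA", "rDNA",
                 "tDNA", "scDNA", "snDNA", "RC")
TRACKS = ("element", "repeat", "gene", "exon")
TIMEPOINTS = ("pre", "post", "M6", "M12")


class SchemaError(ValueError):
    """A file does not have the columns/vocabulary the format requires."""


class ValidationError(ValueError):
    """A row violates a record invariant (reported with its line number)."""


@dataclass
class EccRecord:
    """One detected circle with its coordinates and detection statistics."""

    chrom: str
    start: int
    end: int
    n_split: int = 0
    n_discordant: int = 0
    score: float = 0.0
    mean_cov: float = 0.0
    sd_cov: float = 0.0
    start_inc: float = 0.0
    end_inc: float = 0.0
    uncovered_frac: float = 0.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"end ({self.end}) must exceed start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Catalog:
    """All records of one sample plus its mapped-read denominator.

    ``total_mapped_reads`` excludes mitochondrial-mapped reads; it is the
    per-sample denominator of the eccDNA-per-million (EPM) normalization.
    Records are stored as a DataFrame with :data:`CATALOG_COLUMNS`.
    """

    sample_id: str
    df: pd.DataFrame
    total_mapped_reads: int
    timepoint: str = "pre"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.total_mapped_reads <= 0:
            raise ValidationError("total_mapped_reads must be positive")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}; "
                                  f"allowed: {TIMEPOINTS}")
        missing = [c for c in CATALOG_COLUMNS if c not in self.df.columns]
        if missing:
            raise SchemaError(f"catalog frame missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    def records(self) -> list[EccRecord]:
        """Materialize rows as :class:`EccRecord` objects (small catalogs)."""
        return [
            EccRecord(sample_id=self.sample_id,
                      **{c: row[c] for c in CATALOG_COLUMNS})
            for row in self.df.to_dict("records")
        ]

    @classmethod
    def from_records(cls, records: Iterable[EccRecord], sample_id: str,
                     total_mapped_reads: int, **meta) -> "Catalog":
        rows = [[getattr(r, c) for c in CATALOG_COLUMNS] for r in records]
        df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
        for c in _INT_COLS:
            df[c] = df[c].astype(np.int64)
        return cls(sample_id=sample_id, df=df,
                   total_mapped_reads=total_mapped_reads, **meta)


@dataclass
class AnnotationSet:
    """Labeled genomic intervals on four independent tracks.

    ``element`` and ``repeat`` carry the per-class enrichment vocabulary;
    ``gene`` and ``exon`` carry identities used for gene-level abundance
    (every exon has a ``parent`` gene).  Tracks are independent: the same
    base may be covered by intervals of several tracks/classes.
    """

    df: pd.DataFrame  # columns chrom,start,end,track,label,parent
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "track", "label", "parent"}
        if not need.issubset(self.df.columns):
            raise SchemaError(f"annotation frame needs columns {sorted(need)}")
        bad_track = set(self.df["track"]) - set(TRACKS)
        if bad_track:
            raise SchemaError(
                f"unknown track(s) {sorted(bad_track)}; allowed: {TRACKS}")
        el = self.df[self.df["track"] == "element"]
        bad = set(el["label"]) - set(ELEMENT_LABELS)
        if bad:
            raise SchemaError(
                f"unknown element label(s) {sorted(bad)}; allowed: {ELEMENT_LABELS}")
        rp = self.df[self.df["track"] == "repeat"]
        bad = set(rp["label"]) - set(REPEAT_LABELS)
        if bad:
            raise SchemaError(
                f"unknown repeat label(s) {sorted(bad)}; allowed: {REPEAT_LABELS}")
        ex = self.df[self.df["track"] == "exon"]
        if (ex["parent"] == "").any():
            raise ValidationError("every exon interval needs a parent gene")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, track: str) -> pd.DataFrame:
        return self.df[self.df["track"] == track]

    def tree(self, track: str) -> dict[str, IntervalTree]:
        """Per-contig interval trees for one track (built lazily, cached).

        Interval payload is ``(label, parent)``.
        """
        if track not in self._trees:
            trees: dict[str, IntervalTree] = {}
            for chrom, sub in self.subset(track).groupby("chrom"):
                t = IntervalTree()
                for s, e, lab, par in zip(sub["start"], sub["end"],
                                          sub["label"], sub["parent"]):
                    t.addi(int(s), int(e), (lab, par))
                trees[str(chrom)] = t
            self._trees[track] = trees
        return self._trees[track]

    def class_span(self, track: str) -> dict[str, int]:
        """Total bp covered per class label (union of intervals per class)."""
        out: dict[str, int] = {}
        for (lab,), sub in self.subset(track).groupby(["label"]):
            total = 0
            for _, csub in sub.groupby("chrom"):
                iv = csub[["start", "end"]].sort_values("start").to_numpy()
                cur_s, cur_e = iv[0]
                for s, e in iv[1:]:
                    if s > cur_e:
                        total += cur_e - cur_s
                        cur_s, cur_e = s, e
                    else:
                        cur_e = max(cur_e, e)
                total += cur_e - cur_s
            out[lab] = int(total)
        return out


@dataclass
class SampleSheet:
    """Rows of (patient_id, sample_id, timepoint, catalog_path, clinical_path)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"patient_id", "sample_id", "timepoint"}
        if not need.issubset(self.df.columns):
            raise SchemaError(f"sample sheet needs columns {sorted(need)}")
        dup = self.df.duplicated(subset=["patient_id", "timepoint"])
        if dup.any():
            raise ValidationError(
                "duplicate (patient_id, timepoint) rows: "
                f"{self.df.loc[dup, ['patient_id', 'timepoint']].to_dict('records')}")


# ---------------------------------------------------------------------------
# catalog TSV

def write_catalog(catalog: Catalog, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#sample_id={catalog.sample_id}\n")
        fh.write(f"#patient_id={catalog.patient_id}\n")
        fh.write(f"#timepoint={catalog.timepoint}\n")
        fh.write(f"#total_mapped_reads={catalog.total_mapped_reads}\n")
        catalog.df.to_csv(fh, sep="\t", index=False,
                          columns=CATALOG_COLUMNS, float_format="%.10g")


def read_catalog(path, sample_meta: dict | None = None) -> Catalog:
    """Read a catalog TSV; metadata comes from ``#key=value`` header lines,
    overridable by ``sample_meta``.

    Mitochondrial records (``chrM``/``MT``) are dropped.  Malformed rows are
    rejected with their line number, never silently skipped.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_comment += 1
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        # +2: 1-based line numbering plus the header row
        lineno = int(bad[0]) + n_comment + 2
        raise ValidationError(
            f"{path}: end <= start on line {lineno} "
            f"(start={df.loc[bad[0], 'start']}, end={df.loc[bad[0], 'end']})")
    for c in _INT_COLS:
        df[c] = df[c].astype(np.int64)
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(float)
    is_mito = df["chrom"].isin(MITO_NAMES)
    if is_mito.any():
        log.info("%s: dropping %d mitochondrial record(s)", path, is_mito.sum())
        df = df[~is_mito].reset_index(drop=True)
    if sample_meta:
        meta.update({k: str(v) for k, v in sample_meta.items()})
    return Catalog(
        sample_id=meta.get("sample_id", path.stem),
        df=df[CATALOG_COLUMNS],
        total_mapped_reads=int(meta["total_mapped_reads"]),
        timepoint=meta.get("timepoint", "pre"),
        patient_id=meta.get("patient_id", ""),
    )


# ---------------------------------------------------------------------------
# annotation BED

def write_annotation(annot: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for row in annot.df.itertuples(index=False):
            name = f"{row.track}:{row.label}"
            if row.parent:
                name += f":{row.parent}"
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t+\n")


def read_annotation(path) -> AnnotationSet:
    """Read a BED6-like file whose name column is ``track:label[:parent]``."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise SchemaError(f"{path}:{lineno}: expected >=4 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            toks = parts[3].split(":")
            if len(toks) < 2:
                raise SchemaError(
                    f"{path}:{lineno}: name column must be track:label[:parent]")
            track, label = toks[0], toks[1]
            parent = toks[2] if len(toks) > 2 else ""
            rows.append((chrom, start, end, track, label, parent))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                     "track", "label", "parent"])
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end",
                                   "track", "label", "parent"])
    return AnnotationSet(df=df)


# ---------------------------------------------------------------------------
# FASTA

def write_fasta(contigs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# clinical TSV

MEAL_TIMES = (0, 10, 20, 30, 60, 90, 120)
_GLU_COLS = [f"glu_{t}" for t in MEAL_TIMES]
_INS_COLS = [f"ins_{t}" for t in MEAL_TIMES]
CLINICAL_COLUMNS = ["patient_id", "timepoint", "FPG", "HbA1c"] + _GLU_COLS + _INS_COLS


def read_clinical(path) -> list:
    """One MealTest per row; the time grid is fixed at 0..120 min.

    Missing values are an error (no imputation).  ``glu_0`` is checked for
    consistency with FPG (warning only).
    """
    from .clinical import MealTest  # local import: avoid cycle

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    out = []
    for i, row in df.iterrows():
        for c in CLINICAL_COLUMNS:
            if pd.isna(row[c]):
                raise ValidationError(
                    f"{path}: row {i + 1} (patient {row['patient_id']}): "
                    f"missing value for {c}")
        if abs(row["glu_0"] - row["FPG"]) > 1e-6:
            log.warning("%s: patient %s %s: glu_0 (%.4g) != FPG (%.4g)",
                        path, row["patient_id"], row["timepoint"],
                        row["glu_0"], row["FPG"])
        out.append(MealTest(
            patient_id=str(row["patient_id"]),
            timepoint=str(row["timepoint"]),
            glucose=tuple(float(row[c]) for c in _GLU_COLS),
            insulin=tuple(float(row[c]) for c in _INS_COLS),
            FPG=float(row["FPG"]),
            HbA1c=float(row["HbA1c"]),
        ))
    return out


def write_clinical(meals, path) -> None:
    rows = []
    for m in meals:
        row = {"patient_id": m.patient_id, "timepoint": m.timepoint,
               "FPG": m.FPG, "HbA1c": m.HbA1c}
        row.update({c: v for c, v in zip(_GLU_COLS, m.glucose)})
        row.update({c: v for c, v in zip(_INS_COLS, m.insulin)})
        rows.append(row)
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> SampleSheet:
    return SampleSheet(df=pd.read_csv(path, sep="\t", dtype=str))


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.df.to_csv(path, sep="\t", index=False)
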