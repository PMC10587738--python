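"""Post-detection filtering of candidate circles.

A detected circle is kept only if all five criteria hold, each a strict
inequality: (1) split reads > 2, (2) detector score > 200, (3) mean base
coverage inside the circle > the standard deviation of the coverage
vector, (4) coverage increase at both the start and end coordinate > 0.3,
(5) fraction of uncovered bases inside the circle < 0.1.  Boundary
equality therefore fails.  Pass/fail is a conjunction; the (1)..(5) order
matters only for attributing a record's *first* failing criterion in the
report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Catalog

CRITERION_NAMES = {
    1: "split_reads",
    2: "score",
    3: "cov_mean_gt_sd",
    4: "edge_increase",
    5: "uncovered_frac",
}


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds for the five post-detection criteria (all strict)."""

    min_split: int = 2          # criterion 1: n_split > min_split
    min_score: float = 200.0    # criterion 2: score > min_score
    cov_mean_gt_sd: bool = True  # criterion 3: mean_cov > sd_cov
    min_edge_increase: float = 0.3  # criterion 4: start_inc AND end_inc >
    max_uncovered: float = 0.1  # criterion 5: uncovered_frac <

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_uncovered <= 1.0):
            raise ValueError("max_uncovered must be in [0, 1]")
        if not np.isfinite([self.min_split, self.min_score,
                            self.min_edge_increase]).all():
            raise ValueError("thresholds must be finite")


@dataclass
class FilterReport:
    n_input: int
    n_passed: int
    #: records failing, keyed by their first failing criterion (1..5)
    fail_counts: dict[int, int] = field(default_factory=dict)
    #: 0 for passing records, else the first failing criterion index
    first_fail: np.ndarray | None = None

    @property
    def n_failed(self) -> int:
        return self.n_input - self.n_passed


def compute_circle_stats(depth, flank_start=(), flank_end=(),
                         edge_window: int = 25):
    """Summary statistics of a per-base depth vector inside a circle.

    ``flank_start``/``flank_end`` are depth vectors immediately before the
    start and after the end coordinate; they may be empty (contig edge),
    in which case the flank mean is zero.  The edge-increase ratio is

        (mean of first ``w`` inside bases - mean of ``w`` flank bases)
            / max(mean of first ``w`` inside bases, 1e-9)

    clipped to [0, 1], with ``w = min(edge_window, len(depth))``, and
    symmetrically at the end.  The sd is the population sd (ddof 0).

    Returns ``(mean_cov, sd_cov, start_inc, end_inc, uncovered_frac)``.
    """
    depth = np.asarray(depth, dtype=float)
    if depth.size == 0:
        raise ValueError("empty depth vector")
    mean_cov = float(depth.mean())
    sd_cov = float(depth.std(ddof=0))
    uncovered = float((depth == 0).sum() / depth.size)
    w = min(edge_window, depth.size)
    eps = 1e-9

    def _inc(inside_w, flank):
        flank = np.asarray(flank, dtype=float)
        inside_mean = float(inside_w.mean())
        flank_mean = float(flank[-w:].mean()) if flank.size else 0.0
        return float(np.clip((inside_mean - flank_mean)
                             / max(inside_mean, eps), 0.0, 1.0))

    start_inc = _inc(depth[:w], np.asarray(flank_start, dtype=float))
    end_inc = _inc(depth[-w:], np.asarray(flank_end, dtype=float)[::-1])
    return mean_cov, sd_cov, start_inc, end_inc, uncovered


def evaluate_criteria(df: pd.DataFrame,
                      criteria: FilterCriteria) -> np.ndarray:
    """Per-record boolean matrix, one column per criterion (1..5)."""
    needed = ["n_split", "score", "mean_cov", "sd_cov",
              "start_inc", "end_inc", "uncovered_frac"]
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"records missing statistic field {col!r}")
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(
                f"record index {bad[0]} missing statistic {col!r}")
    ok3 = (df["mean_cov"] > df["sd_cov"]) if criteria.cov_mean_gt_sd \
        else pd.Series(True, index=df.index)
    return np.column_stack([
        (df["n_split"] > criteria.min_split).to_numpy(),
        (df["score"] > criteria.min_score).to_numpy(),
        ok3.to_numpy(),
        ((df["start_inc"] > criteria.min_edge_increase)
         & (df["end_inc"] > criteria.min_edge_increase)).to_numpy(),
        (df["uncovered_frac"] < criteria.max_uncovered).to_numpy(),
    ])


def apply_filters(catalog: Catalog,
                  criteria: FilterCriteria = FilterCriteria()
                  ) -> tuple[Catalog, FilterReport]:
    """Apply the five criteria; return the passing catalog and a report."""
    ok = evaluate_criteria(catalog.df, criteria)
    passed_mask = ok.all(axis=1)
    # first failing criterion, 1-based; 0 for passing records
    first_fail = np.where(passed_mask, 0, np.argmin(ok, axis=1) + 1)
    fail_counts = {k: int((first_fail == k).sum()) for k in range(1, 6)}
    report = FilterReport(
        n_input=len(catalog.df),
        n_passed=int(passed_mask.sum()),
        fail_counts=fail_counts,
        first_fail=first_fail,
    )
    out = Catalog(
        sample_id=catalog.sample_id,
        df=catalog.df[passed_mask].reset_index(drop=True),
        total_mapped_reads=catalog.total_mapped_reads,
        timepoint=catalog.timepoint,
        patient_id=catalog.patient_id,
    )
    return out, report
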