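"""Correlation analyses linking eccDNA load to clinical state.

Delta values (percent change post vs pre) of EPM and of the glycemic
indices are correlated pairwise with Pearson's R (two-sided p from the
t-distribution with n-2 df); exon/intron start proportions are
correlated with fasting plasma glucose across pooled pre+post samples;
and per-patient EPM trajectories over pre/post/M6/M12 are summarized
against remission status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control
from scipy.stats import pearsonr as _scipy_pearsonr
from scipy.stats import spearmanr as _scipy_spearmanr

DELTA_COLUMNS = ["dEPM", "dFPG", "d2hPG", "dHbA1c", "dHOMA_IR",
                 "dHOMA_beta", "dISSI2"]


def pearson(x, y, method: str = "pearson") -> tuple[float, float]:
    """Sample correlation and two-sided p; NaN inputs are rejected.

    Raises ``ValueError`` on n < 3 or a zero-variance vector (the
    correlation is undefined there, not zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "spearman":
        r, p = _scipy_spearmanr(x, y)
    else:
        r, p = _scipy_pearsonr(x, y)
    return float(r), float(p)


def delta_table(epm_pre: pd.Series, epm_post: pd.Series,
                deltas: pd.DataFrame) -> pd.DataFrame:
    """Join per-patient delta-EPM onto the clinical delta frame.

    ``deltas`` comes from :func:`circadyn.clinical.delta_frame`; only
    patients with both EPM timepoints are kept.
    """
    common = [p for p in deltas["patient_id"]
              if p in epm_pre.index and p in epm_post.index]
    out = deltas[deltas["patient_id"].isin(common)].copy()
    depm = (epm_post[common] - epm_pre[common]) / epm_pre[common] * 100.0
    out.insert(1, "dEPM", depm.loc[out["patient_id"]].to_numpy())
    ren = {"dtwo_hour_glucose": "d2hPG"}
    return out.rename(columns=ren)


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    long: pd.DataFrame   # tidy pairs with BH q


def correlate_deltas(table: pd.DataFrame,
                     columns=None, method: str = "pearson"
                     ) -> CorrelationMatrix:
    """Pairwise correlations over the delta columns, pairwise-complete.

    Cells with fewer than 3 complete pairs or zero variance are NaN.
    """
    cols = [c for c in (columns or DELTA_COLUMNS) if c in table.columns]
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    rows = []
    for i, a in enumerate(cols):
        n.loc[a, a] = int(table[a].notna().sum())
        for b in cols[i + 1:]:
            sub = table[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(sub)
            try:
                ri, pi = pearson(sub[a], sub[b], method=method)
            except ValueError:
                ri = pi = np.nan
            r.loc[a, b] = r.loc[b, a] = ri
            p.loc[a, b] = p.loc[b, a] = pi
            rows.append((a, b, ri, pi, len(sub)))
    long = pd.DataFrame(rows, columns=["x", "y", "r", "p", "n"])
    ok = long["p"].notna()
    long["q"] = np.nan
    if ok.any():
        long.loc[ok, "q"] = false_discovery_control(long.loc[ok, "p"],
                                                    method="bh")
    return CorrelationMatrix(r=r, p=p, n=n, long=long)


def fpg_element_corr(fractions: pd.DataFrame, fpg: pd.Series,
                     columns=("exon_fraction", "intron_fraction")
                     ) -> pd.DataFrame:
    """Pearson R and p of each element-start fraction against FPG.

    ``fractions`` is indexed by sample_id with one column per element;
    ``fpg`` is per-sample FPG.  Pre and post samples are pooled into one
    correlation per element.
    """
    common = fractions.index.intersection(fpg.index)
    rows = []
    for col in columns:
        try:
            r, p = pearson(fractions.loc[common, col], fpg.loc[common])
        except ValueError:
            r = p = np.nan
        rows.append((col, r, p, len(common)))
    return pd.DataFrame(rows, columns=["element", "r", "p", "n"])


def trajectory_summary(followup: pd.DataFrame) -> pd.DataFrame:
    """Per-patient EPM trajectory flags plus per-group counts.

    ``followup`` needs columns patient_id, label, epm_pre, epm_post,
    epm_M12 (epm_M6 optional).  Patients missing a required timepoint are
    excluded (logged in the returned frame's attrs).
    """
    need = ["epm_pre", "epm_post", "epm_M12"]
    ok = followup.dropna(subset=need)
    excluded = sorted(set(followup["patient_id"]) - set(ok["patient_id"]))
    out = ok[["patient_id", "label"]].copy()
    out["post_gt_pre"] = (ok["epm_post"] > ok["epm_pre"]).to_numpy()
    out["m12_lt_pre"] = (ok["epm_M12"] < ok["epm_pre"]).to_numpy()
    out.attrs["excluded"] = excluded
    return out


def trajectory_group_counts(summary: pd.DataFrame) -> pd.DataFrame:
    g = summary.groupby("label").agg(
        n=("patient_id", "size"),
        n_post_gt_pre=("post_gt_pre", "sum"),
        n_m12_lt_pre=("m12_lt_pre", "sum"),
    )
    return g.reset_index()
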