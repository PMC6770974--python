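"""Expression-pattern classification from FPKM matrices.

Covers the gene-family expression questions: which members are highly
expressed across tissues, which are restricted to one organ (quantified by
the tissue-specificity index tau), which are transcriptionally silent,
how collinear duplicate pairs diverge in expression, and how members
respond to pathogen infection over a time course (log2 fold change with a
0.001-FPKM pseudocount).  Relative qPCR quantification (2^-ddCt) is
included for wet-lab cross-checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PSEUDOCOUNT = 0.001
TAU_SPECIFIC = 0.85
TAU_MIN_FPKM = 10.0


def read_fpkm(path: str) -> pd.DataFrame:
    """Read a genes-by-samples FPKM table (first column = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative FPKM values")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample labels")
    return df.astype(float)


def classify_high(
    matrix: pd.DataFrame,
    fold: float = 3.0,
    grand_mean: float | None = None,
) -> pd.Series:
    """Label genes whose across-sample mean exceeds ``fold`` x grand mean.

    The grand mean is the mean over every gene x sample entry (or an
    externally supplied baseline).  An all-zero matrix yields all
    ``not_high`` with a warning rather than an error.
    """
    if matrix.size == 0:
        raise ValueError("empty expression matrix")
    if grand_mean is None:
        grand_mean = float(matrix.to_numpy().mean())
    gene_means = matrix.mean(axis=1)
    if grand_mean == 0.0:
        log.warning("grand mean FPKM is zero; no gene can be high-expressed")
        labels = np.full(len(gene_means), "not_high")
    else:
        labels = np.where(gene_means >= fold * grand_mean,
                          "high", "not_high")
    return pd.Series(labels, index=matrix.index, name="expression_level")


def tissue_specificity(row: pd.Series) -> tuple[float, str | None, str]:
    """Tissue-specificity index tau with a specific/broad call.

    tau = sum(1 - x_i / x_max) / (n - 1) lies in [0, 1]; 1 means a single
    expressed tissue.  A gene is called ``specific`` iff tau >= 0.85 and
    its peak is at least 10 FPKM; an all-zero row is ``inactive`` with
    undefined tau.
    """
    x = row.to_numpy(dtype=float)
    if len(x) < 2:
        raise ValueError("tau needs at least two samples")
    if (x < 0).any():
        raise ValueError("negative FPKM")
    x_max = x.max()
    if x_max == 0:
        return math.nan, None, "inactive"
    tau = float((1.0 - x / x_max).sum() / (len(x) - 1))
    top = row.index[int(x.argmax())]
    label = "specific" if tau >= TAU_SPECIFIC and x_max >= TAU_MIN_FPKM \
        else "broad"
    return tau, top, label


def classify_inactive(row: pd.Series, floor_fpkm: float = 1.0) -> str:
    """``inactive`` iff every sample is below the FPKM floor."""
    return "inactive" if (row.to_numpy(dtype=float) < floor_fpkm).all() \
        else "active"


@dataclass
class ResponseProfile:
    gene: str
    log2_change: pd.Series  # per post-baseline timepoint
    category: str  # induced | suppressed | mixed | unchanged


def infection_response(
    timecourse: pd.Series,
    up_thresh: float = 1.0,
    down_thresh: float = -1.0,
    min_peak_fpkm: float = 0.5,
    baseline: str | None = None,
) -> ResponseProfile:
    """Classify a time course relative to its 0 h baseline.

    L_t = log2((FPKM_t + 0.001) / (FPKM_0 + 0.001)).  ``induced`` iff some
    L_t >= +1 and none <= -1; ``suppressed`` symmetric; both -> ``mixed``;
    neither -> ``unchanged``.  Genes never reaching ``min_peak_fpkm`` are
    ``unchanged`` regardless (guards against pseudocount-driven ratios on
    silent genes).
    """
    if baseline is None:
        baseline = timecourse.index[0]
    if baseline not in timecourse.index:
        raise ValueError(f"missing baseline sample {baseline!r}")
    base = float(timecourse[baseline])
    post = timecourse.drop(baseline)
    levels = np.log2((post.to_numpy(dtype=float) + PSEUDOCOUNT)
                     / (base + PSEUDOCOUNT))
    levels = pd.Series(levels, index=post.index, name=timecourse.name)
    # the 1e-3 tolerance absorbs the pseudocount's distortion of exact
    # round-number fold changes (10 -> 20 FPKM gives L = 0.99993)
    up = bool((levels >= up_thresh - 1e-3).any())
    down = bool((levels <= down_thresh + 1e-3).any())
    if float(timecourse.max()) < min_peak_fpkm:
        category = "unchanged"
    elif up and down:
        category = "mixed"
    elif up:
        category = "induced"
    elif down:
        category = "suppressed"
    else:
        category = "unchanged"
    return ResponseProfile(gene=str(timecourse.name), log2_change=levels,
                           category=category)


def classify_responses(
    matrix: pd.DataFrame,
    up_thresh: float = 1.0,
    down_thresh: float = -1.0,
    min_peak_fpkm: float = 0.5,
    baseline: str | None = None,
) -> pd.DataFrame:
    """Apply :func:`infection_response` to every row of a time-course table."""
    rows = {}
    for gene, row in matrix.iterrows():
        profile = infection_response(row, up_thresh, down_thresh,
                                     min_peak_fpkm, baseline)
        rows[gene] = {f"L_{tp}": lv
                      for tp, lv in profile.log2_change.items()}
        rows[gene]["category"] = profile.category
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method."""
    delta_delta = ((ct_target_treated - ct_ref_treated)
                   - (ct_target_control - ct_ref_control))
    return 2.0 ** (-delta_delta)


def pair_divergence(
    row_a: pd.Series,
    row_b: pd.Series,
    r_thresh: float = 0.5,
) -> str:
    """``similar`` iff Pearson r of log2(FPKM+1) profiles >= threshold.

    A constant profile has no defined correlation: two constant, equal
    profiles are ``similar``; any other constant case is ``distinct``.
    """
    if len(row_a) != len(row_b):
        raise ValueError("profiles cover different sample sets")
    if len(row_a) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    a = np.log2(row_a.to_numpy(dtype=float) + 1.0)
    b = np.log2(row_b.to_numpy(dtype=float) + 1.0)
    const_a, const_b = np.ptp(a) == 0, np.ptp(b) == 0
    if const_a or const_b:
        return "similar" if const_a and const_b and np.allclose(a, b) \
            else "distinct"
    r = float(np.corrcoef(a, b)[0, 1])
    return "similar" if r >= r_thresh else "distinct"


def classify_tissue_table(matrix: pd.DataFrame,
                          fold: float = 3.0,
                          floor_fpkm: float = 1.0) -> pd.DataFrame:
    """Per-gene labels: high expression, tau, top tissue, activity."""
    high = classify_high(matrix, fold=fold)
    rows = {}
    for gene, row in matrix.iterrows():
        tau, top, spec = tissue_specificity(row)
        rows[gene] = {
            "mean_fpkm": float(row.mean()),
            "expression_level": high[gene],
            "tau": tau,
            "top_tissue": top if top is not None else "",
            "specificity": spec,
            "activity": classify_inactive(row, floor_fpkm),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out
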