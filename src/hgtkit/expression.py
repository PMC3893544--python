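"""Expression analysis: FPKM profiles, qPCR reference-gene stability and
delta-delta-Ct fold changes.

Reference-gene stability follows the composite-ranking convention: geNorm
M-values, the DeltaCT pairwise-SD measure, and BestKeeper's raw-Ct SD are
each ranked and combined by geometric mean.  Fold changes use the
comparative CT method (2^-ddCt) normalised to the chosen reference gene and
a calibrator condition, with plain two-sample Student's t-tests on the
replicate dCt values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import CountTable, CtTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def fpkm(table: CountTable) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    One fragment is one read pair; counts are assumed to be fragment counts
    already.  FPKM = count / (length_kb * total_fragments_in_stage / 1e6).
    """
    totals = table.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero total fragments in stage(s): {bad}")
    len_kb = table.lengths.loc[table.counts.index] / 1000.0
    return table.counts.div(totals / 1e6, axis=1).div(len_kb, axis=0)


# ---------------------------------------------------------------------------
# Reference-gene stability
# ---------------------------------------------------------------------------

def _mean_ct(ct: CtTable) -> pd.DataFrame:
    """gene x sample mean Ct (replicate technical averaging)."""
    return ct.data.pivot_table(index="gene", columns="sample", values="ct",
                               aggfunc="mean")


def genorm_m(ct: CtTable, genes: list[str] | None = None) -> pd.Series:
    """geNorm M-value per gene: mean SD of pairwise log2 quantity ratios.

    Relative quantities are 2^(minCt - Ct) per gene, so the log2 ratio of
    gene g to gene h across samples is (Ct_h - Ct_g) up to a constant and M
    is invariant to global per-sample shifts.  Lower M = more stable.
    """
    wide = _mean_ct(ct)
    genes = genes or list(wide.index)
    if len(genes) < 3:
        raise ValueError("geNorm needs >= 3 candidate genes")
    if wide.shape[1] < 2:
        raise ValueError("geNorm needs >= 2 samples")
    q = wide.rsub(wide.min(axis=1), axis=0)  # log2 quantity = minCt - Ct
    out = {}
    for g in genes:
        sds = [float((q.loc[g] - q.loc[h]).std(ddof=1)) for h in genes if h != g]
        out[g] = float(np.mean(sds))
    return pd.Series(out, name="genorm_m")


def delta_ct_stability(ct: CtTable, genes: list[str] | None = None) -> pd.Series:
    """DeltaCT-method stability: mean SD of pairwise dCt across samples."""
    wide = _mean_ct(ct)
    genes = genes or list(wide.index)
    out = {}
    for g in genes:
        sds = [float((wide.loc[g] - wide.loc[h]).std(ddof=1)) for h in genes if h != g]
        out[g] = float(np.mean(sds))
    return pd.Series(out, name="delta_ct_sd")


def bestkeeper_sd(ct: CtTable, genes: list[str] | None = None) -> pd.Series:
    """BestKeeper stability: SD of raw Ct values across samples."""
    wide = _mean_ct(ct)
    genes = genes or list(wide.index)
    return pd.Series({g: float(wide.loc[g].std(ddof=1)) for g in genes},
                     name="bestkeeper_sd")


@dataclass
class StabilityReport:
    table: pd.DataFrame           # per-gene measures, ranks, composite

    @property
    def best_gene(self) -> str:
        return self.table["composite_rank"].idxmin()


def stability_rank(ct: CtTable, genes: list[str] | None = None) -> StabilityReport:
    """Composite reference-gene ranking (geometric mean of method ranks).

    Ties share averaged ranks.  With fewer than 3 genes geNorm is skipped
    (warning) and the composite uses the remaining measures.
    """
    wide = _mean_ct(ct)
    genes = genes or list(wide.index)
    measures = {}
    if len(genes) >= 3:
        measures["genorm_m"] = genorm_m(ct, genes)
        measures["delta_ct_sd"] = delta_ct_stability(ct, genes)
    else:
        logger.warning("fewer than 3 genes: geNorm/DeltaCT skipped")
    measures["bestkeeper_sd"] = bestkeeper_sd(ct, genes)
    df = pd.DataFrame(measures)
    ranks = df.rank(axis=0, method="average")
    ranks.columns = [c + "_rank" for c in ranks.columns]
    df = pd.concat([df, ranks], axis=1)
    df["composite_rank"] = scipy.stats.gmean(ranks.to_numpy(), axis=1)
    return StabilityReport(df.sort_values("composite_rank"))


# ---------------------------------------------------------------------------
# Comparative CT (delta-delta-Ct)
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeResult:
    condition: str
    fold: float
    se: float
    ddct: float
    t_statistic: float
    p_value: float
    n: int


def ddct(ct: CtTable, target: str, reference: str,
         calibrator_condition: str) -> list[FoldChangeResult]:
    """Fold changes by the comparative CT method.

    Per replicate, dCt = Ct_target - Ct_reference (paired by sample);
    ddCt = mean dCt(condition) - mean dCt(calibrator); fold = 2^-ddCt.
    The SE of the fold is delta-method propagated from the replicate
    variances; the test is a plain two-sample Student's t on the dCt
    replicates versus the calibrator.
    """
    data = ct.data
    for gene in (target, reference):
        if gene not in set(data["gene"]):
            raise ValueError(f"gene {gene!r} not in the Ct table")
    t = data[data["gene"] == target].set_index("sample")
    r = data[data["gene"] == reference].set_index("sample")
    common = t.index.intersection(r.index)
    dct = (t.loc[common, "ct"] - r.loc[common, "ct"]).to_frame("dct")
    dct["condition"] = t.loc[common, "condition"]
    conds = list(dict.fromkeys(data["condition"]))
    if calibrator_condition not in conds:
        raise ValueError(f"calibrator condition {calibrator_condition!r} missing")
    cal = dct.loc[dct["condition"] == calibrator_condition, "dct"].to_numpy()
    if len(cal) < 2:
        raise ValueError("need >= 2 calibrator replicates")
    out = []
    for cond in conds:
        vals = dct.loc[dct["condition"] == cond, "dct"].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"need >= 2 replicates in condition {cond!r}")
        dd = float(vals.mean() - cal.mean())
        fold = 2.0 ** (-dd)
        var_dd = vals.var(ddof=1) / len(vals) + cal.var(ddof=1) / len(cal)
        se = math.log(2) * fold * math.sqrt(var_dd)
        tt = scipy.stats.ttest_ind(vals, cal, equal_var=True)
        out.append(FoldChangeResult(cond, fold, se, dd,
                                    float(tt.statistic), float(tt.pvalue), len(vals)))
    return out
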