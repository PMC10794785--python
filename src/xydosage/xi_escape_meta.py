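"""Five-dataset meta-analysis of X-inactivation escape.

X-linked genes are classified as "escape" (expressed from the inactive X),
"subject" (silenced on Xi, hence strictly Xa-expressed), or "no_call" by
synthesizing allelic-ratio evidence from five published study dialects:

- ``cotton``:     per-gene mean AR with sd and sample count (SNP-chip,
                  skewed cultures); one-sample one-sided t vs 0, BH < 0.05,
                  genes informative in at least 5 samples.
- ``tukiainen``:  per-individual single-cell significance calls plus a
                  fully-skewed bulk call; included with >= 2 single-cell
                  individuals, or 1 plus the bulk; escape if any shows Xi
                  expression.
- ``garieri``:    per-sample ARs from single fibroblasts; included with
                  >= 2 of 5 samples; escape if any AR > 0.0526 (the
                  threshold implied by an Xa read fraction of 0.95).
- ``sauteraud``:  per-sample raw ARs with skewing coefficients; paired
                  one-sided t of raw AR vs the skewing baseline
                  (1 - skew)/skew over >= 10 samples, BH < 0.01.
- ``sanroman``:   per-sample ARs; one-sample one-sided t vs 0, BH < 0.05.

The allelic ratio (AR) is the lower- over the higher-expressed allele, so
it estimates Xi/Xa expression under skewed X inactivation; 0 is monoallelic
and 1 balanced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DATASETS",
    "ar_from_xa_fraction",
    "baseline_ar",
    "call_cotton",
    "call_tukiainen",
    "call_garieri",
    "call_sauteraud",
    "call_sanroman",
    "synthesize_calls",
    "evidence_to_calls",
    "GARIERI_AR_THRESHOLD",
]

DATASETS = ("cotton", "tukiainen", "garieri", "sauteraud", "sanroman")

#: AR implied by the published Xa read-fraction cutoff of 0.95.
GARIERI_AR_THRESHOLD = 0.0526


def ar_from_xa_fraction(f):
    """Convert an Xa read fraction (Xa reads / total reads) to an AR.

    AR = 1/f - 1, the Xi/Xa ratio implied by the fraction; f = 0.95 gives
    the 0.0526 escape threshold of the single-cell fibroblast dataset.
    """
    f = np.asarray(f, dtype=float)
    if np.any((f <= 0) | (f > 1)):
        raise ValueError("Xa fraction must be in (0, 1]")
    out = 1.0 / f - 1.0
    return float(out) if out.ndim == 0 else out


def baseline_ar(skew):
    """Expected AR of a fully Xi-silenced gene at a given skewing level.

    With a fraction ``skew`` of cells inactivating the same X, a gene with
    no Xi expression still shows AR = (1 - skew)/skew in bulk.
    """
    skew = np.asarray(skew, dtype=float)
    if np.any((skew < 0.5) | (skew > 1)):
        raise ValueError("skewing coefficient must be in [0.5, 1]")
    out = (1.0 - skew) / skew
    return float(out) if out.ndim == 0 else out


def _call_frame(genes, dataset, call, mean_ar, n_informative, flag=None):
    df = pd.DataFrame(
        {
            "gene": genes,
            "dataset": dataset,
            "call": call,
            "mean_ar": mean_ar,
            "n_informative": n_informative,
        }
    )
    df["degenerate_t"] = False if flag is None else flag
    df.loc[df["call"] == "no_data", "mean_ar"] = np.nan
    return df


def _one_sided_t_calls(mean, sd, n, alpha):
    """One-sided one-sample t of mean > 0 with BH, handling sd = 0."""
    mean, sd, n = np.asarray(mean, float), np.asarray(sd, float), np.asarray(n)
    p = np.full(mean.shape, np.nan)
    flag = np.zeros(mean.shape, dtype=bool)
    degenerate = sd == 0
    flag |= degenerate
    p[degenerate & (mean > 0)] = 0.0  # constant positive evidence
    p[degenerate & (mean <= 0)] = 1.0
    ok = ~degenerate
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean[ok] * np.sqrt(n[ok]) / sd[ok]
    p[ok] = stats.t.sf(t, df=n[ok] - 1)
    padj = multipletests(p, method="fdr_bh")[1]
    call = np.where(padj < alpha, "escape", "subject")
    return call, flag


def call_cotton(table: pd.DataFrame, alpha: float = 0.05, min_n: int = 5) -> pd.DataFrame:
    """Summary-statistic dialect: columns gene, mean_ar, sd_ar, n_informative."""
    t = table.copy()
    if (t["sd_ar"] < 0).any():
        raise ValueError("sd_ar must be non-negative")
    inc = t["n_informative"] >= min_n
    call = np.full(len(t), "no_data", dtype=object)
    flag = np.zeros(len(t), dtype=bool)
    if inc.any():
        c, f = _one_sided_t_calls(
            t.loc[inc, "mean_ar"], t.loc[inc, "sd_ar"], t.loc[inc, "n_informative"], alpha
        )
        call[inc.to_numpy()] = c
        flag[inc.to_numpy()] = f
    return _call_frame(t["gene"], "cotton", call, t["mean_ar"], t["n_informative"], flag)


def call_tukiainen(table: pd.DataFrame) -> pd.DataFrame:
    """Per-individual dialect: n_sc_individuals, n_sc_significant, has_bulk,
    bulk_significant, mean_ar. Included with two single-cell individuals or
    one plus bulk; escape if any included sub-dataset shows Xi expression."""
    t = table.copy()
    inc = (t["n_sc_individuals"] >= 2) | ((t["n_sc_individuals"] >= 1) & t["has_bulk"])
    evid = (t["n_sc_significant"] > 0) | (t["has_bulk"] & t["bulk_significant"])
    call = np.where(~inc, "no_data", np.where(evid, "escape", "subject"))
    n_inf = t["n_sc_individuals"] + t["has_bulk"].astype(int)
    return _call_frame(t["gene"], "tukiainen", call, t.get("mean_ar", np.nan), n_inf)


def call_garieri(
    table: pd.DataFrame, min_samples: int = 2, threshold: float = GARIERI_AR_THRESHOLD
) -> pd.DataFrame:
    """Per-sample AR dialect (long: gene, sample, ar), fixed-threshold calls."""
    if (table["ar"] < 0).any():
        raise ValueError("AR values must be non-negative")
    grp = table.groupby("gene")["ar"]
    agg = grp.agg(n="count", mean_ar="mean", any_escape=lambda a: bool((a > threshold).any()))
    call = np.where(
        agg["n"] < min_samples, "no_data", np.where(agg["any_escape"], "escape", "subject")
    )
    return _call_frame(agg.index, "garieri", call, agg["mean_ar"].to_numpy(), agg["n"].to_numpy())


def call_sauteraud(table: pd.DataFrame, alpha: float = 0.01, min_n: int = 10) -> pd.DataFrame:
    """Skew-adjusted dialect (long: gene, sample, raw_ar, skew).

    Paired one-sided t of raw AR exceeding the per-sample skewing baseline;
    the per-dataset mean AR reported for synthesis is the mean skew-adjusted
    excess max(raw - baseline, 0).
    """
    t = table.copy()
    t["baseline"] = baseline_ar(t["skew"].to_numpy())
    t["diff"] = t["raw_ar"] - t["baseline"]
    agg = t.groupby("gene").agg(
        n=("diff", "count"),
        mean_diff=("diff", "mean"),
        sd_diff=("diff", lambda d: d.std(ddof=1)),
        mean_ar=("diff", lambda d: float(np.mean(np.maximum(d, 0.0)))),
    )
    inc = (agg["n"] >= min_n).to_numpy()
    call = np.full(len(agg), "no_data", dtype=object)
    flag = np.zeros(len(agg), dtype=bool)
    if inc.any():
        c, f = _one_sided_t_calls(
            agg.loc[inc, "mean_diff"], agg.loc[inc, "sd_diff"].fillna(0.0), agg.loc[inc, "n"], alpha
        )
        call[inc] = c
        flag[inc] = f
    return _call_frame(agg.index, "sauteraud", call, agg["mean_ar"].to_numpy(), agg["n"].to_numpy(), flag)


def call_sanroman(table: pd.DataFrame, alpha: float = 0.05, min_n: int = 2) -> pd.DataFrame:
    """Per-sample AR dialect (long: gene, sample, ar), one-sample t vs 0."""
    if (table["ar"] < 0).any():
        raise ValueError("AR values must be non-negative")
    agg = table.groupby("gene")["ar"].agg(
        n="count", mean_ar="mean", sd_ar=lambda a: a.std(ddof=1)
    )
    inc = (agg["n"] >= min_n).to_numpy()
    call = np.full(len(agg), "no_data", dtype=object)
    flag = np.zeros(len(agg), dtype=bool)
    if inc.any():
        c, f = _one_sided_t_calls(
            agg.loc[inc, "mean_ar"], agg.loc[inc, "sd_ar"].fillna(0.0), agg.loc[inc, "n"], alpha
        )
        call[inc] = c
        flag[inc] = f
    return _call_frame(agg.index, "sanroman", call, agg["mean_ar"].to_numpy(), agg["n"].to_numpy(), flag)


def synthesize_calls(
    dataset_calls: pd.DataFrame,
    hybrid_fraction: pd.Series | None = None,
    ar_threshold: float = 0.1,
    hybrid_threshold: float = 0.22,
) -> pd.DataFrame:
    """Synthesize per-dataset calls into a final escape/subject/no_call verdict.

    Over the informative studies (call != no_data) for each gene:

    - escape if more than half say escape; or if at least one (but at most
      half) says escape and either two or more say escape or the average AR
      across informative studies is >= ``ar_threshold``;
    - subject if all say subject, or more than half say subject and the
      average AR is below ``ar_threshold``;
    - genes with zero informative studies fall back to the Xi-hybrid-line
      expression fraction: escape at >= ``hybrid_threshold``, subject below
      it, no_call if missing;
    - anything else is no_call.

    The average AR is the unweighted mean of per-dataset mean ARs. Input is
    the concatenation of the per-dataset call frames; output has one row
    per gene with per-dataset calls, counts, average AR, and the final call.
    """
    wide_call = dataset_calls.pivot_table(
        index="gene", columns="dataset", values="call", aggfunc="first"
    )
    wide_ar = dataset_calls.pivot_table(
        index="gene", columns="dataset", values="mean_ar", aggfunc="first"
    )
    genes = wide_call.index
    for ds in DATASETS:
        if ds not in wide_call.columns:
            wide_call[ds] = "no_data"
            wide_ar[ds] = np.nan
    wide_call = wide_call[list(DATASETS)].fillna("no_data")
    wide_ar = wide_ar.reindex(columns=list(DATASETS))

    n_esc = (wide_call == "escape").sum(axis=1)
    n_sub = (wide_call == "subject").sum(axis=1)
    n_inf = n_esc + n_sub
    informative_ar = wide_ar.where(wide_call != "no_data")
    avg_ar = informative_ar.mean(axis=1)

    if hybrid_fraction is None:
        hybrid = pd.Series(np.nan, index=genes)
    else:
        hybrid = pd.Series(hybrid_fraction).reindex(genes)

    final = np.full(len(genes), "no_call", dtype=object)
    has_data = (n_inf > 0).to_numpy()
    esc = (n_esc > n_inf / 2) | ((n_esc > 0) & ((n_esc >= 2) | (avg_ar >= ar_threshold)))
    sub = ((n_sub == n_inf) | ((n_sub > n_inf / 2) & (avg_ar < ar_threshold))) & ~esc
    final[has_data & esc.to_numpy()] = "escape"
    final[has_data & sub.to_numpy()] = "subject"
    no_data = ~has_data
    final[no_data & (hybrid >= hybrid_threshold).to_numpy()] = "escape"
    final[no_data & (hybrid < hybrid_threshold).to_numpy()] = "subject"

    out = wide_call.add_prefix("call_")
    out["n_escape"] = n_esc
    out["n_subject"] = n_sub
    out["avg_ar"] = avg_ar
    out["hybrid_fraction"] = hybrid
    out["final"] = final
    return out.reset_index()


def evidence_to_calls(datasets: dict[str, pd.DataFrame], hybrid_fraction=None) -> pd.DataFrame:
    """Run every dataset-specific caller and synthesize the final calls."""
    callers = {
        "cotton": call_cotton,
        "tukiainen": call_tukiainen,
        "garieri": call_garieri,
        "sauteraud": call_sauteraud,
        "sanroman": call_sanroman,
    }
    frames = [callers[name](tab) for name, tab in datasets.items()]
    return synthesize_calls(pd.concat(frames, ignore_index=True), hybrid_fraction)
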