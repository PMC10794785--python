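"""Peak-to-promoter assignment and regulatory target-set construction.

Maps ChIP-seq-style peak intervals (BED semantics: 0-based, half-open) to
genes via strand-aware promoter windows around the TSS — 1 kb half-width
for transcription-factor promoter binding, 30 kb for hormone-receptor
target definitions — and combines binding with differential-expression
results into "direct target" gene sets (bound AND significantly
responsive). Also computes, per gene, the proportion of cell lines bound
among those expressing it, and delegates enrichment of target sets in
responsive gene sets to the shared-response overlap test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .shared_response import OverlapResult, overlap_test

__all__ = [
    "promoter_windows",
    "assign_peaks_to_tss",
    "direct_targets",
    "binding_proportion",
    "target_enrichment",
    "peak_set_difference",
]


def _tss(annotation: pd.DataFrame) -> np.ndarray:
    return np.where(annotation["strand"] == "+", annotation["start"], annotation["end"])


def promoter_windows(annotation: pd.DataFrame, half_width: int) -> pd.DataFrame:
    """[TSS - half_width, TSS + half_width) windows, clipped at 0."""
    t = _tss(annotation)
    return pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": np.maximum(0, t - half_width),
            "end": t + half_width,
        },
        index=annotation.index,
    )


def assign_peaks_to_tss(
    peaks: pd.DataFrame, annotation: pd.DataFrame, half_width: int
) -> pd.Series:
    """Per-gene bound flag: does any peak intersect the promoter window?

    A gene is bound iff some peak interval shares at least one base with
    [TSS - half_width, TSS + half_width); the TSS is the annotated start for
    + strand genes and the annotated end for - strand genes. Chromosomes
    present in the peaks but absent from the annotation produce a warning
    with a count, not an error.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if (peaks["start"] >= peaks["end"]).any():
        raise ValueError("peaks must satisfy start < end")
    bound = pd.Series(False, index=annotation.index, name="bound")
    ann_chroms = set(annotation["chrom"])
    stray = sorted(set(peaks["chrom"]) - ann_chroms)
    if stray:
        n = int(peaks["chrom"].isin(stray).sum())
        warnings.warn(
            f"{n} peak(s) on {len(stray)} chromosome(s) absent from the annotation "
            f"(e.g. {stray[:3]}); they cannot bind any gene",
            stacklevel=2,
        )
    windows = promoter_windows(annotation, half_width)
    for chrom, pk in peaks.groupby("chrom"):
        if chrom not in ann_chroms:
            continue
        genes = windows[windows["chrom"] == chrom]
        if genes.empty:
            continue
        order = np.argsort(pk["start"].to_numpy(), kind="stable")
        starts = pk["start"].to_numpy()[order]
        ends = pk["end"].to_numpy()[order]
        # running maximum of peak ends in start order: a window (ws, we)
        # intersects some peak iff among peaks with start < we the maximal
        # end exceeds ws
        prefix_max_end = np.maximum.accumulate(ends)
        idx = np.searchsorted(starts, genes["end"].to_numpy(), side="left")
        hit = np.zeros(len(genes), dtype=bool)
        nz = idx > 0
        hit[nz] = prefix_max_end[idx[nz] - 1] > genes["start"].to_numpy()[nz]
        bound.loc[genes.index] = hit
    return bound


def direct_targets(bound_flags: pd.Series, de_results: pd.DataFrame, alpha: float = 0.05) -> set:
    """Genes both bound at the promoter and significantly responsive.

    ``de_results`` must carry gene and adjusted-p (``padj``) columns (or be
    indexed by gene). Bound genes without a DE record are counted and
    warned about, and treated as non-targets.
    """
    if "gene" in de_results.columns:
        padj = de_results.set_index("gene")["padj"]
    else:
        padj = de_results["padj"]
    bound_genes = bound_flags.index[bound_flags.astype(bool)]
    missing = bound_genes.difference(padj.index)
    if len(missing):
        warnings.warn(
            f"{len(missing)} bound gene(s) have no differential-expression record; "
            "treated as non-targets",
            stacklevel=2,
        )
    present = bound_genes.intersection(padj.index)
    sig = padj.loc[present] < alpha
    return set(present[sig.to_numpy()])


def binding_proportion(
    bound_by_cell_line: pd.DataFrame, expressed_by_cell_line: pd.DataFrame
) -> pd.Series:
    """Fraction of expressing cell lines in which each gene's promoter is bound.

    Inputs are genes x cell-line boolean tables over the same cell lines;
    genes expressed in zero lines get a missing value (excluded downstream).
    """
    if list(bound_by_cell_line.columns) != list(expressed_by_cell_line.columns):
        raise ValueError("bound and expressed tables must cover the same cell lines")
    expressed = expressed_by_cell_line.astype(bool)
    bound = bound_by_cell_line.astype(bool) & expressed
    n_expr = expressed.sum(axis=1)
    prop = bound.sum(axis=1) / n_expr.where(n_expr > 0)
    return prop.rename("binding_proportion")


def target_enrichment(
    target_set, responsive_up, responsive_down, universe, n_tests: int = 1
) -> dict[str, OverlapResult]:
    """Hypergeometric enrichment of a target set in up-/down-responsive genes."""
    return {
        "up": overlap_test(target_set, responsive_up, universe, n_tests=n_tests),
        "down": overlap_test(target_set, responsive_down, universe, n_tests=n_tests),
    }


def peak_set_difference(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame) -> pd.DataFrame:
    """Peaks of A absent from B by exact (chrom, start, end) identity.

    Supports pre-computing treatment-specific peaks when the two conditions
    were called on identical coordinates.
    """
    key_b = set(map(tuple, peaks_b[["chrom", "start", "end"]].itertuples(index=False)))
    keep = [
        tuple(row) not in key_b
        for row in peaks_a[["chrom", "start", "end"]].itertuples(index=False)
    ]
    return peaks_a.loc[keep].reset_index(drop=True)
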