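"""Synthetic-data generators with known ground truth.

Every input the inference pipeline consumes can be generated here: a
karyotype sample design (1-4 copies of Chr X, 0-4 copies of Chr Y, 2-3
copies of Chr 21), per-gene dosage effects and negative-binomial counts,
allelic-ratio evidence tables in the five published dialects, windowed
depth-of-coverage profiles for repeat-array length estimation, and
promoter-proximal peak sets. Generators are deterministic given a seed,
and their defaults emulate the study conditions (karyotype series sizes,
per-copy log2 effects mostly below 1.5-fold, shared X/Y effects with
Y responses ~0.7x the X responses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "KaryotypeEntry",
    "KaryotypeDesign",
    "GroundTruth",
    "LCL_DESIGN",
    "FIBROBLAST_DESIGN",
    "generate_design",
    "generate_truth",
    "generate_annotation",
    "generate_counts",
    "generate_allelic_datasets",
    "generate_depth_profile",
    "generate_peaks",
]


@dataclass(frozen=True)
class KaryotypeEntry:
    label: str
    x_copies: int
    y_copies: int
    chr21_copies: int = 2
    n: int = 0

    def __post_init__(self):
        if self.x_copies < 1:
            raise ValueError(
                f"karyotype entry {self.label!r} has {self.x_copies} X copies; "
                "every somatic cell carries at least one active X"
            )
        if self.n < 0:
            raise ValueError(f"karyotype entry {self.label!r} has negative n")
        if not (0 <= self.y_copies <= 4 and 1 <= self.x_copies <= 4):
            raise ValueError(f"karyotype entry {self.label!r} outside supported copy range")
        if self.chr21_copies not in (2, 3):
            raise ValueError(f"karyotype entry {self.label!r} must have 2 or 3 Chr 21 copies")


@dataclass(frozen=True)
class KaryotypeDesign:
    entries: tuple[KaryotypeEntry, ...]
    batches: tuple[str, ...] = ("b1", "b2", "b3")
    cell_type: str = "LCL"

    @property
    def n_samples(self) -> int:
        return sum(e.n for e in self.entries)


def _design(cell_type, spec):
    return KaryotypeDesign(
        entries=tuple(KaryotypeEntry(lab, x, y, n=n) for lab, x, y, n in spec),
        cell_type=cell_type,
    )


# Sample counts per karyotype in the lymphoblastoid (106 samples) and
# fibroblast (99 samples) series.
LCL_DESIGN = _design(
    "LCL",
    [
        ("45,X", 1, 0, 17),
        ("46,XX", 2, 0, 22),
        ("46,XY", 1, 1, 17),
        ("47,XXX", 3, 0, 7),
        ("47,XXY", 2, 1, 11),
        ("47,XYY", 1, 2, 10),
        ("48,XXXX", 4, 0, 1),
        ("48,XXXY", 3, 1, 4),
        ("48,XXYY", 2, 2, 3),
        ("49,XXXXY", 4, 1, 12),
        ("49,XYYYY", 1, 4, 2),
    ],
)

FIBROBLAST_DESIGN = _design(
    "fibroblast",
    [
        ("45,X", 1, 0, 23),
        ("46,XX", 2, 0, 20),
        ("46,XY", 1, 1, 14),
        ("47,XXX", 3, 0, 4),
        ("47,XXY", 2, 1, 30),
        ("47,XYY", 1, 2, 5),
        ("48,XXXY", 3, 1, 1),
        ("49,XXXXY", 4, 1, 1),
        ("49,XYYYY", 1, 4, 1),
    ],
)


def generate_design(design: KaryotypeDesign, seed: int) -> pd.DataFrame:
    """Expand a karyotype design into a per-sample metadata table.

    One row per sample with karyotype label, X/Y/Chr21 copy numbers, the
    derived Xi count (X copies minus the single active X), cell type, and a
    batch label assigned round-robin and then shuffled by ``seed``.
    """
    rows = []
    for e in design.entries:
        for _ in range(e.n):
            rows.append((e.label, e.x_copies, e.y_copies, e.chr21_copies))
    meta = pd.DataFrame(rows, columns=["karyotype", "x_copies", "y_copies", "chr21_copies"])
    meta["xi_copies"] = meta["x_copies"] - 1
    meta["cell_type"] = design.cell_type
    batches = [design.batches[i % len(design.batches)] for i in range(len(meta))]
    rng = np.random.default_rng(seed)
    meta["batch"] = rng.permutation(batches) if len(meta) else pd.Series([], dtype=object)
    meta.index = [f"s{i:04d}" for i in range(len(meta))]
    meta.index.name = "sample"
    return meta


@dataclass
class GroundTruth:
    """Per-gene generating parameters and the truth labels derived from them.

    ``genes`` has one row per gene: baseline mean (normalized counts),
    ``beta_x``/``beta_y``/``beta_21`` log2 fold changes per chromosome copy,
    NB dispersion alpha, responsiveness flags, escape status and Xi
    expression fraction. ``batch_offsets`` is a gene x batch table of log2
    offsets added on top of the dosage model.
    """

    genes: pd.DataFrame
    batch_offsets: pd.DataFrame = field(default=None)

    @property
    def gene_ids(self):
        return self.genes.index


def generate_truth(
    n_genes: int,
    frac_x_responsive: float = 0.18,
    frac_y_responsive: float = 0.06,
    frac_shared: float = 0.04,
    effect_sd: float = 0.2,
    *,
    frac_21_responsive: float = 0.0,
    frac_escape: float = 0.2,
    dispersion: float = 0.05,
    baseline_log_mean: float = np.log(100.0),
    baseline_log_sd: float = 1.0,
    batch_sd: float = 0.1,
    batches: tuple[str, ...] = ("b1", "b2", "b3"),
    seed: int = 0,
) -> GroundTruth:
    """Draw per-gene ground-truth effects.

    Responsive genes draw their per-copy log2 effect from Normal(0,
    ``effect_sd``); the default 0.2 keeps most responses below 1.5-fold, as
    observed for sex-chromosome dosage. Shared genes satisfy
    ``beta_y = 0.7 * beta_x + Normal(0, 0.05)`` so X effects exceed Y effects
    on average with matched sign structure. Fractions are of ``n_genes``
    and realized exactly (rounded counts).
    """
    for name, f in [
        ("frac_x_responsive", frac_x_responsive),
        ("frac_y_responsive", frac_y_responsive),
        ("frac_shared", frac_shared),
        ("frac_21_responsive", frac_21_responsive),
        ("frac_escape", frac_escape),
    ]:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {f}")
    if effect_sd <= 0:
        raise ValueError("effect_sd must be positive")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if frac_shared > min(frac_x_responsive, frac_y_responsive):
        raise ValueError(
            "frac_shared cannot exceed min(frac_x_responsive, frac_y_responsive)"
        )

    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")

    n_shared = round(frac_shared * n_genes)
    n_x = round(frac_x_responsive * n_genes)
    n_y = round(frac_y_responsive * n_genes)
    n_21 = round(frac_21_responsive * n_genes)

    order = rng.permutation(n_genes)
    shared_idx = order[:n_shared]
    x_only_idx = order[n_shared:n_x]
    y_only_idx = order[n_x : n_x + (n_y - n_shared)]

    beta_x = np.zeros(n_genes)
    beta_y = np.zeros(n_genes)
    beta_21 = np.zeros(n_genes)

    beta_x[shared_idx] = rng.normal(0.0, effect_sd, n_shared)
    beta_y[shared_idx] = 0.7 * beta_x[shared_idx] + rng.normal(0.0, 0.05, n_shared)
    # keep sign concordance exact for shared genes (the generating model)
    flip = np.sign(beta_y[shared_idx]) != np.sign(beta_x[shared_idx])
    beta_y[shared_idx] = np.where(flip, 0.7 * beta_x[shared_idx], beta_y[shared_idx])
    beta_x[x_only_idx] = rng.normal(0.0, effect_sd, len(x_only_idx))
    beta_y[y_only_idx] = rng.normal(0.0, effect_sd, len(y_only_idx))
    idx_21 = rng.choice(n_genes, size=n_21, replace=False)
    beta_21[idx_21] = rng.normal(0.0, effect_sd, n_21)

    escape = np.zeros(n_genes, dtype=bool)
    n_escape = round(frac_escape * n_genes)
    escape[rng.choice(n_genes, size=n_escape, replace=False)] = True
    xi_fraction = np.where(escape, rng.uniform(0.15, 0.45, n_genes), 0.0)

    genes = pd.DataFrame(
        {
            "baseline": rng.lognormal(baseline_log_mean, baseline_log_sd, n_genes),
            "beta_x": beta_x,
            "beta_y": beta_y,
            "beta_21": beta_21,
            "dispersion": np.full(n_genes, float(dispersion)),
            "x_responsive": beta_x != 0.0,
            "y_responsive": beta_y != 0.0,
            "shared": np.isin(np.arange(n_genes), shared_idx),
            "escape_status": np.where(escape, "escape", "subject"),
            "xi_fraction": xi_fraction,
        },
        index=gene_ids,
    )
    offsets = pd.DataFrame(
        rng.normal(0.0, batch_sd, (n_genes, len(batches))),
        index=gene_ids,
        columns=list(batches),
    )
    return GroundTruth(genes=genes, batch_offsets=offsets)


_CHROMS = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


def generate_annotation(
    truth: GroundTruth,
    seed: int = 0,
    frac_x_linked: float = 0.04,
    frac_y_linked: float = 0.01,
) -> pd.DataFrame:
    """Invent a gene annotation (chromosome, span, strand, length, class).

    Coordinates are synthetic: genes are scattered on chr1-chr22 plus a small
    X- and Y-linked contingent, with strand-aware spans. ``length`` is the
    effective length used for TPM. Class labels distinguish autosomal, NPX,
    and NPY genes so the autosome-only renormalization control can subset.
    """
    rng = np.random.default_rng(seed)
    n = len(truth.genes)
    n_x = round(frac_x_linked * n)
    n_y = round(frac_y_linked * n)
    chrom = np.array(rng.choice(_CHROMS[:22], size=n))
    sex_idx = rng.choice(n, size=n_x + n_y, replace=False)
    chrom[sex_idx[:n_x]] = "chrX"
    chrom[sex_idx[n_x:]] = "chrY"
    start = rng.integers(10_000, 50_000_000, n)
    span = rng.integers(2_000, 200_000, n)
    ann = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start,
            "end": start + span,
            "strand": rng.choice(["+", "-"], size=n),
            "length": np.maximum(200, rng.lognormal(np.log(1500), 0.5, n)).astype(int),
        },
        index=truth.gene_ids,
    )
    cls = np.where(ann["chrom"] == "chrX", "NPX", np.where(ann["chrom"] == "chrY", "NPY", "autosomal"))
    ann["class"] = cls
    return ann


def tss(annotation: pd.DataFrame) -> pd.Series:
    """Strand-aware transcription start site: start for '+', end for '-'."""
    return pd.Series(
        np.where(annotation["strand"] == "+", annotation["start"], annotation["end"]),
        index=annotation.index,
        name="tss",
    )


def generate_counts(
    meta: pd.DataFrame,
    truth: GroundTruth,
    library_size_mean: float = 2e6,
    seed: int = 0,
    library_size_sigma: float = 0.3,
) -> pd.DataFrame:
    """Draw an integer gene x sample count matrix from the NB dosage model.

    mean_gj = s_j * baseline_g * 2**(beta_x*nX + beta_y*nY + beta_21*(n21-2)
    + batch offset); dispersion alpha_g = 0 degenerates to Poisson. Sample
    scale factors s_j are lognormal(sigma=0.3) around a constant chosen so
    the average library totals ``library_size_mean``.
    """
    if library_size_mean <= 0:
        raise ValueError("library_size_mean must be positive")
    missing = set(meta["batch"]) - set(truth.batch_offsets.columns)
    if missing:
        raise ValueError(f"meta batches {sorted(missing)} absent from truth batch offsets")
    rng = np.random.default_rng(seed)
    g = truth.genes
    n_genes, n_samples = len(g), len(meta)
    log2_mu = (
        np.outer(g["beta_x"], meta["x_copies"])
        + np.outer(g["beta_y"], meta["y_copies"])
        + np.outer(g["beta_21"], meta["chr21_copies"] - 2)
        + truth.batch_offsets.loc[:, meta["batch"]].to_numpy()
    )
    base = g["baseline"].to_numpy()[:, None] * np.exp2(log2_mu)
    scale = library_size_mean / base.sum(axis=0).mean()
    s = scale * rng.lognormal(0.0, library_size_sigma, n_samples)
    mu = base * s[None, :]

    alpha = g["dispersion"].to_numpy()
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        counts[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        a = alpha[~pois][:, None]
        lam = rng.gamma(1.0 / a, a * mu[~pois])
        counts[~pois] = rng.poisson(lam)
    return pd.DataFrame(counts, index=g.index, columns=meta.index)


# ---------------------------------------------------------------------------
# allelic-ratio evidence in the five published dialects


def _betabin(rng, n, f, rho):
    """Beta-binomial draws; rho=0 is binomial, f=0 is exactly zero."""
    f = np.asarray(f, dtype=float)
    out = np.zeros(np.broadcast_shapes(np.shape(n), f.shape), dtype=np.int64)
    pos = np.broadcast_to(f, out.shape) > 0
    if pos.any():
        fb = np.broadcast_to(f, out.shape)[pos]
        nb = np.broadcast_to(n, out.shape)[pos]
        if rho > 0:
            c = (1.0 - rho) / rho
            p = rng.beta(fb * c, (1.0 - fb) * c)
        else:
            p = fb
        out[pos] = rng.binomial(nb, p)
    return out


def _ar_from_counts(low, high):
    low, high = np.minimum(low, high), np.maximum(low, high)
    with np.errstate(divide="ignore", invalid="ignore"):
        ar = np.where(high > 0, low / np.where(high > 0, high, 1), 0.0)
    return ar


def generate_allelic_datasets(
    truth: GroundTruth,
    n_samples_per_dataset: int = 8,
    seed: int = 0,
    *,
    total_reads: int = 100,
    overdispersion: float = 0.02,
) -> dict[str, pd.DataFrame]:
    """Emit allelic-ratio evidence tables in the five study dialects.

    Escape genes express their Xi allele at the truth's Xi fraction; their
    observed allelic ratios are beta-binomial read-sampling realizations
    around xi_fraction / (1 - xi_fraction). Subject genes carry no Xi
    signal, so their Xi read counts are exactly zero (the read-sampling
    model has nothing to draw). Dialects:

    - ``cotton``:     per-gene mean AR, sd, and number of informative samples
    - ``tukiainen``:  per-individual single-cell significance plus a bulk call
    - ``garieri``:    per-sample Xa read fractions (reported as ARs)
    - ``sauteraud``:  per-sample raw ARs with a skewing coefficient
    - ``sanroman``:   per-sample ARs for a one-sample t test
    """
    if n_samples_per_dataset < 2:
        raise ValueError("n_samples_per_dataset must be >= 2")
    rng = np.random.default_rng(seed)
    g = truth.genes
    nss = n_samples_per_dataset
    xi_frac = g["xi_fraction"].to_numpy()
    true_ar = xi_frac / (1.0 - xi_frac)
    genes = g.index.to_numpy()
    n_genes = len(genes)

    def sample_ars(n_cols):
        # Xi read fraction of total is xi_frac itself (Xi at ar relative to
        # Xa=1 puts ar/(1+ar) = xi_frac of reads on the Xi allele)
        f = np.repeat(xi_frac, n_cols).reshape(n_genes, n_cols)
        xi = _betabin(rng, total_reads, f, overdispersion)
        return _ar_from_counts(xi, total_reads - xi)

    # 1. mean AR + sd + n dialect
    ars = sample_ars(nss)
    cotton = pd.DataFrame(
        {
            "gene": genes,
            "mean_ar": ars.mean(axis=1),
            "sd_ar": ars.std(axis=1, ddof=1),
            "n_informative": nss,
        }
    )

    # 2. per-individual significance dialect (single-cell + bulk)
    n_ind = min(3, nss)
    ind_ars = sample_ars(n_ind)
    bulk_ars = sample_ars(1)[:, 0]
    tukiainen = pd.DataFrame(
        {
            "gene": genes,
            "n_sc_individuals": n_ind,
            "n_sc_significant": (ind_ars > 0).sum(axis=1),
            "has_bulk": True,
            "bulk_significant": bulk_ars > 0,
            "mean_ar": np.column_stack([ind_ars, bulk_ars]).mean(axis=1),
        }
    )

    # 3. per-sample Xa-fraction dialect (five fibroblast samples)
    n_g3 = min(5, nss)
    g3_ars = sample_ars(n_g3)
    garieri = pd.DataFrame(
        {
            "gene": np.repeat(genes, n_g3),
            "sample": np.tile([f"f{i}" for i in range(n_g3)], n_genes),
            "ar": g3_ars.ravel(),
        }
    )

    # 4. raw AR + skewing-coefficient dialect
    skews = rng.uniform(0.8, 1.0, nss)
    # expression from each parental X given incomplete skewing
    a1 = skews[None, :] + (1 - skews[None, :]) * true_ar[:, None]
    a2 = (1 - skews[None, :]) + skews[None, :] * true_ar[:, None]
    p_low = a2 / (a1 + a2)
    low = _betabin(rng, total_reads, p_low, overdispersion)
    raw_ar = _ar_from_counts(low, total_reads - low)
    sauteraud = pd.DataFrame(
        {
            "gene": np.repeat(genes, nss),
            "sample": np.tile([f"l{i}" for i in range(nss)], n_genes),
            "raw_ar": raw_ar.ravel(),
            "skew": np.tile(skews, n_genes),
        }
    )

    # 5. per-sample AR dialect
    sr_ars = sample_ars(nss)
    sanroman = pd.DataFrame(
        {
            "gene": np.repeat(genes, nss),
            "sample": np.tile([f"s{i}" for i in range(nss)], n_genes),
            "ar": sr_ars.ravel(),
        }
    )
    return {
        "cotton": cotton,
        "tukiainen": tukiainen,
        "garieri": garieri,
        "sauteraud": sauteraud,
        "sanroman": sanroman,
    }


def generate_depth_profile(
    repeat_copy_factor: float,
    gc_bias_strength: float = 0.0,
    n_windows: int = 200,
    seed: int = 0,
    *,
    base_depth: float = 2.0,
    window_size: int = 1000,
    noise_shape: float = 200.0,
) -> pd.DataFrame:
    """Windowed depth profiles for a repeat array and a single-copy region.

    Single-copy windows draw depth around ``base_depth * g(GC)``; repeat
    windows around ``repeat_copy_factor`` times that. The GC-bias curve is
    the smooth exponential tilt g(gc) = exp(strength * (gc - 0.45)); strength
    0 is flat. Depth noise is Gamma with shape ``noise_shape`` (cv ~ 7%).
    Returns one long table with a ``region`` column in {repeat, single_copy}.
    """
    if repeat_copy_factor <= 0:
        raise ValueError("repeat_copy_factor must be positive")
    if n_windows < 10:
        raise ValueError("need at least 10 windows per region")
    rng = np.random.default_rng(seed)
    frames = []
    for region, factor in [("single_copy", 1.0), ("repeat", repeat_copy_factor)]:
        gc = rng.uniform(0.3, 0.6, n_windows)
        g = np.exp(gc_bias_strength * (gc - 0.45))
        mean = base_depth * factor * g
        depth = rng.gamma(noise_shape, mean / noise_shape)
        start = np.arange(n_windows) * window_size
        frames.append(
            pd.DataFrame(
                {
                    "chrom": "chrY",
                    "start": start,
                    "end": start + window_size,
                    "gc": gc,
                    "depth": depth,
                    "region": region,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_peaks(
    annotation: pd.DataFrame,
    bound_gene_ids,
    window: int = 1000,
    jitter_sd: float = 0.0,
    seed: int = 0,
    *,
    peak_width: int = 200,
) -> pd.DataFrame:
    """One peak per bound gene near its strand-aware TSS (BED semantics).

    Peak centers are jittered by Normal(0, jitter_sd), truncated so the peak
    still intersects the +/- ``window`` promoter window; jitter_sd = 0 puts
    every peak midpoint exactly at the TSS. Coordinates are 0-based,
    half-open.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    bound = list(bound_gene_ids)
    missing = [gid for gid in bound if gid not in annotation.index]
    if missing:
        raise KeyError(f"gene ids absent from annotation: {missing[:5]}")
    rng = np.random.default_rng(seed)
    sites = tss(annotation).loc[bound]
    lim = max(0, window - peak_width // 2 - 1)
    jitter = np.clip(rng.normal(0.0, jitter_sd, len(bound)), -lim, lim).astype(int) if jitter_sd > 0 else 0
    center = sites.to_numpy() + jitter
    start = np.maximum(0, center - peak_width // 2)
    peaks = pd.DataFrame(
        {
            "chrom": annotation.loc[bound, "chrom"].to_numpy(),
            "start": start,
            "end": start + peak_width,
            "name": [f"peak_{gid}" for gid in bound],
            "score": 0,
            "strand": ".",
        }
    )
    return peaks.reset_index(drop=True)
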