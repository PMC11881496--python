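"""Genotype storage, marker QC, genotype coding, GRMs, and linkage disequilibrium.

The container is a dense individuals x markers dosage matrix (dosages in
[0, 2], fractional values allowed for imputed genotypes).  All downstream
models consume either the *centered* coding ``Z`` (dosage minus twice the
allele frequency, so common variants carry more of the genetic variance) or
the *standardized* coding ``X`` (centered and divided by the binomial
standard deviation ``sqrt(2 f (1 - f))``, which up-weights rare alleles).
The two codings give the VanRaden-style GRM ``Z Z' / sum 2 f_j (1 - f_j)``
and the Yang-style GRM ``X X' / M`` respectively.

Allele frequencies are always estimated once, from the full supplied matrix
(reference and target individuals combined), before any split.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "Grm",
    "LdProfile",
    "HweResult",
    "hwe_test",
    "filter_markers",
    "design_matrix",
    "compute_grm",
    "ld_r2",
    "ld_prune",
    "ld_scores",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
]

MARKER_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Dense dosage matrix with per-marker metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_markers)`` float array with values in ``[0, 2]``;
        ``NaN`` marks a missing call (mean-imputed on demand).
    markers
        Frame with columns ``id, chrom, pos, ref, alt``; positions are
        1-based and must be strictly increasing within a chromosome.
    sample_ids
        One identifier per row of ``dosages``.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (samples x markers) array")
        self.markers = self.markers.reset_index(drop=True)
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker metadata lacks columns {missing}")
        if len(self.markers) != self.dosages.shape[1]:
            raise ValueError("marker metadata length does not match dosage columns")
        if not self.sample_ids:
            self.sample_ids = [f"ind{i}" for i in range(self.dosages.shape[0])]
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length does not match dosage rows")
        vals = self.dosages[np.isfinite(self.dosages)]
        if vals.size and (vals.min() < -1e-9 or vals.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        if self.markers["id"].duplicated().any():
            dup = self.markers["id"][self.markers["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate marker id {dup!r}")
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic shape ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["id"].to_numpy()

    # -- per-marker summaries -----------------------------------------
    def call_rate(self) -> np.ndarray:
        return np.mean(np.isfinite(self.dosages), axis=0)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker, from observed calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the marker mean."""
        if not np.isnan(self.dosages).any():
            return self.dosages
        out = self.dosages.copy()
        means = np.nanmean(out, axis=0)
        idx = np.where(np.isnan(out))
        out[idx] = means[idx[1]]
        return out

    # -- subsetting ----------------------------------------------------
    def subset_markers(self, index: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.markers.iloc[index].reset_index(drop=True),
            list(self.sample_ids),
        )

    def select_ids(self, ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = set(ids)
        mask = self.markers["id"].isin(wanted).to_numpy()
        return self.subset_markers(mask)

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [lookup[s] for s in ids]
        return GenotypeMatrix(
            self.dosages[rows, :], self.markers.copy(), list(ids)
        )


@dataclass
class Grm:
    """Genomic relationship matrix together with its construction constants."""

    values: np.ndarray
    mode: str
    denom: float
    n_markers: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.mode not in ("centered", "standardized"):
            raise ValueError(f"unknown GRM mode {self.mode!r}")
        if self.denom <= 0:
            raise ValueError("GRM denominator must be positive")
        asym = np.max(np.abs(self.values - self.values.T))
        if asym > 1e-10:
            raise ValueError(f"GRM not symmetric (max asymmetry {asym:.3g})")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


@dataclass
class LdProfile:
    """Per-marker LD scores (window sums of r2, self term included)."""

    ld_score: np.ndarray
    window_bp: int


class HweResult(NamedTuple):
    p_value: float
    monomorphic: bool


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> HweResult:
    """One-degree-of-freedom chi-square test of Hardy-Weinberg proportions.

    A monomorphic marker (one allele absent) returns ``p = 1`` with the
    ``monomorphic`` flag set; no continuity correction is applied.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotype observations")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p == 0.0 or p == 1.0:
        return HweResult(1.0, True)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return HweResult(float(stats.chi2.sf(chi2, df=1)), False)


def _hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """HWE p-value per marker; fractional dosages are hard-called first."""
    hard = np.rint(geno.dosages)
    pvals = np.empty(geno.n_markers)
    for j in range(geno.n_markers):
        col = hard[:, j]
        col = col[np.isfinite(col)]
        n_aa = int(np.sum(col == 0))
        n_het = int(np.sum(col == 1))
        n_AA = int(np.sum(col == 2))
        pvals[j] = hwe_test(n_AA, n_het, n_aa).p_value
    return pvals


def filter_markers(
    geno: GenotypeMatrix,
    maf_min: float = 0.01,
    hwe_p_min: float = 0.001,
    callrate_min: float = 0.95,
) -> GenotypeMatrix:
    """Drop markers failing MAF, Hardy-Weinberg, or call-rate thresholds.

    Retains markers with MAF >= ``maf_min``, HWE chi-square p >= ``hwe_p_min``
    and call rate >= ``callrate_min``; marker order is preserved.  Raises if
    no marker survives.
    """
    for name, v in (("maf_min", maf_min), ("hwe_p_min", hwe_p_min),
                    ("callrate_min", callrate_min)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    keep = (
        (geno.maf() >= maf_min)
        & (geno.call_rate() >= callrate_min)
        & (_hwe_pvalues(geno) >= hwe_p_min)
    )
    if not keep.any():
        raise ValueError("no markers survive the QC filters")
    return geno.subset_markers(keep)


def design_matrix(geno: GenotypeMatrix, mode: str = "centered") -> np.ndarray:
    """Centered (``Z``) or standardized (``X``) genotype design matrix.

    Frequencies come from the full supplied matrix.  Monomorphic markers are
    rejected by name since neither coding is defined for them.
    """
    if mode not in ("centered", "standardized"):
        raise ValueError(f"unknown coding mode {mode!r}")
    d = geno.imputed()
    f = d.mean(axis=0) / 2.0
    mono = np.flatnonzero((f <= 0.0) | (f >= 1.0))
    if mono.size:
        names = geno.markers["id"].iloc[mono[:5]].tolist()
        raise ValueError(f"monomorphic markers cannot be coded: {names}")
    Z = d - 2.0 * f
    if mode == "standardized":
        Z = Z / np.sqrt(2.0 * f * (1.0 - f))
    return Z


def compute_grm(geno: GenotypeMatrix, mode: str = "centered") -> Grm:
    """GRM under the requested coding.

    ``centered``: ``Z Z' / sum_j 2 f_j (1 - f_j)``; ``standardized``:
    ``X X' / M``.  The denominator is recorded so per-group GRMs can be
    recombined into the all-marker GRM.
    """
    if geno.n_samples < 2:
        raise ValueError("GRM needs at least two individuals")
    W = design_matrix(geno, mode)
    if mode == "centered":
        f = geno.imputed().mean(axis=0) / 2.0
        denom = float(np.sum(2.0 * f * (1.0 - f)))
    else:
        denom = float(geno.n_markers)
    values = (W @ W.T) / denom
    values = 0.5 * (values + values.T)
    return Grm(values, mode, denom, geno.n_markers)


def _zscored(geno: GenotypeMatrix) -> np.ndarray:
    d = geno.imputed()
    mu = d.mean(axis=0)
    sd = d.std(axis=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(
            f"zero-variance dosage column {geno.markers['id'].iloc[j]!r}"
        )
    return (d - mu) / sd


def ld_r2(geno: GenotypeMatrix, marker_i: int | str, marker_j: int | str) -> float:
    """Squared Pearson correlation of two dosage columns, clipped to [0, 1]."""
    ids = list(geno.markers["id"])
    i = ids.index(marker_i) if isinstance(marker_i, str) else int(marker_i)
    j = ids.index(marker_j) if isinstance(marker_j, str) else int(marker_j)
    z = _zscored(geno.subset_markers([i, j]))
    r = float(z[:, 0] @ z[:, 1] / z.shape[0])
    return float(np.clip(r * r, 0.0, 1.0))


def ld_prune(
    geno: GenotypeMatrix, r2_threshold: float = 0.99, window_bp: int = 1_000_000
) -> list[str]:
    """Greedy positional LD pruning; returns retained marker ids.

    Markers are scanned left to right within each chromosome; a marker is
    dropped when its r2 with any already-retained marker closer than
    ``window_bp`` exceeds the threshold.  Among retained markers no
    within-window pair therefore has r2 above the threshold.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2 threshold must lie in (0, 1]")
    z = _zscored(geno)
    n = geno.n_samples
    pos = geno.markers["pos"].to_numpy()
    chroms = geno.markers["chrom"].to_numpy()
    ids = geno.markers["id"].to_numpy()
    kept: list[str] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        kept_idx: list[int] = []
        for j in idx:
            lo = pos[j] - window_bp
            cand = [k for k in kept_idx if pos[k] >= lo]
            ok = True
            if cand:
                r = z[:, cand].T @ z[:, j] / n
                if np.max(r * r) > r2_threshold:
                    ok = False
            if ok:
                kept_idx.append(j)
        kept.extend(ids[kept_idx])
    return kept


def ld_scores(geno: GenotypeMatrix, window_bp: int = 1_000_000) -> LdProfile:
    """Per-marker LD score: sum of r2 with all markers within ``window_bp``.

    The self term is included, so every score is at least 1.
    """
    z = _zscored(geno)
    n = geno.n_samples
    pos = geno.markers["pos"].to_numpy()
    chroms = geno.markers["chrom"].to_numpy()
    scores = np.empty(geno.n_markers)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        cpos = pos[idx]
        lo = np.searchsorted(cpos, cpos - window_bp, side="left")
        hi = np.searchsorted(cpos, cpos + window_bp, side="right")
        for local_j, j in enumerate(idx):
            window = idx[lo[local_j]:hi[local_j]]
            r = z[:, window].T @ z[:, j] / n
            scores[j] = float(np.sum(np.clip(r * r, 0.0, 1.0)))
    return LdProfile(scores, window_bp)


# ----------------------------------------------------------------------
# I/O: plain dosage TSV and minimal VCF
# ----------------------------------------------------------------------

def write_dosage_tsv(geno: GenotypeMatrix, path) -> None:
    """One marker per row: ``marker_id chrom pos ref alt <sample...>``."""
    header = ["marker_id", "chrom", "pos", "ref", "alt", *geno.sample_ids]
    frame = pd.concat(
        [
            geno.markers.rename(columns={"id": "marker_id"})[
                ["marker_id", "chrom", "pos", "ref", "alt"]
            ],
            pd.DataFrame(geno.dosages.T, columns=geno.sample_ids),
        ],
        axis=1,
    )
    frame.to_csv(path, sep="\t", index=False, header=header, float_format="%.6g")


def read_dosage_tsv(path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t")
    meta = frame[["marker_id", "chrom", "pos", "ref", "alt"]].rename(
        columns={"marker_id": "id"}
    )
    samples = [c for c in frame.columns if c not in
               ("marker_id", "chrom", "pos", "ref", "alt")]
    dos = frame[samples].to_numpy(dtype=np.float64).T
    return GenotypeMatrix(dos, meta, samples)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF with a DS FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        for chrom in pd.unique(geno.markers["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.sample_ids) + "\n")
        for j, row in geno.markers.iterrows():
            ds = "\t".join(
                "." if not np.isfinite(v) else f"{v:.4g}"
                for v in geno.dosages[:, j]
            )
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}"
                     f"\t{row['alt']}\t.\t.\t.\tDS\t{ds}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read bi-allelic records; DS dosages preferred, GT fallback."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        try:
            ds = np.asarray(var.format("DS"), dtype=np.float64).reshape(-1)
        except (KeyError, TypeError, ValueError):
            gt = np.asarray(var.gt_types, dtype=np.float64)
            # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
            ds = np.where(gt == 3, 2.0, gt)
            ds[gt == 2] = np.nan
        rows.append(ds)
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                     var.REF, var.ALT[0]))
    markers = pd.DataFrame(meta, columns=MARKER_COLUMNS)
    return GenotypeMatrix(np.array(rows).T, markers, samples)
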