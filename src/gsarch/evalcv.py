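"""Cross-validation evaluation: reliability, bootstrap comparisons, bias.

The validation design is a forward split by birth date: individuals born
before the cutoff form the reference population, the rest the target.
Reliability is the squared correlation between genomic estimated breeding
values (GEBV) and pre-corrected phenotypes ("trait deviations") divided by
the trait heritability.  Method comparisons resample the target
individuals with replacement (the same index across all method columns,
a paired design) and call a difference significant when one method is
higher in at least 97.5% of the resamples.  Dispersion bias is the
regression slope of trait deviations on predictions (1 = correctly
scaled).  Cumulative-PIP regions aggregate per-marker posterior inclusion
probabilities over a fixed 1 Mb grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationReport",
    "PipRegion",
    "split_by_date",
    "reliability",
    "bootstrap_compare",
    "dispersion_bias",
    "pip_regions",
    "combine_overall_score",
]


@dataclass
class EvaluationReport:
    methods: list[str]
    reliability: dict                  # method -> point estimate
    boot_ci: dict                      # method -> (lo, hi)
    diff_ci: dict                      # (a, b) -> (lo, hi) for rel_a - rel_b
    exceedance: dict                   # (a, b) -> P(rel_a > rel_b) over resamples
    significant: dict                  # (a, b) -> bool, 97.5% one-sided rule
    bias_coef: dict = field(default_factory=dict)
    n_target: int = 0
    n_boot: int = 0


@dataclass
class PipRegion:
    chrom: str
    window_start: int   # 1-based, inclusive
    window_end: int
    cumulative_pip: float
    n_markers: int


def split_by_date(birth_dates: pd.Series, cutoff) -> tuple[list, list]:
    """Reference/target partition by birth date.

    Individuals born strictly before ``cutoff`` are reference; those born
    on or after it are target.  ``birth_dates`` is indexed by sample id.
    """
    dates = pd.to_datetime(birth_dates)
    cutoff = pd.to_datetime(cutoff)
    ref = list(dates.index[dates < cutoff])
    target = list(dates.index[dates >= cutoff])
    if not ref:
        raise ValueError("empty reference set: no individuals born before cutoff")
    if not target:
        raise ValueError("empty target set: no individuals born on/after cutoff")
    return ref, target


def reliability(gebv: np.ndarray, trait_dev: np.ndarray, h2: float) -> float:
    """cor(GEBV, trait deviation)^2 / h2."""
    gebv = np.asarray(gebv, dtype=float).ravel()
    trait_dev = np.asarray(trait_dev, dtype=float).ravel()
    if gebv.size != trait_dev.size or gebv.size < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if not 0.0 < h2 <= 1.0:
        raise ValueError("h2 must lie in (0, 1]")
    if np.std(gebv) == 0:
        raise ValueError("zero-variance GEBV: reliability undefined")
    r = np.corrcoef(gebv, trait_dev)[0, 1]
    return float(r * r / h2)


def dispersion_bias(gebv: np.ndarray, trait_dev: np.ndarray) -> float:
    """OLS slope of trait deviations on predictions."""
    gebv = np.asarray(gebv, dtype=float).ravel()
    trait_dev = np.asarray(trait_dev, dtype=float).ravel()
    v = np.var(gebv)
    if v == 0:
        raise ValueError("zero-variance GEBV: slope undefined")
    return float(np.cov(gebv, trait_dev, ddof=0)[0, 1] / v)


def _boot_reliabilities(table: np.ndarray, y: np.ndarray, h2: float,
                        n_boot: int, seed: int,
                        chunk: int = 500) -> np.ndarray:
    """(n_boot, K) reliabilities under paired resampling of individuals."""
    rng = np.random.default_rng(seed)
    n, K = table.shape
    out = np.empty((n_boot, K))
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        g = table[idx]                       # (b, n, K)
        yb = y[idx]                          # (b, n)
        gm = g.mean(axis=1, keepdims=True)
        ym = yb.mean(axis=1, keepdims=True)
        gc = g - gm
        yc = yb - ym
        cov = np.einsum("bnk,bn->bk", gc, yc) / n
        sg = np.sqrt(np.einsum("bnk,bnk->bk", gc, gc) / n)
        sy = np.sqrt(np.einsum("bn,bn->b", yc, yc) / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cov / (sg * sy[:, None])
        out[done:done + b] = np.nan_to_num(r * r) / h2
        done += b
    return out


def bootstrap_compare(
    gebv_table: pd.DataFrame,
    trait_dev: np.ndarray,
    h2: float,
    n_boot: int = 10_000,
    seed: int = 0,
) -> EvaluationReport:
    """Bootstrap reliabilities and pairwise significance across methods.

    ``gebv_table`` has target individuals as rows and methods as columns.
    Each resample draws individuals with replacement once and reuses the
    same index for every method column, so method differences are paired.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    if gebv_table.isna().any().any():
        raise ValueError("GEBV table contains missing cells")
    y = np.asarray(trait_dev, dtype=float).ravel()
    table = gebv_table.to_numpy(dtype=float)
    if table.shape[0] != y.size:
        raise ValueError("GEBV table and trait deviations are misaligned")
    methods = list(gebv_table.columns)
    rel_point = {m: reliability(table[:, k], y, h2)
                 for k, m in enumerate(methods)}
    boots = _boot_reliabilities(table, y, h2, n_boot, seed)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    boot_ci = {m: (float(lo[k]), float(hi[k])) for k, m in enumerate(methods)}
    diff_ci, exceed, signif = {}, {}, {}
    for a in range(len(methods)):
        for b in range(len(methods)):
            if a == b:
                continue
            d = boots[:, a] - boots[:, b]
            dlo, dhi = np.percentile(d, [2.5, 97.5])
            pair = (methods[a], methods[b])
            diff_ci[pair] = (float(dlo), float(dhi))
            exceed[pair] = float(np.mean(d > 0))
            signif[pair] = exceed[pair] >= 0.975
    bias = {m: dispersion_bias(table[:, k], y) for k, m in enumerate(methods)}
    return EvaluationReport(
        methods=methods, reliability=rel_point, boot_ci=boot_ci,
        diff_ci=diff_ci, exceedance=exceed, significant=signif,
        bias_coef=bias, n_target=y.size, n_boot=n_boot,
    )


def pip_regions(
    pip: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    window_bp: int = 1_000_000,
    threshold: float = 0.5,
) -> list[PipRegion]:
    """Windows of a fixed grid whose summed PIP exceeds the threshold.

    The grid is non-overlapping, anchored at position 1 on each chromosome.
    """
    frame = pd.DataFrame({
        "chrom": np.asarray(chrom),
        "win": (np.asarray(pos, dtype=np.int64) - 1) // window_bp,
        "pip": np.asarray(pip, dtype=float),
    })
    out = []
    agg = frame.groupby(["chrom", "win"], sort=True)["pip"].agg(["sum", "size"])
    for (c, w), row in agg.iterrows():
        if row["sum"] > threshold:
            out.append(PipRegion(
                chrom=str(c),
                window_start=int(w) * window_bp + 1,
                window_end=(int(w) + 1) * window_bp,
                cumulative_pip=float(row["sum"]),
                n_markers=int(row["size"]),
            ))
    return out


def combine_overall_score(shoulder, top, buttock_side, buttock_rear,
                          weights=(1.0, 1.0, 2.0, 2.0)):
    """Weighted overall muscular-development score.

    Individual scores are combined with weights 1 for shoulder and top
    muscling and 2 for buttock muscling (side and rear view), normalized by
    the weight sum so all-equal inputs return that value.
    """
    w = np.asarray(weights, dtype=float)
    parts = [np.asarray(x, dtype=float) for x in
             (shoulder, top, buttock_side, buttock_rear)]
    return sum(wi * p for wi, p in zip(w, parts)) / w.sum()
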