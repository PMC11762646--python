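"""Mutual information, resampling inference, and correlation analyses.

Mutual information quantifies an unspecified (possibly non-linear)
dependence between two variables — here, between the number of miRNAs
regulating a transcription factor and the size of that factor's regulon.
Both variables are discretized by equal-width binning (10 x 10 by default)
and the plug-in (maximum-likelihood) estimator is evaluated in nats:

    MI = sum_ij p(i,j) ln[ p(i,j) / (p(i) p(j)) ]

Relative MI (rMI) rescales MI by the maximum extractable for the dataset,
min(H(X), H(Y)) on the same binning, giving a value in [0, 1].

Inference: percentile bootstrap confidence intervals on MI by paired case
resampling, and a permutation p-value obtained by shuffling y — the plug-in
MI is biased upward on finite samples, so the permutation null (not a
bootstrap one) is what carries significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MIResult:
    mi_nats: float
    rmi: float
    ci_low: float
    ci_high: float
    p_perm: float
    n_boot: int
    n_perm: int
    bins_x: int
    bins_y: int
    seed: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int


@dataclass
class CorrelationTable:
    """Symmetric pairwise-Pearson matrix with pairwise-complete observations."""

    columns: list[str]
    r: "np.ndarray"         # correlation; NaN where not computable
    p: "np.ndarray"
    n: "np.ndarray"         # complete observations per pair

    def cell(self, a: str, b: str) -> CorrelationResult:
        i, j = self.columns.index(a), self.columns.index(b)
        return CorrelationResult(float(self.r[i, j]), float(self.p[i, j]),
                                 int(self.n[i, j]))


# ---------------------------------------------------------------------------
# binning and the plug-in estimator

def _bin_codes(v: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width bin indices over [min, max]; a constant vector occupies
    a single bin."""
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        return np.zeros(v.size, dtype=np.intp)
    edges = np.linspace(lo, hi, bins + 1)
    codes = np.searchsorted(edges, v, side="right") - 1
    return np.clip(codes, 0, bins - 1).astype(np.intp)


def _mi_from_codes(cx: np.ndarray, cy: np.ndarray, bx: int, by: int) -> float:
    joint = np.bincount(cx * by + cy, minlength=bx * by).astype(float)
    n = joint.sum()
    p = joint / n
    px = p.reshape(bx, by).sum(axis=1)
    py = p.reshape(bx, by).sum(axis=0)
    outer = np.outer(px, py).ravel()
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


def _entropy_from_codes(c: np.ndarray, bins: int) -> float:
    p = np.bincount(c, minlength=bins).astype(float)
    p /= p.sum()
    nz = p > 0
    return float(-np.sum(p[nz] * np.log(p[nz])))


def _check_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 10:
        raise ValueError("need at least 10 paired observations")
    return x, y


def mutual_information(x, y, bins_x: int = 10, bins_y: int = 10) -> float:
    """Plug-in MI in nats after independent equal-width binning of x and y."""
    if bins_x < 2 or bins_y < 2:
        raise ValueError("bins must be >= 2")
    x, y = _check_xy(x, y)
    return _mi_from_codes(_bin_codes(x, bins_x), _bin_codes(y, bins_y),
                          bins_x, bins_y)


def relative_mi(x, y, bins_x: int = 10, bins_y: int = 10) -> float:
    """MI / min(H(X), H(Y)) on the binned marginals; 0 when a marginal is
    degenerate (constant vector)."""
    if bins_x < 2 or bins_y < 2:
        raise ValueError("bins must be >= 2")
    x, y = _check_xy(x, y)
    cx, cy = _bin_codes(x, bins_x), _bin_codes(y, bins_y)
    hmin = min(_entropy_from_codes(cx, bins_x), _entropy_from_codes(cy, bins_y))
    if hmin <= 0.0:
        return 0.0
    return _mi_from_codes(cx, cy, bins_x, bins_y) / hmin


def resample_mi(x, y, bins_x: int = 10, bins_y: int = 10,
                n_boot: int = 1000, n_perm: int = 1000,
                seed: int = 0) -> MIResult:
    """MI with a 95% percentile bootstrap CI and a permutation p-value.

    p_perm = (1 + #{permuted MI >= observed}) / (1 + n_perm); fully
    reproducible given ``seed``.
    """
    if n_boot < 100 or n_perm < 100:
        logger.warning("n_boot=%d / n_perm=%d below 100; estimates will be "
                       "coarse", n_boot, n_perm)
    x, y = _check_xy(x, y)
    rng = np.random.default_rng(seed)
    cx, cy = _bin_codes(x, bins_x), _bin_codes(y, bins_y)
    mi = _mi_from_codes(cx, cy, bins_x, bins_y)
    rmi = relative_mi(x, y, bins_x, bins_y)

    n = x.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        # rebin the resampled data: the bootstrap replicates the full pipeline
        boots[b] = _mi_from_codes(_bin_codes(x[idx], bins_x),
                                  _bin_codes(y[idx], bins_y), bins_x, bins_y)
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])

    perm_ge = 0
    for _ in range(n_perm):
        if _mi_from_codes(cx, rng.permutation(cy), bins_x, bins_y) >= mi:
            perm_ge += 1
    p_perm = (1 + perm_ge) / (1 + n_perm)

    return MIResult(mi_nats=mi, rmi=rmi, ci_low=float(ci_low),
                    ci_high=float(ci_high), p_perm=float(p_perm),
                    n_boot=n_boot, n_perm=n_perm, bins_x=bins_x,
                    bins_y=bins_y, seed=seed)


# ---------------------------------------------------------------------------
# correlations

def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with the two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic),
                             p_two_sided=float(res.pvalue), n=x.size)


UTR_COLUMNS = ["utr3_length", "transcript_length", "n_verified",
               "n_pred_A", "n_pred_B"]


def correlation_table(utr_table, columns=None) -> CorrelationTable:
    """Pairwise Pearson matrix over the UTR-analysis columns.

    Rows with missing values are dropped pairwise; pairs with fewer than 3
    complete rows (or a constant vector) are flagged not-computable (NaN).
    """
    import pandas as pd

    cols = list(columns) if columns is not None else UTR_COLUMNS
    df = pd.DataFrame(utr_table)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"utr table missing columns: {missing}")
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        n[i, i] = int(df[cols[i]].notna().sum())
        for j in range(i + 1, k):
            sub = df[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(sub)
            try:
                cr = pearson(sub[cols[i]].to_numpy(), sub[cols[j]].to_numpy())
            except ValueError:
                continue  # flagged not-computable (NaN)
            r[i, j] = r[j, i] = cr.r
            p[i, j] = p[j, i] = cr.p_two_sided
    return CorrelationTable(columns=cols, r=r, p=p, n=n)


# ---------------------------------------------------------------------------
# chance k-mer occurrence

def kmer_chance_spacing(k: int) -> int:
    """Expected spacing, 4^k, between chance occurrences of a fixed k-mer in
    uniform random nucleotide sequence (a 6-mer seed match every 4096 nt)."""
    if not 1 <= k <= 15:
        raise ValueError("k must be in [1, 15]")
    return 4 ** k


def expected_kmer_count(length: int, k: int) -> float:
    """Expected number of chance occurrences of a fixed k-mer in a random
    sequence of the given length: (L - k + 1) / 4^k."""
    if length < k:
        return 0.0
    return (length - k + 1) / kmer_chance_spacing(k)
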