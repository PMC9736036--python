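"""Per-bin univariate discovery: Kruskal–Wallis tests, median fold changes,
Benjamini–Yekutieli FDR control and discriminant-bin selection.

Tests run on the per-sample representative spectra (one row per sample), so
the sample size is the number of patients, not the number of burns — testing
individual burns would pseudo-replicate within patients. The Kruskal–Wallis
H statistic (two groups, tie-corrected, chi-square reference with 1 df) is
computed vectorised across all 4000 bins. p-values are adjusted with the
Benjamini–Hochberg–Yekutieli step-up procedure (the arbitrary-dependence
variant with the harmonic inflation factor c(m) = Σ 1/k), appropriate here
because neighbouring spectral bins are strongly dependent. A bin is called
discriminant when q ≤ 0.001 and |log2 median fold change| ≥ 1, the fold
change oriented cancer/normal so cancer-upregulated lipids come out
positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata
from statsmodels.stats.multitest import multipletests

from .multivariate import NEGATIVE_CLASS, POSITIVE_CLASS
from .preprocessing import FeatureMatrix

__all__ = [
    "BinTestResult",
    "kruskal_wallis_per_bin",
    "log2_median_fold_change",
    "adjust_benjamini_yekutieli",
    "select_discriminant_bins",
    "univariate_table",
]

Q_THRESHOLD_DEFAULT = 0.001
FC_THRESHOLD_DEFAULT = 1.0


@dataclass(frozen=True)
class BinTestResult:
    bin_mz: float  # lower edge of the bin
    p_value: float
    q_value: float
    log2_median_fc: float  # cancer over normal; NaN when undefined
    selected: bool


def _binary_groups(M: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(M.labels)
    pos = labels == POSITIVE_CLASS
    neg = labels == NEGATIVE_CLASS
    if not np.array_equal(pos | neg, np.ones(len(labels), dtype=bool)):
        raise ValueError("feature matrix must contain only normal/cancer rows")
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    return pos, neg


def kruskal_wallis_per_bin(M: FeatureMatrix) -> np.ndarray:
    """Two-group Kruskal–Wallis p-value for every bin (vectorised).

    H is tie-corrected; bins with zero variance across all samples get
    p = 1 (no evidence either way).
    """
    pos, neg = _binary_groups(M)
    X = M.X
    n = X.shape[0]
    ranks = rankdata(X, axis=0)
    r_pos = ranks[pos].sum(axis=0)
    r_neg = ranks[neg].sum(axis=0)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    h = (12.0 / (n * (n + 1))) * (r_pos**2 / n_pos + r_neg**2 / n_neg) - 3.0 * (n + 1)

    # tie correction per bin: C = 1 − Σ(t³−t)/(n³−n)
    sorted_x = np.sort(X, axis=0)
    correction = np.ones(X.shape[1])
    denom = float(n**3 - n)
    for j in range(X.shape[1]):
        _, counts = np.unique(sorted_x[:, j], return_counts=True)
        ties = float(((counts.astype(float)) ** 3 - counts).sum())
        correction[j] = 1.0 - ties / denom
    p = np.ones(X.shape[1])
    ok = correction > 0
    p[ok] = chi2.sf(h[ok] / correction[ok], df=1)
    return p


def log2_median_fold_change(M: FeatureMatrix) -> np.ndarray:
    """log2(median cancer / median normal) per bin.

    A zero median is replaced by the smallest positive value observed in
    that bin across all samples; a bin with no positive value at all is NaN
    (undefined, excluded from selection).
    """
    pos, neg = _binary_groups(M)
    X = M.X
    med_pos = np.median(X[pos], axis=0)
    med_neg = np.median(X[neg], axis=0)
    positives = np.where(X > 0, X, np.inf)
    smallest_pos = positives.min(axis=0)
    all_zero = ~np.isfinite(smallest_pos)
    eps = np.where(all_zero, np.nan, smallest_pos)
    num = np.where(med_pos > 0, med_pos, eps)
    den = np.where(med_neg > 0, med_neg, eps)
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.log2(num / den)
    fc[all_zero] = np.nan
    return fc


def adjust_benjamini_yekutieli(p: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini–Yekutieli step-up q-values (arbitrary dependence variant)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def univariate_table(
    M: FeatureMatrix,
    q_threshold: float = Q_THRESHOLD_DEFAULT,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Full per-bin results table: bin_mz, p, q, log2 fold change, selected."""
    p = kruskal_wallis_per_bin(M)
    q = adjust_benjamini_yekutieli(p)
    fc = log2_median_fold_change(M)
    with np.errstate(invalid="ignore"):
        selected = (q <= q_threshold) & (np.abs(fc) >= fc_threshold) & np.isfinite(fc)
    return pd.DataFrame({
        "bin_mz": M.bin_edges(),
        "p_value": p,
        "q_value": q,
        "log2_median_fc": fc,
        "selected": selected,
    })


def select_discriminant_bins(
    results: pd.DataFrame | Sequence[BinTestResult],
    q_threshold: float = Q_THRESHOLD_DEFAULT,
    fc_threshold: float = FC_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Bins passing both thresholds, sorted by q ascending then |fc| descending.

    Deterministic tie order by bin m/z. Accepts the DataFrame produced by
    :func:`univariate_table` or a sequence of :class:`BinTestResult`.
    """
    if not isinstance(results, pd.DataFrame):
        results = pd.DataFrame([
            {"bin_mz": r.bin_mz, "p_value": r.p_value, "q_value": r.q_value,
             "log2_median_fc": r.log2_median_fc}
            for r in results
        ])
    if results.empty:
        return results.assign(selected=pd.Series(dtype=bool)) if "selected" not in results else results
    df = results.copy()
    with np.errstate(invalid="ignore"):
        keep = (
            (df["q_value"] <= q_threshold)
            & (df["log2_median_fc"].abs() >= fc_threshold)
            & df["log2_median_fc"].notna()
        )
    out = df[keep].copy()
    out["abs_fc"] = out["log2_median_fc"].abs()
    out = out.sort_values(
        ["q_value", "abs_fc", "bin_mz"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="abs_fc")
    out["selected"] = True
    return out.reset_index(drop=True)
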