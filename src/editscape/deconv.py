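"""Bulk-tissue cell-type deconvolution and detection-saturation analyses.

Cellular composition is estimated by non-negative least squares against a
cell-type expression signature on log2-CPM values; excitatory and
inhibitory neuronal fractions are summed into one neuronal population.
Detection saturation sweeps a sliding sample-fraction threshold over a
site x sample detection matrix and tracks how strongly cell-type-associated
sites dominate the universally detected ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

NEURONAL_PARTS = ("excitatory", "inhibitory")


def cpm_filter_log(counts: pd.DataFrame, min_cpm: float = 1.0, min_fraction: float = 0.5) -> pd.DataFrame:
    """CPM-filter a gene x sample count table and return log2(CPM + 1).

    Genes are kept when CPM >= ``min_cpm`` in at least ``min_fraction`` of
    samples (inclusive).  Zero library sizes are an error.
    """
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    cpm = counts / lib * 1e6
    keep = (cpm >= min_cpm).mean(axis=1) >= min_fraction
    return np.log2(cpm.loc[keep] + 1)


def estimate_fractions_nnls(
    bulk: pd.DataFrame,
    signature: pd.DataFrame,
    sum_neuronal: bool = True,
    min_shared_genes: int = 10,
) -> pd.DataFrame:
    """Per-sample cell-type fractions by NNLS on shared genes.

    Solves min ||S f - b|| s.t. f >= 0 per sample, optionally sums
    excitatory + inhibitory into 'neuronal', then normalizes fractions to
    sum to 1.  Returns sample x cell type fractions plus the residual norm.
    """
    shared = signature.index.intersection(bulk.index)
    if len(shared) < min_shared_genes:
        raise ValueError(f"only {len(shared)} genes shared between bulk and signature")
    S = signature.loc[shared].to_numpy(dtype=float)
    rows = []
    for sample in bulk.columns:
        b = bulk.loc[shared, sample].to_numpy(dtype=float)
        f, rnorm = nnls(S, b)
        est = dict(zip(signature.columns, f))
        if sum_neuronal and all(ct in est for ct in NEURONAL_PARTS):
            est["neuronal"] = sum(est.pop(ct) for ct in NEURONAL_PARTS)
        total = sum(est.values())
        if total > 0:
            est = {k: v / total for k, v in est.items()}
        rows.append({"sample_id": sample, **est, "residual_norm": float(rnorm)})
    return pd.DataFrame(rows).set_index("sample_id")


def variance_explained(response: pd.Series | np.ndarray, predictor: pd.Series | np.ndarray) -> float:
    """R^2 of a single-covariate ordinary least squares fit."""
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 samples")
    if np.var(x) == 0:
        raise ValueError("constant predictor")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


def detection_saturation(
    detection: pd.DataFrame,
    categories: pd.Series,
    thresholds: np.ndarray | None = None,
    associated_labels: tuple[str, ...] = ("specific", "enriched"),
) -> pd.DataFrame:
    """Sliding sample-fraction threshold over a boolean detection matrix.

    At threshold t a site is retained when detected in >= t * n samples;
    for each t the retained count and the fraction of retained sites whose
    category starts with one of ``associated_labels`` (cell-type-associated
    sites) are reported.
    """
    if detection.size == 0:
        raise ValueError("empty detection matrix")
    if thresholds is None:
        thresholds = np.linspace(0, 1, 11)
    det = detection.to_numpy(dtype=bool)
    frac = det.mean(axis=1)
    cats = categories.loc[detection.index]
    assoc = cats.astype(str).str.startswith(associated_labels).to_numpy()
    rows = []
    for t in thresholds:
        keep = frac >= t
        n_ret = int(keep.sum())
        rows.append(
            {
                "threshold": float(t),
                "retained": n_ret,
                "associated_fraction": float(assoc[keep].mean()) if n_ret else np.nan,
            }
        )
    return pd.DataFrame(rows)


def fold_enrichment_90_10(
    detection: pd.DataFrame,
    categories: pd.Series,
    hi: float = 0.9,
    lo: float = 0.1,
    n_perm: int = 1000,
    definition: str = "share",
    seed: int = 0,
) -> pd.DataFrame:
    """Category fold enrichment among near-universal vs rarely shared sites.

    For category c, FE(c) = share of c among sites detected in >= 90% of
    samples over its share among sites detected in >= 10% ('share'
    definition; 'count' uses raw retained counts).  Significance by label
    permutation.  A category absent at the 10% threshold yields a missing
    FE.
    """
    frac = detection.to_numpy(dtype=bool).mean(axis=1)
    cats = categories.loc[detection.index].astype(str).to_numpy()
    hi_mask, lo_mask = frac >= hi, frac >= lo
    if hi_mask.sum() == 0 or lo_mask.sum() == 0:
        raise ValueError("a threshold retains no sites")

    def _fe(cat_arr, c):
        n_hi = (cat_arr[hi_mask] == c).sum()
        n_lo = (cat_arr[lo_mask] == c).sum()
        if n_lo == 0:
            return np.nan
        if definition == "share":
            return (n_hi / hi_mask.sum()) / (n_lo / lo_mask.sum())
        if definition == "count":
            return n_hi / n_lo
        raise ValueError(f"unknown definition {definition!r}")

    rng = np.random.default_rng(seed)
    rows = []
    for c in sorted(set(cats)):
        fe_obs = _fe(cats, c)
        if np.isnan(fe_obs):
            rows.append({"category": c, "fold_enrichment": np.nan, "p": np.nan})
            continue
        exceed = 0
        for _ in range(n_perm):
            fe_p = _fe(rng.permutation(cats), c)
            if not np.isnan(fe_p) and fe_p >= fe_obs:
                exceed += 1
        rows.append(
            {"category": c, "fold_enrichment": float(fe_obs), "p": (1 + exceed) / (n_perm + 1)}
        )
    return pd.DataFrame(rows).set_index("category")
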