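"""cis editing quantitative trait locus (edQTL) mapping.

Editing levels per donor are tested against imputed allele dosages of every
SNP within a 1 Mb cis window by a linear model with sex, age, RIN and death
type as covariates; p values are BH-adjusted jointly across all tested
pairs of all chromosomes and the most significant SNP per site (the
max-edQTL) is selected among significant pairs.  Missing editing values are
imputed by predictive mean matching (k nearest predictions among observed
donors), with median imputation as fallback.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import GenotypeMatrix
from .stats import bh_adjust


def _pmm_impute(levels: pd.DataFrame, k: int, max_predictors: int, rng) -> pd.DataFrame:
    """Predictive mean matching against the most-correlated complete sites."""
    out = levels.copy()
    complete = levels.dropna()
    if complete.empty:
        return out.apply(lambda row: row.fillna(row.median()), axis=1)
    comp_t = complete.T  # donor x complete-site
    for sid, row in levels.iterrows():
        miss = row.isna()
        if not miss.any():
            continue
        obs = row[~miss]
        if len(obs) < 3:
            continue  # handled upstream (dropped with report)
        corr = comp_t.loc[obs.index].corrwith(obs).abs().drop(sid, errors="ignore").dropna()
        preds = corr.sort_values(ascending=False).index[:max_predictors]
        if len(preds) == 0:
            out.loc[sid] = row.fillna(obs.median())
            continue
        X_obs = np.column_stack([np.ones(len(obs)), comp_t.loc[obs.index, preds].to_numpy()])
        beta, *_ = np.linalg.lstsq(X_obs, obs.to_numpy(), rcond=None)
        X_all = np.column_stack([np.ones(len(row)), comp_t.loc[row.index, preds].to_numpy()])
        yhat = pd.Series(X_all @ beta, index=row.index)
        filled = row.copy()
        for donor in row.index[miss]:
            dist = (yhat[obs.index] - yhat[donor]).abs().sort_values()
            candidates = dist.index[: min(k, len(dist))]
            filled[donor] = obs[candidates[rng.integers(len(candidates))]]
        out.loc[sid] = filled
    return out


def prepare_editing_for_qtl(
    levels: pd.DataFrame,
    min_detection_fraction: float = 0.5,
    method: str = "pmm",
    k: int = 5,
    max_predictors: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter to well-detected sites and impute the remaining missingness.

    Sites observed in fewer than ``min_detection_fraction`` of donors are
    dropped, as are sites with < 3 observed values; the rest are completed
    by predictive mean matching (``method='pmm'``) or per-site median
    (``method='median'``).  Returns (complete matrix, drop report).
    """
    if not 0 < min_detection_fraction <= 1:
        raise ValueError("detection fraction must lie in (0, 1]")
    frac = levels.notna().mean(axis=1)
    report = []
    keep = levels[frac >= min_detection_fraction]
    for sid in levels.index[frac < min_detection_fraction]:
        report.append({"site_id": sid, "reason": "below-detection-fraction"})
    enough = keep.notna().sum(axis=1) >= 3
    for sid in keep.index[~enough]:
        report.append({"site_id": sid, "reason": "fewer-than-3-observed"})
    keep = keep[enough]
    rng = np.random.default_rng(seed)
    if method == "pmm":
        filled = _pmm_impute(keep, k=k, max_predictors=max_predictors, rng=rng)
    elif method == "median":
        filled = keep.apply(lambda row: row.fillna(row.median()), axis=1)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return filled, pd.DataFrame(report, columns=["site_id", "reason"])


def _covariate_design(covariates: pd.DataFrame) -> np.ndarray:
    parts = [np.ones((len(covariates), 1))]
    for c in covariates.columns:
        col = covariates[c]
        if col.dtype == object or str(col.dtype) == "category" or col.dtype == bool:
            parts.append(pd.get_dummies(col, drop_first=True, dtype=float).to_numpy())
        else:
            parts.append(col.to_numpy(dtype=float)[:, None])
    return np.column_stack(parts)


def map_cis_edqtl(
    levels: pd.DataFrame,
    site_positions: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    window: int = 1_000_000,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Additive linear-model cis-edQTL scan.

    For every (SNP, site) pair with |SNP - site| <= ``window`` on the same
    chromosome: editing ~ dosage + covariates, via exact Frisch-Waugh
    residualization (identical to full normal-equation OLS).  BH FDR is
    computed across all pairs jointly.  Monomorphic SNPs are skipped with a
    report.  Returns (pair table, skip report).
    """
    donors = list(levels.columns)
    geno = genotypes.dosages[donors]
    covariates = covariates.loc[donors]
    Z = _covariate_design(covariates)
    proj = Z @ np.linalg.pinv(Z)
    resid = lambda v: v - proj @ v  # noqa: E731
    p_full = Z.shape[1] + 1
    df = len(donors) - p_full

    y_resid = {sid: resid(levels.loc[sid].to_numpy(dtype=float)) for sid in levels.index}
    sites_by_chrom = {
        chrom: list(zip(sub.index, sub["pos"]))
        for chrom, sub in site_positions.groupby("chrom")
    }
    snp_tab = genotypes.snps.set_index("snp_id")
    skip_rows, rows = [], []
    for snp_id, snp in snp_tab.iterrows():
        dos = geno.loc[snp_id].to_numpy(dtype=float)
        if np.var(dos) == 0:
            skip_rows.append({"snp_id": snp_id, "reason": "monomorphic"})
            continue
        x_t = resid(dos)
        xtx = float(x_t @ x_t)
        for sid, pos in sites_by_chrom.get(snp["chrom"], ()):
            distance = int(snp["pos"] - pos)
            if abs(distance) > window:
                continue
            y_t = y_resid[sid]
            beta = float(x_t @ y_t) / xtx
            rss = float(((y_t - beta * x_t) ** 2).sum())
            se = np.sqrt(rss / df / xtx) if df > 0 else np.nan
            t = beta / se if se and se > 0 else 0.0
            p = float(2 * sps.t.sf(abs(t), df)) if se and se > 0 else 1.0
            rows.append(
                {
                    "snp_id": snp_id,
                    "site_id": sid,
                    "distance": distance,
                    "beta": beta,
                    "se": float(se),
                    "t": float(t),
                    "p": p,
                }
            )
    pairs = pd.DataFrame(
        rows, columns=["snp_id", "site_id", "distance", "beta", "se", "t", "p"]
    )
    if len(pairs):
        pairs["fdr"] = bh_adjust(pairs["p"])
        pairs["significant"] = pairs["fdr"] < fdr_threshold
    else:
        pairs["fdr"] = []
        pairs["significant"] = []
    return pairs, pd.DataFrame(skip_rows, columns=["snp_id", "reason"])


def select_max_edqtl(pairs: pd.DataFrame) -> pd.DataFrame:
    """The most significant SNP-site pair per site, among significant pairs.

    Ties on p are broken by larger |beta|, then smaller |distance|, then
    lexicographic SNP id.
    """
    sig = pairs[pairs["significant"]].copy()
    if sig.empty:
        return sig
    sig["_absbeta"] = -sig["beta"].abs()
    sig["_absdist"] = sig["distance"].abs()
    sig = sig.sort_values(["site_id", "p", "_absbeta", "_absdist", "snp_id"])
    out = sig.groupby("site_id", sort=True).head(1).drop(columns=["_absbeta", "_absdist"])
    return out.set_index("site_id")


def distance_profile(max_pairs: pd.DataFrame, bin_width: int = 100_000, radius: int = 200_000):
    """Histogram of |SNP - site| distances and the fraction within a radius."""
    if max_pairs.empty:
        raise ValueError("no max-edQTL pairs")
    d = max_pairs["distance"].abs().to_numpy()
    edges = np.arange(0, d.max() + bin_width + 1, bin_width)
    counts, edges = np.histogram(d, bins=edges)
    hist = pd.DataFrame({"bin_start": edges[:-1].astype(int), "count": counts})
    return hist, float((d <= radius).mean())


def annotate_edqtl_celltype(
    max_pairs: pd.DataFrame,
    labels: pd.Series,
    associated_prefixes: tuple[str, ...] = ("specific", "enriched"),
) -> tuple[pd.DataFrame, dict]:
    """Join cell-type labels onto max-edQTLs and compare |beta| across groups.

    Sites whose label starts with one of ``associated_prefixes`` form the
    cell-type-associated group; a two-sided Mann-Whitney U test compares
    their |beta| with the remaining max-edQTLs.  Groups with < 2 members
    skip the comparison.
    """
    out = max_pairs.copy()
    out["cell_type_label"] = labels.reindex(out.index).fillna("none")
    out["associated"] = out["cell_type_label"].astype(str).str.startswith(associated_prefixes)
    a = out.loc[out["associated"], "beta"].abs().to_numpy()
    b = out.loc[~out["associated"], "beta"].abs().to_numpy()
    if len(a) < 2 or len(b) < 2:
        test = {"skipped": True, "n_associated": len(a), "n_other": len(b)}
    else:
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = {
            "skipped": False,
            "n_associated": len(a),
            "n_other": len(b),
            "u": float(u),
            "p": float(p),
        }
    return out, test
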