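"""Pseudo-bulk validation of editing sites from pooled single nuclei.

Nuclei are assigned to marker-defined pools (neuronal split by SOX6,
oligodendrocytes by SOX10, plus glial/vascular pools), sites discovered in
sorted-nuclei RNA-seq are re-quantified in each pool, and a site validates
when the pool's median editing rate across replicates lies within 50% of
the sorted-population median.  A rank test probes whether validated sites
sit closer to the transcript 3' end (a coverage-bias signature of 3'-biased
single-nucleus libraries).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sites import SiteMatrix, quantify_supervised

POOL_RULES = (
    # (pool, required-present markers, required-absent markers); first match wins
    ("MGE-GABA", ("RBFOX3", "SOX6"), ()),
    ("GLU", ("RBFOX3",), ("SOX6",)),
    ("OLIG", ("SOX10",), ("RBFOX3",)),
    ("astrocyte", ("GFAP",), ("RBFOX3",)),
    ("endothelial", ("CLDN5",), ("RBFOX3",)),
    ("microglia", ("TMEM119",), ("RBFOX3",)),
)


def assign_pools(markers: pd.DataFrame) -> pd.DataFrame:
    """Deterministic marker-based pool assignment per nucleus.

    ``markers`` is nucleus x marker presence (boolean or counts; nonzero
    counts as present).  Precedence: MGE-GABA (RBFOX3+/SOX6+), GLU
    (RBFOX3+/SOX6-), OLIG (RBFOX3-/SOX10+), astrocyte (GFAP+), endothelial
    (CLDN5+), microglia (TMEM119+), else unassigned.
    """
    present = markers.astype(bool)
    pools = []
    for _, row in present.iterrows():
        pool = "unassigned"
        for name, need, absent in POOL_RULES:
            if all(row.get(m, False) for m in need) and not any(row.get(m, False) for m in absent):
                pool = name
                break
        pools.append(pool)
    out = present.copy()
    out.insert(0, "pool", pools)
    return out


def pool_quantify(
    pool_samples,
    site_list: pd.DataFrame,
    min_coverage: int = 10,
    min_edited: int = 3,
    threshold_sweep: range | None = None,
) -> SiteMatrix | dict[int, SiteMatrix]:
    """Re-quantify sorted-population sites in pseudo-bulk pools.

    With ``threshold_sweep`` (e.g. ``range(3, 21)``) one matrix per minimum
    coverage is returned; site counts are then monotone non-increasing in
    the threshold.
    """
    if threshold_sweep is not None:
        return {
            t: quantify_supervised(pool_samples, site_list, min_coverage=t, min_edited=min_edited)
            for t in threshold_sweep
        }
    return quantify_supervised(pool_samples, site_list, min_coverage=min_coverage, min_edited=min_edited)


def validate_sites(
    fans_medians: pd.Series,
    pooled: SiteMatrix,
    tolerance: float = 0.5,
    rule: str = "relative",
    min_coverage: int = 10,
) -> pd.DataFrame:
    """Apply the 50%-concordance rule between pools and sorted populations.

    A site validates when |pool median - FANS median| <= tolerance * FANS
    median (relative rule; 'absolute' compares against ``tolerance`` in
    level units).  The pool median is taken across replicates with a
    non-missing call; sites with no qualifying replicate are unvalidated
    with zero pool coverage.  A FANS median of exactly 0 validates only a
    pool median of 0 and is flagged.
    """
    rows = []
    for sid in fans_medians.index:
        if sid in pooled.levels.index:
            lv = pooled.levels.loc[sid].dropna()
            pool_median = float(lv.median()) if len(lv) else np.nan
            pool_cov = float(pooled.coverage.loc[sid].median())
        else:
            pool_median, pool_cov = np.nan, 0.0
        fm = float(fans_medians.loc[sid])
        flagged = fm == 0
        if np.isnan(pool_median):
            ok = False
        elif rule == "relative":
            ok = abs(pool_median - fm) <= tolerance * fm if fm > 0 else pool_median == 0
        elif rule == "absolute":
            ok = abs(pool_median - fm) <= tolerance
        else:
            raise ValueError(f"unknown rule {rule!r}")
        rows.append(
            {
                "site_id": sid,
                "fans_median": fm,
                "pool_median": pool_median,
                "pool_coverage": pool_cov,
                "validated": bool(ok),
                "zero_fans_flag": flagged,
            }
        )
    return pd.DataFrame(rows).set_index("site_id")


def tss_bias_test(
    validation: pd.DataFrame,
    tss_distance: pd.Series,
    coverage: pd.Series,
) -> pd.DataFrame:
    """Two-sided rank test: are validated sites farther from the TSS?

    Sites are binned by read coverage into high (top quintile), medium
    (middle three quintiles) and low (bottom quintile); a Mann-Whitney U
    test compares TSS distances of validated vs non-validated sites
    overall and per bin.  Comparisons with < 2 sites on either side are
    skipped with a note.
    """
    df = validation.copy()
    df["tss_distance"] = tss_distance.loc[df.index]
    df["coverage_bin"] = "medium"
    q = coverage.loc[df.index].rank(pct=True)
    df.loc[q > 0.8, "coverage_bin"] = "high"
    df.loc[q <= 0.2, "coverage_bin"] = "low"

    rows = []
    groups = [("overall", df)] + [(b, df[df["coverage_bin"] == b]) for b in ("high", "medium", "low")]
    for name, sub in groups:
        a = sub.loc[sub["validated"], "tss_distance"].to_numpy()
        b = sub.loc[~sub["validated"], "tss_distance"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            rows.append(
                {"group": name, "n_validated": len(a), "n_other": len(b), "u": np.nan, "p": np.nan, "skipped": True}
            )
            continue
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "group": name,
                "n_validated": len(a),
                "n_other": len(b),
                "u": float(u),
                "p": float(p),
                "median_validated": float(np.median(a)),
                "median_other": float(np.median(b)),
                "skipped": False,
            }
        )
    return pd.DataFrame(rows).set_index("group")
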