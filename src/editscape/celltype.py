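"""Cell-type specificity and enrichment statistics for editing sites.

Differential editing follows the covariate-adjusted linear-model design of
bulk differential analyses: editing ~ cell type + age + PMI, with donor as
a repeated measure handled through a consensus intra-donor correlation and
compound-symmetry generalized least squares (a fixed-effect donor term is
available as a fallback).  Effect sizes are reported both as the difference
of group means (editing-level units) and Cohen's d; p values are BH-adjusted
across all sites of a contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import Gene
from .sites import SiteMatrix
from .stats import bh_adjust, cohens_d


def _design_matrix(meta: pd.DataFrame, group_col: np.ndarray, covariates, donor_dummies: bool):
    cols = [np.ones(len(meta)), group_col]
    names = ["intercept", "group"]
    for c in covariates:
        cols.append(pd.to_numeric(meta[c]).to_numpy(dtype=float))
        names.append(c)
    if donor_dummies:
        dd = pd.get_dummies(meta["donor"], drop_first=True, dtype=float)
        for c in dd.columns:
            cols.append(dd[c].to_numpy())
            names.append(f"donor_{c}")
    return np.column_stack(cols), names


def estimate_consensus_correlation(
    residuals: np.ndarray, donors: pd.Series, hat: np.ndarray | None = None
) -> float:
    """Average intra-donor residual correlation across sites.

    The analogue of limma's duplicateCorrelation consensus: residual
    products of sample pairs sharing a donor, scaled by the residual
    variance, averaged over all sites and pairs.  OLS residuals have
    E[e_i e_j] = -sigma^2 H_ij even under independence, so the hat matrix
    ``hat`` (when given) is used to de-bias both the cross-products and the
    variance.
    """
    donors = np.asarray(donors)
    n = len(donors)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if donors[i] == donors[j]]
    if not pairs:
        return 0.0
    mean_sq = np.nanmean(residuals**2)
    if mean_sq == 0:
        return 0.0
    cross = np.nanmean([residuals[:, i] * residuals[:, j] for i, j in pairs])
    if hat is not None:
        sigma2 = mean_sq / (1 - np.trace(hat) / n)
        h_bar = float(np.mean([hat[i, j] for i, j in pairs]))
        rho = (cross + sigma2 * h_bar) / sigma2
    else:
        rho = cross / mean_sq
    return float(np.clip(rho, -0.3, 0.95))


def _gls_fit(y: np.ndarray, X: np.ndarray, Vinv: np.ndarray):
    XtVi = X.T @ Vinv
    XtViX_inv = np.linalg.inv(XtVi @ X)
    beta = XtViX_inv @ (XtVi @ y)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = max(float(resid @ Vinv @ resid) / df, 0.0)
    se = np.sqrt(np.diag(XtViX_inv) * sigma2)
    return beta, se, df


def differential_editing(
    matrix: SiteMatrix,
    contrast: tuple[str, str],
    covariates: tuple[str, ...] = ("age", "PMI"),
    donor_handling: str = "gls",
    adar_covariates: tuple[str, ...] = (),
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-site differential editing between two cell types.

    Returns a table with delta (mean(A) - mean(B)), t, p, fdr, Cohen's d
    and a degenerate flag (zero within-group variance gives p = 1, never an
    exception).  ``donor_handling``: 'gls' (compound-symmetry GLS with a
    consensus intra-donor correlation), 'fixed' (donor dummies; absorbs
    donor-level covariates) or 'none'.
    """
    ct_a, ct_b = contrast
    meta = matrix.samples
    keep = meta["cell_type"].isin(contrast)
    meta = meta[keep]
    for ct in contrast:
        if (meta["cell_type"] == ct).sum() < 3:
            raise ValueError(f"need >= 3 samples in group {ct}")
    levels = matrix.levels[meta.index]
    complete = levels.dropna()
    group = (meta["cell_type"] == ct_a).to_numpy(dtype=float)
    covs = tuple(covariates) + tuple(adar_covariates)
    X, names = _design_matrix(meta, group, covs, donor_dummies=(donor_handling == "fixed"))
    gi = names.index("group")
    Y = complete.to_numpy()

    n = len(meta)
    if donor_handling == "gls":
        # first pass: OLS residuals -> consensus intra-donor correlation
        beta_ols, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        resid = Y - (X @ beta_ols).T
        hat = X @ np.linalg.pinv(X)
        rho = estimate_consensus_correlation(resid, meta["donor"], hat=hat)
        same_donor = (meta["donor"].to_numpy()[:, None] == meta["donor"].to_numpy()[None, :])
        V = np.where(same_donor, rho, 0.0)
        np.fill_diagonal(V, 1.0)
        Vinv = np.linalg.inv(V)
    else:
        Vinv = np.eye(n)

    a_ids = meta.index[meta["cell_type"] == ct_a]
    b_ids = meta.index[meta["cell_type"] == ct_b]
    rows = []
    for sid, y in zip(complete.index, Y):
        va = complete.loc[sid, a_ids]
        vb = complete.loc[sid, b_ids]
        delta = float(va.mean() - vb.mean())
        degenerate = va.nunique() == 1 and vb.nunique() == 1
        if degenerate:
            t_stat, p = 0.0, 1.0
            d = 0.0
        else:
            beta, se, df = _gls_fit(y, X, Vinv)
            t_stat = beta[gi] / se[gi] if se[gi] > 0 else 0.0
            p = float(2 * sps.t.sf(abs(t_stat), df)) if se[gi] > 0 else 1.0
            try:
                d = cohens_d(va, vb)
            except ValueError:
                d = 0.0
        rows.append(
            {
                "site_id": sid,
                "contrast": f"{ct_a}_vs_{ct_b}",
                "delta": delta,
                "t": float(t_stat),
                "p": p,
                "cohens_d": d,
                "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(rows).set_index("site_id")
    out["fdr"] = bh_adjust(out["p"]) if len(out) else []
    out["significant"] = out["fdr"] < fdr_threshold
    return out


# ------------------------------------------------------------ specificity


def classify_specificity(
    detected: dict[str, set],
    requery: pd.DataFrame,
    differential: dict[tuple[str, str], pd.DataFrame],
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Assign each site a specific / enriched / shared label.

    ``detected`` maps cell type -> detected site ids; ``requery`` carries
    zero-class labels for single-cell-type sites; ``differential`` maps a
    contrast (A, B) to its result table with 'fdr' and 'delta' (mean A -
    mean B).  A specific site must have re-query evidence for the other
    cell types; an enriched site wins at least one significant contrast.
    """
    cts = list(detected)
    all_sites = sorted(set().union(*detected.values()))
    req = requery.set_index(["site_id", "cell_type"])["label"] if len(requery) else pd.Series(dtype=object)
    rows = []
    for sid in all_sites:
        present = [ct for ct in cts if sid in detected[ct]]
        if len(present) == 1:
            ct = present[0]
            evidence = {}
            for other in cts:
                if other == ct:
                    continue
                if (sid, other) not in req.index:
                    raise ValueError(f"site {sid} lacks re-query evidence for {other}")
                evidence[other] = req.loc[(sid, other)]
            rows.append({"site_id": sid, "label": f"specific:{ct}", "evidence": evidence})
            continue
        wins = []  # (fdr, winner)
        for (a, b), table in differential.items():
            if a not in present or b not in present or sid not in table.index:
                continue
            rec = table.loc[sid]
            if rec["fdr"] < fdr_threshold:
                winner = a if rec["delta"] > 0 else b
                wins.append((float(rec["fdr"]), winner, f"{a}_vs_{b}"))
        if wins:
            wins.sort()
            rows.append(
                {
                    "site_id": sid,
                    "label": f"enriched:{wins[0][1]}",
                    "evidence": {c: f for f, _, c in wins},
                }
            )
        else:
            rows.append({"site_id": sid, "label": "shared", "evidence": {}})
    return pd.DataFrame(rows).set_index("site_id")


# ------------------------------------------------------- variance partition


def variance_partition(
    levels: pd.DataFrame,
    factors: pd.DataFrame,
    categorical: tuple[str, ...] = ("cell_type", "donor"),
    max_condition: float = 1e8,
) -> pd.DataFrame:
    """Fraction of per-site editing variance attributable to each factor.

    Attribution is sequential: the designed grouping factor (cell type)
    first, by the unbiased between-group moment estimator (between-group
    variance of group means minus the within-group noise share); then the
    continuous factors in a joint linear fit on the residuals, each
    contributing Var(x_f beta_f); then the remaining grouping factors
    (donor), again by moments.  This avoids the exact collinearity of donor
    indicators with donor-level covariates while keeping the designed
    cell-type contrast from being soaked up by incidental sample-level
    covariates.  Fractions are clipped at 0 and normalized to sum to 1
    with the residual.  Collinear continuous factors raise an error naming
    the pair.
    """
    factors = factors.loc[levels.columns]
    cont = [c for c in factors.columns if c not in categorical]
    cat_first = [c for c in categorical[:1] if c in factors.columns]
    cat_last = [c for c in categorical[1:] if c in factors.columns]

    Xc = np.column_stack(
        [np.ones(len(factors))] + [pd.to_numeric(factors[c]).to_numpy(dtype=float) for c in cont]
    )
    norms = np.linalg.norm(Xc, axis=0)
    if np.linalg.cond(Xc / np.where(norms == 0, 1, norms)) > max_condition:
        worst, pair = 0.0, (cont[0], cont[0])
        for i, a in enumerate(cont):
            for b in cont[i + 1 :]:
                r = abs(np.corrcoef(factors[a].astype(float), factors[b].astype(float))[0, 1])
                if r > worst:
                    worst, pair = r, (a, b)
        raise ValueError(f"collinear factors: {pair[0]} and {pair[1]}")

    complete = levels.dropna()
    Y = complete.to_numpy().T  # samples x sites
    group_codes = {c: pd.factorize(factors[c])[0] for c in cat_first + cat_last}

    def _group_strip(r: np.ndarray, codes: np.ndarray) -> tuple[float, np.ndarray]:
        groups = [r[codes == g] for g in np.unique(codes)]
        means = np.array([g.mean() for g in groups])
        within = np.array([g.var(ddof=1) if len(g) > 1 else 0.0 for g in groups])
        k = np.mean([len(g) for g in groups])
        between = max(float(np.var(means, ddof=0) - within.mean() / k), 0.0)
        stripped = r.copy()
        for g, m in zip(np.unique(codes), means):
            stripped[codes == g] -= m
        return between, stripped

    rows = []
    for i, sid in enumerate(complete.index):
        var_parts: dict[str, float] = {}
        r = Y[:, i].copy()
        for c in cat_first:
            var_parts[c], r = _group_strip(r, group_codes[c])
        beta, *_ = np.linalg.lstsq(Xc, r, rcond=None)
        for j, c in enumerate(cont):
            var_parts[c] = float(np.var(Xc[:, j + 1] * beta[j + 1]))
        r = r - Xc @ beta
        for c in cat_last:
            var_parts[c], r = _group_strip(r, group_codes[c])
        var_resid = float(np.var(r))
        total = sum(var_parts.values()) + var_resid
        if total == 0:
            frac = {c: 0.0 for c in var_parts}
            frac["residual"] = 1.0
        else:
            frac = {c: v / total for c, v in var_parts.items()}
            frac["residual"] = var_resid / total
        rows.append({"site_id": sid, **frac})
    return pd.DataFrame(rows).set_index("site_id")


def adar_association(
    levels: pd.DataFrame,
    expression: pd.Series,
    donors: pd.Series,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-site regression of editing level on one ADAR's expression.

    Donor is adjusted for with fixed effects; slopes, p values and BH FDR
    are reported.  Constant expression is an error; a constant editing site
    gets slope 0, p = 1 and a degenerate flag.
    """
    expression = expression.loc[levels.columns].astype(float)
    if expression.nunique() <= 1:
        raise ValueError("ADAR expression is constant across samples")
    donors = donors.loc[levels.columns]
    Z = np.column_stack([np.ones(len(expression)), pd.get_dummies(donors, drop_first=True, dtype=float)])
    # Frisch-Waugh: residualize expression and levels against donor + intercept
    proj = Z @ np.linalg.pinv(Z)
    x_t = expression.to_numpy() - proj @ expression.to_numpy()
    xtx = float(x_t @ x_t)
    p_full = Z.shape[1] + 1
    df = len(expression) - p_full
    rows = []
    for sid, y in levels.dropna().iterrows():
        yv = y.to_numpy(dtype=float)
        if np.all(yv == yv[0]):
            rows.append({"site_id": sid, "slope": 0.0, "p": 1.0, "degenerate": True})
            continue
        y_t = yv - proj @ yv
        slope = float(x_t @ y_t) / xtx
        rss = float(((y_t - slope * x_t) ** 2).sum())
        se = np.sqrt(rss / df / xtx)
        t = slope / se if se > 0 else 0.0
        p = float(2 * sps.t.sf(abs(t), df)) if se > 0 else 1.0
        rows.append({"site_id": sid, "slope": slope, "p": p, "degenerate": False})
    out = pd.DataFrame(rows).set_index("site_id")
    out["fdr"] = bh_adjust(out["p"]) if len(out) else []
    out["significant"] = out["fdr"] < fdr_threshold
    return out


# ------------------------------------------------------------ gene density


def gene_editing_density(
    sites: pd.DataFrame,
    genes: list[Gene] | pd.DataFrame,
    interval: str = "normal",
) -> pd.DataFrame:
    """Editing density per gene: site count / log2(gene length + 1).

    Outliers lie beyond the 99% interval around the grand mean of the
    density distribution (normal-theory by default; ``interval='quantile'``
    uses the empirical [0.5%, 99.5%] band).
    """
    if isinstance(genes, pd.DataFrame):
        gtab = genes[["gene_id", "length"]].copy()
    else:
        gtab = pd.DataFrame({"gene_id": [g.gene_id for g in genes], "length": [g.length for g in genes]})
    if (gtab["length"] <= 0).any():
        raise ValueError("gene length must be positive")
    counts = sites.groupby("gene_id").size() if len(sites) else pd.Series(dtype=int)
    gtab["n_sites"] = gtab["gene_id"].map(counts).fillna(0).astype(int)
    gtab["density"] = gtab["n_sites"] / np.log2(gtab["length"] + 1)
    dens = gtab["density"].to_numpy()
    if len(dens) < 2:
        gtab["outlier"] = False
        return gtab.set_index("gene_id")
    if interval == "normal":
        z = sps.norm.ppf(0.995)
        lo, hi = dens.mean() - z * dens.std(ddof=1), dens.mean() + z * dens.std(ddof=1)
    elif interval == "quantile":
        lo, hi = np.quantile(dens, [0.005, 0.995])
    else:
        raise ValueError(f"unknown interval method {interval!r}")
    gtab["outlier"] = (gtab["density"] < lo) | (gtab["density"] > hi)
    return gtab.set_index("gene_id")


# ---------------------------------------------------------------- overlaps


def overlap_enrichment(set_a, set_b, background, odds_ratio_cap: float = 1e6) -> tuple[float, float]:
    """One-sided Fisher exact test for over-representation of A in B.

    The 2x2 table is (|A&B|, |A\\B|, |B\\A|, |bg\\(A|B)|); returns
    (odds ratio, p).  Division by an empty cell caps the odds ratio.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background set is empty")
    a, b = set(set_a) & bg, set(set_b) & bg
    n11 = len(a & b)
    n12 = len(a - b)
    n21 = len(b - a)
    n22 = len(bg - (a | b))
    _, p = sps.fisher_exact([[n11, n12], [n21, n22]], alternative="greater")
    if n12 * n21 == 0:
        orat = odds_ratio_cap if n11 * n22 > 0 else (0.0 if n11 == 0 else odds_ratio_cap)
    else:
        orat = (n11 * n22) / (n12 * n21)
    return float(min(orat, odds_ratio_cap)), float(p)


class _MergedIntervals:
    """Disjoint sorted intervals with O(log n) covered-length queries."""

    def __init__(self, intervals: list[tuple[int, int]]):
        merged = []
        for s, e in sorted(intervals):
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        self.starts = np.array([s for s, _ in merged], dtype=np.int64)
        self.ends = np.array([e for _, e in merged], dtype=np.int64)
        lens = self.ends - self.starts + 1
        self.cum = np.concatenate([[0], np.cumsum(lens)])

    def covered_up_to(self, x: np.ndarray) -> np.ndarray:
        """Total covered bases in (-inf, x]."""
        x = np.asarray(x, dtype=np.int64)
        i = np.searchsorted(self.starts, x, side="right")  # intervals starting <= x
        j = np.maximum(i - 1, 0)
        # full length of intervals before the one containing/preceding x,
        # plus the clipped overlap within that interval
        partial = np.clip(np.minimum(x, self.ends[j]) - self.starts[j] + 1, 0, None)
        return np.where(i > 0, self.cum[j] + partial, 0)

    def overlap(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        if len(self.starts) == 0:
            return np.zeros(len(starts), dtype=np.int64)
        return self.covered_up_to(ends) - self.covered_up_to(starts - 1)


def permutation_region_overlap(
    query: pd.DataFrame,
    target: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_perm: int = 1000,
    statistic: str = "bases",
    seed: int = 0,
) -> dict[str, float]:
    """Permutation test of regional overlap, regioneR-style.

    Each permutation redraws the query regions uniformly within their own
    chromosome, preserving lengths and per-chromosome counts; significance
    is p = (1 + #{perm >= observed}) / (n_perm + 1).  ``statistic`` is
    'bases' (total overlapping bases, default) or 'count' (number of query
    regions touching a target).
    """
    for df in (query, target):
        for r in df.itertuples():
            L = chrom_lengths[r.chrom]
            if r.end - r.start + 1 > L:
                raise ValueError(f"region {r.chrom}:{r.start}-{r.end} longer than its chromosome")

    merged = {
        chrom: _MergedIntervals(
            [(r.start, r.end) for r in target[target["chrom"] == chrom].itertuples()]
        )
        for chrom in target["chrom"].unique()
    }

    def _score(frames: dict[str, tuple[np.ndarray, np.ndarray]]) -> float:
        total = 0.0
        for chrom, (starts, ends) in frames.items():
            m = merged.get(chrom)
            if m is None:
                continue
            ov = m.overlap(starts, ends)
            total += float((ov > 0).sum()) if statistic == "count" else float(ov.sum())
        return total

    by_chrom = {}
    for chrom in query["chrom"].unique():
        sub = query[query["chrom"] == chrom]
        by_chrom[chrom] = (
            sub["start"].to_numpy(dtype=np.int64),
            sub["end"].to_numpy(dtype=np.int64),
        )
    observed = _score(by_chrom)

    rng = np.random.default_rng(seed)
    perm_scores = np.empty(n_perm)
    lengths = {c: e - s + 1 for c, (s, e) in by_chrom.items()}
    for b in range(n_perm):
        frames = {}
        for chrom, lens in lengths.items():
            L = chrom_lengths[chrom]
            starts = rng.integers(1, L - lens + 2)
            frames[chrom] = (starts, starts + lens - 1)
        perm_scores[b] = _score(frames)
    p = (1 + int((perm_scores >= observed).sum())) / (n_perm + 1)
    sd = perm_scores.std(ddof=1)
    z = (observed - perm_scores.mean()) / sd if sd > 0 else 0.0
    return {
        "observed": observed,
        "p": float(p),
        "z": float(z),
        "perm_mean": float(perm_scores.mean()),
        "perm_sd": float(sd),
    }
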