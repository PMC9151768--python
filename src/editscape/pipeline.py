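"""End-to-end drivers chaining the site-calling and cell-type stages."""

from __future__ import annotations

import pandas as pd

from .celltype import classify_specificity, differential_editing
from .genome import GenomeBundle
from .sites import (
    FilterReport,
    SiteMatrix,
    apply_filter_cascade,
    call_denovo,
    impute_missing_median,
    quantify_supervised,
    requery_other_celltypes,
)


def discover_and_classify(
    samples,
    genome: GenomeBundle,
    k: int = 8,
    n: int = 9,
    min_coverage: int = 10,
    min_edited: int = 3,
    min_ratio: float = 0.05,
    fdr_threshold: float = 0.05,
    covariates: tuple[str, ...] = ("age", "PMI"),
) -> tuple[pd.DataFrame, SiteMatrix, FilterReport]:
    """De novo discovery, filter cascade, re-query and specificity labels.

    Runs the full sorted-population workflow: candidate calling, the
    six-rule cascade, per-cell-type detection sets (>= k of n samples),
    third-round re-query of single-cell-type sites, covariate-adjusted
    differential editing for every cell-type pair on jointly detected
    sites, and specific/enriched/shared classification.  Returns
    (labels, retained site matrix, filter report).
    """
    cand = call_denovo(samples, genome, min_coverage=min_coverage, min_edited=min_edited, min_ratio=min_ratio)
    sm, report = apply_filter_cascade(
        cand, genome, k=k, n=n, min_coverage=min_coverage, min_edited=min_edited, min_ratio=min_ratio
    )
    if sm.sites.empty:
        return pd.DataFrame(columns=["label", "evidence"]), sm, report

    cell_types = sorted(sm.samples["cell_type"].dropna().unique())
    det_counts = {
        ct: sm.levels[sm.samples.index[sm.samples["cell_type"] == ct]].notna().sum(axis=1)
        for ct in cell_types
    }
    detected = {ct: set(sm.sites.index[det_counts[ct] >= k]) for ct in cell_types}

    in_n_types = pd.Series(0, index=sm.sites.index)
    for ct in cell_types:
        in_n_types[list(detected[ct])] += 1
    unique_ids = sorted(in_n_types.index[in_n_types == 1])
    requery = (
        requery_other_celltypes(
            sm.sites.loc[unique_ids].reset_index(), samples,
            min_coverage=min_coverage, min_edited=min_edited,
        )
        if unique_ids
        else pd.DataFrame(columns=["site_id", "cell_type", "label"])
    )

    quantified = quantify_supervised(
        samples, sm.sites.reset_index(), min_coverage=min_coverage, min_edited=min_edited
    )
    diffs = {}
    for i, ct_a in enumerate(cell_types):
        for ct_b in cell_types[i + 1 :]:
            shared_ids = sorted(detected[ct_a] & detected[ct_b])
            if not shared_ids:
                continue
            pair_ids = quantified.samples.index[quantified.samples["cell_type"].isin([ct_a, ct_b])]
            sub = quantified.subset_sites(shared_ids).subset_samples(list(pair_ids))
            for ct in (ct_a, ct_b):
                sub = impute_missing_median(sub, ct)
            diffs[(ct_a, ct_b)] = differential_editing(
                sub, (ct_a, ct_b), covariates=covariates, fdr_threshold=fdr_threshold
            )

    labels = classify_specificity(detected, requery, diffs, fdr_threshold=fdr_threshold)
    return labels, sm, report
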