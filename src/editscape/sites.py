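"""Editing-site quantification, the filter cascade, and site annotation.

Candidate sites come from two routes: de novo mismatch calling on pileups
and supervised quantification of a known-sites catalog.  Both feed the same
ordered filter cascade: (1) multi-allelic removal, (2) coverage/edited/ratio
thresholds, (3) blacklist and homopolymer exclusion, (4) common-SNP removal
(MAF > 0.05), (5) splice-site proximity (+-5 bp), (6) per-cell-type
detection rate (>= k of n samples).  A FilterReport records removals per
rule and always conserves counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome import Gene, GenomeBundle
from .simulate import SimulatedSample, site_id

GENIC_PRECEDENCE = ("CDS", "5'UTR", "3'UTR", "splice-adjacent", "intron", "downstream-TSS", "intergenic")

FILTER_RULES = (
    "multi-allelic",
    "thresholds",
    "blacklist-homopolymer",
    "common-snp",
    "splice-adjacent",
    "detection-rate",
)


@dataclass
class SiteMatrix:
    """Sites x samples editing levels with coverage, counts and metadata.

    ``levels`` holds edited/coverage in [0, 1] or NaN where a sample failed
    the calling thresholds; ``coverage`` and ``edited`` are always recorded
    (needed by the re-query step).
    """

    sites: pd.DataFrame  # index site_id; chrom, pos, strand, ...
    levels: pd.DataFrame  # site x sample
    coverage: pd.DataFrame
    edited: pd.DataFrame
    samples: pd.DataFrame  # index sample_id; cell_type, donor, covariates

    def validate(self) -> None:
        for m in (self.levels, self.coverage, self.edited):
            if m.shape != self.levels.shape or list(m.index) != list(self.levels.index):
                raise ValueError("matrices must share dimensions and site order")
        lv = self.levels.to_numpy()
        if np.nanmin(lv, initial=0.0) < 0 or np.nanmax(lv, initial=0.0) > 1:
            raise ValueError("editing levels must lie in [0, 1]")

    def subset_samples(self, sample_ids) -> "SiteMatrix":
        return SiteMatrix(
            sites=self.sites,
            levels=self.levels[sample_ids],
            coverage=self.coverage[sample_ids],
            edited=self.edited[sample_ids],
            samples=self.samples.loc[sample_ids],
        )

    def subset_sites(self, site_ids) -> "SiteMatrix":
        return SiteMatrix(
            sites=self.sites.loc[site_ids],
            levels=self.levels.loc[site_ids],
            coverage=self.coverage.loc[site_ids],
            edited=self.edited.loc[site_ids],
            samples=self.samples,
        )


@dataclass
class FilterReport:
    """Per-rule removal counts for one cascade run (order-faithful)."""

    input_count: int
    removed: list[tuple[str, int]] = field(default_factory=list)
    retained_count: int = 0

    def check_conservation(self) -> None:
        total = self.retained_count + sum(c for _, c in self.removed)
        if total != self.input_count:
            raise ValueError(
                f"filter report does not conserve counts: {self.input_count} in, "
                f"{total} accounted for"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "removed": c} for r, c in self.removed]
        rows.append({"rule": "retained", "removed": self.retained_count})
        return pd.DataFrame(rows)


def _edited_base(strand: str) -> str:
    """Reference base that an A>G edit reads as on the given site strand."""
    return "G" if strand == "+" else "C"


def _as_sample_list(samples) -> list[SimulatedSample]:
    if isinstance(samples, SimulatedSample):
        return [samples]
    return list(samples)


def _sample_meta(samples: list[SimulatedSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        rows.append({"sample_id": s.sample_id, "cell_type": s.cell_type, "donor": s.donor, **s.covariates})
    return pd.DataFrame(rows).set_index("sample_id")


def quantify_supervised(
    samples,
    site_list: pd.DataFrame,
    genome: GenomeBundle | None = None,
    min_coverage: int = 10,
    min_edited: int = 3,
) -> SiteMatrix:
    """Supervised quantification of a given site list across samples.

    A sample's editing level at a site is called only when coverage >=
    ``min_coverage`` and edited reads >= ``min_edited``; otherwise the level
    is missing but coverage/edited counts stay recorded for the re-query
    step.  Site positions must be adenosines of their stated strand when a
    genome is supplied.
    """
    samples = _as_sample_list(samples)
    sites = site_list.copy()
    if "site_id" not in sites.columns:
        sites["site_id"] = [site_id(c, p, s) for c, p, s in zip(sites["chrom"], sites["pos"], sites["strand"])]
    sites = sites.set_index("site_id")
    if genome is not None:
        for sid, r in sites.iterrows():
            if r["chrom"] not in genome.chromosomes or not (
                1 <= r["pos"] <= len(genome.chromosomes[r["chrom"]])
            ):
                raise ValueError(f"site {sid} lies outside the genome")
            if genome.strand_base(r["chrom"], r["pos"], r["strand"]) != "A":
                raise ValueError(f"site {sid} is not an adenosine on its stated strand")

    n, m = len(sites), len(samples)
    cov = np.zeros((n, m), dtype=int)
    edi = np.zeros((n, m), dtype=int)
    for j, s in enumerate(samples):
        p = s.pileup.set_index(["chrom", "pos"])
        for i, (_, r) in enumerate(sites.iterrows()):
            key = (r["chrom"], r["pos"])
            if key in p.index:
                row = p.loc[key]
                if isinstance(row, pd.DataFrame):
                    row = row.iloc[0]
                cov[i, j] = int(row["coverage"])
                edi[i, j] = int(row[_edited_base(r["strand"])])
    ids = [s.sample_id for s in samples]
    coverage = pd.DataFrame(cov, index=sites.index, columns=ids)
    edited = pd.DataFrame(edi, index=sites.index, columns=ids)
    with np.errstate(divide="ignore", invalid="ignore"):
        levels = edited / coverage.replace(0, np.nan)
    levels = levels.where((coverage >= min_coverage) & (edited >= min_edited))
    return SiteMatrix(sites=sites, levels=levels, coverage=coverage, edited=edited, samples=_sample_meta(samples))


def call_denovo(
    samples,
    genome: GenomeBundle | None = None,
    min_coverage: int = 10,
    min_edited: int = 3,
    min_ratio: float = 0.05,
    multiallelic_min_reads: int = 3,
    multiallelic_min_fraction: float = 0.01,
) -> pd.DataFrame:
    """De novo candidate calling: every qualifying mismatch, all 12 types.

    Returns one row per (sample, position) with the dominant alternate
    base; positions where two or more alternate bases each reach
    ``multiallelic_min_reads`` reads and ``multiallelic_min_fraction`` of
    coverage are flagged multi-allelic.
    """
    samples = _as_sample_list(samples)
    rows = []
    for s in samples:
        for r in s.pileup.itertuples():
            ref = r.ref
            cov = r.coverage
            if cov < min_coverage:
                continue
            counts = {"A": r.A, "C": r.C, "G": r.G, "T": r.T}
            alts = sorted(
                ((b, c) for b, c in counts.items() if b != ref and c > 0),
                key=lambda x: (-x[1], x[0]),
            )
            if not alts:
                continue
            alt, n_alt = alts[0]
            ratio = n_alt / cov
            if n_alt < min_edited or ratio < min_ratio:
                continue
            multi = (
                sum(
                    1
                    for _, c in alts
                    if c >= multiallelic_min_reads and c / cov >= multiallelic_min_fraction
                )
                >= 2
            )
            strand = "-" if (ref, alt) in (("T", "C"),) else "+"
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "cell_type": s.cell_type,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "strand": strand,
                    "ref": ref,
                    "alt": alt,
                    "substitution": f"{ref}>{alt}",
                    "coverage": cov,
                    "edited": n_alt,
                    "ratio": ratio,
                    "multi_allelic": multi,
                }
            )
    cols = [
        "sample_id",
        "cell_type",
        "chrom",
        "pos",
        "strand",
        "ref",
        "alt",
        "substitution",
        "coverage",
        "edited",
        "ratio",
        "multi_allelic",
    ]
    return pd.DataFrame(rows, columns=cols)


def apply_filter_cascade(
    candidates: pd.DataFrame,
    genome: GenomeBundle,
    k: int = 8,
    n: int = 9,
    min_coverage: int = 10,
    min_edited: int = 3,
    min_ratio: float = 0.05,
    max_snp_maf: float = 0.05,
    splice_within: int = 5,
) -> tuple[SiteMatrix, FilterReport]:
    """Ordered filter cascade over a long-format candidate table.

    ``candidates`` must carry sample_id, cell_type, chrom, pos, coverage,
    edited and (optionally) ratio and multi_allelic columns; a site removed
    by rule j is never re-counted by a later rule.  Rule 6 keeps a site iff
    some cell type detects it in >= k of its n samples, where a sample
    detects a site only when its own coverage/edited/ratio pass the
    thresholds.
    """
    if k > n:
        raise ValueError(f"detection rule k={k} exceeds group size n={n}")
    cand = candidates.copy()
    if "ratio" not in cand.columns:
        cand["ratio"] = cand["edited"] / cand["coverage"].replace(0, np.nan)
    if "multi_allelic" not in cand.columns:
        cand["multi_allelic"] = False
    if "strand" not in cand.columns:
        cand["strand"] = "+"
    cand["detects"] = (
        (cand["coverage"] >= min_coverage)
        & (cand["edited"] >= min_edited)
        & (cand["ratio"] >= min_ratio)
    )

    key_cols = ["chrom", "pos", "strand"]
    site_keys = cand[key_cols].drop_duplicates().reset_index(drop=True)
    report = FilterReport(input_count=len(site_keys))
    alive = pd.MultiIndex.from_frame(site_keys)
    cand_by_site = cand.set_index(key_cols, drop=False).sort_index()

    def _drop(rule: str, mask_drop: pd.Series):
        nonlocal alive
        removed = int(mask_drop.sum())
        report.removed.append((rule, removed))
        alive = alive[~mask_drop.to_numpy()]

    # (1) multi-allelic in any sample
    multi = cand.groupby(key_cols)["multi_allelic"].any()
    _drop("multi-allelic", multi.loc[alive])

    # (2) per-sample thresholds; site needs at least one detecting sample
    det_any = cand.groupby(key_cols)["detects"].any()
    _drop("thresholds", ~det_any.loc[alive])

    # (3) blacklist / homopolymer overlap
    def _site_mask(fn) -> pd.Series:
        return pd.Series([fn(c, p, s) for c, p, s in alive], index=alive)

    _drop(
        "blacklist-homopolymer",
        _site_mask(
            lambda c, p, s: genome.in_intervals(c, p, genome.blacklist_intervals)
            or genome.in_intervals(c, p, genome.homopolymer_intervals)
        ),
    )

    # (4) common genomic variants
    _drop(
        "common-snp",
        _site_mask(lambda c, p, s: (genome.snp_maf(c, p) or 0.0) > max_snp_maf),
    )

    # (5) splice-site proximity
    _drop("splice-adjacent", _site_mask(lambda c, p, s: genome.near_splice_site(c, p, within=splice_within)))

    # (6) detection in >= k of n samples for at least one cell type
    det = cand[cand["detects"]].groupby(key_cols + ["cell_type"]).size()
    max_det = det.groupby(level=key_cols).max() if len(det) else pd.Series(dtype=int)
    max_det = max_det.reindex(alive, fill_value=0)
    _drop("detection-rate", max_det < k)

    report.retained_count = len(alive)
    report.check_conservation()

    retained = cand_by_site.loc[cand_by_site.index.isin(alive)]
    sm = _matrix_from_candidates(retained, key_cols)
    return sm, report


def _matrix_from_candidates(cand: pd.DataFrame, key_cols) -> SiteMatrix:
    cand = cand.reset_index(drop=True)
    cand["site_id"] = [site_id(c, p, s) for c, p, s in zip(cand["chrom"], cand["pos"], cand["strand"])]
    sites = (
        cand[["site_id", "chrom", "pos", "strand"]]
        .drop_duplicates("site_id")
        .set_index("site_id")
        .sort_values(["chrom", "pos"])
    )
    coverage = (
        cand.pivot_table(index="site_id", columns="sample_id", values="coverage", aggfunc="first")
        .reindex(sites.index)
        .fillna(0)
        .astype(int)
    )
    edited = (
        cand.pivot_table(index="site_id", columns="sample_id", values="edited", aggfunc="first")
        .reindex(sites.index)
        .fillna(0)
        .astype(int)
    )
    detects = (
        cand.assign(detects=cand["detects"].astype(int))
        .pivot_table(index="site_id", columns="sample_id", values="detects", aggfunc="first")
        .reindex(sites.index)
        .reindex(columns=coverage.columns)
        .fillna(0)
        .astype(bool)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        levels = (edited / coverage.replace(0, np.nan)).where(detects)
    meta_cols = [c for c in ("cell_type", "donor") if c in cand.columns]
    meta = cand[["sample_id"] + meta_cols].drop_duplicates("sample_id").set_index("sample_id")
    meta = meta.reindex(coverage.columns)
    return SiteMatrix(sites=sites, levels=levels, coverage=coverage, edited=edited, samples=meta)


def requery_other_celltypes(
    unique_sites: pd.DataFrame,
    samples,
    min_coverage: int = 10,
    min_edited: int = 3,
) -> pd.DataFrame:
    """Third-round quantification of single-cell-type sites elsewhere.

    For each site detected in exactly one cell type, the other cell types
    are labeled ``covered-unedited`` when their median coverage is >=
    ``min_coverage`` with median edited reads < ``min_edited`` (high
    coverage, little-to-no editing), and ``insufficient-coverage``
    otherwise.  Returns a long table (site_id, cell_type, label, coverage,
    edited).
    """
    samples = _as_sample_list(samples)
    sm = quantify_supervised(samples, unique_sites, min_coverage=min_coverage, min_edited=min_edited)
    rows = []
    by_ct = sm.samples.groupby("cell_type").groups
    for sid in sm.sites.index:
        for ct, ids in by_ct.items():
            cov = float(sm.coverage.loc[sid, ids].median())
            edi = float(sm.edited.loc[sid, ids].median())
            label = "covered-unedited" if cov >= min_coverage and edi < min_edited else "insufficient-coverage"
            rows.append({"site_id": sid, "cell_type": ct, "label": label, "coverage": cov, "edited": edi})
    return pd.DataFrame(rows)


def impute_missing_median(matrix: SiteMatrix, group: str) -> SiteMatrix:
    """Median-impute missing levels within one cell type.

    Missing entries of samples belonging to ``group`` are replaced by the
    median of that site's observed levels within the same cell type;
    observed values are untouched.  A site with no observed value in the
    group is an error.
    """
    ids = matrix.samples.index[matrix.samples["cell_type"] == group]
    sub = matrix.levels[ids]
    all_missing = sub.isna().all(axis=1)
    if all_missing.any():
        bad = list(matrix.levels.index[all_missing])[:5]
        raise ValueError(f"sites missing in every {group} sample cannot be imputed: {bad}")
    medians = sub.median(axis=1)
    filled = sub.apply(lambda col: col.fillna(medians))
    levels = matrix.levels.copy()
    levels[ids] = filled
    return SiteMatrix(
        sites=matrix.sites,
        levels=levels,
        coverage=matrix.coverage,
        edited=matrix.edited,
        samples=matrix.samples,
    )


# ---------------------------------------------------------------- annotation


def _region_of(genome: GenomeBundle, chrom: str, pos: int, strand: str, tss_flank: int = 1_000) -> str:
    gene = None
    for g in genome.genes:
        if g.chrom == chrom and g.start <= pos <= g.end:
            if gene is None or g.strand == strand:
                gene = g
                if g.strand == strand:
                    break
    if gene is not None:
        for a, b in gene.cds:
            if a <= pos <= b:
                return "CDS"
        for a, b in gene.utr5:
            if a <= pos <= b:
                return "5'UTR"
        for a, b in gene.utr3:
            if a <= pos <= b:
                return "3'UTR"
        if genome.near_splice_site(chrom, pos, within=5):
            return "splice-adjacent"
        return "intron"
    for g in genome.genes:
        if g.chrom == chrom and abs(pos - g.tss) <= tss_flank:
            return "downstream-TSS"
    return "intergenic"


def _repeat_class(genome: GenomeBundle, chrom: str, pos: int) -> str:
    if genome.in_intervals(chrom, pos, genome.alu_intervals):
        return "Alu"
    if genome.in_intervals(chrom, pos, genome.l1_intervals):
        return "L1"
    return "none"


def _is_recoding(genome: GenomeBundle, gene: Gene, pos: int) -> bool:
    """Does editing the adenosine change the encoded amino acid?"""
    cds_pos = sorted(p for a, b in gene.cds for p in range(a, b + 1))
    if pos not in cds_pos:
        return False
    seq = "".join(genome.base(gene.chrom, p) for p in cds_pos)
    idx = cds_pos.index(pos)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        idx = len(seq) - 1 - idx
    codon_start = (idx // 3) * 3
    codon = list(seq[codon_start : codon_start + 3])
    if len(codon) < 3:
        return False
    offset = idx - codon_start
    if codon[offset] != "A":
        return False
    edited = codon.copy()
    edited[offset] = "G"
    return Seq("".join(codon)).translate() != Seq("".join(edited)).translate()


def annotate_sites(
    sites: pd.DataFrame,
    genome: GenomeBundle,
    catalog: set | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate sites with genic region, repeat class, catalog status, recoding.

    Genic precedence: CDS > 5'UTR > 3'UTR > splice-adjacent > intron >
    downstream-TSS > intergenic.  Catalog status is an exact
    (chrom, pos, strand) match.  C>T / G>A substitutions are tagged
    provisional.
    """
    if catalog is None:
        known = set()
    elif isinstance(catalog, pd.DataFrame):
        known = set(zip(catalog["chrom"], catalog["pos"], catalog["strand"]))
    else:
        known = set(catalog)
    out = sites.reset_index() if sites.index.name == "site_id" else sites.copy()
    if "site_id" not in out.columns:
        out["site_id"] = [site_id(c, p, s) for c, p, s in zip(out["chrom"], out["pos"], out["strand"])]
    regions, repeats, status, recoding, provisional = [], [], [], [], []
    for r in out.itertuples():
        region = _region_of(genome, r.chrom, r.pos, r.strand)
        regions.append(region)
        repeats.append(_repeat_class(genome, r.chrom, r.pos))
        status.append("known" if (r.chrom, r.pos, r.strand) in known else "not-in-catalog")
        rec = False
        if region == "CDS":
            gene = genome.gene_at(r.chrom, r.pos)
            if gene is not None:
                rec = _is_recoding(genome, gene, r.pos)
        recoding.append(rec)
        sub = getattr(r, "substitution", None)
        provisional.append(sub in ("C>T", "G>A"))
    out["genic_region"] = regions
    out["repeat_class"] = repeats
    out["catalog_status"] = status
    out["recoding"] = recoding
    out["provisional"] = provisional
    return out
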