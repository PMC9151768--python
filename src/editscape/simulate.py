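"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:
per-site binomial editing with cell-type-structured true rates, uniform
sequencing miscalls, hyper-edited reads carrying dense A>G runs, additive
genotype effects on editing levels, pseudo-bulk pools with reduced coverage
and a 3' coverage bias, and bulk tissue as noisy non-negative mixtures of
cell-type expression signatures.

Each operation takes an explicit ``seed`` and records it in its output, so
identical calls are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import COMPLEMENT, Gene, GenomeBundle

CELL_TYPES = ("MGE-GABA", "GLU", "OLIG")

SPECIFIC_CLASSES = tuple(f"specific:{ct}" for ct in CELL_TYPES)

DEFAULT_CLASS_PROPORTIONS = {
    "specific:MGE-GABA": 0.15,
    "specific:GLU": 0.15,
    "specific:OLIG": 0.15,
    "enriched": 0.20,
    "shared-equal": 0.20,
    "null": 0.15,
}

#: Editing levels of detectable selective sites: Beta(2,3) rescaled to
#: [0.10, 0.95].  The floor reflects that the pipeline's own 5% editing-ratio
#: threshold makes lower-level sites undetectable by definition.
DEFAULT_RATE_DIST = {"a": 2.0, "b": 3.0, "loc": 0.10, "scale": 0.85}


def site_id(chrom: str, pos: int, strand: str) -> str:
    return f"{chrom}:{pos}:{strand}"


@dataclass
class TruthTable:
    """Ground-truth editing rates per site per cell type.

    ``sites`` columns: site_id, chrom, pos, strand, gene_id, class_label and
    one ``rate_<cell type>`` column per cell type (values in [0, 1]).
    """

    sites: pd.DataFrame
    adar_scale: dict[str, float] = field(default_factory=dict)
    edqtl_effects: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)
    seed: int | None = None

    @property
    def rate_columns(self) -> list[str]:
        return [c for c in self.sites.columns if c.startswith("rate_")]

    def rates(self, cell_type: str) -> pd.Series:
        return self.sites.set_index("site_id")[f"rate_{cell_type}"]

    def validate(self) -> None:
        r = self.sites[self.rate_columns].to_numpy()
        if np.any((r < 0) | (r > 1)):
            raise ValueError("true editing rates must lie in [0, 1]")
        spec = self.sites["class_label"].str.startswith("specific:")
        nonzero = (r > 0).sum(axis=1)
        if np.any(nonzero[spec.to_numpy()] != 1):
            raise ValueError("a 'specific' site must have exactly one nonzero cell type")


@dataclass
class SimulatedSample:
    """One simulated library: a pileup table plus sample-level metadata."""

    sample_id: str
    cell_type: str
    donor: str
    covariates: dict[str, float | str]
    pileup: pd.DataFrame
    mapped_bases: int
    reads: list[tuple[str, str]] | None = None

    def __post_init__(self):
        if self.mapped_bases <= 0:
            raise ValueError("mapped-base count must be positive")


@dataclass
class GenotypeMatrix:
    """SNP x donor allele dosages with positions and minor-allele frequency."""

    snps: pd.DataFrame  # snp_id, chrom, pos, maf
    dosages: pd.DataFrame  # index snp_id, columns donor ids, values in [0, 2]

    def validate(self) -> None:
        d = self.dosages.to_numpy()
        if np.any((d < 0) | (d > 2)):
            raise ValueError("dosages must lie in [0, 2]")


# --------------------------------------------------------------------- truth


def _editable_positions(genome: GenomeBundle, avoid_filter_regions: bool, flank: int = 4):
    """Adenosines of the annotated strand inside gene bodies.

    With ``avoid_filter_regions`` the generator skips positions a faithful
    filter cascade would always discard (splice-adjacent, homopolymer,
    blacklist, common SNPs), so that planted sites are recoverable in
    principle.
    """
    out = []
    for g in genome.genes:
        L = len(genome.chromosomes[g.chrom])
        for pos in range(g.start, g.end + 1):
            if pos <= flank or pos > L - flank:
                continue
            if genome.strand_base(g.chrom, pos, g.strand) != "A":
                continue
            if avoid_filter_regions:
                if genome.near_splice_site(g.chrom, pos, within=5):
                    continue
                if genome.in_intervals(g.chrom, pos, genome.homopolymer_intervals):
                    continue
                if genome.in_intervals(g.chrom, pos, genome.blacklist_intervals):
                    continue
                maf = genome.snp_maf(g.chrom, pos)
                if maf is not None and maf > 0.05:
                    continue
            out.append((g.chrom, pos, g.strand, g.gene_id))
    return out


def _class_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n sites across classes."""
    if abs(sum(proportions.values()) - 1.0) > 1e-8:
        raise ValueError("class proportions must sum to 1")
    raw = {k: v * n for k, v in proportions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_editing_truth(
    genome: GenomeBundle,
    n_sites: int = 300,
    class_proportions: dict[str, float] | None = None,
    rate_dist: dict[str, float] | None = None,
    delta: float = 0.2,
    avoid_filter_regions: bool = True,
    seed: int = 0,
) -> TruthTable:
    """Plant editing sites on genic adenosines with class-structured rates.

    Classes: ``specific:<ct>`` (one cell type edits, the others are exactly
    zero), ``enriched`` (all cell types edit; one is higher by ``delta``
    before clipping), ``shared-equal`` (identical rates) and ``null``
    (never edited; these exercise the false-positive side of site calling).
    """
    rng = np.random.default_rng(seed)
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    dist = dict(rate_dist or DEFAULT_RATE_DIST)
    pool = _editable_positions(genome, avoid_filter_regions)
    if n_sites > len(pool):
        raise ValueError(f"requested {n_sites} sites but only {len(pool)} eligible adenosines")
    counts = _class_counts(props, n_sites)
    idx = rng.choice(len(pool), size=n_sites, replace=False)
    chosen = [pool[i] for i in idx]

    labels = [lbl for lbl, c in counts.items() for _ in range(c)]
    rng.shuffle(labels)

    base = dist["loc"] + dist["scale"] * rng.beta(dist["a"], dist["b"], size=n_sites)
    rows = []
    for (chrom, pos, strand, gene_id), lbl, r in zip(chosen, labels, base):
        rates = {ct: 0.0 for ct in CELL_TYPES}
        if lbl.startswith("specific:"):
            rates[lbl.split(":", 1)[1]] = r
        elif lbl == "enriched":
            hi, lo = rng.choice(CELL_TYPES, size=2, replace=False)
            for ct in CELL_TYPES:
                rates[ct] = r
            rates[hi] = min(r + delta, 1.0)
            lbl = f"enriched:{hi}"
        elif lbl == "shared-equal":
            for ct in CELL_TYPES:
                rates[ct] = r
        elif lbl != "null":
            raise ValueError(f"unknown class label {lbl!r}")
        rows.append(
            {
                "site_id": site_id(chrom, pos, strand),
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "gene_id": gene_id,
                "class_label": lbl,
                **{f"rate_{ct}": rates[ct] for ct in CELL_TYPES},
            }
        )
    sites = pd.DataFrame(rows).sort_values(["chrom", "pos"], ignore_index=True)
    tt = TruthTable(sites=sites, seed=seed)
    tt.validate()
    return tt


def alu_editing_truth(genome: GenomeBundle, rate: float) -> TruthTable:
    """A truth table editing every Alu adenosine at one shared rate.

    Convenience input for Alu-editing-index simulations.
    """
    rows = []
    for chrom, ivs in genome.alu_intervals.items():
        for start, end, strand in ivs:
            for pos in range(start, end + 1):
                if genome.strand_base(chrom, pos, strand) != "A":
                    continue
                rows.append(
                    {
                        "site_id": site_id(chrom, pos, strand),
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strand,
                        "gene_id": "",
                        "class_label": "shared-equal",
                        **{f"rate_{ct}": rate for ct in CELL_TYPES},
                    }
                )
    return TruthTable(sites=pd.DataFrame(rows))


# ------------------------------------------------------------------- pileups


def default_fans_design(n_donors: int = 9, seed: int = 0) -> pd.DataFrame:
    """Donor x cell-type sample sheet mirroring a 3-population FANS design.

    Covariates: age, PMI, pH, sex, RIN per donor; ADAR1/2/3 expression per
    sample with cell-type-level means (neurons above oligodendrocytes).
    """
    rng = np.random.default_rng(seed)
    donors = [f"D{i + 1}" for i in range(n_donors)]
    cov = {
        d: {
            "age": float(rng.uniform(25, 90)),
            "PMI": float(rng.uniform(5, 40)),
            "pH": float(rng.uniform(6.0, 7.0)),
            "sex": "M" if rng.random() < 0.5 else "F",
            "RIN": float(rng.uniform(6.0, 9.5)),
        }
        for d in donors
    }
    adar_mean = {
        "MGE-GABA": (40.0, 30.0, 12.0),
        "GLU": (42.0, 32.0, 10.0),
        "OLIG": (25.0, 15.0, 4.0),
    }
    rows = []
    for ct in CELL_TYPES:
        for d in donors:
            m1, m2, m3 = adar_mean[ct]
            rows.append(
                {
                    "sample_id": f"{d}_{ct}",
                    "cell_type": ct,
                    "donor": d,
                    **cov[d],
                    "ADAR1": float(max(rng.normal(m1, 4), 1.0)),
                    "ADAR2": float(max(rng.normal(m2, 4), 1.0)),
                    "ADAR3": float(max(rng.normal(m3, 2), 0.1)),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


def _pileup_rows(rng, records, mean_coverage, error_rate):
    """Binomial pileup counts for (chrom,pos,strand,ref,rate) records.

    Counts are reference-strand counts; editing on a minus-strand site
    appears as T>C on the reference.  Every row conserves
    coverage = A + C + G + T.
    """
    rows = []
    for chrom, pos, strand, ref, rate in records:
        cov = int(rng.poisson(mean_coverage))
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        if cov > 0:
            edited = int(rng.binomial(cov, min(max(rate, 0.0), 1.0)))
            edited_base = "G" if strand == "+" else "C"
            counts[edited_base] += edited
            rest = cov - edited
            n_err = int(rng.binomial(rest, error_rate)) if rest else 0
            counts[ref] += rest - n_err
            others = [b for b in "ACGT" if b != ref]
            for b in rng.choice(others, size=n_err):
                counts[b] += 1
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "ref": ref,
                **counts,
                "coverage": cov,
            }
        )
    return rows


def simulate_pileups(
    truth: TruthTable,
    genome: GenomeBundle,
    design: pd.DataFrame | None = None,
    mean_coverage: float = 100.0,
    error_rate: float = 0.001,
    n_background: int = 200,
    read_length: int = 100,
    seed: int = 0,
) -> list[SimulatedSample]:
    """Per-sample pileups at truth sites plus error-only background adenosines.

    Coverage ~ Poisson(mean); edited reads ~ Binomial(coverage, rate scaled
    by the sample's ADAR factor); unedited reads miscall uniformly at
    ``error_rate``.
    """
    if mean_coverage <= 0:
        raise ValueError("mean coverage must be positive")
    if not 0 <= error_rate <= 0.05:
        raise ValueError("error rate must lie in [0, 0.05]")
    rng = np.random.default_rng(seed)
    if design is None:
        design = default_fans_design(seed=seed)

    site_recs = [
        (r.chrom, r.pos, r.strand, "A" if r.strand == "+" else "T")
        for r in truth.sites.itertuples()
    ]
    taken = set(zip(truth.sites["chrom"], truth.sites["pos"]))
    bg_pool = [
        (c, p, s, "A" if s == "+" else "T")
        for (c, p, s, _g) in _editable_positions(genome, avoid_filter_regions=False)
        if (c, p) not in taken
    ]
    n_bg = min(n_background, len(bg_pool))
    bg_idx = rng.choice(len(bg_pool), size=n_bg, replace=False) if n_bg else []
    bg_recs = [bg_pool[i] for i in bg_idx]

    exonic = sum(g.length for g in genome.genes)
    samples = []
    for sid, meta in design.iterrows():
        ct = meta["cell_type"]
        scale = truth.adar_scale.get(sid, 1.0)
        rates = truth.sites[f"rate_{ct}"].to_numpy() * scale
        recs = [(c, p, s, ref, float(r)) for (c, p, s, ref), r in zip(site_recs, rates)]
        recs += [(c, p, s, ref, 0.0) for (c, p, s, ref) in bg_recs]
        pileup = pd.DataFrame(
            _pileup_rows(rng, recs, mean_coverage, error_rate)
        ).sort_values(["chrom", "pos"], ignore_index=True)
        samples.append(
            SimulatedSample(
                sample_id=sid,
                cell_type=ct,
                donor=meta["donor"],
                covariates={k: meta[k] for k in meta.index if k not in ("cell_type", "donor")},
                pileup=pileup,
                mapped_bases=int(mean_coverage * exonic * read_length // 100) or 1,
            )
        )
    return samples


# ------------------------------------------------------------- hyper-editing


@dataclass
class HyperReadSet:
    """Simulated reads plus the planted hyper-editing ground truth."""

    reads: list[tuple[str, str]]  # (read id, sequence as sequenced)
    truth_clusters: pd.DataFrame  # chrom, strand, start, end, n_sites
    truth_sites: pd.DataFrame  # chrom, pos, strand
    read_length: int
    seed: int


def simulate_hyperedited_reads(
    genome: GenomeBundle,
    n_clusters: int = 12,
    reads_per_cluster: int = 4,
    read_length: int = 100,
    cluster_density: float = 0.6,
    n_background_reads: int = 40,
    minus_fraction: float = 0.3,
    revcomp_fraction: float = 0.3,
    error_rate: float = 0.001,
    seed: int = 0,
) -> HyperReadSet:
    """Reads carrying dense A>G runs, mixed with error-only background reads.

    Each cluster is a genomic window emitting several overlapping reads in
    which ``cluster_density`` of the transcript-strand adenosines read as G
    (T>C on the reference for minus-strand clusters); per read, exactly
    ceil(density x #A) adenosines are converted at randomly chosen
    positions, so every hyper-edited read carries at least the configured
    fraction.  ``revcomp_fraction`` of reads are emitted
    reverse-complemented, emulating sequencing orientation.  The planted
    cluster span (min..max edited position) is recorded for recovery tests.
    """
    if read_length < 50:
        raise ValueError("read length must be >= 50")
    n_reads = n_clusters * reads_per_cluster
    if cluster_density == 0 and n_reads > 0:
        raise ValueError("cluster density 0 with hyper-edited reads requested is contradictory")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome.chromosomes)

    anchors: list[tuple[str, int]] = []
    tries = 0
    span = 2 * read_length
    while len(anchors) < n_clusters and tries < n_clusters * 200:
        tries += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = len(genome.chromosomes[chrom])
        start = int(rng.integers(1, L - span))
        if any(c == chrom and abs(s - start) < 4 * read_length for c, s in anchors):
            continue
        anchors.append((chrom, start))
    if len(anchors) < n_clusters:
        raise ValueError("could not place the requested clusters without collisions")

    reads: list[tuple[str, str]] = []
    cluster_rows, site_rows = [], []
    rid = 0
    for ci, (chrom, cstart) in enumerate(anchors):
        strand = "-" if rng.random() < minus_fraction else "+"
        target, mutated = ("A", "G") if strand == "+" else ("T", "C")
        edited_positions: set[int] = set()
        for _ in range(reads_per_cluster):
            offset = int(rng.integers(0, read_length // 2 + 1))
            start = cstart + offset
            template = list(genome.fetch(chrom, start, start + read_length - 1))
            a_idx = [i for i, b in enumerate(template) if b == target]
            n_edit = int(np.ceil(cluster_density * len(a_idx)))
            chosen = set(rng.choice(a_idx, size=n_edit, replace=False)) if n_edit else set()
            for i, b in enumerate(template):
                if i in chosen:
                    template[i] = mutated
                    edited_positions.add(start + i)
                elif rng.random() < error_rate:
                    template[i] = str(rng.choice([x for x in "ACGT" if x != b]))
            seq = "".join(template)
            if rng.random() < revcomp_fraction:
                seq = "".join(COMPLEMENT[b] for b in reversed(seq))
            reads.append((f"hyper_{rid}", seq))
            rid += 1
        if edited_positions:
            pos_sorted = sorted(edited_positions)
            cluster_rows.append(
                {
                    "chrom": chrom,
                    "strand": strand,
                    "start": pos_sorted[0],
                    "end": pos_sorted[-1],
                    "n_sites": len(pos_sorted),
                    "cluster_id": f"truth_{ci}",
                }
            )
            site_rows.extend({"chrom": chrom, "pos": p, "strand": strand} for p in pos_sorted)

    for bi in range(n_background_reads):
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = len(genome.chromosomes[chrom])
        start = int(rng.integers(1, L - read_length))
        template = list(genome.fetch(chrom, start, start + read_length - 1))
        for i, b in enumerate(template):
            if rng.random() < error_rate:
                template[i] = str(rng.choice([x for x in "ACGT" if x != b]))
        seq = "".join(template)
        if rng.random() < revcomp_fraction:
            seq = "".join(COMPLEMENT[b] for b in reversed(seq))
        reads.append((f"bg_{bi}", seq))

    return HyperReadSet(
        reads=reads,
        truth_clusters=pd.DataFrame(
            cluster_rows, columns=["chrom", "strand", "start", "end", "n_sites", "cluster_id"]
        ),
        truth_sites=pd.DataFrame(site_rows, columns=["chrom", "pos", "strand"]),
        read_length=read_length,
        seed=seed,
    )


# ------------------------------------------------------------- edQTL inputs


def simulate_genotypes_and_edqtl(
    truth: TruthTable,
    genome: GenomeBundle,
    n_donors: int = 150,
    maf_range: tuple[float, float] = (0.05, 0.5),
    beta: float = 0.08,
    n_edqtl: int = 20,
    n_null_snps: int = 80,
    max_snp_distance: int = 50_000,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Hardy-Weinberg genotypes plus additive cis effects on editing levels.

    ``n_edqtl`` truth sites receive a causal SNP within ``max_snp_distance``
    whose dosage shifts the donor's true rate by ``beta`` per allele
    (clipped to [0, 1]); ``n_null_snps`` additional SNPs carry no effect.
    """
    lo, hi = maf_range
    if not (0.05 <= lo <= hi <= 0.5):
        raise ValueError("MAF range must lie within [0.05, 0.5]")
    rng = np.random.default_rng(seed)
    donors = [f"G{i + 1}" for i in range(n_donors)]

    editable = truth.sites[truth.sites["class_label"] != "null"]
    n_edqtl = min(n_edqtl, len(editable))
    target_idx = rng.choice(editable.index.to_numpy(), size=n_edqtl, replace=False)

    snp_rows, dosage_rows, effect_rows = [], [], []
    warnings: list[str] = []

    def _draw_dosages(maf):
        p = np.array([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2])
        return rng.choice([0, 1, 2], size=n_donors, p=p)

    for k, ti in enumerate(target_idx):
        site = truth.sites.loc[ti]
        L = len(genome.chromosomes[site["chrom"]])
        offset = int(rng.integers(-max_snp_distance, max_snp_distance + 1))
        pos = int(np.clip(site["pos"] + offset, 1, L))
        maf = float(rng.uniform(lo, hi))
        snp_id = f"snp_q{k}"
        snp_rows.append({"snp_id": snp_id, "chrom": site["chrom"], "pos": pos, "maf": maf})
        dosage_rows.append(_draw_dosages(maf))
        effect_rows.append({"snp_id": snp_id, "site_id": site["site_id"], "beta": beta})
        base = max(site[f"rate_{ct}"] for ct in CELL_TYPES)
        if np.all(np.clip(base + beta * np.array([0, 1, 2]), 0, 1) == np.clip(base, 0, 1)):
            warnings.append(f"effect on {site['site_id']} fully clipped at the bounds")

    for k in range(n_null_snps):
        chrom = sorted(genome.chromosomes)[int(rng.integers(len(genome.chromosomes)))]
        L = len(genome.chromosomes[chrom])
        maf = float(rng.uniform(lo, hi))
        snp_id = f"snp_n{k}"
        snp_rows.append({"snp_id": snp_id, "chrom": chrom, "pos": int(rng.integers(1, L + 1)), "maf": maf})
        dosage_rows.append(_draw_dosages(maf))

    snps = pd.DataFrame(snp_rows)
    dosages = pd.DataFrame(
        np.array(dosage_rows), index=snps["snp_id"].to_list(), columns=donors
    )
    geno = GenotypeMatrix(snps=snps, dosages=dosages)
    geno.validate()

    updated = TruthTable(
        sites=truth.sites.copy(),
        adar_scale=dict(truth.adar_scale),
        edqtl_effects=pd.DataFrame(effect_rows, columns=["snp_id", "site_id", "beta"]),
        warnings=list(truth.warnings) + warnings,
        seed=truth.seed,
    )
    return geno, updated


def simulate_donor_editing_levels(
    truth: TruthTable,
    genotypes: GenotypeMatrix,
    noise_sd: float = 0.05,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk per-donor editing levels carrying the planted cis effects.

    Returns (site x donor level matrix, donor covariate table with sex, age,
    RIN and death type).  A donor's level is the site's maximal cell-type
    rate plus beta x dosage for its causal SNP, Gaussian noise of
    ``noise_sd``, clipped to [0, 1]; ``missing_rate`` entries are masked.
    """
    rng = np.random.default_rng(seed)
    donors = list(genotypes.dosages.columns)
    effects = (
        truth.edqtl_effects.set_index("site_id")
        if truth.edqtl_effects is not None and len(truth.edqtl_effects)
        else pd.DataFrame(columns=["snp_id", "beta"])
    )
    base = truth.sites.set_index("site_id")[[f"rate_{ct}" for ct in CELL_TYPES]].max(axis=1)
    keep = base[base > 0]
    levels = np.empty((len(keep), len(donors)))
    for i, (sid, b) in enumerate(keep.items()):
        mu = np.full(len(donors), b)
        if sid in effects.index:
            eff = effects.loc[sid]
            mu = mu + eff["beta"] * genotypes.dosages.loc[eff["snp_id"]].to_numpy()
        levels[i] = np.clip(mu + rng.normal(0, noise_sd, size=len(donors)), 0, 1)
    mat = pd.DataFrame(levels, index=keep.index, columns=donors)
    if missing_rate > 0:
        mask = rng.random(mat.shape) < missing_rate
        mat = mat.mask(mask)
    covars = pd.DataFrame(
        {
            "sex": rng.choice(["M", "F"], size=len(donors)),
            "age": rng.uniform(25, 90, size=len(donors)),
            "RIN": rng.uniform(5.5, 9.5, size=len(donors)),
            "death_type": rng.choice(["fast", "intermediate", "slow"], size=len(donors)),
        },
        index=donors,
    )
    return mat, covars


# --------------------------------------------------------- pseudo-bulk pools


def simulate_pseudobulk_pools(
    truth: TruthTable,
    genome: GenomeBundle,
    n_replicates: int = 3,
    nuclei_per_pool: int = 100,
    coverage_per_nucleus: float = 0.3,
    bias_strength: float = 0.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> list[SimulatedSample]:
    """Pseudo-bulk pools: pooled nuclei, low coverage, optional 3' bias.

    Mean coverage at a site is ``nuclei_per_pool * coverage_per_nucleus *
    exp(-bias_strength * d3 / gene length)`` where ``d3`` is the distance
    from the site to its gene's 3' end; editing rates are inherited from the
    pool's cell-type truth.
    """
    if nuclei_per_pool <= 0 or n_replicates <= 0:
        raise ValueError("pool sizes must be positive")
    rng = np.random.default_rng(seed)
    genes = {g.gene_id: g for g in genome.genes}
    samples = []
    exonic = sum(g.length for g in genome.genes)
    site_info = list(
        zip(
            truth.sites["chrom"],
            truth.sites["pos"],
            truth.sites["strand"],
            truth.sites["gene_id"],
        )
    )
    rel_d3 = []
    for chrom, pos, strand, gid in site_info:
        g: Gene | None = genes.get(gid)
        if g is not None and g.length > 1:
            rel_d3.append(abs(g.three_prime_end - pos) / g.length)
        else:
            rel_d3.append(0.0)
    for ct in CELL_TYPES:
        rates = truth.sites[f"rate_{ct}"].to_numpy()
        for rep in range(n_replicates):
            rows = []
            for (chrom, pos, strand, _gid), d3, rate in zip(site_info, rel_d3, rates):
                mean_cov = nuclei_per_pool * coverage_per_nucleus * np.exp(-bias_strength * d3)
                ref = "A" if strand == "+" else "T"
                rows.extend(
                    _pileup_rows(rng, [(chrom, pos, strand, ref, float(rate))], mean_cov, error_rate)
                )
            pileup = pd.DataFrame(rows).sort_values(["chrom", "pos"], ignore_index=True)
            samples.append(
                SimulatedSample(
                    sample_id=f"pool_{ct}_rep{rep + 1}",
                    cell_type=ct,
                    donor=f"pooldonor{rep + 1}",
                    covariates={},
                    pileup=pileup,
                    mapped_bases=max(int(nuclei_per_pool * coverage_per_nucleus * exonic), 1),
                )
            )
    return samples


# ------------------------------------------------------------- bulk mixtures


def make_signature(
    n_genes: int = 200,
    cell_types: tuple[str, ...] = (
        "astrocyte",
        "oligodendrocyte",
        "microglia",
        "endothelial",
        "excitatory",
        "inhibitory",
    ),
    markers_per_type: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """A gene x cell-type expression signature with exclusive marker blocks."""
    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1}" for i in range(n_genes)]
    sig = pd.DataFrame(
        rng.uniform(0.5, 3.0, size=(n_genes, len(cell_types))), index=genes, columns=cell_types
    )
    for j, ct in enumerate(cell_types):
        block = slice(j * markers_per_type, (j + 1) * markers_per_type)
        sig.iloc[block, :] = rng.uniform(0.0, 0.5, size=(markers_per_type, len(cell_types)))
        sig.iloc[block, j] = rng.uniform(8.0, 15.0, size=markers_per_type)
    return sig


def simulate_bulk_mixtures(
    signature: pd.DataFrame,
    fractions: pd.DataFrame,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Bulk expression = signature . fractions + Gaussian noise, floored at 0.

    ``fractions`` is sample x cell type and each row must sum to 1.
    """
    if (fractions.to_numpy() < 0).any():
        raise ValueError("fractions must be non-negative")
    sums = fractions.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-8):
        raise ValueError("fractions must sum to 1 per sample")
    if list(fractions.columns) != list(signature.columns):
        fractions = fractions[signature.columns]
    rng = np.random.default_rng(seed)
    clean = signature.to_numpy() @ fractions.to_numpy().T
    noisy = clean + rng.normal(0, noise_sd, size=clean.shape)
    return pd.DataFrame(
        np.maximum(noisy, 0.0), index=signature.index, columns=fractions.index
    )
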