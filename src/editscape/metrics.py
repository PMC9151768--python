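"""Global editing metrics: Alu editing index, hyper-editing, local motifs.

The hyper-editing detector re-aligns reads that fail normal alignment after
collapsing the edited base pair: all A are rewritten to G in both reads and
genome (and T to C for the antisense pass), hyper-edited reads then match
exactly, and restoring the original sequences reveals the A>G mismatch run.
Alignment uses exact k-mer seeding with ungapped extension, which is
adequate for the desk-scale genomes this package targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import COMPLEMENT, GenomeBundle


@dataclass
class GlobalMetrics:
    """Per-sample global editing summary."""

    sample_id: str
    aei: float
    n_hyper_sites: int
    mapped_bases: int

    @property
    def normalized_he_rate(self) -> float:
        return normalized_he_rate(self.n_hyper_sites, self.mapped_bases)


@dataclass(frozen=True)
class HyperCluster:
    """A contiguous run of hyper-edited adenosines with supporting reads."""

    chrom: str
    strand: str
    start: int
    end: int
    sites: tuple[int, ...]
    read_ids: tuple[str, ...]
    mean_spacing: float

    def __post_init__(self):
        if not (self.start <= min(self.sites) <= max(self.sites) <= self.end):
            raise ValueError("cluster bounds must bracket its member sites")
        if list(self.sites) != sorted(self.sites):
            raise ValueError("member sites must be sorted")


def compute_aei(pileup: pd.DataFrame, alu_intervals: dict[str, list[tuple[int, int, str]]]) -> float:
    """Alu editing index: edited reads over total adenosine coverage in Alus.

    Strand-aware: a plus-strand Alu contributes G reads at reference-A
    positions; a minus-strand Alu contributes C reads at reference-T
    positions.  Raises when no covered Alu adenosine exists.
    """
    edited = 0
    total = 0
    for r in pileup.itertuples():
        for iv in alu_intervals.get(r.chrom, []):
            start, end = iv[0], iv[1]
            strand = iv[2] if len(iv) > 2 else "+"
            if start <= r.pos <= end:
                if strand == "+" and r.ref == "A":
                    edited += r.G
                    total += r.coverage
                elif strand == "-" and r.ref == "T":
                    edited += r.C
                    total += r.coverage
                break
    if total == 0:
        raise ValueError("no Alu adenosine coverage: AEI undefined")
    return edited / total


def normalized_he_rate(n_sites: int, mapped_bases: int) -> float:
    """Hyper-editing sites per million mapped bases: n / MM * 1e6."""
    if mapped_bases <= 0:
        raise ValueError("mapped-base count must be positive")
    return n_sites / mapped_bases * 1e6


# ----------------------------------------------------------- hyper-editing


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


class _TransformedIndex:
    """Exact k-mer index over a base-collapsed genome."""

    def __init__(self, genome: GenomeBundle, src: str, dst: str, k: int):
        self.k = k
        self.src, self.dst = src, dst
        self.seqs = {c: s.replace(src, dst) for c, s in genome.chromosomes.items()}
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, s in self.seqs.items():
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                hits = self.index.setdefault(kmer, [])
                if len(hits) < 4:  # enough to recognise ambiguity
                    hits.append((chrom, i))

    def candidates(self, read_t: str) -> set[tuple[str, int]]:
        k, L = self.k, len(read_t)
        cands = set()
        for off in (0, L // 2, L - k):
            if off < 0:
                continue
            for chrom, i in self.index.get(read_t[off : off + k], []):
                start = i - off
                if start >= 0 and start + L <= len(self.seqs[chrom]):
                    cands.add((chrom, start))
        return cands

    def mismatches(self, read_t: str, chrom: str, start: int) -> int:
        ref = self.seqs[chrom][start : start + len(read_t)]
        return sum(1 for a, b in zip(read_t, ref) if a != b)


def detect_hyperediting(
    reads: list[tuple[str, str]],
    genome: GenomeBundle,
    min_sites: int = 5,
    min_fraction: float = 0.6,
    max_mismatch_fraction: float = 0.9,
    kmer_size: int = 16,
    max_transformed_mismatches: int = 3,
    max_cluster_gap: int = 100,
    min_sites_per_cluster: int = 5,
    max_snp_maf: float = 0.05,
) -> tuple[pd.DataFrame, list[HyperCluster], dict[str, int]]:
    """Detect hyper-edited reads and cluster their A>G sites.

    A read qualifies when, after unique transformed alignment, it carries
    >= ``min_sites`` A>G mismatches covering >= ``min_fraction`` of the
    adenosines in its window while total mismatches stay <=
    ``max_mismatch_fraction`` of its length.  Cluster boundaries are
    extended by the mean inter-site distance and overlapping clusters are
    merged (idempotent); sites at common SNPs (MAF > ``max_snp_maf``) are
    dropped.  Returns (site table, clusters, alignment report).
    """
    passes = {
        "+": _TransformedIndex(genome, "A", "G", kmer_size),
        "-": _TransformedIndex(genome, "T", "C", kmer_size),
    }
    report = {"aligned": 0, "ambiguous": 0, "unaligned": 0, "hyper_reads": 0}
    site_support: dict[tuple[str, str, int], set[str]] = {}

    for read_id, seq in reads:
        hits = []
        for strand, idx in passes.items():
            src, dst = idx.src, idx.dst
            for oriented in (seq, _revcomp(seq)):
                read_t = oriented.replace(src, dst)
                for chrom, start in idx.candidates(read_t):
                    if idx.mismatches(read_t, chrom, start) <= max_transformed_mismatches:
                        hits.append((strand, oriented, chrom, start))
        loci = {(h[2], h[3]) for h in hits}
        if not hits:
            report["unaligned"] += 1
            continue
        if len(loci) > 1:
            report["ambiguous"] += 1
            continue
        report["aligned"] += 1
        strand, oriented, chrom, start = hits[0]
        ref = genome.chromosomes[chrom][start : start + len(oriented)]
        target, mutated = ("A", "G") if strand == "+" else ("T", "C")
        edit_pos = []
        n_mismatch = 0
        n_target = 0
        for i, (rb, gb) in enumerate(zip(oriented, ref)):
            if gb == target:
                n_target += 1
            if rb != gb:
                n_mismatch += 1
                if gb == target and rb == mutated:
                    edit_pos.append(start + i + 1)  # back to 1-based
        if (
            len(edit_pos) >= min_sites
            and n_target > 0
            and len(edit_pos) / n_target >= min_fraction
            and n_mismatch / len(oriented) <= max_mismatch_fraction
        ):
            report["hyper_reads"] += 1
            for p in edit_pos:
                maf = genome.snp_maf(chrom, p)
                if maf is not None and maf > max_snp_maf:
                    continue
                site_support.setdefault((chrom, strand, p), set()).add(read_id)

    site_rows = [
        {"chrom": c, "strand": s, "pos": p, "n_reads": len(ids)}
        for (c, s, p), ids in sorted(site_support.items())
    ]
    sites = pd.DataFrame(site_rows, columns=["chrom", "strand", "pos", "n_reads"])

    clusters = _build_clusters(site_support, max_cluster_gap, min_sites_per_cluster)
    return sites, clusters, report


def _build_clusters(site_support, max_gap: int, min_sites: int) -> list[HyperCluster]:
    by_region: dict[tuple[str, str], list[int]] = {}
    for chrom, strand, pos in site_support:
        by_region.setdefault((chrom, strand), []).append(pos)

    raw = []
    for (chrom, strand), positions in sorted(by_region.items()):
        positions = sorted(positions)
        run = [positions[0]]
        for p in positions[1:]:
            if p - run[-1] <= max_gap:
                run.append(p)
            else:
                raw.append((chrom, strand, run))
                run = [p]
        raw.append((chrom, strand, run))

    extended = []
    for chrom, strand, run in raw:
        if len(run) < min_sites:
            continue
        spacing = float(np.mean(np.diff(run))) if len(run) > 1 else 0.0
        extended.append(
            {
                "chrom": chrom,
                "strand": strand,
                "start": max(1, int(np.floor(run[0] - spacing))),
                "end": int(np.ceil(run[-1] + spacing)),
                "sites": list(run),
                "spacing": spacing,
            }
        )

    merged = merge_clusters(extended)
    out = []
    for m in merged:
        sites_sorted = tuple(sorted(m["sites"]))
        read_ids = sorted(
            {rid for p in sites_sorted for rid in site_support[(m["chrom"], m["strand"], p)]}
        )
        spacing = float(np.mean(np.diff(sites_sorted))) if len(sites_sorted) > 1 else 0.0
        out.append(
            HyperCluster(
                chrom=m["chrom"],
                strand=m["strand"],
                start=m["start"],
                end=m["end"],
                sites=sites_sorted,
                read_ids=tuple(read_ids),
                mean_spacing=spacing,
            )
        )
    return out


def merge_clusters(clusters: list[dict]) -> list[dict]:
    """Merge overlapping extended clusters per (chrom, strand); idempotent."""
    by_region: dict[tuple[str, str], list[dict]] = {}
    for c in clusters:
        by_region.setdefault((c["chrom"], c["strand"]), []).append(c)
    out = []
    for (chrom, strand), group in sorted(by_region.items()):
        group = sorted(group, key=lambda c: (c["start"], c["end"]))
        current = dict(group[0], sites=list(group[0]["sites"]))
        for c in group[1:]:
            if c["start"] <= current["end"]:
                current["end"] = max(current["end"], c["end"])
                current["sites"].extend(c["sites"])
            else:
                out.append(current)
                current = dict(c, sites=list(c["sites"]))
        out.append(current)
    return out


# ------------------------------------------------------------------- motifs


def extend_cluster_bounds(sites: list[int]) -> tuple[int, int, float]:
    """[min, max] extended by the mean inter-site distance on both ends."""
    sites = sorted(sites)
    spacing = float(np.mean(np.diff(sites))) if len(sites) > 1 else 0.0
    return int(np.floor(sites[0] - spacing)), int(np.ceil(sites[-1] + spacing)), spacing


def motif_profile(
    sites: pd.DataFrame,
    genome: GenomeBundle,
    flank: int = 4,
    pseudocount: float = 1.0,
    log2_cap: float = 8.0,
    max_background: int = 50_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Nucleotide frequencies around edited adenosines, vs genomic background.

    Sequences are read on the site strand (reverse-complemented for '-'),
    so the centre position is 100% A by construction.  Enrichment is
    log2(observed / background) over genome-wide adenosine contexts, with
    ``pseudocount`` in every cell and values capped at +-``log2_cap``.
    Sites whose flank leaves the chromosome are skipped and reported.
    """
    positions = list(range(-flank, flank + 1))
    obs = np.zeros((len(positions), 4))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    skipped: list[str] = []
    for r in sites.itertuples():
        L = len(genome.chromosomes[r.chrom])
        if r.pos - flank < 1 or r.pos + flank > L:
            skipped.append(f"{r.chrom}:{r.pos}:{r.strand}")
            continue
        ctx = genome.fetch(r.chrom, r.pos - flank, r.pos + flank)
        if r.strand == "-":
            ctx = _revcomp(ctx)
        for i, b in enumerate(ctx):
            obs[i, base_idx[b]] += 1

    if obs.sum() == 0:
        raise ValueError("no site has full flanks inside its chromosome")

    rng = np.random.default_rng(seed)
    bg = np.zeros_like(obs)
    contexts = []
    for chrom, seq in genome.chromosomes.items():
        for strand, target in (("+", "A"), ("-", "T")):
            arr = np.frombuffer(seq.encode(), dtype="S1")
            hits = np.flatnonzero(arr == target.encode()) + 1
            hits = hits[(hits > flank) & (hits <= len(seq) - flank)]
            contexts.extend((chrom, int(p), strand) for p in hits)
    if len(contexts) > max_background:
        keep = rng.choice(len(contexts), size=max_background, replace=False)
        contexts = [contexts[i] for i in keep]
    for chrom, pos, strand in contexts:
        ctx = genome.fetch(chrom, pos - flank, pos + flank)
        if strand == "-":
            ctx = _revcomp(ctx)
        for i, b in enumerate(ctx):
            bg[i, base_idx[b]] += 1

    freq = obs / obs.sum(axis=1, keepdims=True)
    obs_p = (obs + pseudocount) / (obs + pseudocount).sum(axis=1, keepdims=True)
    bg_p = (bg + pseudocount) / (bg + pseudocount).sum(axis=1, keepdims=True)
    enrich = np.clip(np.log2(obs_p / bg_p), -log2_cap, log2_cap)
    freq_df = pd.DataFrame(freq, index=positions, columns=list("ACGT"))
    enrich_df = pd.DataFrame(enrich, index=positions, columns=list("ACGT"))
    return freq_df, enrich_df, skipped
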