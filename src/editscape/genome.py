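"""Synthetic genomes with gene models, repeats and variant annotations.

All coordinates in this package are 1-based and intervals are closed on both
ends (the pileup/VCF convention); BED export converts to 0-based half-open at
the boundary.  Sites are always described on the annotated transcript strand:
an editing site inside a minus-strand gene appears as T>C on the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASES = np.array(["A", "C", "G", "T"])
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class Gene:
    """A gene model: sorted, non-overlapping exons on one strand.

    ``tss`` is the first transcribed base (gene start on '+', gene end on
    '-').  ``cds``, ``utr5`` and ``utr3`` partition the exonic bases.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...]
    utr3: tuple[tuple[int, int], ...]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def three_prime_end(self) -> int:
        return self.end if self.strand == "+" else self.start

    def splice_sites(self) -> list[int]:
        """Internal exon boundaries (donor/acceptor positions)."""
        out = []
        for i in range(len(self.exons) - 1):
            out.append(self.exons[i][1])
            out.append(self.exons[i + 1][0])
        return out


@dataclass
class GenomeBundle:
    """A small reference genome plus the annotations the pipeline consumes.

    Interval lists are per-chromosome; Alu/L1 intervals carry the strand on
    which the element is annotated (Alu elements are A-rich on that strand,
    so the Alu-editing-index denominator is never empty).
    """

    chromosomes: dict[str, str]
    genes: list[Gene]
    alu_intervals: dict[str, list[tuple[int, int, str]]]
    l1_intervals: dict[str, list[tuple[int, int, str]]]
    blacklist_intervals: dict[str, list[tuple[int, int]]]
    homopolymer_intervals: dict[str, list[tuple[int, int]]]
    splice_sites: dict[str, list[int]]
    snp_positions: list[tuple[str, int, float]]
    seed: int | None = None
    _snp_index: dict[tuple[str, int], float] = field(default=None, repr=False, compare=False)

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.chromosomes[chrom][pos - 1]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Reference sequence for a 1-based closed interval."""
        return self.chromosomes[chrom][start - 1 : end]

    def strand_base(self, chrom: str, pos: int, strand: str) -> str:
        b = self.base(chrom, pos)
        return b if strand == "+" else COMPLEMENT[b]

    def snp_maf(self, chrom: str, pos: int) -> float | None:
        if self._snp_index is None:
            self._snp_index = {(c, p): m for c, p, m in self.snp_positions}
        return self._snp_index.get((chrom, pos))

    def gene_at(self, chrom: str, pos: int) -> Gene | None:
        """The gene whose span contains the position (first match)."""
        for g in self.genes:
            if g.chrom == chrom and g.start <= pos <= g.end:
                return g
        return None

    def near_splice_site(self, chrom: str, pos: int, within: int = 5) -> bool:
        return any(abs(pos - s) <= within for s in self.splice_sites.get(chrom, []))

    def in_intervals(self, chrom: str, pos: int, intervals: dict) -> bool:
        for iv in intervals.get(chrom, []):
            if iv[0] <= pos <= iv[1]:
                return True
        return False

    # ------------------------------------------------------------------ I/O
    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.chromosomes):
                fh.write(f">{name}\n")
                seq = self.chromosomes[name]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def serialize(self) -> str:
        """Deterministic text rendering (used for byte-identity checks)."""
        parts = []
        for name in sorted(self.chromosomes):
            parts.append(f">{name}\n{self.chromosomes[name]}")
        for g in self.genes:
            parts.append(
                f"gene\t{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t"
                f"{g.exons}\t{g.cds}\t{g.utr5}\t{g.utr3}"
            )
        for label, ivs in (
            ("alu", self.alu_intervals),
            ("l1", self.l1_intervals),
            ("blacklist", self.blacklist_intervals),
            ("homopolymer", self.homopolymer_intervals),
        ):
            for chrom in sorted(ivs):
                for iv in ivs[chrom]:
                    parts.append(f"{label}\t{chrom}\t{iv}")
        for chrom in sorted(self.splice_sites):
            parts.append(f"splice\t{chrom}\t{sorted(self.splice_sites[chrom])}")
        for c, p, m in self.snp_positions:
            parts.append(f"snp\t{c}\t{p}\t{m:.6f}")
        return "\n".join(parts) + "\n"

    def write_bed(self, path, which: str) -> None:
        """Write an interval track as BED (0-based half-open)."""
        ivs = getattr(self, f"{which}_intervals")
        with open(path, "w") as fh:
            for chrom in sorted(ivs):
                for iv in ivs[chrom]:
                    strand = iv[2] if len(iv) > 2 else "."
                    fh.write(f"{chrom}\t{iv[0] - 1}\t{iv[1]}\t{which}\t.\t{strand}\n")


def _random_seq(rng: np.random.Generator, n: int, p=(0.3, 0.2, 0.2, 0.3)) -> np.ndarray:
    return rng.choice(BASES, size=n, p=p)


def build_synthetic_genome(
    chrom_lengths: dict[str, int] | None = None,
    n_genes_per_chrom: int = 8,
    alu_density: float = 0.08,
    l1_density: float = 0.02,
    n_blacklist_per_chrom: int = 2,
    n_homopolymers_per_chrom: int = 10,
    n_snps_per_chrom: int = 40,
    gene_length: tuple[int, int] = (2_000, 6_000),
    n_exons: int = 3,
    seed: int = 0,
) -> GenomeBundle:
    """Generate a deterministic synthetic genome with annotations.

    Alu elements (~300 bp) are rewritten to be A-rich on their annotated
    strand; homopolymer runs (>=6 bp) are planted and recorded; SNP positions
    get minor-allele frequencies spanning the 0.05 filter boundary.

    Raises ``ValueError`` when the requested genes cannot fit on a
    chromosome or a chromosome is shorter than 10 kb.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 100_000, "chr2": 100_000}
    for name, L in chrom_lengths.items():
        if L < 10_000:
            raise ValueError(f"chromosome {name} shorter than 10 kb ({L})")
    rng = np.random.default_rng(seed)

    chromosomes: dict[str, np.ndarray] = {}
    genes: list[Gene] = []
    alu: dict[str, list] = {}
    l1: dict[str, list] = {}
    blacklist: dict[str, list] = {}
    homopoly: dict[str, list] = {}
    splice: dict[str, list] = {}
    snps: list[tuple[str, int, float]] = []

    for chrom in sorted(chrom_lengths):
        L = int(chrom_lengths[chrom])
        seq = _random_seq(rng, L)

        # genes laid out in evenly spaced slots with flanking gaps
        slot = L // max(n_genes_per_chrom, 1)
        min_glen = gene_length[0]
        if n_genes_per_chrom > 0 and slot < min_glen + 400:
            raise ValueError(
                f"cannot fit {n_genes_per_chrom} genes of >= {min_glen} bp "
                f"on {chrom} ({L} bp)"
            )
        splice[chrom] = []
        for gi in range(n_genes_per_chrom):
            lo = gi * slot + 200
            glen = int(rng.integers(gene_length[0], min(gene_length[1], slot - 400) + 1))
            gstart = int(rng.integers(lo, lo + max(slot - glen - 400, 1)))
            gend = gstart + glen - 1
            strand = "+" if rng.random() < 0.5 else "-"
            # split the span into n_exons exons separated by introns
            # cut points on a 100 bp grid so every exon/intron is >= 100 bp
            grid = np.arange(1, glen // 100 - 1)
            cuts = np.sort(rng.choice(grid, size=2 * (n_exons - 1), replace=False)) * 100
            bounds = [0] + [int(c) for c in cuts] + [glen]
            exons = []
            for k in range(n_exons):
                a = gstart + bounds[2 * k]
                b = gstart + bounds[2 * k + 1] - 1
                if k == n_exons - 1:
                    b = gend
                exons.append((a, max(a, b)))
            exons = tuple(exons)
            # UTRs at transcript ends, CDS in between (exonic partition)
            first, last = (exons[0], exons[-1]) if strand == "+" else (exons[-1], exons[0])
            u5_len = min(100, first[1] - first[0])
            u3_len = min(300, last[1] - last[0])
            if strand == "+":
                utr5 = ((first[0], first[0] + u5_len - 1),)
                utr3 = ((last[1] - u3_len + 1, last[1]),)
            else:
                utr5 = ((first[1] - u5_len + 1, first[1]),)
                utr3 = ((last[0], last[0] + u3_len - 1),)
            cds = []
            for (a, b) in exons:
                lo_c, hi_c = a, b
                for (ua, ub) in (utr5[0], utr3[0]):
                    if ua <= lo_c <= ub:
                        lo_c = ub + 1
                    if ua <= hi_c <= ub:
                        hi_c = ua - 1
                if lo_c <= hi_c:
                    cds.append((lo_c, hi_c))
            tss = gstart if strand == "+" else gend
            g = Gene(
                gene_id=f"{chrom}_g{gi + 1}",
                chrom=chrom,
                strand=strand,
                tss=tss,
                exons=exons,
                cds=tuple(cds),
                utr5=utr5,
                utr3=utr3,
            )
            genes.append(g)
            splice[chrom].extend(g.splice_sites())

        # repeats: non-overlapping placements drawn left to right
        alu[chrom], l1[chrom] = [], []
        n_alu = int(alu_density * L / 300)
        n_l1 = int(l1_density * L / 1_000)
        taken: list[tuple[int, int]] = []

        def _place(length_range, n_elems):
            placed = []
            tries = 0
            while len(placed) < n_elems and tries < n_elems * 50:
                tries += 1
                length = int(rng.integers(*length_range))
                start = int(rng.integers(1, L - length))
                end = start + length - 1
                if any(s <= end and start <= e for s, e in taken):
                    continue
                taken.append((start, end))
                placed.append((start, end))
            return placed

        for start, end in _place((250, 351), n_alu):
            strand = "+" if rng.random() < 0.5 else "-"
            rich = "A" if strand == "+" else "T"
            comp = {b: 0.45 if b == rich else 0.55 / 3 for b in "ACGT"}
            seq[start - 1 : end] = rng.choice(BASES, size=end - start + 1, p=[comp[b] for b in "ACGT"])
            alu[chrom].append((start, end, strand))
        for start, end in _place((800, 1_501), n_l1):
            strand = "+" if rng.random() < 0.5 else "-"
            l1[chrom].append((start, end, strand))

        blacklist[chrom] = []
        for _ in range(n_blacklist_per_chrom):
            start = int(rng.integers(1, L - 500))
            blacklist[chrom].append((start, start + int(rng.integers(200, 500))))

        homopoly[chrom] = []
        for _ in range(n_homopolymers_per_chrom):
            run = int(rng.integers(6, 11))
            start = int(rng.integers(1, L - run))
            base = str(rng.choice(BASES))
            seq[start - 1 : start - 1 + run] = base
            homopoly[chrom].append((start, start + run - 1))

        pos_pool = rng.choice(np.arange(1, L + 1), size=n_snps_per_chrom, replace=False)
        for p in np.sort(pos_pool):
            maf = float(rng.uniform(0.005, 0.5))
            snps.append((chrom, int(p), maf))

        chromosomes[chrom] = "".join(seq)

    return GenomeBundle(
        chromosomes=chromosomes,
        genes=genes,
        alu_intervals=alu,
        l1_intervals=l1,
        blacklist_intervals=blacklist,
        homopolymer_intervals=homopoly,
        splice_sites={c: sorted(set(v)) for c, v in splice.items()},
        snp_positions=snps,
        seed=seed,
    )
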