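"""Independent brute-force oracles and hand-built fixtures for the tests.

Everything here is deliberately naive (per-site predicate evaluation, plain
loops) and shares no code with the package's vectorised implementations.
"""

import numpy as np
import pandas as pd

from editscape.genome import GenomeBundle


def make_toy_genome(n_sites: int, seed: int):
    """An all-adenosine chromosome whose annotations exercise every rule boundary.

    Returns (genome, candidate long table, per-site attribute table).  Site i
    sits at position 100 + 150*i; attributes sweep coverage 9/10/11, edited
    2/3, ratio 4.9/5.0/5.1%, splice distance 4/5/6 bp, SNP MAF 0.04/0.06,
    multi-allelic flags, and detection in 7/8/9 of 9 samples of one cell type.
    """
    rng = np.random.default_rng(seed)
    L = 100 + 150 * n_sites + 1_000
    positions = [100 + 150 * i for i in range(n_sites)]
    attrs = pd.DataFrame(
        {
            "pos": positions,
            "coverage": rng.choice([9, 10, 11], n_sites),
            "edited": rng.choice([2, 3], n_sites),
            "ratio": rng.choice([0.049, 0.050, 0.051], n_sites),
            "splice_dist": rng.choice([4, 5, 6, -1], n_sites),  # -1: no splice site nearby
            "maf": rng.choice([np.nan, 0.04, 0.06], n_sites),
            "multi": rng.choice([False, False, False, True], n_sites),
            "in_blacklist": rng.choice([False, False, False, True], n_sites),
            "in_homopolymer": rng.choice([False, False, False, True], n_sites),
            "n_detect": rng.choice([7, 8, 9], n_sites),
        }
    )
    splice = [int(p - d) for p, d in zip(attrs["pos"], attrs["splice_dist"]) if d > 0]
    snps = [("toy", int(p), float(m)) for p, m in zip(attrs["pos"], attrs["maf"]) if not np.isnan(m)]
    blacklist = [(int(p) - 1, int(p) + 1) for p, b in zip(attrs["pos"], attrs["in_blacklist"]) if b]
    homopoly = [(int(p), int(p)) for p, h in zip(attrs["pos"], attrs["in_homopolymer"]) if h]
    genome = GenomeBundle(
        chromosomes={"toy": "A" * L},
        genes=[],
        alu_intervals={"toy": []},
        l1_intervals={"toy": []},
        blacklist_intervals={"toy": blacklist},
        homopolymer_intervals={"toy": homopoly},
        splice_sites={"toy": sorted(splice)},
        snp_positions=snps,
    )
    rows = []
    for r in attrs.itertuples():
        for j in range(9):
            passing = j < r.n_detect
            rows.append(
                {
                    "sample_id": f"S{j}",
                    "cell_type": "CT1",
                    "chrom": "toy",
                    "pos": r.pos,
                    "strand": "+",
                    "ref": "A",
                    "alt": "G",
                    "coverage": r.coverage if passing else 5,
                    "edited": r.edited if passing else 0,
                    "ratio": r.ratio if passing else 0.0,
                    "multi_allelic": bool(r.multi),
                }
            )
    return genome, pd.DataFrame(rows), attrs


def brute_force_cascade(attrs: pd.DataFrame, k: int = 8) -> tuple[set, dict]:
    """Sequential per-predicate evaluation of the six filter rules."""
    removed = {r: 0 for r in (
        "multi-allelic", "thresholds", "blacklist-homopolymer", "common-snp",
        "splice-adjacent", "detection-rate",
    )}
    retained = set()
    for r in attrs.itertuples():
        sample_detects = r.coverage >= 10 and r.edited >= 3 and r.ratio >= 0.05
        if r.multi:
            removed["multi-allelic"] += 1
        elif not sample_detects:  # no sample can detect: failing samples have cov 5
            removed["thresholds"] += 1
        elif r.in_blacklist or r.in_homopolymer:
            removed["blacklist-homopolymer"] += 1
        elif not np.isnan(r.maf) and r.maf > 0.05:
            removed["common-snp"] += 1
        elif 0 < r.splice_dist <= 5:
            removed["splice-adjacent"] += 1
        elif r.n_detect < k:
            removed["detection-rate"] += 1
        else:
            retained.add(("toy", int(r.pos), "+"))
    return retained, removed


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up, O(n^2)-naive."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = n - rank_from_end
        running_min = min(running_min, p[idx] * n / rank)
        adj[idx] = running_min
    return adj


def brute_force_hypergeom_tail(n11, n12, n21, n22) -> float:
    """Exhaustive one-sided Fisher tail: P(X >= n11) by direct summation."""
    from math import comb

    N = n11 + n12 + n21 + n22
    K = n11 + n12  # size of A
    M = n11 + n21  # size of B
    total = comb(N, K)
    p = 0.0
    for x in range(n11, min(K, M) + 1):
        p += comb(M, x) * comb(N - M, K - x) / total
    return p
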