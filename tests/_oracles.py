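"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately written from first principles (explicit
loops, rank definitions, set algebra) and shares no code with the package
paths it checks.
"""

from __future__ import annotations

import math

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def brute_force_cytosine_scan(reference: dict[str, str], k: int):
    """Enumerate (chrom, pos, strand, context, kmer) over both strands."""

    def context_of(two: str) -> str | None:
        if len(two) != 2 or "N" in two:
            return None
        if two[0] == "G":
            return "CpG"
        if two[1] == "G":
            return "CHG"
        return "CHH"

    flank = k // 2
    out = set()
    for chrom, seq in reference.items():
        n = len(seq)
        # forward strand
        for pos in range(n):
            if seq[pos] != "C":
                continue
            ctx = context_of(seq[pos + 1 : pos + 3]) if pos + 2 < n else None
            if ctx is None:
                continue
            if pos - flank < 0 or pos + flank + 1 > n:
                continue
            kmer = seq[pos - flank : pos + flank + 1]
            if "N" in kmer:
                continue
            out.add((chrom, pos, "+", ctx, kmer))
        # reverse strand: scan the reverse complement with forward logic
        rc = revcomp(seq)
        for rpos in range(n):
            if rc[rpos] != "C":
                continue
            ctx = context_of(rc[rpos + 1 : rpos + 3]) if rpos + 2 < n else None
            if ctx is None:
                continue
            if rpos - flank < 0 or rpos + flank + 1 > n:
                continue
            kmer = rc[rpos - flank : rpos + flank + 1]
            if "N" in kmer:
                continue
            out.add((chrom, n - 1 - rpos, "-", ctx, kmer))
    return out


def two_pass_mean_std(values) -> tuple[float, float]:
    """Textbook two-pass mean and population standard deviation."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, math.sqrt(var)


def evenly_spaced_subsample(values, m: int):
    """Index-formula oracle for signal subsampling when len > m."""
    n = len(values)
    return [values[(i * n) // m] for i in range(m)]


def pearson_r(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    return pearson_r(midranks(x), midranks(y))


def rmse(x, y) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)) / len(x))


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the normalized Mann-Whitney U with midrank tie handling."""
    ranks = midranks(scores)
    n_pos = sum(1 for l in labels if l == 1)
    n_neg = len(labels) - n_pos
    rank_sum_pos = sum(r for r, l in zip(ranks, labels) if l == 1)
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2
    return u / (n_pos * n_neg)


def balance_counts_oracle(pos_kmers, neg_kmers) -> dict[str, tuple[int, int]]:
    """Expected per-kmer bounds after negative balancing.

    Returns kmer -> (max kept negatives for shared kmers, available).
    """
    pos_counts = {}
    for k in pos_kmers:
        pos_counts[k] = pos_counts.get(k, 0) + 1
    neg_counts = {}
    for k in neg_kmers:
        neg_counts[k] = neg_counts.get(k, 0) + 1
    out = {}
    for k, n_avail in neg_counts.items():
        if k in pos_counts:
            out[k] = (min(pos_counts[k], n_avail), n_avail)
    return out


def select_sites_oracle(reports, context, min_cov=5, meth_min=0.9, rule="union"):
    """Replicate-combination set algebra for high-confidence site selection."""
    meth_sets, unmeth_sets = [], []
    nonzero = set()
    for report in reports:
        meth, unmeth = set(), set()
        for rec in report:
            if rec.context != context:
                continue
            key = (rec.chrom, rec.pos, rec.strand)
            cov = rec.count_methylated + rec.count_unmethylated
            if rec.count_methylated > 0:
                nonzero.add(key)
            if cov < min_cov:
                continue
            freq = rec.count_methylated / cov
            if freq >= meth_min:
                meth.add(key)
            elif freq == 0.0:
                unmeth.add(key)
        meth_sets.append(meth)
        unmeth_sets.append(unmeth)
    if rule == "intersection":
        methylated = set.intersection(*meth_sets)
        unmethylated = set.intersection(*unmeth_sets)
    else:
        methylated = set.union(*meth_sets)
        unmethylated = set.union(*unmeth_sets) - nonzero
    return methylated - unmethylated, unmethylated - methylated
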