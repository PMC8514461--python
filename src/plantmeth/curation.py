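"""Training-set curation: high-confidence site selection, k-mer balancing,
and iterative denoising.

High-confidence training sites come from bisulfite sequencing: a cytosine
with at least ``min_coverage`` mapped reads and methylation frequency of at
least ``meth_freq_min`` is a positive; one with at least ``min_coverage``
reads and zero frequency in every replicate is a negative.  Positives are
combined across replicates by intersection (CpG, where replicate agreement
is demanded) or union (CHG/CHH, where positives are scarce).

Because the k-mer composition of positive and negative sites differs —
sharply so for CHH — negatives are balanced against positives per k-mer
before training, so the classifier cannot exploit sequence composition alone
to separate the classes.

Positives selected at frequency >= 0.9 can still contain unmethylated
molecules.  The iterative denoising procedure repeatedly two-fold
cross-predicts the training set with freshly trained models, averages each
sample's methylation score over R rounds, removes positives scoring below
0.5, rebalances the negatives, and stops after I iterations or once at
least ``retention_stop`` of the iteration's positives survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .io_formats import BisulfiteSiteRecord

logger = logging.getLogger(__name__)

SiteKey = tuple[str, int, str]

# fit_score(train, to_score, epochs, seed) -> P_m for to_score, in order
FitScore = Callable[[Sequence, Sequence, int, int], np.ndarray]

DEFAULT_REPLICATE_RULES = {"CpG": "intersection", "CHG": "union", "CHH": "union"}


@dataclass
class CurationConfig:
    min_coverage: int = 5
    meth_freq_min: float = 0.9
    unmeth_freq_max: float = 0.0
    replicate_rules: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_REPLICATE_RULES))
    max_samples: int = 20_000_000
    denoise_iterations: int = 10  # I
    denoise_rounds: int = 3  # R
    denoise_epochs: int = 3  # E
    retention_stop: float = 0.99

    def __post_init__(self) -> None:
        if not 0.0 <= self.unmeth_freq_max < self.meth_freq_min <= 1.0:
            raise ValueError("need 0 <= unmeth_freq_max < meth_freq_min <= 1")
        if min(self.denoise_iterations, self.denoise_rounds, self.denoise_epochs) < 1:
            raise ValueError("I, R and E must all be >= 1")


@dataclass
class HighConfidenceSets:
    methylated: set[SiteKey]
    unmethylated: set[SiteKey]
    context: str


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def select_high_confidence_sites(
    reports: Sequence[Sequence[BisulfiteSiteRecord]],
    context: str,
    cfg: CurationConfig = CurationConfig(),
) -> HighConfidenceSets:
    """Select high-confidence methylated / unmethylated sites of one context.

    ``reports`` holds one record list per bisulfite replicate.  Positives
    qualify per replicate (coverage >= min_coverage, frequency >=
    meth_freq_min) and are combined by the context's replicate rule.
    Negatives must qualify in at least one replicate (coverage >=
    min_coverage, frequency <= unmeth_freq_max) and show zero methylated
    reads in every replicate that covers them.
    """
    if len(reports) == 0:
        raise ValueError("at least one bisulfite report is required")
    rule = cfg.replicate_rules.get(context, "union")
    meth_per_rep: list[set[SiteKey]] = []
    unmeth_per_rep: list[set[SiteKey]] = []
    nonzero_anywhere: set[SiteKey] = set()
    for report in reports:
        meth: set[SiteKey] = set()
        unmeth: set[SiteKey] = set()
        for rec in report:
            if rec.context != context:
                continue
            key = (rec.chrom, rec.pos, rec.strand)
            if rec.count_methylated > 0:
                nonzero_anywhere.add(key)
            freq = rec.frequency
            if freq is None or rec.coverage < cfg.min_coverage:
                continue
            if freq >= cfg.meth_freq_min:
                meth.add(key)
            elif freq <= cfg.unmeth_freq_max:
                unmeth.add(key)
        meth_per_rep.append(meth)
        unmeth_per_rep.append(unmeth)
    if rule == "intersection":
        methylated = set.intersection(*meth_per_rep)
        unmethylated = set.intersection(*unmeth_per_rep)
    else:
        methylated = set.union(*meth_per_rep)
        # qualify in >=1 replicate, zero methylated reads in all replicates
        unmethylated = set.union(*unmeth_per_rep) - nonzero_anywhere
    methylated -= unmethylated & methylated  # defensive; cannot overlap by construction
    unmethylated -= methylated
    return HighConfidenceSets(methylated=methylated, unmethylated=unmethylated, context=context)


def balance_negative_samples(s_pos: Sequence, s_neg: Sequence, rng_seed=0) -> list:
    """Balance negatives against positives per k-mer.

    For every k-mer shared by both sets, at most as many negatives as there
    are positives of that k-mer are kept (drawn at random).  If the result is
    smaller than the positive set, the deficit is filled at random from
    k-mers present only in the negatives.  Output size is at most |s_pos|
    unless the negatives run out first.
    """
    rng = _as_rng(rng_seed)
    pos_counts: dict[str, int] = {}
    for s in s_pos:
        pos_counts[s.kmer] = pos_counts.get(s.kmer, 0) + 1
    neg_by_kmer: dict[str, list] = {}
    for s in s_neg:
        neg_by_kmer.setdefault(s.kmer, []).append(s)

    out: list = []
    for kmer in sorted(set(pos_counts) & set(neg_by_kmer)):
        pool = neg_by_kmer[kmer]
        want = pos_counts[kmer]
        if len(pool) <= want:
            out.extend(pool)
        else:
            idx = rng.choice(len(pool), size=want, replace=False)
            out.extend(pool[i] for i in sorted(idx))
    deficit = len(s_pos) - len(out)
    if deficit > 0:
        extra_pool = [s for kmer in sorted(set(neg_by_kmer) - set(pos_counts)) for s in neg_by_kmer[kmer]]
        if extra_pool:
            take = min(deficit, len(extra_pool))
            idx = rng.choice(len(extra_pool), size=take, replace=False)
            out.extend(extra_pool[i] for i in sorted(idx))
    return out


def subsample_training_set(
    s_pos: Sequence, s_neg: Sequence, max_samples: int = 20_000_000, rng_seed=0
) -> tuple[list, list]:
    """Random half-positive / half-negative subsample of at most max_samples.

    Each class is capped at max_samples // 2; a class smaller than its cap is
    kept whole (the other class does not fill the gap, preserving balance).
    """
    rng = _as_rng(rng_seed)
    cap = max_samples // 2

    def take(pool: Sequence) -> list:
        if len(pool) <= cap:
            return list(pool)
        idx = rng.choice(len(pool), size=cap, replace=False)
        return [pool[i] for i in sorted(idx)]

    return take(s_pos), take(s_neg)


def denoise_samples(
    samples: Sequence,
    fit_score: FitScore,
    cfg: CurationConfig = CurationConfig(),
    rng_seed=0,
) -> tuple[list, list[dict]]:
    """Iteratively remove suspect positives by two-fold cross-prediction.

    Per iteration: R rounds of a random half/half split, training a fresh
    model on each half and scoring the other, accumulate each sample's
    methylation probability; positives with mean score < 0.5 are removed;
    negatives are rebalanced against the surviving positives; stop after I
    iterations or when the iteration retains >= ``retention_stop`` of its
    positives.

    Returns the denoised sample list and a per-iteration log with the
    retained-positive fraction.
    """
    rng = _as_rng(rng_seed)
    pos = [s for s in samples if s.label == 1]
    neg = [s for s in samples if s.label == 0]
    if not pos or not neg:
        raise ValueError("denoising needs both positive and negative samples")
    history: list[dict] = []
    for iteration in range(1, cfg.denoise_iterations + 1):
        current = pos + neg
        n = len(current)
        scores = np.zeros(n)
        for _ in range(cfg.denoise_rounds):
            order = rng.permutation(n)
            half = n // 2
            idx1, idx2 = order[:half], order[half:]
            s1 = [current[i] for i in idx1]
            s2 = [current[i] for i in idx2]
            seed1 = int(rng.integers(2**31))
            seed2 = int(rng.integers(2**31))
            scores[idx2] += fit_score(s1, s2, cfg.denoise_epochs, seed1)
            scores[idx1] += fit_score(s2, s1, cfg.denoise_epochs, seed2)
        mean_scores = scores / cfg.denoise_rounds
        p_total = len(pos)
        kept = [s for s, sc in zip(current, mean_scores) if s.label == 1 and sc >= 0.5]
        pos = kept
        neg = balance_negative_samples(pos, neg, rng)
        retention = len(pos) / p_total
        history.append({"iteration": iteration, "retained": len(pos), "retention": retention})
        logger.info("denoise iteration %d: retained %d/%d positives (%.3f)", iteration, len(pos), p_total, retention)
        if retention >= cfg.retention_stop:
            break
    return pos + neg, history
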