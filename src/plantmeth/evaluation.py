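"""Site-level and read-level evaluation against bisulfite truth.

Site-level: per-site methylation frequencies from nanopore calls are joined
with a bisulfite cytosine report on (chrom, pos, strand), both sides
filtered to at least ``min_coverage`` mapped reads, and compared with
Pearson r (plus r^2), Spearman rho, and RMSE.

Read-level: per-read methylation probabilities for samples whose truth
labels come from fully methylated (frequency 1) and fully unmethylated
(frequency 0) bisulfite sites are scored with accuracy, sensitivity,
specificity and AUC on class-balanced random subsamples, repeated several
times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .calling import SiteFrequency
from .io_formats import BisulfiteSiteRecord


class UndefinedCorrelationError(ValueError):
    """Raised when fewer than two joined sites are available."""


@dataclass
class EvalReport:
    n_sites: int
    pearson_r: float
    r_squared: float
    spearman_rho: float
    rmse: float
    per_context: dict[str, "EvalReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n_sites": self.n_sites,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "spearman_rho": self.spearman_rho,
            "rmse": self.rmse,
        }
        if self.per_context:
            out["per_context"] = {ctx: rep.to_dict() for ctx, rep in self.per_context.items()}
        return out


def _metrics(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    if x.size < 2:
        raise UndefinedCorrelationError(f"need >= 2 joined sites, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant frequency vector; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    return r, r * r, rho, rmse


def compare_frequencies(
    nanopore: Sequence[SiteFrequency],
    bisulfite: Sequence[BisulfiteSiteRecord],
    min_coverage: int = 5,
) -> EvalReport:
    """Inner-join nanopore and bisulfite sites and compare frequencies.

    Only sites with at least ``min_coverage`` mapped reads on *both* sides
    enter the comparison.  The report carries a per-context breakdown for
    contexts with at least two joined sites.
    """
    nano = pd.DataFrame(
        {
            "chrom": [f.chrom for f in nanopore],
            "pos": [f.pos for f in nanopore],
            "strand": [f.strand for f in nanopore],
            "context": [f.context for f in nanopore],
            "cov_nano": [f.coverage for f in nanopore],
            "freq_nano": [f.frequency for f in nanopore],
        }
    )
    bis = pd.DataFrame(
        {
            "chrom": [r.chrom for r in bisulfite],
            "pos": [r.pos for r in bisulfite],
            "strand": [r.strand for r in bisulfite],
            "cov_bis": [r.coverage for r in bisulfite],
            "freq_bis": [r.frequency if r.coverage > 0 else np.nan for r in bisulfite],
        }
    )
    joined = nano.merge(bis, on=["chrom", "pos", "strand"], how="inner")
    joined = joined[(joined.cov_nano >= min_coverage) & (joined.cov_bis >= min_coverage)]
    x = joined.freq_nano.to_numpy(dtype=np.float64)
    y = joined.freq_bis.to_numpy(dtype=np.float64)
    r, r2, rho, rmse = _metrics(x, y)
    report = EvalReport(n_sites=len(joined), pearson_r=r, r_squared=r2, spearman_rho=rho, rmse=rmse)
    for ctx, sub in joined.groupby("context"):
        if len(sub) >= 2:
            try:
                cr, cr2, crho, crmse = _metrics(
                    sub.freq_nano.to_numpy(dtype=np.float64),
                    sub.freq_bis.to_numpy(dtype=np.float64),
                )
            except UndefinedCorrelationError:
                continue
            report.per_context[ctx] = EvalReport(
                n_sites=len(sub), pearson_r=cr, r_squared=cr2, spearman_rho=crho, rmse=crmse
            )
    return report


def compare_against_replicates(
    nanopore: Sequence[SiteFrequency],
    replicates: Sequence[Sequence[BisulfiteSiteRecord]],
    min_coverage: int = 5,
) -> tuple[list[EvalReport], EvalReport]:
    """Compare against each bisulfite replicate; also return mean metrics."""
    reports = [compare_frequencies(nanopore, rep, min_coverage) for rep in replicates]
    mean = EvalReport(
        n_sites=int(np.mean([r.n_sites for r in reports])),
        pearson_r=float(np.mean([r.pearson_r for r in reports])),
        r_squared=float(np.mean([r.r_squared for r in reports])),
        spearman_rho=float(np.mean([r.spearman_rho for r in reports])),
        rmse=float(np.mean([r.rmse for r in reports])),
    )
    return reports, mean


def read_level_metrics(
    p_methylated: np.ndarray,
    truth_labels: np.ndarray,
    n_subsample: int = 100_000,
    repeats: int = 5,
    seed: int = 1,
) -> dict:
    """Class-balanced, repeated read-level evaluation.

    Per repeat, up to ``n_subsample`` positives and as many negatives are
    drawn without replacement; accuracy, sensitivity, specificity and AUC
    are computed per repeat and averaged.  Predicted calls use the strict
    P_m > 0.5 rule.
    """
    p = np.asarray(p_methylated, dtype=np.float64)
    y = np.asarray(truth_labels, dtype=np.int64)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must align")
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("both classes must be present for read-level evaluation")
    rng = np.random.default_rng(seed)
    per_repeat = []
    for _ in range(repeats):
        ip = rng.choice(pos_idx, size=min(n_subsample, pos_idx.size), replace=False)
        im = rng.choice(neg_idx, size=min(n_subsample, neg_idx.size), replace=False)
        idx = np.concatenate([ip, im])
        calls = (p[idx] > 0.5).astype(int)
        truth = y[idx]
        tp = int(np.sum((calls == 1) & (truth == 1)))
        tn = int(np.sum((calls == 0) & (truth == 0)))
        fp = int(np.sum((calls == 1) & (truth == 0)))
        fn = int(np.sum((calls == 0) & (truth == 1)))
        per_repeat.append(
            {
                "accuracy": (tp + tn) / idx.size,
                "sensitivity": tp / (tp + fn),
                "specificity": tn / (tn + fp),
                "auc": float(roc_auc_score(truth, p[idx])),
            }
        )
    summary = {}
    for key in ("accuracy", "sensitivity", "specificity", "auc"):
        vals = np.array([r[key] for r in per_repeat])
        summary[key] = float(vals.mean())
        summary[key + "_sd"] = float(vals.std(ddof=1)) if repeats > 1 else 0.0
    summary["repeats"] = per_repeat
    return summary
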