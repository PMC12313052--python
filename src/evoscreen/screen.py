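"""Pooled-competition fitness estimation and screen QC statistics.

Fitness of a variant is the slope of its log2 relative abundance against
generations of competitive growth, averaged over replicate cultivations and
centered so that the read-weighted pool mean is zero.  QC statistics mirror
the ones reported for pooled barcode screens: the Gini index of the starting
pool (uniformity), pairwise Pearson correlation of replicates per time
point, and the correlation of per-variant fitness between growth conditions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "relative_abundance",
    "variant_fitness",
    "gini_index",
    "replicate_correlation",
    "condition_correlation",
]

UNMATCHED_ROW = "_unmatched"


@dataclass
class CountMatrix:
    """Barcode/variant x sample read counts plus per-sample metadata.

    ``counts``: DataFrame, variants as rows, samples as columns (an optional
    ``_unmatched`` row is excluded from analyses).  ``samples``: DataFrame
    indexed like the count columns with columns ``condition``, ``replicate``
    and ``generation``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns and sample sheet rows do not align")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        for col in ("condition", "replicate", "generation"):
            if col in self.samples.columns and col == "generation":
                if (self.samples["generation"] < 0).any():
                    raise ValueError("negative generation in sample sheet")

    @property
    def variants(self) -> list[str]:
        return [v for v in self.counts.index if v != UNMATCHED_ROW]

    def matched(self) -> pd.DataFrame:
        return self.counts.loc[self.variants]

    def subset(self, condition) -> "CountMatrix":
        keep = self.samples.index[self.samples["condition"] == condition]
        if len(keep) == 0:
            raise ValueError(f"no samples for condition {condition!r}")
        return CountMatrix(self.counts[keep], self.samples.loc[keep])

    # -- plain-text round trip ------------------------------------------------
    def write_tsv(self, counts_path, samples_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="variant")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def read_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="variant")
        samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
        return cls(counts=counts, samples=samples)


def relative_abundance(column, pseudocount: float = 0.5) -> np.ndarray:
    """Pseudocounted relative frequencies of one sample column; sums to 1."""
    x = np.asarray(column, dtype=float)
    if (x < 0).any():
        raise ValueError("negative counts")
    if x.sum() == 0:
        raise ValueError("all-zero count column")
    x = x + pseudocount
    return x / x.sum()


def gini_index(abundance) -> float:
    """Gini inequality of an abundance vector: 0 = uniform, -> 1 = one-hot.

    Computed as the mean absolute difference between all pairs divided by
    twice the mean; scale invariant.
    """
    x = np.asarray(abundance, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundance")
    if x.sum() == 0:
        raise ValueError("all-zero abundance vector")
    n = len(x)
    xs = np.sort(x)
    # identity: sum_ij |xi - xj| = 2 * sum_i (2i - n + 1) * x_(i)
    mad = 2.0 * np.sum((2 * np.arange(1, n + 1) - n - 1) * xs) / (n * n)
    return float(mad / (2.0 * x.mean()))


def _log2_freq(counts: pd.DataFrame, pseudocount: float) -> pd.DataFrame:
    freq = counts.apply(lambda c: relative_abundance(c, pseudocount), axis=0)
    return np.log2(pd.DataFrame(freq, index=counts.index, columns=counts.columns))


def variant_fitness(
    counts: CountMatrix,
    condition,
    pseudocount: float = 0.5,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Per-variant fitness under one condition, from replicate time courses.

    Per replicate, fitness is the ordinary-least-squares slope of log2
    relative abundance versus generation; per condition the replicate slopes
    are averaged and centered by the read-weighted pool mean, so the pool
    average fitness is zero.  The confidence interval is a t-interval over
    replicate slopes.  Variants never observed (zero counts at every time
    point of every replicate) are flagged: their estimate is a lower bound.

    Returns a DataFrame with columns ``variant, condition, fitness, ci_low,
    ci_high, n_replicates, is_lower_bound``.
    """
    sub = counts.subset(condition)
    matched = sub.matched()
    meta = sub.samples
    replicates = sorted(meta["replicate"].unique())
    slopes = np.full((len(replicates), len(matched.index)), np.nan)
    for r_idx, rep in enumerate(replicates):
        cols = meta.index[meta["replicate"] == rep]
        gens = meta.loc[cols, "generation"].to_numpy(dtype=float)
        if len(cols) < 2:
            raise ValueError(f"replicate {rep!r} has fewer than 2 generations")
        order = np.argsort(gens)
        gens = gens[order]
        y = _log2_freq(matched[cols], pseudocount).to_numpy()[:, order]
        g = gens - gens.mean()
        slopes[r_idx] = (y * g).sum(axis=1) / (g * g).sum()

    mean_slope = slopes.mean(axis=0)
    weights = matched.sum(axis=1).to_numpy(dtype=float)
    if weights.sum() == 0:
        raise ValueError("no matched reads in condition")
    pool_mean = float(np.average(mean_slope, weights=weights))
    fitness = mean_slope - pool_mean

    n_rep = len(replicates)
    if n_rep > 1:
        se = slopes.std(axis=0, ddof=1) / np.sqrt(n_rep)
        tcrit = stats.t.ppf(0.5 + conf_level / 2, df=n_rep - 1)
        ci_low, ci_high = fitness - tcrit * se, fitness + tcrit * se
    else:
        ci_low = ci_high = np.full_like(fitness, np.nan)

    never_seen = (matched.to_numpy() == 0).all(axis=1)
    return pd.DataFrame(
        {
            "variant": matched.index,
            "condition": condition,
            "fitness": fitness,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "n_replicates": n_rep,
            "is_lower_bound": never_seen,
        }
    ).reset_index(drop=True)


def replicate_correlation(
    counts: CountMatrix,
    condition,
    threshold: float = 0.8,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, float]:
    """Pairwise replicate Pearson r per time point, plus pass fraction.

    Correlations are computed on log2 relative abundances.  A sample
    (replicate x generation) passes when its mean correlation with the other
    replicates of the same time point exceeds ``threshold``; the second
    return value is the passing fraction over all such samples.  Zero
    variance in a column yields a missing (NaN) correlation.
    """
    sub = counts.subset(condition)
    matched = sub.matched()
    meta = sub.samples
    log2f = _log2_freq(matched, pseudocount)

    rows = []
    per_sample: dict[str, list[float]] = {}
    for gen, group in meta.groupby("generation"):
        cols = list(group.index)
        if len(cols) < 2:
            continue
        for ca, cb in itertools.combinations(cols, 2):
            a, b = log2f[ca].to_numpy(), log2f[cb].to_numpy()
            if a.std() == 0 or b.std() == 0:
                r = np.nan
            else:
                r = float(stats.pearsonr(a, b).statistic)
            rows.append(
                {
                    "generation": gen,
                    "replicate_a": meta.loc[ca, "replicate"],
                    "replicate_b": meta.loc[cb, "replicate"],
                    "r": r,
                }
            )
            per_sample.setdefault(ca, []).append(r)
            per_sample.setdefault(cb, []).append(r)

    table = pd.DataFrame(rows, columns=["generation", "replicate_a", "replicate_b", "r"])
    if not per_sample:
        return table, float("nan")
    passing = [np.nanmean(v) > threshold for v in per_sample.values()]
    return table, float(np.mean(passing))


def condition_correlation(fit_a: pd.DataFrame, fit_b: pd.DataFrame) -> tuple[float, float]:
    """Pearson r (and two-sided p) of per-variant fitness between conditions."""
    merged = fit_a.merge(fit_b, on="variant", suffixes=("_a", "_b"))
    if len(merged) != len(fit_a) or len(merged) != len(fit_b):
        raise ValueError("fitness tables cover different variant sets")
    if len(merged) < 3:
        raise ValueError("need at least 3 paired fitness values")
    res = stats.pearsonr(merged["fitness_a"], merged["fitness_b"])
    return float(res.statistic), float(res.pvalue)
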