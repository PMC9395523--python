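"""Cross-species negative-binomial differential expression.

Counts per ortholog cluster per sample (one sample per species) are
filtered to the core transcriptome, normalised by median-of-ratios size
factors, given per-cluster NB2 dispersions by shrunken method-of-moments,
and tested for a phenotype-group effect with a Wald test on an NB
log-link regression (intercept + group indicator, size factors as
offsets), with Benjamini-Hochberg adjustment across clusters.

The modelling surface follows the Model/Results convention:

>>> model = GroupContrastNB(counts, sample_group)      # doctest: +SKIP
>>> res = model.fit()                                  # doctest: +SKIP
>>> res.summary()                                      # doctest: +SKIP

The NB2 law has variance mu + alpha * mu**2; alpha = 0 is the Poisson
limit.  Each species contributes a single sample, so species identity is
confounded with replication — the test treats species as independent
samples, which is the design being emulated, not a claim this package
resolves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MAX_IRLS_ITER = 100
IRLS_TOL = 1e-8


class DEError(ValueError):
    """Invalid differential-expression input."""


@dataclass
class CountsTable:
    """Integer read counts (clusters x samples) with group labels."""

    counts: pd.DataFrame
    sample_group: dict[str, str]  # sample id -> "A" | "B"

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size == 0:
            raise DEError("empty counts table")
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)) or (arr < 0).any():
                raise DEError("counts must be nonnegative integers")
        unlabeled = [s for s in self.counts.columns if s not in self.sample_group]
        if unlabeled:
            raise DEError(f"samples without a group label: {unlabeled}")
        bad = {s: g for s, g in self.sample_group.items() if g not in ("A", "B")}
        if bad:
            raise DEError(f"group labels must be 'A' or 'B': {bad}")

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_group[s] == label]

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="cluster")


def filter_core_transcriptome(
    table: CountsTable, min_count: int = 1
) -> CountsTable:
    """Keep clusters with at least ``min_count`` reads in every sample.

    The default (>= 1 everywhere) is the "at least one read mapped in all
    genomes" core-transcriptome rule; ``min_count=2`` gives the stricter
    "reads > 1" reading.  Row order is preserved.
    """
    keep = (table.counts >= min_count).all(axis=1)
    return CountsTable(table.counts.loc[keep], dict(table.sample_group))


def size_factors(table: CountsTable) -> pd.Series:
    """Median-of-ratios normalisation factors per sample.

    For each cluster with all-positive counts, the ratio of each sample's
    count to the cluster's geometric mean; the factor of a sample is the
    median of its ratios.
    """
    counts = table.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise DEError(
            "no cluster has positive counts in every sample; filter to the "
            "core transcriptome first"
        )
    sub = counts[positive]
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo_mean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=table.sample_ids, name="size_factor")


def estimate_dispersions(
    table: CountsTable,
    factors: pd.Series,
) -> pd.Series:
    """Per-cluster NB2 dispersions: method of moments with empirical-Bayes
    shrinkage toward the panel's trimmed-mean dispersion.

    On size-factor-normalised counts, within each group the moment
    estimate alpha = (s^2 - mean) / mean^2 is formed and the per-cluster
    raw estimate is the sample-size-weighted mean over groups.  Each raw
    estimate is then shrunk toward the panel prior (trimmed mean of the
    truncated raw values) with weight tau^2 / (tau^2 + v_i), where v_i is
    the delta-method sampling variance of cluster i's moment estimate and
    tau^2 the between-cluster dispersion variance in excess of sampling
    noise.  When the panel's dispersions are homogeneous tau^2 -> 0 and
    the common value is used (keeping the Wald denominator essentially
    noise-free); heterogeneous panels retain per-cluster estimates.
    Results are truncated at 0.
    """
    for label in ("A", "B"):
        if len(table.group_samples(label)) < 2:
            raise DEError(f"group {label} has fewer than 2 samples")
    norm = table.counts.to_numpy(dtype=float) / factors.reindex(
        table.sample_ids
    ).to_numpy()
    n_total = norm.shape[1]
    raw = np.zeros(norm.shape[0])
    inv_mu = np.zeros(norm.shape[0])  # sample-size-weighted mean of 1/mu_g
    var_scale = 0.0  # sum over groups of w_g^2 * 2/(n_g - 1)
    for label in ("A", "B"):
        cols = [table.sample_ids.index(s) for s in table.group_samples(label)]
        w_g = len(cols) / n_total
        sub = norm[:, cols]
        mu = np.maximum(sub.mean(axis=1), 1e-300)
        s2 = sub.var(axis=1, ddof=1)
        raw += w_g * (s2 - mu) / mu**2
        inv_mu += w_g / mu
        var_scale += w_g**2 * 2.0 / (len(cols) - 1)
    truncated = np.maximum(raw, 0.0)
    if len(truncated) > 2:
        prior = float(stats.trim_mean(truncated, 0.125))
    else:
        prior = float(truncated.mean())
    # delta-method variance of the raw moment estimate at the prior
    v = var_scale * (inv_mu + prior) ** 2
    tau2 = max(0.0, float(raw.var()) - float(v.mean()))
    w = tau2 / (tau2 + v)
    shrunk = w * raw + (1.0 - w) * prior
    return pd.Series(np.maximum(shrunk, 0.0), index=table.cluster_ids, name="alpha")


def _nb_irls(
    y: np.ndarray,
    group: np.ndarray,
    offset: np.ndarray,
    alpha: float,
):
    """Fit an NB log-link regression (intercept + group) by IRLS.

    Returns (beta, se_beta, converged); beta[1] is the group effect on
    the natural-log scale.
    """
    X = np.column_stack([np.ones_like(group, dtype=float), group.astype(float)])
    # moment start from group means of offset-corrected counts
    adj = y / np.exp(offset)
    mean_a = max(adj[group == 0].mean(), 1e-8)
    mean_b = max(adj[group == 1].mean(), 1e-8)
    beta = np.array([np.log(mean_a), np.log(mean_b) - np.log(mean_a)])
    converged = False
    for _ in range(MAX_IRLS_ITER):
        eta = X @ beta + offset
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < IRLS_TOL:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = X @ beta + offset
    mu = np.exp(np.clip(eta, -30, 30))
    w = mu / (1.0 + alpha * mu)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se, converged


def wald_test(
    table: CountsTable,
    factors: pd.Series,
    dispersions: pd.Series,
) -> pd.DataFrame:
    """Per-cluster NB Wald test of group B versus group A.

    Returns a frame indexed by cluster with columns baseMean, log2fc, se,
    wald, p and converged; p is NaN for non-converged fits (never forced
    to 1).  log2fc and its standard error are on the log2 scale.
    """
    for label in ("A", "B"):
        if len(table.group_samples(label)) < 2:
            raise DEError(f"group {label} has fewer than 2 samples")
    f = factors.reindex(table.sample_ids).to_numpy(dtype=float)
    offset = np.log(f)
    group = np.array(
        [0 if table.sample_group[s] == "A" else 1 for s in table.sample_ids]
    )
    rows = []
    ln2 = np.log(2.0)
    for cid in table.cluster_ids:
        y = table.counts.loc[cid].to_numpy(dtype=float)
        alpha = float(dispersions.loc[cid])
        beta, se, converged = _nb_irls(y, group, offset, alpha)
        log2fc = beta[1] / ln2
        se2 = se[1] / ln2
        wald = log2fc / se2 if se2 > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(wald)) if converged else np.nan
        rows.append(
            {
                "cluster": cid,
                "baseMean": float(np.mean(y / f)),
                "log2fc": log2fc,
                "se": se2,
                "wald": wald,
                "p": p,
                "converged": converged,
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped
    at 1; NaN inputs stay NaN and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise DEError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    result = np.empty(m)
    result[order] = adjusted
    out[mask] = result
    return out


class GroupContrastNB:
    """NB differential-expression model for a two-group species contrast.

    Parameters
    ----------
    counts : CountsTable or pandas.DataFrame
        Clusters x samples integer counts.
    sample_group : mapping, optional
        Sample id -> "A" / "B"; required when ``counts`` is a plain frame.
    core_min_count : int
        Core-transcriptome filter threshold (reads >= this in every
        sample); default 1.
    """

    def __init__(
        self,
        counts,
        sample_group: dict[str, str] | None = None,
        core_min_count: int = 1,
    ) -> None:
        if isinstance(counts, CountsTable):
            self.data = counts
        else:
            if sample_group is None:
                raise DEError("sample_group is required with a plain frame")
            self.data = CountsTable(pd.DataFrame(counts), dict(sample_group))
        self.core_min_count = core_min_count

    @classmethod
    def from_files(cls, counts_tsv, groups_csv, **kwargs) -> "GroupContrastNB":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
        groups = pd.read_csv(groups_csv)
        mapping = dict(zip(groups.iloc[:, 0], groups.iloc[:, 1]))
        return cls(counts, mapping, **kwargs)

    def fit(self, alpha_threshold: float = 0.05) -> "GroupContrastResults":
        core = filter_core_transcriptome(self.data, self.core_min_count)
        if core.counts.shape[0] == 0:
            raise DEError("no cluster survives the core-transcriptome filter")
        factors = size_factors(core)
        dispersions = estimate_dispersions(core, factors)
        results = wald_test(core, factors, dispersions)
        results["padj"] = adjust_bh(results["p"].to_numpy())
        return GroupContrastResults(
            model=self,
            table=results,
            size_factors=factors,
            dispersions=dispersions,
            alpha_threshold=alpha_threshold,
            n_input=self.data.counts.shape[0],
        )


@dataclass
class GroupContrastResults:
    """Fitted group contrast: per-cluster effects, tests and diagnostics."""

    model: GroupContrastNB
    table: pd.DataFrame
    size_factors: pd.Series
    dispersions: pd.Series
    alpha_threshold: float
    n_input: int

    @property
    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[t["padj"] < self.alpha_threshold]

    def volcano_frame(self) -> pd.DataFrame:
        """log2fc vs -log10 p, ready for a volcano plot."""
        frame = self.table[["log2fc", "p", "padj"]].copy()
        with np.errstate(divide="ignore"):
            frame["neg_log10_p"] = -np.log10(frame["p"])
        return frame

    def summary(self) -> str:
        t = self.table
        up = ((t["padj"] < self.alpha_threshold) & (t["log2fc"] > 0)).sum()
        down = ((t["padj"] < self.alpha_threshold) & (t["log2fc"] < 0)).sum()
        lines = [
            "Cross-species NB group contrast (B vs A)",
            f"  clusters tested (core transcriptome): {len(t)} of {self.n_input}",
            f"  samples: {len(self.size_factors)} "
            f"(A={len(self.model.data.group_samples('A'))}, "
            f"B={len(self.model.data.group_samples('B'))})",
            f"  size factors: min {self.size_factors.min():.3f}, "
            f"max {self.size_factors.max():.3f}",
            f"  median dispersion: {self.dispersions.median():.4f}",
            f"  significant at padj < {self.alpha_threshold:g}: "
            f"{up} up, {down} down",
            f"  non-converged fits: {(~t['converged']).sum()}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="cluster")
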