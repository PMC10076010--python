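"""Per-sample protein expression: TMM normalization and differential testing.

Sample-level expression is the column-sum of each sample's single-exosome
matrix.  Between-sample scaling uses the trimmed mean of M-values (TMM):
with reference sample r chosen as the one whose upper-quartile/library-size
statistic is closest to the mean, each sample s gets

    log2 f_s = sum_g w_g M_g / sum_g w_g,
    M_g = log2[(y_gs / N_s) / (y_gr / N_r)],
    A_g = 0.5 [log2(y_gs / N_s) + log2(y_gr / N_r)],
    w_g = 1 / [(N_s - y_gs)/(N_s y_gs) + (N_r - y_gr)/(N_r y_gr)],

over proteins positive in both samples, after double trimming (30% on M,
5% on A, by average ranks); factors are rescaled to geometric mean 1.

Differential expression follows a normality-routed scheme per protein:
Shapiro-Wilk on each group; if both look normal, an F-ratio variance check
routes to Student's t (equal variances) or Welch's t; otherwise a Wilcoxon
rank-sum test.  P-values are Benjamini-Hochberg adjusted and calls are made
at q < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .readproc import ExosomeProteinMatrix


@dataclass
class SampleExpressionTable:
    """Samples x proteins count table with group labels."""

    counts: pd.DataFrame  # samples x proteins, nonnegative integers
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.groups.index):
            self.groups = self.groups.reindex(self.counts.index)
        if self.groups.isna().any():
            raise ValueError("every sample needs a group label")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")

    @classmethod
    def from_matrices(
        cls,
        matrices: Sequence[ExosomeProteinMatrix],
        groups: Mapping[str, str],
    ) -> "SampleExpressionTable":
        rows = {m.sample_id: aggregate_counts(m) for m in matrices}
        proteins = matrices[0].protein_names
        counts = pd.DataFrame.from_dict(rows, orient="index")
        counts.columns = proteins
        return cls(counts, pd.Series({s: groups[s] for s in counts.index}))


@dataclass
class TmmFactors:
    """Per-sample TMM scaling factors (geometric mean 1) plus provenance."""

    factors: pd.Series
    reference: str
    logratio_trim: float = 0.30
    sum_trim: float = 0.05

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_gm = np.log(self.factors.to_numpy()).mean()
        if abs(log_gm) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")


def aggregate_counts(matrix: ExosomeProteinMatrix) -> np.ndarray:
    """Per-protein totals: column sums over all exosomes of a sample."""
    return np.asarray(matrix.counts.sum(axis=0)).ravel().astype(np.int64)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """TMM factor of one sample against the reference (canonical definition)."""
    n_obs, n_ref = obs.sum(), ref.sum()
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        warnings.warn("sample shares no positive protein with reference; "
                      "TMM factor set to 1")
        return 1.0
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    log_r = np.log2((o / n_obs) / (r / n_ref))
    abs_e = 0.5 * (np.log2(o / n_obs) + np.log2(r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_l = rankdata(log_r)
    rank_s = rankdata(abs_e)
    keep = (rank_l >= lo_l) & (rank_l <= hi_l) & (rank_s >= lo_s) & (rank_s <= hi_s)
    if not keep.any():
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f)


def tmm_factors(
    table: SampleExpressionTable,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> TmmFactors:
    """Compute TMM normalization factors for every sample.

    Reference selection: the sample whose 75th-percentile count over library
    size is closest to the mean of that statistic across samples.
    """
    counts = table.counts.to_numpy(dtype=float)
    if counts.shape[0] < 2:
        raise ValueError("TMM needs at least 2 samples")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = table.counts.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total counts: {bad}")
    uq = np.quantile(counts, 0.75, axis=1) / totals
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[ref_idx]
    raw = np.array([
        1.0 if i == ref_idx else
        _tmm_pair(counts[i], ref, logratio_trim, sum_trim)
        for i in range(counts.shape[0])
    ])
    raw /= np.exp(np.log(raw).mean())  # geometric mean 1
    return TmmFactors(
        factors=pd.Series(raw, index=table.counts.index, name="tmm_factor"),
        reference=str(table.counts.index[ref_idx]),
        logratio_trim=logratio_trim,
        sum_trim=sum_trim,
    )


def normalize(table: SampleExpressionTable, factors: TmmFactors) -> pd.DataFrame:
    """Counts-per-million on TMM-effective library sizes.

    value(s, p) = counts(s, p) / (total(s) * f_s) * 1e6.
    """
    counts = table.counts.to_numpy(dtype=float)
    eff = counts.sum(axis=1) * factors.factors.reindex(table.counts.index).to_numpy()
    values = counts / eff[:, None] * 1e6
    return pd.DataFrame(values, index=table.counts.index,
                        columns=table.counts.columns)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs are excluded from the
    family and returned as NaN in place."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        vals = p[mask]
        if (vals < 0).any() or (vals > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out


def _route_test(
    a: np.ndarray, b: np.ndarray, alpha_normality: float, fallback: str
) -> tuple[str, float]:
    """Choose and run the two-sample test for one protein."""
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return "none", np.nan
    normal = True
    for g in (a, b):
        if np.ptp(g) == 0:
            normal = False
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if st.shapiro(g).pvalue <= alpha_normality:
                normal = False
                break
    if normal or fallback == "parametric":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            equal_var = False
        else:
            f = np.var(a, ddof=1) / np.var(b, ddof=1)
            dist = st.f(len(a) - 1, len(b) - 1)
            p_f = 2 * min(dist.cdf(f), dist.sf(f))
            equal_var = p_f > 0.05
        res = st.ttest_ind(b, a, equal_var=equal_var)
        return ("t" if equal_var else "welch"), float(res.pvalue)
    # exact null distribution where feasible: the normal approximation is
    # badly conservative in the extreme tail at small n
    pooled = np.concatenate([a, b])
    exact_ok = max(len(a), len(b)) <= 25 and len(np.unique(pooled)) == len(pooled)
    res = st.mannwhitneyu(b, a, alternative="two-sided",
                          method="exact" if exact_ok else "asymptotic")
    return "wilcoxon", float(res.pvalue)


def diff_expression(
    normalized: pd.DataFrame,
    groups: pd.Series,
    group_a: str | None = None,
    group_b: str | None = None,
    alpha_normality: float = 0.05,
    fallback: str = "wilcoxon",
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-protein differential expression between two groups.

    Returns a frame with columns log2fc (B over A, pseudocount 0.5), test,
    p, q and a significance flag at q < 0.05.  Proteins constant in both
    groups get a missing p and are excluded from the FDR family.

    With ``log_scale`` (default) the normality check and the t/Welch tests
    run on log2(value + 0.5): expression noise is multiplicative, so the log
    is the scale on which the Gaussian model — and hence the Shapiro-Wilk
    routing — is meaningful.  Fold changes are always reported from the raw
    group means.
    """
    if fallback not in ("wilcoxon", "parametric"):
        raise ValueError("fallback must be 'wilcoxon' or 'parametric'")
    groups = groups.reindex(normalized.index)
    levels = [g for g in dict.fromkeys(groups) if pd.notna(g)]
    if group_a is None or group_b is None:
        if len(levels) != 2:
            raise ValueError("need exactly two groups (or pass group_a/group_b)")
        group_a, group_b = levels
    mat_a = normalized.loc[groups == group_a].to_numpy(dtype=float)
    mat_b = normalized.loc[groups == group_b].to_numpy(dtype=float)
    if mat_a.shape[0] < 3 or mat_b.shape[0] < 3:
        raise ValueError("each group needs at least 3 samples")

    tests, pvals, lfcs = [], [], []
    for j in range(normalized.shape[1]):
        a, b = mat_a[:, j], mat_b[:, j]
        lfcs.append(np.log2((b.mean() + 0.5) / (a.mean() + 0.5)))
        if log_scale:
            a, b = np.log2(a + 0.5), np.log2(b + 0.5)
        test, p = _route_test(a, b, alpha_normality, fallback)
        tests.append(test)
        pvals.append(p)
    q = bh_adjust(pvals)
    return pd.DataFrame(
        {
            "log2fc": lfcs,
            "test": tests,
            "p": pvals,
            "q": q,
            "significant": (q < 0.05) & ~np.isnan(q),
        },
        index=normalized.columns,
    )
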