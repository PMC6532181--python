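"""Distributional screening of features between reactive and non-reactive peptides.

Two two-sample tests per feature (Mann–Whitney for a location shift,
Kolmogorov–Smirnov for any distributional difference), group means, a
composite-score histogram, and p-masked within-group correlation matrices.
The screen answers: which of the seven features differ between the
MHC-binding peptides that do and do not activate CD8+ T cells, and does
the dependence structure among features differ between the two groups?
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .epitope_features import FEATURE_COLUMNS, LabeledDataset
from .processing_scores import er_delivery_score

__all__ = [
    "ks_two_sample",
    "mann_whitney",
    "FeatureScreenReport",
    "screen_features",
    "composite_scores",
    "composite_histogram",
    "MaskedCorrelationMatrix",
    "masked_correlations",
]

#: features entering the ER-delivery composite
COMPOSITE_FEATURES = ["expression", "tap", "cleavage"]


def _check_samples(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return x, y


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    Returns (D, p) with D the maximum ECDF separation and p from the
    asymptotic Kolmogorov distribution (adequate at the sample sizes this
    screen targets; mildly conservative below ~n=25 per group).
    """
    x, y = _check_samples(x, y)
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test (U for the first sample, ties get 1/2).

    p by the normal approximation with tie correction and continuity
    correction.
    """
    x, y = _check_samples(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class FeatureScreenReport:
    """Per-feature screen results: tests, -log10 p, group means, flags."""

    table: pd.DataFrame  # index: feature name
    alpha: float
    bonferroni: bool = False

    def significant_features(self, test: str = "mwu") -> list[str]:
        col = f"{test}_significant"
        return self.table.index[self.table[col]].tolist()

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="feature")

    def __repr__(self) -> str:  # noqa: D105
        sig = self.significant_features()
        return (
            f"<FeatureScreenReport alpha={self.alpha} "
            f"significant(MWU)={sig}>"
        )


def screen_features(
    data: LabeledDataset,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> FeatureScreenReport:
    """Run both tests on every feature column, positives vs negatives.

    Constant (degenerate) feature columns are reported as non-significant
    with ``degenerate=True`` rather than raising. With ``bonferroni`` the
    significance flags use alpha / n_features (raw p values are always
    reported).
    """
    data.require_both_classes()
    pos = data.features[data.labels == 1]
    neg = data.features[data.labels == 0]
    thr = alpha / len(FEATURE_COLUMNS) if bonferroni else alpha
    rows = []
    for feat in FEATURE_COLUMNS:
        x, y = pos[feat].to_numpy(float), neg[feat].to_numpy(float)
        degenerate = np.ptp(np.concatenate([x, y])) == 0
        if degenerate:
            d, ks_p, u, mwu_p = 0.0, 1.0, len(x) * len(y) / 2.0, 1.0
        else:
            d, ks_p = ks_two_sample(x, y)
            u, mwu_p = mann_whitney(x, y)
        rows.append(
            {
                "feature": feat,
                "ks_D": d,
                "ks_p": ks_p,
                "ks_neglog10_p": -np.log10(ks_p) if ks_p > 0 else np.inf,
                "mwu_U": u,
                "mwu_p": mwu_p,
                "mwu_neglog10_p": -np.log10(mwu_p) if mwu_p > 0 else np.inf,
                "mean_pos": float(np.mean(x)),
                "mean_neg": float(np.mean(y)),
                "ks_significant": bool(ks_p < thr) and not degenerate,
                "mwu_significant": bool(mwu_p < thr) and not degenerate,
                "degenerate": bool(degenerate),
            }
        )
    table = pd.DataFrame(rows).set_index("feature")
    return FeatureScreenReport(table=table, alpha=alpha, bonferroni=bonferroni)


def composite_scores(data: LabeledDataset) -> pd.Series:
    """ER-delivery composite (expression + TAP + cleavage) per candidate."""
    f = data.features
    return pd.Series(
        [
            er_delivery_score(e, t, c)
            for e, t, c in zip(f["expression"], f["tap"], f["cleavage"])
        ],
        index=f.index,
        name="er_delivery",
    )


def composite_histogram(
    data: LabeledDataset, bins: int | np.ndarray = 20
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-group histogram of the composite score on shared bin edges.

    Returns (bin_edges, DataFrame with columns 'pos' and 'neg' of counts).
    """
    data.require_both_classes()
    scores = composite_scores(data).to_numpy()
    edges = np.histogram_bin_edges(scores, bins=bins)
    pos_counts, _ = np.histogram(scores[data.labels == 1], bins=edges)
    neg_counts, _ = np.histogram(scores[data.labels == 0], bins=edges)
    counts = pd.DataFrame({"pos": pos_counts, "neg": neg_counts})
    return edges, counts


@dataclass
class MaskedCorrelationMatrix:
    """Within-group feature correlations with non-significant entries masked."""

    group: str
    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame  # True = hidden (p >= threshold, diagonal, degenerate)
    p_threshold: float

    @property
    def retained_features(self) -> list[str]:
        keep = (~self.mask).any(axis=1)
        return self.r.index[keep].tolist()

    def rendered(self) -> pd.DataFrame:
        """r with masked cells as NaN, all-masked rows/columns dropped."""
        shown = self.r.where(~self.mask)
        keep = self.retained_features
        return shown.loc[keep, keep]

    def to_long(self) -> pd.DataFrame:
        recs = []
        feats = list(self.r.index)
        for i, fi in enumerate(feats):
            for fj in feats[i + 1 :]:
                recs.append(
                    {
                        "group": self.group,
                        "feature_i": fi,
                        "feature_j": fj,
                        "r": self.r.at[fi, fj],
                        "p": self.p.at[fi, fj],
                        "masked": bool(self.mask.at[fi, fj]),
                    }
                )
        return pd.DataFrame(recs)


def _corr_matrix(
    df: pd.DataFrame, group: str, p_threshold: float, method: str
) -> MaskedCorrelationMatrix:
    feats = list(df.columns)
    n = len(feats)
    r = pd.DataFrame(np.eye(n), index=feats, columns=feats)
    p = pd.DataFrame(np.zeros((n, n)), index=feats, columns=feats)
    mask = pd.DataFrame(np.eye(n, dtype=bool), index=feats, columns=feats)
    for fi, fj in combinations(feats, 2):
        x, y = df[fi].to_numpy(float), df[fj].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rij, pij, hidden = np.nan, np.nan, True
        else:
            if method == "spearman":
                rij, pij = stats.spearmanr(x, y)
            elif method == "pearson":
                rij, pij = stats.pearsonr(x, y)
            else:
                raise ValueError(f"unknown correlation method {method!r}")
            hidden = not (pij < p_threshold)
        r.loc[fi, fj] = r.loc[fj, fi] = rij
        p.loc[fi, fj] = p.loc[fj, fi] = pij
        mask.loc[fi, fj] = mask.loc[fj, fi] = hidden
    return MaskedCorrelationMatrix(group=group, r=r, p=p, mask=mask, p_threshold=p_threshold)


def masked_correlations(
    data: LabeledDataset,
    p_threshold: float = 0.005,
    method: str = "spearman",
) -> dict[str, MaskedCorrelationMatrix]:
    """Pairwise feature correlations within positives and within negatives.

    Rank (Spearman) correlation by default — robust to the heavy-tailed
    expression scale; Pearson available via ``method``. Entries with
    p >= ``p_threshold`` are masked; constant columns are masked with NaN.
    Requires at least 3 observations per group.
    """
    data.require_both_classes()
    out = {}
    for group, sel in (("pos", data.labels == 1), ("neg", data.labels == 0)):
        sub = data.features[sel]
        if len(sub) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 observations")
        out[group] = _corr_matrix(sub, group, p_threshold, method)
    return out
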