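"""Baseline marker-ranking methods: Welch t-test, Wilcoxon rank-sum, COSG.

These are the comparison methods for the two-step Wasserstein/MCC
signature.  The t-test is Welch's (unequal variances), the safer default
for heteroskedastic omics features; zero-variance features get p = 1 so
rankings are total.  The Wilcoxon test is the two-sided Mann-Whitney
rank-sum with average ranks for ties (exact null distribution when both
groups have <= 8 samples and no ties, tie-corrected normal approximation
otherwise).  COSG scores each feature column by cosine similarity to the
"ideal" marker — the binary indicator of membership in the target group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .datasets import OmicsDataset, SampleSelection, ValidationError

METHODS = ("wmcc", "ttest", "wilcoxon", "cosg")


@dataclass
class RankedFeatureList:
    """Ordered (feature, score) pairs produced by one ranking method.

    Score semantics depend on the method: p-values (ascending) for the
    statistical tests, cosine similarity (descending) for COSG, MCC
    (descending) for the two-step signature.
    """

    method: str
    entries: list[tuple[str, float]]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.entries]

    def top(self, k: int) -> list[str]:
        return self.features[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "feature": [f for f, _ in self.entries],
                "score": [s for _, s in self.entries],
            }
        )


def _two_group_blocks(dataset, sel_a, sel_b, min_size):
    for name, sel in (("A", sel_a), ("B", sel_b)):
        if sel.n_selected < min_size:
            raise ValidationError(f"group {name} needs at least {min_size} samples")
    if np.any(sel_a.mask & sel_b.mask):
        raise ValidationError("groups overlap")
    return dataset.dense_block(sel_a.indices), dataset.dense_block(sel_b.indices)


def ttest_rank(
    dataset: OmicsDataset, sel_a: SampleSelection, sel_b: SampleSelection
) -> RankedFeatureList:
    """Per-feature two-sided Welch t-test; rank by p ascending, ties by
    |t| descending.  Features with zero pooled variance get p = 1, t = 0."""
    import warnings

    xa, xb = _two_group_blocks(dataset, sel_a, sel_b, min_size=2)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant features trigger scipy's precision-loss warning; they get p=1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = scipy.stats.ttest_ind(xa, xb, axis=0, equal_var=False)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    order = np.lexsort((np.arange(p.size), -np.abs(t), p))
    return RankedFeatureList(
        "ttest", [(str(dataset.feature_names[i]), float(p[i])) for i in order]
    )


def wilcoxon_rank(
    dataset: OmicsDataset, sel_a: SampleSelection, sel_b: SampleSelection
) -> RankedFeatureList:
    """Per-feature two-sided Wilcoxon/Mann-Whitney rank-sum; p ascending.

    The exact null distribution is used when both groups have <= 8 samples
    and the feature has no ties; otherwise the tie-corrected normal
    approximation (with continuity correction).
    """
    xa, xb = _two_group_blocks(dataset, sel_a, sel_b, min_size=1)
    na, nb = xa.shape[0], xb.shape[0]
    pvals = np.empty(xa.shape[1])
    for j in range(xa.shape[1]):
        a, b = xa[:, j], xb[:, j]
        has_ties = np.unique(np.concatenate([a, b])).size < na + nb
        method = "exact" if (na <= 8 and nb <= 8 and not has_ties) else "asymptotic"
        if np.ptp(np.concatenate([a, b])) == 0:  # constant feature: no evidence
            pvals[j] = 1.0
            continue
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        pvals[j] = min(res.pvalue, 1.0)
    order = np.lexsort((np.arange(pvals.size), pvals))
    return RankedFeatureList(
        "wilcoxon", [(str(dataset.feature_names[i]), float(pvals[i])) for i in order]
    )


def cosg_rank(dataset: OmicsDataset, sel_a: SampleSelection) -> RankedFeatureList:
    """Cosine similarity of each feature column to the ideal marker vector.

    The ideal marker of the target group is its binary membership
    indicator over samples (expressed exclusively in the group); features
    are ranked by descending similarity.  Zero-norm features score 0.
    """
    if sel_a.n_selected == 0:
        raise ValidationError("target group is empty")
    if sel_a.n_selected == dataset.n_samples:
        raise ValidationError("target group must not contain all samples")
    ideal = sel_a.mask.astype(np.float64)
    X = dataset.matrix
    import scipy.sparse as sp

    if sp.issparse(X):
        num = np.asarray(X.T @ ideal).ravel()
        norms = np.sqrt(np.asarray(X.multiply(X).sum(axis=0)).ravel())
    else:
        num = X.T @ ideal
        norms = np.linalg.norm(X, axis=0)
    den = norms * np.linalg.norm(ideal)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = np.where(den > 0, num / den, 0.0)
    order = np.lexsort((np.arange(cos.size), -cos))
    return RankedFeatureList(
        "cosg", [(str(dataset.feature_names[i]), float(cos[i])) for i in order]
    )


def rank_features(
    dataset: OmicsDataset,
    sel_a: SampleSelection,
    sel_b: SampleSelection | None,
    method: str,
    n_top: int | None = None,
    **signature_kwargs,
) -> RankedFeatureList:
    """Uniform front-end over all ranking methods.

    ``method`` is one of ``wmcc`` (the two-step Wasserstein + MCC
    signature), ``ttest``, ``wilcoxon``, ``cosg``.  ``sel_b=None`` means
    "A vs Rest".
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if method == "cosg":
        out = cosg_rank(dataset, sel_a)
    else:
        sb = sel_b if sel_b is not None else sel_a.complement()
        if method == "ttest":
            out = ttest_rank(dataset, sel_a, sb)
        elif method == "wilcoxon":
            out = wilcoxon_rank(dataset, sel_a, sb)
        else:
            from .signatures import compute_signature

            kwargs = dict(signature_kwargs)
            kwargs.setdefault("n_prefilter", min(500, dataset.n_features))
            kwargs.setdefault("n_top", min(n_top or 100, kwargs["n_prefilter"]))
            sig = compute_signature(dataset, sel_a, sel_b, **kwargs)
            out = RankedFeatureList(
                "wmcc", [(e.feature, e.mcc) for e in sig.entries]
            )
    if n_top is not None:
        out = RankedFeatureList(out.method, out.entries[:n_top])
    return out
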