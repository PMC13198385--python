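"""Two-step marker-signature discovery and oriented signatures.

Step 1 ranks every feature by the closed-form 2-Wasserstein distance
between the two univariate Gaussians fitted to Group A and Group B
(W = sqrt((mu_A - mu_B)^2 + (sigma_A - sigma_B)^2)) and keeps the
``n_prefilter`` features with the largest distributional difference.
Unlike a t-test this distance responds to variance shifts as well as mean
shifts.

Step 2 scans, for each surviving feature, candidate split thresholds
(midpoints between consecutive distinct values, capped at ``max_grid``
quantile-spaced candidates) in both polarities, scores each threshold by
the Matthews Correlation Coefficient of the implied group-A prediction,
and keeps the MCC-optimal threshold.  The final signature is ranked by MCC
(descending), ties broken by Wasserstein distance then feature index, and
truncated to ``n_top`` (default 100) entries.

Oriented signatures rank features by Pearson correlation with the scalar
positions obtained by projecting the selected samples' embedding
coordinates onto a user-drawn arrow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import (
    GroupStats,
    OmicsDataset,
    SampleSelection,
    ValidationError,
    group_stats,
)

UP = "up_in_A"
DOWN = "down_in_A"


# ----------------------------------------------------------------------
# step 1: Gaussian Wasserstein pre-filter


def gaussian_wasserstein(stats: GroupStats) -> np.ndarray:
    """Closed-form 2-Wasserstein distance between fitted Gaussians, per feature.

    For univariate normals N(mu1, sigma1^2) and N(mu2, sigma2^2) the
    2-Wasserstein distance is sqrt((mu1 - mu2)^2 + (sigma1 - sigma2)^2);
    it reduces to \\|dmu\\| for a pure mean shift and \\|dsigma\\| for a pure
    variance shift.
    """
    return np.sqrt((stats.means_a - stats.means_b) ** 2 + (stats.stds_a - stats.stds_b) ** 2)


def rank_by_wasserstein(
    dataset: OmicsDataset,
    sel_a: SampleSelection,
    sel_b: SampleSelection,
    n_prefilter: int,
) -> np.ndarray:
    """Indices of the ``n_prefilter`` features with the largest Wasserstein
    distance between groups, in descending order (ties: ascending index)."""
    if n_prefilter < 1:
        raise ValueError("n_prefilter must be >= 1")
    if n_prefilter > dataset.n_features:
        warnings.warn(
            f"n_prefilter={n_prefilter} exceeds n_features={dataset.n_features}; clamped"
        )
        n_prefilter = dataset.n_features
    w = gaussian_wasserstein(group_stats(dataset, sel_a, sel_b))
    order = np.argsort(-w, kind="stable")  # stable: ties stay in index order
    return order[:n_prefilter]


# ----------------------------------------------------------------------
# step 2: MCC-optimal threshold


def mcc(tp, tn, fp, fn) -> float:
    """Matthews correlation coefficient from confusion counts.

    Defined as 0 when any factor of the denominator is 0 (the usual
    convention for degenerate confusion matrices).
    """
    counts = [float(c) for c in (tp, tn, fp, fn)]
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be non-negative")
    if sum(counts) < 1:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = counts
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _mcc_vec(tp, tn, fp, fn):
    tp, tn, fp, fn = (np.asarray(x, dtype=np.float64) for x in (tp, tn, fp, fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (tp * tn - fp * fn) / np.sqrt(denom), 0.0)
    return out


def _candidate_thresholds(values: np.ndarray, max_grid: int) -> np.ndarray:
    """Midpoints of consecutive distinct sorted values, subsampled to at
    most ``max_grid`` quantile-spaced candidates."""
    u = np.unique(values)
    if u.size < 2:
        return np.empty(0)
    cand = (u[:-1] + u[1:]) / 2.0
    if cand.size > max_grid:
        idx = np.unique(np.round(np.linspace(0, cand.size - 1, max_grid)).astype(int))
        cand = cand[idx]
    return cand


def best_threshold_mcc(
    values,
    in_group_a,
    max_grid: int = 100,
) -> tuple[float, str, float]:
    """MCC-optimal split threshold for one feature.

    Scans candidate thresholds in both polarities — ``up_in_A`` predicts
    membership in A where value > theta, ``down_in_A`` where value < theta
    — and returns ``(theta, direction, mcc)`` for the maximizing pair.
    Ties prefer the smaller theta, then ``up_in_A``.  Constant features
    return ``(constant, up_in_A, 0.0)``.
    """
    v = np.asarray(values, dtype=np.float64)
    a = np.asarray(in_group_a, dtype=bool)
    if v.shape != a.shape:
        raise ValueError("values and in_group_a must have the same length")
    na = int(a.sum())
    nb = int(v.size - na)
    if na == 0 or nb == 0:
        raise ValidationError("both classes must be non-empty")
    cand = _candidate_thresholds(v, max_grid)
    if cand.size == 0:
        return float(v[0]), UP, 0.0

    # thresholds are strict midpoints, so v > theta <=> not (v < theta)
    pred_up = v[None, :] > cand[:, None]
    tp = (pred_up & a[None, :]).sum(axis=1)
    fp = pred_up.sum(axis=1) - tp
    fn = na - tp
    tn = nb - fp
    mcc_up = _mcc_vec(tp, tn, fp, fn)
    mcc_down = _mcc_vec(fn, fp, tn, tp)  # complement prediction

    best = max(mcc_up.max(), mcc_down.max())
    # candidates are sorted ascending; first hit = smallest theta, up before down
    hit_up = np.flatnonzero(mcc_up == best)
    hit_down = np.flatnonzero(mcc_down == best)
    i_up = hit_up[0] if hit_up.size else np.inf
    i_down = hit_down[0] if hit_down.size else np.inf
    if i_up <= i_down:
        return float(cand[int(i_up)]), UP, float(best)
    return float(cand[int(i_down)]), DOWN, float(best)


# ----------------------------------------------------------------------
# signature results


@dataclass
class SignatureEntry:
    feature: str
    wasserstein: float
    threshold: float
    direction: str
    mcc: float


@dataclass
class SignatureResult:
    """Rank-ordered marker features for a two-group comparison."""

    entries: list[SignatureEntry]
    mode: str = "a_vs_rest"
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def features(self) -> list[str]:
        return [e.feature for e in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "feature": [e.feature for e in self.entries],
                "wasserstein": [e.wasserstein for e in self.entries],
                "threshold": [e.threshold for e in self.entries],
                "direction": [e.direction for e in self.entries],
                "mcc": [e.mcc for e in self.entries],
            }
        )


def compute_signature(
    dataset: OmicsDataset,
    sel_a: SampleSelection,
    sel_b: SampleSelection | None = None,
    n_prefilter: int = 500,
    n_top: int = 100,
    max_grid: int = 100,
) -> SignatureResult:
    """Two-step signature: Wasserstein pre-filter then MCC threshold scan.

    ``sel_b=None`` selects "A vs Rest" (B = complement of A); an explicit
    ``sel_b`` compares two subsets and samples in neither group are
    ignored.  Returns the ``n_top`` best entries ranked by MCC descending,
    ties by Wasserstein descending then feature index.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    mode = "a_vs_b" if sel_b is not None else "a_vs_rest"
    if sel_b is None:
        sel_b = sel_a.complement()
    if n_top > n_prefilter:
        raise ValueError("n_top must not exceed n_prefilter")

    kept = rank_by_wasserstein(dataset, sel_a, sel_b, n_prefilter)
    w = gaussian_wasserstein(group_stats(dataset, sel_a, sel_b))

    rows = np.concatenate([sel_a.indices, sel_b.indices])
    in_a = np.zeros(rows.size, dtype=bool)
    in_a[: sel_a.n_selected] = True
    block = dataset.dense_block(rows, kept)

    thetas = np.empty(kept.size)
    dirs: list[str] = []
    mccs = np.empty(kept.size)
    for j in range(kept.size):
        thetas[j], d, mccs[j] = best_threshold_mcc(block[:, j], in_a, max_grid)
        dirs.append(d)

    order = np.lexsort((kept, -w[kept], -mccs))
    entries = [
        SignatureEntry(
            feature=str(dataset.feature_names[kept[j]]),
            wasserstein=float(w[kept[j]]),
            threshold=float(thetas[j]),
            direction=dirs[j],
            mcc=float(mccs[j]),
        )
        for j in order[:n_top]
    ]
    return SignatureResult(
        entries=entries,
        mode=mode,
        params={
            "n_prefilter": int(min(n_prefilter, dataset.n_features)),
            "n_top": int(n_top),
            "max_grid": int(max_grid),
            "n_a": sel_a.n_selected,
            "n_b": sel_b.n_selected,
        },
    )


# ----------------------------------------------------------------------
# oriented signatures


@dataclass
class Arrow:
    """Directed segment drawn in a named embedding."""

    start: np.ndarray
    end: np.ndarray
    embedding_name: str = ""

    def __post_init__(self):
        self.start = np.asarray(self.start, dtype=np.float64)
        self.end = np.asarray(self.end, dtype=np.float64)
        if self.start.shape != self.end.shape:
            raise ValidationError("arrow start and end must have the same dimension")
        if np.allclose(self.start, self.end):
            raise ValidationError("zero-length arrow")


def project_onto_arrow(points: np.ndarray, arrow: Arrow) -> np.ndarray:
    """Scalar position of each point along the arrow.

    ``t = (p - start) . (end - start) / |end - start|^2``: 0 at the arrow
    start, 1 at its tip; points beyond the segment give t outside [0, 1]
    and are kept.  The component orthogonal to the arrow is ignored.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    d = arrow.end - arrow.start
    if pts.shape[1] != d.shape[0]:
        raise ValidationError("points and arrow live in different dimensions")
    return (pts - arrow.start) @ d / float(d @ d)


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation; 0 when either vector is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    den = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if den == 0.0:
        return 0.0
    return float(np.clip(xc @ yc / den, -1.0, 1.0))


@dataclass
class OrientedSignatureResult:
    """Features ranked by correlation with arrow-projection positions."""

    entries: list[tuple[str, float]]
    arrow: Arrow
    absolute: bool = False

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def features(self) -> list[str]:
        return [f for f, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "feature": [f for f, _ in self.entries],
                "pearson_r": [r for _, r in self.entries],
            }
        )


def oriented_signature(
    dataset: OmicsDataset,
    sel: SampleSelection,
    arrow: Arrow,
    n_top: int = 100,
    embedding: str | None = None,
    absolute: bool = False,
) -> OrientedSignatureResult:
    """Rank features by Pearson correlation with positions along an arrow.

    The selected samples' embedding coordinates are projected onto the
    arrow; each feature is then correlated with the projection positions.
    Default ranking is signed r descending ("most positively correlated
    first"); ``absolute=True`` ranks by \\|r\\| instead.  Requires at least
    3 selected samples.
    """
    if sel.n_selected < 3:
        raise ValidationError("oriented signature needs at least 3 selected samples")
    name = embedding or arrow.embedding_name or next(iter(dataset.embeddings))
    if name not in dataset.embeddings:
        raise KeyError(f"unknown embedding {name!r}")
    rows = sel.indices
    t = project_onto_arrow(dataset.embeddings[name][rows], arrow)

    X = dataset.dense_block(rows)
    xc = X - X.mean(axis=0)
    tc = t - t.mean()
    tss = float(tc @ tc)
    num = xc.T @ tc
    den = np.sqrt((xc**2).sum(axis=0) * tss)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip(np.where(den > 0, num / den, 0.0), -1.0, 1.0)

    key = -np.abs(r) if absolute else -r
    order = np.lexsort((np.arange(r.size), key))[:n_top]
    entries = [(str(dataset.feature_names[i]), float(r[i])) for i in order]
    return OrientedSignatureResult(entries=entries, arrow=arrow, absolute=absolute)
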