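"""Synthetic omics datasets with planted marker structure.

The generator emulates the structure the signature methods assume: groups
of samples (clusters) with planted mean-shift and variance-shift marker
features against a background of exchangeable null features, plus an
optional latent trajectory for testing oriented signatures.  Base noise is
either clean standard Gaussian (for unit tests with known moments) or
lognormal pseudo-counts, ``round(exp(z))``, mimicking log-normalizable
expression counts.  A PCA embedding of the standardized matrix is stored
under ``"X_pca"``.

Markers are exclusive to one cluster by default (the "ideal feature"
regime); ``shared_markers=True`` plants every marker in every cluster
pair-wise shifted instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .datasets import OmicsDataset

_U_SD = 1.0 / np.sqrt(12.0)  # population sd of Uniform(0, 1)


@dataclass
class TrajectoryConfig:
    """Latent-trajectory block: features correlated with a Uniform(0,1)
    latent position ``u`` at a configurable theoretical Pearson r."""

    n_correlated: int = 20
    correlation: float = 0.8
    u_range: tuple[float, float] = (0.0, 1.0)


@dataclass
class SimulationConfig:
    n_samples: int = 300
    n_features: int = 500
    clusters: tuple = (("c1", 1 / 3), ("c2", 1 / 3), ("c3", 1 / 3))
    mean_shift_markers: int | dict = 5      # per cluster (or {label: count})
    mean_shift_delta: float = 3.0    # in units of the base noise sd
    variance_shift_markers: int | dict = 0  # per cluster (or {label: count})
    variance_shift_ratio: float = 3.0  # sigma_cluster / sigma_rest
    noise: str = "gaussian"          # or "lognormal-counts"
    embedding: str = "pca2"          # pca2 | pca3
    shared_markers: bool = False
    trajectory: TrajectoryConfig | None = None
    seed: int = 0

    def __post_init__(self):
        props = [p for _, p in self.clusters]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        n_markers = sum(
            self.markers_for(lab, "mean") + self.markers_for(lab, "variance")
            for lab, _ in self.clusters
        )
        if n_markers > self.n_features:
            raise ValueError("more planted markers than features")
        if self.noise not in ("gaussian", "lognormal-counts"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        if self.embedding not in ("pca2", "pca3"):
            raise ValueError(f"unknown embedding spec {self.embedding!r}")

    def markers_for(self, label: str, kind: str) -> int:
        """Planted marker count of the given kind for one cluster label."""
        spec = self.mean_shift_markers if kind == "mean" else self.variance_shift_markers
        if isinstance(spec, dict):
            return int(spec.get(label, 0))
        return int(spec)


def _cluster_assignment(config: SimulationConfig) -> np.ndarray:
    """Deterministic label vector honouring the configured proportions."""
    n = config.n_samples
    counts = [int(np.floor(p * n)) for _, p in config.clusters]
    for i in range(n - sum(counts)):  # distribute the rounding remainder
        counts[i % len(counts)] += 1
    labels = np.concatenate(
        [np.full(c, lab, dtype=object) for (lab, _), c in zip(config.clusters, counts)]
    )
    return labels


def _embed(X: np.ndarray, n_components: int, seed: int) -> np.ndarray:
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    return PCA(n_components=n_components, random_state=seed).fit_transform(Z)


def simulate_dataset(config: SimulationConfig) -> tuple[OmicsDataset, pd.DataFrame]:
    """Draw a clustered dataset with planted markers.

    Returns the dataset and a ground-truth table with one row per planted
    marker: feature name, cluster, marker type (``mean_shift`` /
    ``variance_shift``) and planted effect size.  Mean shifts add
    ``delta`` (in base-noise sd units) to the marker feature inside its
    cluster; variance shifts multiply the in-cluster noise by ``ratio``.
    Effects are applied on the Gaussian latent scale, before the optional
    lognormal-counts transform.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    noise_rng, emb_seed = rng.spawn(1)[0], int(rng.integers(2**31 - 1))
    n, f = config.n_samples, config.n_features
    labels = _cluster_assignment(config)

    Z = noise_rng.standard_normal((n, f))
    truth_rows = []
    next_feature = 0
    feature_names = np.array([f"f{j:04d}" for j in range(f)], dtype=object)

    cluster_labels = [lab for lab, _ in config.clusters]
    for ci, lab in enumerate(cluster_labels):
        in_cluster = labels == lab
        if config.shared_markers and len(cluster_labels) > 1:
            # marker shared with the next cluster (cyclically)
            in_cluster = in_cluster | (labels == cluster_labels[(ci + 1) % len(cluster_labels)])
        for _ in range(config.markers_for(lab, "mean")):
            j = next_feature
            next_feature += 1
            Z[in_cluster, j] += config.mean_shift_delta
            truth_rows.append(
                {"feature": feature_names[j], "cluster": lab,
                 "type": "mean_shift", "effect": config.mean_shift_delta}
            )
        for _ in range(config.markers_for(lab, "variance")):
            j = next_feature
            next_feature += 1
            Z[in_cluster, j] *= config.variance_shift_ratio
            truth_rows.append(
                {"feature": feature_names[j], "cluster": lab,
                 "type": "variance_shift", "effect": config.variance_shift_ratio}
            )

    X = np.rint(np.exp(Z)) if config.noise == "lognormal-counts" else Z
    emb = _embed(X, 3 if config.embedding == "pca3" else 2, emb_seed)

    ds = OmicsDataset(
        matrix=X,
        feature_names=feature_names,
        sample_ids=np.array([f"s{i:04d}" for i in range(n)], dtype=object),
        annotations=pd.DataFrame({"cluster": labels.astype(str)},
                                 index=[f"s{i:04d}" for i in range(n)]),
        embeddings={"X_pca": emb},
    )
    truth = pd.DataFrame(truth_rows, columns=["feature", "cluster", "type", "effect"])
    return ds, truth


def simulate_trajectory(config: SimulationConfig) -> tuple[OmicsDataset, np.ndarray]:
    """Draw a dataset whose first embedding axis is a latent trajectory.

    Samples receive a latent position ``u ~ Uniform(0, 1)``; the first
    ``n_correlated`` features are ``u`` plus Gaussian noise scaled so the
    theoretical Pearson correlation with ``u`` equals the configured
    ``correlation``; the remaining features are independent standard
    normal nulls.  The stored embedding ``"X_traj"`` has ``u`` as its
    first axis, so a straight arrow along axis 1 recovers ``u`` exactly.
    """
    if config.trajectory is None:
        raise ValueError("config.trajectory block is required")
    traj = config.trajectory
    if not 0 < traj.correlation <= 1:
        raise ValueError("trajectory correlation must be in (0, 1]")
    if traj.n_correlated > config.n_features:
        raise ValueError("more trajectory features than features")
    rng = np.random.default_rng(config.seed)
    n, f = config.n_samples, config.n_features

    lo, hi = traj.u_range
    u = rng.uniform(lo, hi, size=n)
    u01 = (u - lo) / (hi - lo)
    X = rng.standard_normal((n, f))
    rho = traj.correlation
    noise_sd = 0.0 if rho == 1.0 else _U_SD * np.sqrt(1.0 / rho**2 - 1.0)
    for j in range(traj.n_correlated):
        X[:, j] = u01 + noise_sd * rng.standard_normal(n)

    emb = np.column_stack([u, 0.05 * rng.standard_normal(n)])
    ds = OmicsDataset(
        matrix=X,
        feature_names=np.array([f"f{j:04d}" for j in range(f)], dtype=object),
        sample_ids=np.array([f"s{i:04d}" for i in range(n)], dtype=object),
        annotations=pd.DataFrame({"cluster": ["all"] * n},
                                 index=[f"s{i:04d}" for i in range(n)]),
        embeddings={"X_traj": emb},
    )
    return ds, u
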