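"""Planted-block synthetic expression data for end-to-end testing.

The generator emulates the study conditions the pipeline targets: a few
hundred strictly positive expression features over a small cohort
(default 17 samples), organized into correlation blocks.  Each block k
has a latent factor ``z_k`` (standard normal over samples); feature i
of block k is ``exp(a * z_k + eps_i)`` with Gaussian feature noise, so
values are log-normal — strictly positive with intensity-like skew,
valid for ratio metafeatures and probability profiles.

The signal coefficient ``a = noise_sd * sqrt(rho / (1 - rho))`` makes
the population Pearson correlation of the log-values between two
features of the same block exactly ``rho_within``; features of
different blocks are independent.  ``noise_sd = 0`` is the exact limit:
features are noiseless monotone transforms of their latent
(correlation 1).

Marker vectors are blends ``alpha * z_k + sqrt(1 - alpha^2) * eta``
with ``alpha = min(1, rho_target / sqrt(rho_within))``, so the expected
correlation between the marker and a block member is ``rho_target``
(clipped at the attainable maximum ``sqrt(rho_within)``).

All randomness flows from a single integer seed; the same parameters
always produce the identical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PlantedDataset:
    """A synthetic expression matrix with known block structure."""

    X: pd.DataFrame
    labels: dict[str, int]
    latents: np.ndarray  # (n_blocks, n_samples)
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return self.latents.shape[0]


def planted_expression(
    n_blocks: int = 5,
    features_per_block: int = 30,
    n_samples: int = 17,
    rho_within: float = 0.9,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> PlantedDataset:
    """Generate a positive expression matrix with planted correlation blocks."""
    if n_samples < 5:
        raise ValueError(f"need at least 5 samples, got {n_samples}")
    if n_blocks < 1 or features_per_block < 1:
        raise ValueError("n_blocks and features_per_block must be positive")
    if not 0 < rho_within < 1:
        raise ValueError(f"rho_within must lie in (0, 1), got {rho_within}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be nonnegative, got {noise_sd}")
    rng = np.random.default_rng(seed)
    latents = rng.standard_normal((n_blocks, n_samples))
    if noise_sd > 0:
        a = noise_sd * np.sqrt(rho_within / (1.0 - rho_within))
    else:
        a = 1.0  # noiseless limit: features are exact transforms of the latent
    rows = {}
    labels = {}
    for k in range(n_blocks):
        for i in range(features_per_block):
            fid = f"B{k}F{i:03d}"
            eps = rng.standard_normal(n_samples) * noise_sd
            rows[fid] = np.exp(a * latents[k] + eps)
            labels[fid] = k
    X = pd.DataFrame.from_dict(rows, orient="index")
    X.columns = [f"S{j:02d}" for j in range(n_samples)]
    params = dict(
        n_blocks=n_blocks,
        features_per_block=features_per_block,
        n_samples=n_samples,
        rho_within=rho_within,
        noise_sd=noise_sd,
        seed=seed,
    )
    return PlantedDataset(X=X, labels=labels, latents=latents, params=params)


def planted_marker(
    dataset: PlantedDataset,
    block_id: int,
    rho_target: float = 0.9,
    seed: int = 0,
    name: str | None = None,
) -> np.ndarray:
    """A marker vector correlated with one planted block's members.

    The marker is a noisy copy of the block's latent factor, calibrated
    so its expected correlation with block members is ``rho_target``.
    The marker is also stored on the dataset under ``name`` (default
    ``marker_block<k>``).
    """
    if not 0 <= block_id < dataset.n_blocks:
        raise ValueError(
            f"unknown block {block_id}; dataset has {dataset.n_blocks} blocks"
        )
    if not 0 < rho_target <= 1:
        raise ValueError(f"rho_target must lie in (0, 1], got {rho_target}")
    rng = np.random.default_rng(seed)
    rho_within = dataset.params["rho_within"]
    alpha = min(1.0, rho_target / np.sqrt(rho_within))
    z = dataset.latents[block_id]
    eta = rng.standard_normal(z.size)
    marker = alpha * z + np.sqrt(max(0.0, 1.0 - alpha**2)) * eta
    dataset.markers[name or f"marker_block{block_id}"] = marker
    return marker


def null_marker(dataset: PlantedDataset, seed: int = 0, name: str = "null") -> np.ndarray:
    """A marker vector independent of every planted block (pure noise)."""
    rng = np.random.default_rng(seed)
    marker = rng.standard_normal(dataset.X.shape[1])
    dataset.markers[name] = marker
    return marker


def labels_as_clustering(dataset: PlantedDataset) -> dict[str, int]:
    """The planted block labels in clustering-assignment form."""
    return dict(dataset.labels)
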