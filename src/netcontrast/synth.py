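"""Synthetic connectome cohorts with planted condition effects.

Emulates the data structure the analysis assumes: several datasets of
participants, each measured under a fear and a neutral condition, with
block-structured symmetric connectivity (stronger within-network than
between-network weights, a fraction of between-network edges negative),
subject- and dataset-level random offsets, edge-level Gaussian noise, and
an additive within-network weight increase planted in one network for the
fear condition.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import NodeTable, ConnectivityRecord, MANIFEST_COLUMNS, default_node_table

__all__ = ["SyntheticConfig", "GroundTruth", "generate_cohort", "summarize_truth"]


class ConfigError(ValueError):
    """Raised for inconsistent generator configuration."""


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the emulated study's structure.

    ``dataset_sizes`` defaults to the four source datasets' post-exclusion
    sizes; ``mu_within``/``mu_between`` set the block means of the
    connectivity weights on an unconstrained real scale (only weight ranks
    matter downstream once matrices are absolute-valued and proportionally
    thresholded); ``effect_delta`` is added to every edge with both
    endpoints in ``affected_network`` in the fear condition.
    """

    partition: NodeTable = field(default_factory=default_node_table)
    dataset_sizes: tuple[int, ...] = (18, 29, 34, 28)
    dataset_ids: tuple[str, ...] = ("A", "B", "C", "D")
    mu_within: float = 0.5
    mu_between: float = 0.2
    sigma_subject: float = 0.05
    sigma_dataset: float = 0.05
    sigma_noise: float = 0.1
    effect_delta: float = 0.15
    affected_network: str = "Somatomotor"
    neg_fraction: float = 0.3
    age_mean: float = 22.06
    age_sd: float = 4.79
    clip_unit: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.dataset_sizes) != len(self.dataset_ids):
            raise ConfigError("dataset_sizes and dataset_ids lengths differ")
        if any(n <= 0 for n in self.dataset_sizes):
            raise ConfigError("dataset sizes must be positive")
        if not self.mu_within > self.mu_between >= 0:
            raise ConfigError("require mu_within > mu_between >= 0")
        if min(self.sigma_subject, self.sigma_dataset, self.sigma_noise) < 0:
            raise ConfigError("standard deviations must be nonnegative")
        if not 0.0 <= self.neg_fraction <= 1.0:
            raise ConfigError("neg_fraction must lie in [0, 1]")
        if self.affected_network not in set(self.partition.table["network"]):
            raise ConfigError(
                f"affected_network {self.affected_network!r} not in partition"
            )

    @property
    def n_nodes(self) -> int:
        return self.partition.n_nodes


@dataclass
class GroundTruth:
    """What was planted, for downstream recovery evaluation."""

    affected_node_ids: np.ndarray
    effect_delta: float
    subject_offsets: pd.Series  # indexed by participant_id
    dataset_offsets: pd.Series  # indexed by dataset_id


def _truncated_ages(rng: np.random.Generator, n: int, mean: float, sd: float
                    ) -> np.ndarray:
    """Ages from a normal truncated below at 18 (recruitment floor)."""
    lo = (18.0 - mean) / sd
    tn = stats.truncnorm(lo, np.inf, loc=mean, scale=sd)
    return tn.ppf(rng.uniform(size=n))


def _symmetric_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    out = np.zeros((n, n))
    out[iu] = rng.normal(0.0, sd, size=len(iu[0]))
    return out + out.T


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[ConnectivityRecord], GroundTruth, pd.DataFrame]:
    """Draw a full cohort: two matrices per participant plus ground truth.

    The neutral matrix is ``block mean + dataset offset + subject offset +
    edge noise`` with a ``neg_fraction`` of between-network edges
    sign-flipped; the fear matrix is identical in expectation except that
    edges inside ``affected_network`` gain ``effect_delta``.  The returned
    manifest has empty path columns until the matrices are written out.
    """
    rng = np.random.default_rng(config.seed)
    part = config.partition
    n = part.n_nodes
    labels = part.community_labels
    same_net = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)

    base = np.where(same_net, config.mu_within, config.mu_between).astype(float)
    np.fill_diagonal(base, 0.0)

    affected = part.nodes_in_network(config.affected_network)
    in_affected = np.zeros(n, dtype=bool)
    in_affected[affected] = True
    effect_mask = np.outer(in_affected, in_affected)
    np.fill_diagonal(effect_mask, False)

    dataset_offsets = pd.Series(
        rng.normal(0.0, config.sigma_dataset, size=len(config.dataset_ids)),
        index=list(config.dataset_ids),
    )

    records: list[ConnectivityRecord] = []
    manifest_rows = []
    subject_offsets = {}
    for ds_id, ds_n in zip(config.dataset_ids, config.dataset_sizes):
        ages = _truncated_ages(rng, ds_n, config.age_mean, config.age_sd)
        for k in range(ds_n):
            pid = f"{ds_id}{k + 1:03d}"
            subj_off = rng.normal(0.0, config.sigma_subject)
            subject_offsets[pid] = subj_off

            # per-subject sign pattern on between-network edges
            signs = np.ones((n, n))
            between_iu = ~same_net[iu]
            flips = rng.uniform(size=between_iu.sum()) < config.neg_fraction
            sign_u = np.ones(len(iu[0]))
            sign_u[np.flatnonzero(between_iu)[flips]] = -1.0
            signs[iu] = sign_u
            signs = np.triu(signs, 1) + np.triu(signs, 1).T

            mean = base + subj_off + dataset_offsets[ds_id]
            np.fill_diagonal(mean, 0.0)
            for condition in ("fear", "neutral"):
                w = mean + _symmetric_noise(rng, n, config.sigma_noise)
                if condition == "fear":
                    w = w + config.effect_delta * effect_mask
                w = w * signs
                np.fill_diagonal(w, 0.0)
                if config.clip_unit:
                    w = np.clip(w, -1.0, 1.0)
                records.append(
                    ConnectivityRecord(
                        participant_id=pid,
                        dataset_id=ds_id,
                        condition=condition,
                        age=float(ages[k]),
                        matrix=w,
                    )
                )
            manifest_rows.append((pid, ds_id, float(ages[k]), "", ""))

    truth = GroundTruth(
        affected_node_ids=affected.copy(),
        effect_delta=config.effect_delta if config.effect_delta != 0 else 0.0,
        subject_offsets=pd.Series(subject_offsets),
        dataset_offsets=dataset_offsets,
    )
    manifest = pd.DataFrame(manifest_rows, columns=MANIFEST_COLUMNS)
    return records, truth, manifest


def summarize_truth(truth: GroundTruth, node_table: NodeTable) -> pd.DataFrame:
    """Per-node planted/not-planted flags for recovery scoring.

    With ``effect_delta == 0`` nothing was planted and all flags are False.
    """
    ids = np.asarray(truth.affected_node_ids)
    if ids.size and (ids.min() < 0 or ids.max() >= node_table.n_nodes):
        raise ValueError("ground-truth node id outside the node table")
    planted = np.zeros(node_table.n_nodes, dtype=bool)
    if truth.effect_delta != 0:
        planted[ids] = True
    return pd.DataFrame(
        {"node_id": np.arange(node_table.n_nodes), "planted": planted}
    )


def make_config(partition: NodeTable | None = None, **kwargs) -> SyntheticConfig:
    """Convenience constructor allowing a custom partition with defaults."""
    if partition is not None:
        kwargs["partition"] = partition
    return SyntheticConfig(**kwargs)
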