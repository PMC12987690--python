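"""Trajectory data container, CSV I/O and trajectory-level bootstrap resampling.

The universal input is a balanced panel: ``n`` subjects observed over ``T``
stages, each stage contributing a feature vector, a binary action in
{-1, +1}, a reward, and the (known) probability with which the behavior
policy assigned the action actually taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import as_rng

__all__ = [
    "TrajectoryDataset",
    "ValidationError",
    "default_schema",
    "read_trajectories",
    "write_trajectories",
    "bootstrap_resample",
]


class ValidationError(ValueError):
    """Raised when a dataset violates the structural invariants."""


def default_schema(d: int) -> dict:
    """Default long-format column mapping for ``d`` features."""
    return {
        "subject_id": "subject_id",
        "stage": "stage",
        "features": [f"x{j}" for j in range(1, d + 1)],
        "action": "action",
        "reward": "reward",
        "behavior_prob": "behavior_prob",
    }


@dataclass
class TrajectoryDataset:
    """Balanced longitudinal dataset of n subjects x T stages.

    Attributes
    ----------
    features : ndarray, shape (n, T, d)
    actions : ndarray, shape (n, T), values in {-1, +1}
    rewards : ndarray, shape (n, T)
    behavior_prob : ndarray, shape (n, T)
        Probability of the action actually taken under the behavior policy.
    subject_ids : ndarray, shape (n,), optional labels preserved through I/O.
    """

    features: np.ndarray
    actions: np.ndarray
    rewards: np.ndarray
    behavior_prob: np.ndarray
    subject_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.actions = np.asarray(self.actions)
        self.rewards = np.asarray(self.rewards, dtype=float)
        self.behavior_prob = np.asarray(self.behavior_prob, dtype=float)
        if self.subject_ids is None:
            self.subject_ids = np.arange(1, self.features.shape[0] + 1)
        else:
            self.subject_ids = np.asarray(self.subject_ids)
        self.validate()

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def T(self) -> int:
        return self.features.shape[1]

    @property
    def d(self) -> int:
        return self.features.shape[2]

    def validate(self, p0: float = 1e-8) -> None:
        """Check shapes, action domain, positivity and missingness.

        Idempotent and side-effect free; raises :class:`ValidationError`
        on the first violated invariant.
        """
        if p0 <= 0:
            raise ValueError("p0 must be positive")
        if self.features.ndim != 3:
            raise ValidationError("features must have shape (n, T, d)")
        n, T, _ = self.features.shape
        if n < 1 or T < 1 or self.features.shape[2] < 1:
            raise ValidationError("n, T, d must all be positive")
        for name in ("actions", "rewards", "behavior_prob"):
            arr = getattr(self, name)
            if arr.shape != (n, T):
                raise ValidationError(f"{name} must have shape (n, T)={(n, T)}, got {arr.shape}")
        if self.subject_ids.shape != (n,):
            raise ValidationError("subject_ids must have length n")
        if not np.all(np.isin(self.actions, (-1, 1))):
            bad = np.argwhere(~np.isin(self.actions, (-1, 1)))[0]
            raise ValidationError(
                f"actions must be -1 or +1; subject index {bad[0]}, stage {bad[1] + 1} "
                f"has value {self.actions[tuple(bad)]}"
            )
        for name in ("features", "rewards", "behavior_prob"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"{name} contains missing or non-finite values")
        if np.any(self.behavior_prob < p0) or np.any(self.behavior_prob > 1.0):
            bad = np.argwhere((self.behavior_prob < p0) | (self.behavior_prob > 1.0))[0]
            raise ValidationError(
                f"behavior_prob must lie in [{p0}, 1]; subject index {bad[0]}, "
                f"stage {bad[1] + 1} has value {self.behavior_prob[tuple(bad)]}"
            )

    def subset(self, idx) -> "TrajectoryDataset":
        """New dataset containing trajectories ``idx`` (with repetition allowed)."""
        idx = np.asarray(idx)
        return TrajectoryDataset(
            features=self.features[idx].copy(),
            actions=self.actions[idx].copy(),
            rewards=self.rewards[idx].copy(),
            behavior_prob=self.behavior_prob[idx].copy(),
            subject_ids=np.arange(1, len(idx) + 1),
        )


def read_trajectories(path, schema: dict | None = None) -> TrajectoryDataset:
    """Read a long-format CSV (one row per subject-stage) into a dataset.

    Subjects are ordered by first appearance; stages must be contiguous
    1..T (in order) and T must be common across subjects.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema is None:
        feat_cols = sorted(
            (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        schema = default_schema(len(feat_cols))
        schema["features"] = feat_cols
    missing = [
        c
        for c in [schema["subject_id"], schema["stage"], schema["action"],
                  schema["reward"], schema["behavior_prob"], *schema["features"]]
        if c not in df.columns
    ]
    if missing:
        raise ValidationError(f"missing column(s): {missing}")
    if not schema["features"]:
        raise ValidationError("schema declares no feature columns")

    sid_col = schema["subject_id"]
    order = df[sid_col].drop_duplicates().tolist()  # first-appearance order
    groups = [df[df[sid_col] == s] for s in order]
    T = len(groups[0])
    for s, g in zip(order, groups):
        stages = g[schema["stage"]].to_numpy()
        if len(g) != T:
            raise ValidationError(f"subject {s!r} has {len(g)} stages, expected {T}")
        if not np.array_equal(stages, np.arange(1, len(g) + 1)):
            raise ValidationError(f"subject {s!r}: stages must be contiguous 1..T in order")

    feats = np.stack([g[schema["features"]].to_numpy(dtype=float) for g in groups])
    actions = np.stack([g[schema["action"]].to_numpy() for g in groups])
    rewards = np.stack([g[schema["reward"]].to_numpy(dtype=float) for g in groups])
    mu = np.stack([g[schema["behavior_prob"]].to_numpy(dtype=float) for g in groups])

    for i, s in enumerate(order):
        for t in range(T):
            if actions[i, t] not in (-1, 1):
                raise ValidationError(
                    f"subject {s!r}, stage {t + 1}: action {actions[i, t]} not in {{-1, +1}}"
                )
            if not (0.0 < mu[i, t] <= 1.0):
                raise ValidationError(
                    f"subject {s!r}, stage {t + 1}: behavior_prob {mu[i, t]} outside (0, 1]"
                )
    return TrajectoryDataset(feats, actions.astype(int), rewards, mu,
                             subject_ids=np.asarray(order))


def write_trajectories(ds: TrajectoryDataset, path, schema: dict | None = None) -> None:
    """Write the dataset as long-format CSV at full float precision."""
    if schema is None:
        schema = default_schema(ds.d)
    rows = {
        schema["subject_id"]: np.repeat(ds.subject_ids, ds.T),
        schema["stage"]: np.tile(np.arange(1, ds.T + 1), ds.n),
    }
    def full_precision(arr):  # shortest exact round-trip representation
        return [repr(float(v)) for v in arr]

    flat = ds.features.reshape(ds.n * ds.T, ds.d)
    for j, col in enumerate(schema["features"]):
        rows[col] = full_precision(flat[:, j])
    rows[schema["action"]] = ds.actions.reshape(-1)
    rows[schema["reward"]] = full_precision(ds.rewards.reshape(-1))
    rows[schema["behavior_prob"]] = full_precision(ds.behavior_prob.reshape(-1))
    pd.DataFrame(rows).to_csv(path, index=False)


def bootstrap_resample(ds: TrajectoryDataset, seed) -> TrajectoryDataset:
    """Resample n whole trajectories with replacement (never stage-wise)."""
    rng = as_rng(seed)
    idx = rng.integers(0, ds.n, size=ds.n)
    return ds.subset(idx)
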