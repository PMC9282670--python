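"""Virtual respondent cohorts.

Simulates the study population: latent skin-cancer risk measures drawn from
``Normal(mean, SD)`` (default 0, 1), category responses to every bank item
sampled from the partial credit model at the respondent's true measure, and
a binary cancer label assigned by thresholding the TRUE measure at a cutoff
(default 0.88 logits; the boundary itself counts as cancer).  Splitting
utilities produce the 70:30 hold-out partition and (stratified) k-folds
used for classifier benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import pcm
from .item_bank import ItemBank

__all__ = [
    "SimulationConfig",
    "SplitSpec",
    "Cohort",
    "generate_cohort",
    "split_holdout",
    "make_folds",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort simulation settings (defaults are the study conditions)."""

    n: int = 1000
    ability_mean: float = 0.0
    ability_sd: float = 1.0
    cutoff: float = 0.88
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.ability_sd <= 0:
            raise ValueError("ability_sd must be > 0")


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out / k-fold splitting settings."""

    train_fraction: float = 0.7
    folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class Cohort:
    """Simulated respondents: responses, true abilities, labels, ids."""

    responses: np.ndarray  # (n, n_items) integer category scores
    thetas: np.ndarray  # (n,) logits
    labels: np.ndarray  # (n,) in {0, 1}; 1 = cancer
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        self.thetas = np.asarray(self.thetas, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.thetas)
        if self.ids is None:
            self.ids = np.arange(1, n + 1)
        self.ids = np.asarray(self.ids)
        if not (self.responses.shape[0] == n == len(self.labels) == len(self.ids)):
            raise ValueError("inconsistent cohort shapes")
        if len(set(self.ids.tolist())) != n:
            raise ValueError("cohort ids must be unique")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def n(self) -> int:
        return len(self.thetas)

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def subset(self, idx: np.ndarray) -> "Cohort":
        return Cohort(
            responses=self.responses[idx],
            thetas=self.thetas[idx],
            labels=self.labels[idx],
            ids=self.ids[idx],
        )


def generate_cohort(bank: ItemBank, config: SimulationConfig) -> Cohort:
    """Simulate a cohort from the item bank under ``config``.

    Abilities are Normal(ability_mean, ability_sd); each item column is
    sampled from the PCM at the true abilities; ``label = 1`` iff
    ``theta >= cutoff``.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    thetas = rng.normal(config.ability_mean, config.ability_sd, size=config.n)
    cols = [pcm.sample_responses(thetas, item, rng) for item in bank]
    responses = np.column_stack(cols)
    labels = (thetas >= config.cutoff).astype(np.int64)
    return Cohort(responses=responses, thetas=thetas, labels=labels)


def split_holdout(cohort: Cohort, spec: SplitSpec) -> tuple[Cohort, Cohort]:
    """Seeded 70:30-style hold-out partition (unstratified shuffle)."""
    n_train = int(round(cohort.n * spec.train_fraction))
    if n_train < 1 or n_train >= cohort.n:
        raise ValueError(f"degenerate split: {n_train} train of {cohort.n}")
    perm = np.random.default_rng(spec.seed).permutation(cohort.n)
    return cohort.subset(perm[:n_train]), cohort.subset(perm[n_train:])


def make_folds(cohort: Cohort, spec: SplitSpec) -> list[tuple[Cohort, Cohort]]:
    """Seeded k-fold partition; stratified by label when ``spec.stratified``."""
    if spec.folds > cohort.n:
        raise ValueError("more folds than respondents")
    cls = StratifiedKFold if spec.stratified else KFold
    kf = cls(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    return [
        (cohort.subset(tr), cohort.subset(te))
        for tr, te in kf.split(cohort.responses, cohort.labels)
    ]


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort CSV: columns id, theta, label, item_1..item_K."""
    df = pd.DataFrame(
        cohort.responses,
        columns=[f"item_{j + 1}" for j in range(cohort.n_items)],
    )
    df.insert(0, "label", cohort.labels)
    df.insert(0, "theta", cohort.thetas)
    df.insert(0, "id", cohort.ids)
    df.to_csv(path, index=False)


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort` (lossless)."""
    df = pd.read_csv(path)
    for col in ("id", "theta", "label"):
        if col not in df.columns:
            raise ValueError(f"cohort CSV missing required column {col!r}")
    item_cols = [c for c in df.columns if c.startswith("item_")]
    if not item_cols:
        raise ValueError("cohort CSV has no item_* columns")
    item_cols = sorted(item_cols, key=lambda c: int(c.split("_")[1]))
    return Cohort(
        responses=df[item_cols].to_numpy(dtype=np.int64),
        thetas=df["theta"].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=np.int64),
        ids=df["id"].to_numpy(),
    )
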