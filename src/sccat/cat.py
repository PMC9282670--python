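"""Computerized adaptive testing (CAT) engine.

The adaptive loop: start at theta 0, administer a seeded random first item,
then repeatedly (1) update the provisional ability by a Newton-Raphson step
on the score equation, (2) recompute the standard error
``SE = 1 / sqrt(sum information)``, (3) stop once the SE falls below the
standard error of measurement ``SEM = SD * sqrt(1 - reliability)`` (or the
ability estimate stops moving, or the bank is exhausted), otherwise
(4) administer the unused item with maximum information at the current
ability.  On stop, unanswered items are imputed with their model-expected
scores at the final ability so a complete feature vector is available for
classification, and person-fit statistics (infit/outfit mean squares, the
df-adjusted mean square v and its t transform) summarise how well the
observed pattern matches the model.

The raw Newton step diverges on perfect/zero response patterns, so updates
are capped at 1 logit per step and the ability is clamped to [-6, 6]; both
safeguards can be disabled for the textbook formula.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import pcm
from .item_bank import ItemBank, ItemParameters

__all__ = [
    "StopRule",
    "CatSession",
    "FitReport",
    "update_theta",
    "standard_error",
    "select_next_item",
    "should_stop",
    "impute_unanswered",
    "fit_statistics",
    "run_cat",
    "converge_theta",
    "trajectory_flatness",
    "SimulatedResponder",
    "ReplayResponder",
]

THETA_CLAMP = 6.0
MAX_NEWTON_STEP = 1.0


@dataclass(frozen=True)
class StopRule:
    """Termination settings for a CAT session.

    ``sem_threshold`` is the standard error of measurement the session must
    beat; by default it is derived from a questionnaire SD of 1.0 logits and
    a Cronbach alpha of .78: ``SEM = 1.0 * sqrt(1 - .78) = 0.469``.  As a
    secondary rule the session also stops once at least ``min_items`` have
    been administered and the provisional ability moved by less than
    ``theta_residual_tol`` between steps.
    """

    sem_threshold: float = 0.469
    reliability: float = 0.78
    sd: float = 1.0
    theta_residual_tol: float = 0.05
    min_items: int = 5
    max_items: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.reliability < 1.0:
            raise ValueError("reliability must be in (0, 1)")
        if self.sem_threshold <= 0:
            raise ValueError("sem_threshold must be > 0")

    @classmethod
    def from_reliability(cls, reliability: float, sd: float = 1.0, **kw) -> "StopRule":
        """Build a rule with ``sem_threshold = sd * sqrt(1 - reliability)``."""
        sem = sem_from_reliability(reliability, sd)
        return cls(sem_threshold=sem, reliability=reliability, sd=sd, **kw)


def sem_from_reliability(reliability: float, sd: float = 1.0) -> float:
    """Standard error of measurement: SEM = SD * sqrt(1 - reliability)."""
    if not 0.0 <= reliability < 1.0:
        raise ValueError("reliability must be in [0, 1)")
    return sd * math.sqrt(1.0 - reliability)


@dataclass
class CatSession:
    """The evolving record of one adaptive test."""

    bank: ItemBank
    initial_theta: float = 0.0
    administered: list[tuple[int, float]] = field(default_factory=list)
    theta_trajectory: list[float] = field(default_factory=list)
    se_trajectory: list[float] = field(default_factory=list)
    final_theta: float | None = None
    final_se: float | None = None
    imputed_vector: np.ndarray | None = None
    stopped_because: str | None = None

    @property
    def current_theta(self) -> float:
        return self.theta_trajectory[-1] if self.theta_trajectory else self.initial_theta

    @property
    def administered_ids(self) -> list[int]:
        return [iid for iid, _ in self.administered]

    @property
    def n_administered(self) -> int:
        return len(self.administered)

    @property
    def is_stopped(self) -> bool:
        return self.stopped_because is not None

    @property
    def items_saved_fraction(self) -> float:
        """Fraction of the bank not administered: (N - answered) / N."""
        return (len(self.bank) - self.n_administered) / len(self.bank)

    def administer(self, item_id: int, observed: float) -> None:
        """Record one response (validated against the item's categories)."""
        if item_id in self.administered_ids:
            raise ValueError(f"item {item_id} already administered")
        item = self.bank[item_id]
        if not 0 <= observed <= item.max_score:
            raise ValueError(
                f"response {observed} out of range 0..{item.max_score} for item {item_id}"
            )
        self.administered.append((item_id, float(observed)))

    def _observed_and_items(self) -> tuple[np.ndarray, list[ItemParameters]]:
        obs = np.array([o for _, o in self.administered], dtype=float)
        items = [self.bank[iid] for iid in self.administered_ids]
        return obs, items

    def to_dict(self) -> dict:
        """JSON-ready session log (administered order, trajectories, result)."""
        d = {
            "initial_theta": self.initial_theta,
            "administered": [
                {"item_id": iid, "observed": obs} for iid, obs in self.administered
            ],
            "theta_trajectory": list(self.theta_trajectory),
            "se_trajectory": list(self.se_trajectory),
            "final_theta": self.final_theta,
            "final_se": self.final_se,
            "stopped_because": self.stopped_because,
            "items_saved_fraction": self.items_saved_fraction,
        }
        if self.imputed_vector is not None:
            d["imputed_vector"] = [float(v) for v in self.imputed_vector]
        if self.n_administered >= 2 and self.is_stopped:
            d["fit"] = fit_statistics(self).to_dict()
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass(frozen=True)
class FitReport:
    """Person-fit diagnostics for one session.

    ``z_scores`` are standardised residuals ``(O - E) / sqrt(Var)`` per
    administered item; outfit is their mean square, infit the
    information-weighted mean square, ``v = outfit * n / (n - 1)`` the
    df-adjusted mean square and ``t = ln(v) + v - 1`` its approximately
    unit-normal transform.  Outfit above 2.0 flags an aberrant pattern.
    """

    infit_mnsq: float
    outfit_mnsq: float
    z_scores: tuple[float, ...]
    v: float
    t_statistic: float
    df: int

    OUTFIT_ABERRANT_CUTOFF = 2.0

    @property
    def aberrant(self) -> bool:
        return self.outfit_mnsq > self.OUTFIT_ABERRANT_CUTOFF

    def to_dict(self) -> dict:
        return {
            "infit_mnsq": self.infit_mnsq,
            "outfit_mnsq": self.outfit_mnsq,
            "z_scores": list(self.z_scores),
            "v": self.v,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "aberrant": self.aberrant,
        }


def update_theta(
    session: CatSession,
    max_step: float | None = MAX_NEWTON_STEP,
    clamp: float | None = THETA_CLAMP,
) -> float:
    """One Newton-Raphson step on the score equation.

    ``theta_{m+1} = theta_m + sum(O - E) / sum(Var)`` with expectation and
    variance evaluated at the current provisional theta.  The step is capped
    at ``max_step`` logits and the result clamped to ``[-clamp, clamp]``
    (pass ``None`` to disable either safeguard).
    """
    if not session.administered:
        raise ValueError("cannot update theta before any item is administered")
    theta = session.current_theta
    obs, items = session._observed_and_items()
    residual = sum(o - pcm.expected_score(theta, it) for o, it in zip(obs, items))
    total_var = sum(pcm.item_information(theta, it) for it in items)
    step = residual / total_var
    if max_step is not None:
        step = float(np.clip(step, -max_step, max_step))
    theta = theta + step
    if clamp is not None:
        theta = float(np.clip(theta, -clamp, clamp))
    return theta


def converge_theta(
    session: CatSession,
    tol: float = 1e-6,
    max_iter: int = 200,
    max_step: float | None = MAX_NEWTON_STEP,
    clamp: float | None = THETA_CLAMP,
) -> float:
    """Iterate capped Newton steps to convergence of the score equation.

    Converges to the maximum-likelihood theta where ``sum(O - E) = 0`` for
    interior patterns; perfect/zero patterns settle at the clamp boundary.
    """
    probe = CatSession(bank=session.bank, initial_theta=session.current_theta)
    probe.administered = list(session.administered)
    for _ in range(max_iter):
        new = update_theta(probe, max_step=max_step, clamp=clamp)
        delta = abs(new - probe.current_theta)
        probe.theta_trajectory = [new]
        if delta < tol:
            break
    return probe.current_theta


def standard_error(session: CatSession, theta: float | None = None) -> float:
    """CAT standard error: ``1 / sqrt(sum information over administered)``."""
    if not session.administered:
        raise ValueError("no administered items")
    theta = session.current_theta if theta is None else theta
    total = sum(
        pcm.item_information(theta, session.bank[iid]) for iid in session.administered_ids
    )
    return 1.0 / math.sqrt(total)


def select_next_item(session: CatSession) -> int:
    """Unadministered item with maximum information at the current theta.

    Ties break toward the lowest ``item_id``.
    """
    theta = session.current_theta
    used = set(session.administered_ids)
    best_id, best_info = None, -np.inf
    for item in session.bank:
        if item.item_id in used:
            continue
        info = pcm.item_information(theta, item)
        if info > best_info:
            best_id, best_info = item.item_id, info
    if best_id is None:
        raise ValueError("item bank exhausted")
    return best_id


def should_stop(session: CatSession, rule: StopRule) -> tuple[bool, str | None]:
    """Apply the dual stop rule; returns ``(stop, reason)``.

    Stops on SE below the SEM threshold (primary), on a provisional-theta
    residual below tolerance after ``min_items``, or on bank exhaustion.
    """
    if not session.administered:
        return False, None
    if standard_error(session) < rule.sem_threshold:
        return True, "sem_reached"
    if session.n_administered >= rule.min_items and len(session.theta_trajectory) >= 2:
        if abs(session.theta_trajectory[-1] - session.theta_trajectory[-2]) < rule.theta_residual_tol:
            return True, "theta_converged"
    limit = rule.max_items if rule.max_items is not None else len(session.bank)
    if session.n_administered >= min(limit, len(session.bank)):
        return True, "items_exhausted"
    return False, None


def impute_unanswered(session: CatSession, theta: float | None = None) -> np.ndarray:
    """Complete the response vector with model-expected scores.

    Administered positions keep the observed category; every unanswered
    item gets ``expected_score(final theta)``.  Returns a vector the length
    of the bank, in item order.
    """
    if theta is None:
        theta = session.final_theta if session.final_theta is not None else session.current_theta
    vec = np.array([pcm.expected_score(theta, item) for item in session.bank])
    for iid, obs in session.administered:
        vec[iid - 1] = obs
    return vec


def t_transform(v: float, df: int, method: str = "log") -> float:
    """Map a df-adjusted mean square to an approximate N(0,1) deviate.

    ``method="log"`` (default): ``t = ln(v) + v - 1``.  ``method="wilson_hilferty"``:
    cube-root standardisation ``(v^(1/3) - 1) * 3/q + q/3`` with ``q = sqrt(2/df)``.
    """
    if v <= 0:
        raise ValueError("mean square must be positive for the t transform")
    if method == "log":
        return math.log(v) + v - 1.0
    if method == "wilson_hilferty":
        q = math.sqrt(2.0 / df)
        return (v ** (1.0 / 3.0) - 1.0) * 3.0 / q + q / 3.0
    raise ValueError(f"unknown t method {method!r}")


def fit_statistics(
    session: CatSession, theta: float | None = None, t_method: str = "log"
) -> FitReport:
    """Person-fit report at the (final) theta over the administered items."""
    if session.n_administered < 2:
        raise ValueError("fit statistics need at least 2 administered items")
    if theta is None:
        theta = session.final_theta if session.final_theta is not None else session.current_theta
    obs, items = session._observed_and_items()
    expected = np.array([pcm.expected_score(theta, it) for it in items])
    var = np.array([pcm.item_information(theta, it) for it in items])
    resid = obs - expected
    z = resid / np.sqrt(var)
    n = len(obs)
    outfit = float(np.mean(z**2))
    infit = float(np.sum(resid**2) / np.sum(var))
    df = n - 1
    v = outfit * n / df
    t = t_transform(v, df, method=t_method) if v > 0 else -float("inf")
    return FitReport(
        infit_mnsq=infit,
        outfit_mnsq=outfit,
        z_scores=tuple(float(x) for x in z),
        v=v,
        t_statistic=t,
        df=df,
    )


class SimulatedResponder:
    """Responds by sampling the PCM at a fixed true ability."""

    def __init__(self, theta: float, rng: np.random.Generator | int | None = None):
        self.theta = theta
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    def __call__(self, item: ItemParameters) -> int:
        return pcm.sample_response(self.theta, item, self.rng)


class ReplayResponder:
    """Replays a fixed full-length response vector (bank order)."""

    def __init__(self, responses):
        self.responses = np.asarray(responses, dtype=float)

    def __call__(self, item: ItemParameters) -> float:
        return float(self.responses[item.item_id - 1])


def run_cat(
    bank: ItemBank,
    responder: Callable[[ItemParameters], float],
    rule: StopRule | None = None,
    seed: int | None = 0,
    initial_theta: float = 0.0,
    iterate_between_items: bool = False,
) -> CatSession:
    """Run one full adaptive test.

    The first item is chosen uniformly at random (seeded); thereafter items
    are selected by maximum information.  By default the provisional theta
    takes one capped Newton step per administered item, with full iteration
    to convergence only at session end (``iterate_between_items=True``
    converges after every item instead).
    """
    rule = rule or StopRule()
    session = CatSession(bank=bank, initial_theta=initial_theta)
    rng = np.random.default_rng(seed)
    next_id = int(rng.integers(1, len(bank) + 1))
    while True:
        observed = responder(bank[next_id])
        session.administer(next_id, observed)
        theta = (
            converge_theta(session) if iterate_between_items else update_theta(session)
        )
        session.theta_trajectory.append(theta)
        session.se_trajectory.append(standard_error(session))
        stop, reason = should_stop(session, rule)
        if stop:
            session.stopped_because = reason
            break
        next_id = select_next_item(session)
    session.final_theta = converge_theta(session)
    session.final_se = standard_error(session, theta=session.final_theta)
    session.imputed_vector = impute_unanswered(session)
    return session


def trajectory_flatness(session: CatSession, window: int = 5) -> float | None:
    """Correlation of the last ``window`` provisional thetas with step number.

    A value near 0 indicates a flat trajectory (the estimate has settled);
    diagnostic only — not part of the stop rule.  ``None`` when fewer than
    ``window`` steps exist or the trajectory is constant.
    """
    traj = session.theta_trajectory
    if len(traj) < window:
        return None
    tail = np.asarray(traj[-window:])
    if np.allclose(tail, tail[0]):
        return None
    return float(np.corrcoef(np.arange(window), tail)[0, 1])
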