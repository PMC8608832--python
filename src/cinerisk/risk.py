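"""Risk predictor: cine fingerprint -> cine risk score via a Cox-loss network.

The predictor is a small feed-forward network on the fingerprint posterior
means whose training loss is the negated Cox partial log-likelihood, so it
learns a proportional-hazards linear predictor directly from censored
outcomes.  The reported cine risk score is the logistic transform of the
linear predictor, mapping it onto a 0-1 scale; all rank-based statistics
(concordance, median split) are invariant to that monotone map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Adam, Dense, sigmoid
from .fingerprint import Fingerprint
from .io import CohortTable

__all__ = [
    "RiskResult",
    "PredictorConfig",
    "cox_partial_log_likelihood",
    "cox_loss_and_gradient",
    "train_risk_predictor",
    "predict_risk",
    "combine_fold_predictions",
]


@dataclass
class RiskResult:
    subject_id: str
    outcome_label: str
    linear_predictor: float
    cine_risk_score: float
    fold_id: int = -1


# ---------------------------------------------------------------------------
# Cox partial likelihood (Breslow ties), value and gradient
# ---------------------------------------------------------------------------


def _pll_and_grad(
    eta: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, np.ndarray]:
    """Breslow partial log-likelihood and its gradient w.r.t. eta."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order].astype(bool)
    x = eta[order]
    # stabilise exp against large eta
    shift = x.max()
    ex = np.exp(x - shift)
    rev_cumsum = np.cumsum(ex[::-1])[::-1]
    # first index of each tie group -> shared risk-set sum
    first = np.zeros(len(t), dtype=int)
    for i in range(1, len(t)):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    S = rev_cumsum[first]  # risk-set sum (shifted scale) per index
    log_S = np.log(S) + shift
    pll = float(np.sum(x[e] - log_S[e]))

    # gradient: e_j - exp(eta_j) * sum_{events i: t_i <= t_j} 1/S_i
    inv_S_at_events = np.where(e, 1.0 / S, 0.0)
    csum = np.cumsum(inv_S_at_events)
    # subject j is in the risk set of every event with t_i <= t_j (ties included)
    last = np.zeros(len(t), dtype=int)
    last[-1] = len(t) - 1
    for i in range(len(t) - 2, -1, -1):
        last[i] = last[i + 1] if t[i] == t[i + 1] else i
    grad_sorted = e.astype(float) - ex * csum[last]
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return pll, grad


def cox_partial_log_likelihood(
    linear_predictors: np.ndarray,
    times: np.ndarray,
    event_flags: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Cox partial log-likelihood sum_i [eta_i - log sum_{t_j >= t_i} exp(eta_j)].

    The sum runs over event subjects; tied event times share the full risk
    set (Breslow).  Invariant to adding a constant to every eta.
    """
    if ties != "breslow":
        raise ValueError("only Breslow tie handling is supported for the training loss")
    eta = np.asarray(linear_predictors, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(event_flags, dtype=int)
    if not (len(eta) == len(times) == len(events)):
        raise ValueError("linear_predictors, times and event_flags must have equal length")
    if events.sum() == 0:
        raise ValueError("partial likelihood undefined with zero events")
    return _pll_and_grad(eta, times, events)[0]


def cox_loss_and_gradient(
    eta: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, np.ndarray]:
    """Training loss (negated partial log-likelihood / n_events) and d(loss)/d(eta)."""
    n_events = int(np.sum(events))
    if n_events == 0:
        raise ValueError("partial likelihood undefined with zero events")
    pll, grad = _pll_and_grad(
        np.asarray(eta, float), np.asarray(times, float), np.asarray(events, int)
    )
    return -pll / n_events, -grad / n_events


# ---------------------------------------------------------------------------
# Predictor network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictorConfig:
    """Risk-head hyper-parameters.

    Cohorts are small (tens of events), so the head is deliberately tiny
    and ridge-penalised (``weight_decay`` on the weights, not biases);
    without it the Cox loss drives the network to a near-perfect in-sample
    ranking that does not generalise out-of-fold.  ``hidden_dim = 0``
    selects a single affine layer (a linear proportional-hazards readout,
    the most shrinkage-friendly member of the family and the default).
    """

    hidden_dim: int = 0
    epochs: int = 400
    learning_rate: float = 1e-2
    weight_decay: float = 0.1
    recon_weight: float = 0.0  # auxiliary fingerprint-reconstruction L2 head
    min_events: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim < 0 or self.epochs < 1:
            raise ValueError("hidden_dim must be >= 0 and epochs positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.recon_weight < 0 or self.weight_decay < 0:
            raise ValueError("recon_weight and weight_decay must be >= 0")


class RiskPredictor:
    """Feed-forward net: fingerprint mean -> linear predictor eta."""

    def __init__(self, input_dim: int, config: PredictorConfig, outcome_label: str):
        self.input_dim = input_dim
        self.config = config
        self.outcome_label = outcome_label
        self.history: list[float] = []
        self._mu = np.zeros(input_dim, dtype=np.float32)
        self._sd = np.ones(input_dim, dtype=np.float32)
        # the Cox partial likelihood identifies eta only up to an additive
        # constant; anchor each trained model to training-set mean 0 / sd 1
        # so out-of-fold predictions from different folds pool comparably
        self._eta_loc = 0.0
        self._eta_scale = 1.0
        rng = np.random.default_rng(config.seed)
        h = config.hidden_dim
        self.l1 = Dense(input_dim, h, rng) if h > 0 else None
        self.l2 = Dense(h if h > 0 else input_dim, 1, rng)
        self.l3 = Dense(h, input_dim, rng) if (config.recon_weight > 0 and h > 0) else None

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return ((X - self._mu) / self._sd).astype(np.float32)

    def fit(self, X: np.ndarray, times: np.ndarray, events: np.ndarray) -> "RiskPredictor":
        cfg = self.config
        self._mu = X.mean(axis=0).astype(np.float32)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0).astype(np.float32)
        Xs = self._standardize(X)
        layers = [lay for lay in (self.l1, self.l2, self.l3) if lay is not None]
        opt = Adam([p for lay in layers for p in lay.params], lr=cfg.learning_rate)
        for epoch in range(cfg.epochs):
            if self.l1 is not None:
                h = np.tanh(self.l1.forward(Xs))
            else:
                h = Xs
            eta = self.l2.forward(h)[:, 0].astype(np.float64)
            loss, dloss_deta = cox_loss_and_gradient(eta, times, events)
            dh = self.l2.backward(dloss_deta[:, None].astype(np.float32))
            if self.l3 is not None:
                xhat = self.l3.forward(h)
                diff = xhat - Xs
                loss += cfg.recon_weight * float(np.mean(diff**2))
                dh = dh + self.l3.backward(
                    (cfg.recon_weight * 2.0 / diff.size * diff).astype(np.float32)
                )
            if not np.isfinite(loss):
                raise RuntimeError(f"NaN/inf risk loss at epoch {epoch}")
            if self.l1 is not None:
                self.l1.backward((dh * (1 - h**2)).astype(np.float32))
            if cfg.weight_decay > 0:
                for lay in layers:
                    lay.gW += np.float32(cfg.weight_decay) * lay.W
                loss += 0.5 * cfg.weight_decay * sum(float((lay.W**2).sum()) for lay in layers)
            opt.step([g for lay in layers for g in lay.grads])
            self.history.append(float(loss))
        eta_train = self._raw_eta(Xs)
        self._eta_loc = float(eta_train.mean())
        sd = float(eta_train.std())
        self._eta_scale = sd if sd > 0 else 1.0
        return self

    def _raw_eta(self, xs: np.ndarray) -> np.ndarray:
        h = np.tanh(xs @ self.l1.W + self.l1.b) if self.l1 is not None else xs
        return (h @ self.l2.W + self.l2.b)[:, 0].astype(np.float64)

    def predict_eta(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=np.float32))
        if x.shape[1] != self.input_dim:
            raise ValueError(f"fingerprint dimension {x.shape[1]} != model input {self.input_dim}")
        return (self._raw_eta(self._standardize(x)) - self._eta_loc) / self._eta_scale


def train_risk_predictor(
    fingerprints: list[Fingerprint],
    cohort: CohortTable,
    train_ids: set[str] | list[str],
    config: PredictorConfig = PredictorConfig(),
) -> RiskPredictor:
    """Train per-outcome on training subjects; competing deaths are censoring
    for the primary outcome (the cohort's ``event_flags`` semantics)."""
    train_ids = set(train_ids)
    if not train_ids:
        raise ValueError("empty training set")
    by_id = {fp.subject_id: fp for fp in fingerprints}
    missing = train_ids - set(by_id)
    if missing:
        raise KeyError(f"training ids without fingerprints: {sorted(missing)[:5]}")
    sub = cohort.subset(sorted(train_ids))
    times, events = sub.times(), sub.event_flags()
    if events.sum() < config.min_events:
        raise ValueError(
            f"outcome {cohort.outcome_label!r} has {int(events.sum())} events in the "
            f"training set; need >= {config.min_events}"
        )
    X = np.stack([by_id[r.subject_id].mean for r in sub.records])
    model = RiskPredictor(X.shape[1], config, cohort.outcome_label)
    return model.fit(X, times, events)


def predict_risk(model: RiskPredictor, fp: Fingerprint) -> RiskResult:
    """Deterministic linear predictor and logistic cine risk score for one subject."""
    eta = float(model.predict_eta(fp.mean)[0])
    return RiskResult(
        subject_id=fp.subject_id,
        outcome_label=model.outcome_label,
        linear_predictor=eta,
        cine_risk_score=float(sigmoid(np.array([eta]))[0]),
        fold_id=fp.fold_id,
    )


def combine_fold_predictions(
    per_fold_results: list[list[RiskResult]],
    expected_ids: set[str] | list[str] | None = None,
) -> list[RiskResult]:
    """Pool out-of-fold predictions into one full-cohort result list.

    Each subject must be predicted exactly once (by the model whose
    training excluded it); duplicates or — when ``expected_ids`` is given —
    gaps raise.
    """
    combined = [r for fold in per_fold_results for r in fold]
    ids = [r.subject_id for r in combined]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"subject(s) predicted in more than one validation fold: {dupes[:5]}")
    if expected_ids is not None:
        gaps = set(expected_ids) - set(ids)
        if gaps:
            raise ValueError(f"subjects missing an out-of-fold prediction: {sorted(gaps)[:5]}")
    return combined
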