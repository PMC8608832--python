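"""Cine fingerprint extractor: a probabilistic encoder-decoder.

The extractor compresses a whole cine sequence into a low-dimensional
Gaussian posterior — the *cine fingerprint* (posterior mean + log
variance) — trained fully unsupervised on an L2 reconstruction error plus
a Kullback-Leibler regularizer toward a standard-normal prior (the usual
variational-autoencoder objective).  Time is handled by flattening the
(t, H, W) stack into one input vector, so the latent code must jointly
represent anatomy and its motion over the cycle.

The encoder-decoder is shared across frames: every frame of every
training sequence is a training sample, each frame is encoded to its own
small Gaussian posterior, and the sequence fingerprint is the
concatenation of the per-frame posteriors in frame order.  Weight sharing
multiplies the effective training-set size by the frame count and puts
frame-to-frame contrast (the heart's contraction pattern) directly on
latent coordinates where a small risk head can reach it.

Because the number of training frames is far below the pixel count, the
frames occupy a low-dimensional linear subspace; the network therefore
front-ends an exact principal-component basis computed from the training
frames (an orthonormal projection that preserves the L2 objective up to
the constant out-of-basis residual) and trains the dense variational
encoder-decoder on PC scores.  This makes epochs cheap enough to train to
convergence on one CPU.  Backprop is hand-written; see ``docs/methods.md``
for the architecture rationale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from ._nn import Adam, Dense
from .io import CineSequence

__all__ = ["Fingerprint", "ExtractorConfig", "elbo_loss", "train_extractor", "extract_fingerprint"]

_LOGVAR_CLIP = 10.0


@dataclass
class Fingerprint:
    """Per-subject latent code: posterior mean and log variance."""

    mean: np.ndarray
    log_variance: np.ndarray
    subject_id: str = ""
    fold_id: int = -1

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.log_variance = np.asarray(self.log_variance, dtype=np.float64)
        if self.mean.shape != self.log_variance.shape:
            raise ValueError("mean and log_variance must have the same length")
        if not (np.all(np.isfinite(self.mean)) and np.all(np.isfinite(self.log_variance))):
            raise ValueError("fingerprint entries must be finite")


@dataclass(frozen=True)
class ExtractorConfig:
    """Extractor hyper-parameters.

    ``latent_dim`` is the per-frame posterior size; the sequence
    fingerprint has ``n_frames * latent_dim`` entries.  ``kl_weight``
    multiplies a KL term that is *summed* over latent dimensions while
    the reconstruction error is *averaged* over ~10^3-10^4 pixels, so a
    weight of order 1e-4 corresponds to the classical evidence-lower-bound
    balance; weights near 1 drive the posterior to the prior (posterior
    collapse) and leave the fingerprint empty.  ``pca_dim`` caps the
    principal-component front end (it is also capped at n_frames - 1).
    """

    latent_dim: int = 8
    hidden_dim: int = 128
    pca_dim: int = 64
    epochs: int = 400
    batch_size: int = 64
    learning_rate: float = 2e-3
    kl_weight: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        for name in ("hidden_dim", "pca_dim", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")


def elbo_loss(
    reconstruction: np.ndarray,
    target: np.ndarray,
    mean: np.ndarray,
    log_variance: np.ndarray,
    kl_weight: float = 1.0,
) -> tuple[float, float, float]:
    """Training objective: mean-squared error + weighted KL to N(0, I).

    ``l2`` is the mean squared intensity difference over all elements;
    ``kl`` is ``sum_d 0.5 (mu_d^2 + exp(logvar_d) - 1 - logvar_d)``,
    averaged over the batch when mean/log_variance are 2D.  Returns
    ``(total, l2, kl)`` with ``total = l2 + kl_weight * kl``.
    """
    reconstruction = np.asarray(reconstruction, dtype=float)
    target = np.asarray(target, dtype=float)
    if reconstruction.shape != target.shape:
        raise ValueError(
            f"shape mismatch: reconstruction {reconstruction.shape} vs target {target.shape}"
        )
    mean = np.atleast_2d(np.asarray(mean, dtype=float))
    log_variance = np.atleast_2d(np.asarray(log_variance, dtype=float))
    if mean.shape != log_variance.shape:
        raise ValueError("mean / log_variance shape mismatch")
    l2 = float(np.mean((reconstruction - target) ** 2))
    kl_per = 0.5 * np.sum(mean**2 + np.exp(log_variance) - 1.0 - log_variance, axis=1)
    kl = float(np.mean(kl_per))
    return l2 + kl_weight * kl, l2, kl


class CineFingerprintExtractor:
    """Frame-shared variational encoder-decoder over a training-set PCA basis."""

    def __init__(self, input_shape: tuple[int, int, int], config: ExtractorConfig):
        self.input_shape = tuple(input_shape)
        self.config = config
        self.history: list[dict[str, float]] = []
        rng = np.random.default_rng(config.seed)
        self._rng = rng
        d_in = int(np.prod(input_shape[1:]))  # pixels per frame
        self._frame_dim = d_in
        # PCA front end, filled in by fit(); identity-sized placeholders
        self.pixel_mean = np.zeros(d_in, dtype=np.float32)
        self.basis: np.ndarray | None = None  # (d_in, K), orthonormal columns
        self.score_scale: np.ndarray | None = None  # per-component std
        self._residual_l2 = 0.0  # constant out-of-basis pixel MSE
        # dense layers are created once the PC dimension K is known
        self.enc1: Dense | None = None
        self.enc2: Dense | None = None
        self.dec1: Dense | None = None
        self.dec2: Dense | None = None

    def _build(self, K: int) -> None:
        d, h = self.config.latent_dim, self.config.hidden_dim
        self.enc1 = Dense(K, h, self._rng)
        self.enc2 = Dense(h, 2 * d, self._rng)
        self.dec1 = Dense(d, h, self._rng)
        self.dec2 = Dense(h, K, self._rng)

    # -- forward pieces ----------------------------------------------------

    def _project(self, X: np.ndarray) -> np.ndarray:
        """Pixels -> standardized PC scores."""
        assert self.basis is not None and self.score_scale is not None
        return ((X - self.pixel_mean) @ self.basis) / self.score_scale

    def _encode(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        h1 = np.tanh(self.enc1.forward(y))
        st = self.enc2.forward(h1)
        d = self.config.latent_dim
        mu, logvar = st[:, :d], np.clip(st[:, d:], -_LOGVAR_CLIP, _LOGVAR_CLIP)
        return h1, mu, logvar

    def _decode(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h2 = np.tanh(self.dec1.forward(z))
        yhat = self.dec2.forward(h2)
        return h2, yhat

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        """Deterministic pixel-space reconstruction from the posterior means.

        ``X`` holds flattened sequences, one per row; the reconstruction is
        assembled frame by frame.
        """
        X = np.atleast_2d(np.asarray(X, dtype=np.float32))
        n = X.shape[0]
        frames = X.reshape(n * self.input_shape[0], self._frame_dim)
        y = self._project(frames)
        _, mu, _ = self._encode(y)
        _, yhat = self._decode(mu)
        recon = (yhat * self.score_scale) @ self.basis.T + self.pixel_mean
        return np.clip(recon, 0.0, 1.0).reshape(n, -1)

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray) -> "CineFingerprintExtractor":
        """Train on (n_sequences, t*H*W) float32 rows in [0, 1].

        Every frame becomes an independent training sample of the shared
        encoder-decoder.
        """
        cfg = self.config
        n_seq = X.shape[0]
        X = X.reshape(n_seq * self.input_shape[0], self._frame_dim)
        n, d_in = X.shape
        self.pixel_mean = X.mean(axis=0).astype(np.float32)
        Xc = (X - self.pixel_mean).astype(np.float32)
        K = min(cfg.pca_dim, max(n - 1, 1))
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        self.basis = Vt[:K].T.astype(np.float32)
        scores = U[:, :K] * S[:K]
        sd = scores.std(axis=0)
        self.score_scale = np.where(sd > 0, sd, 1.0).astype(np.float32)
        self._residual_l2 = float((np.sum(S**2) - np.sum(S[:K] ** 2)) / (n * d_in))
        Y = (scores / self.score_scale).astype(np.float32)

        self._build(K)
        layers = [self.enc1, self.enc2, self.dec1, self.dec2]
        opt = Adam([p for lay in layers for p in lay.params], lr=cfg.learning_rate)
        # component weights make the PC-space objective equal the pixel MSE
        w2 = (self.score_scale**2 / d_in).astype(np.float32)
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            ep_l2 = ep_kl = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                y = Y[idx]
                B = len(idx)
                h1, mu, logvar = self._encode(y)
                eps = self._rng.standard_normal(mu.shape).astype(np.float32)
                std = np.exp(0.5 * logvar)
                z = mu + std * eps
                h2, yhat = self._decode(z)

                diff = yhat - y
                l2 = float(np.mean((diff**2) @ w2)) + self._residual_l2
                kl = float(np.mean(0.5 * np.sum(mu**2 + np.exp(logvar) - 1 - logvar, axis=1)))
                if not np.isfinite(l2 + kl):
                    raise RuntimeError(
                        f"NaN/inf loss at epoch {epoch} (l2={l2}, kl={kl}); "
                        "lower the learning rate"
                    )
                ep_l2 += l2 * B
                ep_kl += kl * B

                dyhat = (2.0 / B) * diff * w2
                dh2 = self.dec2.backward(dyhat.astype(np.float32))
                dz = self.dec1.backward((dh2 * (1 - h2**2)).astype(np.float32))
                dmu = dz + (cfg.kl_weight / B) * mu
                dlogvar = dz * eps * 0.5 * std + (cfg.kl_weight / B) * 0.5 * (
                    np.exp(logvar) - 1.0
                )
                # clip is identity inside the bounds; zero gradient outside
                dlogvar[np.abs(logvar) >= _LOGVAR_CLIP] = 0.0
                dst = np.concatenate([dmu, dlogvar], axis=1).astype(np.float32)
                dh1 = self.enc2.backward(dst)
                self.enc1.backward((dh1 * (1 - h1**2)).astype(np.float32))
                opt.step([g for lay in layers for g in lay.grads])
            self.history.append(
                {"epoch": epoch, "l2": ep_l2 / n, "kl": ep_kl / n,
                 "total": ep_l2 / n + cfg.kl_weight * ep_kl / n}
            )
        return self

    # -- persistence ---------------------------------------------------------

    def save(self, path, fold_id: int = -1) -> None:
        """Checkpoint basis + weights + config (+ fold id) to an .npz file."""
        np.savez(
            path,
            config=json.dumps({**self.config.__dict__, "fold_id": fold_id}),
            input_shape=np.array(self.input_shape),
            pixel_mean=self.pixel_mean,
            basis=self.basis,
            score_scale=self.score_scale,
            residual_l2=np.array(self._residual_l2),
            **{
                f"{name}_{p}": getattr(getattr(self, name), p)
                for name in ("enc1", "enc2", "dec1", "dec2")
                for p in ("W", "b")
            },
        )

    @classmethod
    def load(cls, path) -> tuple["CineFingerprintExtractor", int]:
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["config"]))
        fold_id = meta.pop("fold_id", -1)
        model = cls(tuple(int(v) for v in data["input_shape"]), ExtractorConfig(**meta))
        model.pixel_mean = data["pixel_mean"]
        model.basis = data["basis"]
        model.score_scale = data["score_scale"]
        model._residual_l2 = float(data["residual_l2"])
        model._build(model.basis.shape[1])
        for name in ("enc1", "enc2", "dec1", "dec2"):
            lay = getattr(model, name)
            lay.W = data[f"{name}_W"]
            lay.b = data[f"{name}_b"]
        return model, int(fold_id)

    # -- inference ---------------------------------------------------------

    def encode_array(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Sequence fingerprints (mu, logvar) without sampling.

        ``x`` holds flattened sequences, (n, t*H*W) or (t*H*W,); each frame
        is encoded separately and the per-frame posteriors concatenated in
        frame order, giving ``t * latent_dim`` entries per sequence.
        """
        if self.basis is None:
            raise RuntimeError("model is untrained")
        x = np.atleast_2d(np.asarray(x, dtype=np.float32))
        n = x.shape[0]
        frames = x.reshape(n * self.input_shape[0], self._frame_dim)
        _, mu, logvar = self._encode(self._project(frames))
        return (
            mu.reshape(n, -1).astype(np.float64),
            logvar.reshape(n, -1).astype(np.float64),
        )


def _flatten(seq: CineSequence, shape: tuple[int, int, int]) -> np.ndarray:
    if seq.frames.shape != shape:
        raise ValueError(
            f"sequence {seq.subject_id!r} has shape {seq.frames.shape}; model expects {shape}"
        )
    return seq.frames.astype(np.float32).reshape(-1)


def train_extractor(
    sequences: list[CineSequence],
    train_ids: set[str] | list[str],
    config: ExtractorConfig,
) -> CineFingerprintExtractor:
    """Train the extractor, unsupervised, on the training subjects only."""
    train_ids = set(train_ids)
    if not train_ids:
        raise ValueError("empty training set")
    by_id = {s.subject_id: s for s in sequences}
    missing = train_ids - set(by_id)
    if missing:
        raise KeyError(f"training ids without sequences: {sorted(missing)[:5]}")
    shapes = {by_id[i].frames.shape for i in train_ids}
    if len(shapes) != 1:
        raise ValueError(f"sequences must share one shape; got {shapes}")
    shape = shapes.pop()
    X = np.stack([_flatten(by_id[i], shape) for i in sorted(train_ids)])
    model = CineFingerprintExtractor(shape, config)
    return model.fit(X)


def extract_fingerprint(
    model: CineFingerprintExtractor, seq: CineSequence, fold_id: int = -1
) -> Fingerprint:
    """Posterior mean / log-variance of one sequence; deterministic (no sampling)."""
    mu, logvar = model.encode_array(_flatten(seq, model.input_shape))
    return Fingerprint(mean=mu[0], log_variance=logvar[0],
                       subject_id=seq.subject_id, fold_id=fold_id)
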