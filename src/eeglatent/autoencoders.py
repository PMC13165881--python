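"""Variational and transformer autoencoders over session feature vectors.

Two models compress the standardized 10-stream session vectors:

* a baseline VAE with 16-unit encoder/decoder hidden layers and a 2-D
  diagonal-Gaussian latent posterior, trained on squared reconstruction
  error plus the closed-form KL to the standard-normal prior;
* a deterministic transformer autoencoder in which each scalar feature
  becomes a learned 64-dimensional token, 4-head self-attention (key
  dim 16) models cross-band interactions over the 10 tokens, and a dense
  layer compresses the attention output to a 16-D latent code, trained
  on mean squared reconstruction error alone.

Both follow the statsmodels idiom: construct a model from data, call
``fit()``, work with the returned Results object (latent codes, training
trace, reconstruction errors, ``summary()``).  Training is plain-numpy
(see :mod:`eeglatent._autodiff`) and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._autodiff import Adam, Tensor, glorot_uniform
from .session_io import CohortMatrix
from .streams import N_STREAMS

__all__ = [
    "VaeConfig",
    "TaeConfig",
    "PosteriorParams",
    "LatentCodes",
    "DivergenceError",
    "kl_gaussian",
    "vae_forward",
    "vae_loss",
    "tae_forward",
    "mha_forward",
    "reconstruction_errors",
    "train",
    "VariationalAutoencoder",
    "TransformerAutoencoder",
]


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


@dataclass
class VaeConfig:
    input_dim: int = N_STREAMS
    hidden_units: int = 16
    latent_dim: int = 2
    epochs: int = 200
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0


@dataclass
class TaeConfig:
    input_dim: int = N_STREAMS
    embed_dim: int = 64
    heads: int = 4
    key_dim: int = 16
    latent_dim: int = 16
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 1e-3
    token_mode: str = "per_feature"  # or "single_vector"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.heads * self.key_dim != self.embed_dim:
            raise ValueError("heads * key_dim must equal embed_dim")
        if self.token_mode not in ("per_feature", "single_vector"):
            raise ValueError(f"unknown token_mode: {self.token_mode!r}")


@dataclass
class PosteriorParams:
    """Diagonal-Gaussian posterior parameters for one session (or a batch)."""

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.log_var = np.asarray(self.log_var, float)
        if self.mu.shape != self.log_var.shape:
            raise ValueError("mu and log_var must have matching shapes")


@dataclass
class LatentCodes:
    """Per-session latent vectors with aligned labels."""

    codes: np.ndarray
    model_tag: str
    labels: pd.DataFrame | None = None
    projection: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, float)
        if not np.all(np.isfinite(self.codes)):
            raise ValueError("latent codes must be finite")
        if self.labels is not None and len(self.labels) != len(self.codes):
            raise ValueError("labels must align with codes")

    def to_frame(self) -> pd.DataFrame:
        df = self.labels.copy() if self.labels is not None else pd.DataFrame(
            index=range(len(self.codes))
        )
        for j in range(self.codes.shape[1]):
            df[f"z{j + 1}"] = self.codes[:, j]
        if self.projection is not None:
            df["u1"] = self.projection[:, 0]
            df["u2"] = self.projection[:, 1]
        return df


def kl_gaussian(mu, log_var=None):
    """KL divergence of a diagonal Gaussian from the standard normal.

    ``-1/2 * sum_j (1 + log s_j^2 - mu_j^2 - s_j^2)``, summed over latent
    dimensions (last axis).  Accepts a :class:`PosteriorParams` or a pair
    of arrays; returns a scalar for a single vector, an array for a batch.
    """
    if isinstance(mu, PosteriorParams):
        mu, log_var = mu.mu, mu.log_var
    mu = np.asarray(mu, float)
    log_var = np.asarray(log_var, float)
    val = -0.5 * np.sum(1.0 + log_var - mu**2 - np.exp(log_var), axis=-1)
    return float(val) if val.ndim == 0 else val


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------

def _init_vae(cfg: VaeConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    d, h, L = cfg.input_dim, cfg.hidden_units, cfg.latent_dim
    return {
        "w_enc": Tensor(glorot_uniform(rng, d, h)),
        "b_enc": Tensor(np.zeros(h)),
        "w_post": Tensor(glorot_uniform(rng, h, 2 * L)),
        "b_post": Tensor(np.zeros(2 * L)),
        "w_dec1": Tensor(glorot_uniform(rng, L, h)),
        "b_dec1": Tensor(np.zeros(h)),
        "w_dec2": Tensor(glorot_uniform(rng, h, d)),
        "b_dec2": Tensor(np.zeros(d)),
    }


def _init_tae(cfg: TaeConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    d, E, L = cfg.input_dim, cfg.embed_dim, cfg.latent_dim
    n_tokens = d if cfg.token_mode == "per_feature" else 1
    params = {
        "w_embed": Tensor(
            glorot_uniform(rng, 1, E, shape=(d, E))
            if cfg.token_mode == "per_feature"
            else glorot_uniform(rng, d, E)
        ),
        "b_embed": Tensor(
            np.zeros((d, E)) if cfg.token_mode == "per_feature" else np.zeros(E)
        ),
        "w_q": Tensor(glorot_uniform(rng, E, E)),
        "w_k": Tensor(glorot_uniform(rng, E, E)),
        "w_v": Tensor(glorot_uniform(rng, E, E)),
        "w_o": Tensor(glorot_uniform(rng, E, E)),
        "w_lat": Tensor(glorot_uniform(rng, n_tokens * E, L)),
        "b_lat": Tensor(np.zeros(L)),
        "w_dec_h": Tensor(glorot_uniform(rng, L, E)),
        "b_dec_h": Tensor(np.zeros(E)),
        "w_out": Tensor(glorot_uniform(rng, E, d)),
        "b_out": Tensor(np.zeros(d)),
    }
    return params


def _as_tensors(params: dict) -> dict[str, Tensor]:
    return {
        k: (v if isinstance(v, Tensor) else Tensor(np.asarray(v, float)))
        for k, v in params.items()
    }


def params_to_arrays(params: dict[str, Tensor]) -> dict[str, np.ndarray]:
    return {k: np.array(v.data) for k, v in params.items()}


# ---------------------------------------------------------------------------
# Forward graphs
# ---------------------------------------------------------------------------

def _vae_graph(X: Tensor, P: dict[str, Tensor], eps: np.ndarray, latent_dim: int):
    h = (X @ P["w_enc"] + P["b_enc"]).relu()
    pp = h @ P["w_post"] + P["b_post"]
    mu = pp[:, :latent_dim]
    log_var = pp[:, latent_dim:]
    sigma = (log_var * 0.5).exp()
    z = mu + sigma * Tensor(eps)
    dh = (z @ P["w_dec1"] + P["b_dec1"]).relu()
    xhat = dh @ P["w_dec2"] + P["b_dec2"]
    return mu, log_var, z, xhat


def _mha_graph(H: Tensor, P: dict[str, Tensor], heads: int, key_dim: int):
    B, T, E = H.shape
    Q = (H @ P["w_q"]).reshape(B, T, heads, key_dim).swapaxes(1, 2)
    K = (H @ P["w_k"]).reshape(B, T, heads, key_dim).swapaxes(1, 2)
    V = (H @ P["w_v"]).reshape(B, T, heads, key_dim).swapaxes(1, 2)
    scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(key_dim))
    attn = scores.softmax(axis=-1)
    heads_out = (attn @ V).swapaxes(1, 2).reshape(B, T, E)
    return heads_out @ P["w_o"], attn


def _tae_graph(X: Tensor, P: dict[str, Tensor], cfg: TaeConfig):
    B = X.shape[0]
    if cfg.token_mode == "per_feature":
        # token i = x_i * w_i + b_i in R^embed_dim
        H = X.reshape(B, cfg.input_dim, 1) * P["w_embed"] + P["b_embed"]
        n_tokens = cfg.input_dim
    else:
        H = (X @ P["w_embed"] + P["b_embed"]).relu().reshape(B, 1, cfg.embed_dim)
        n_tokens = 1
    M, attn = _mha_graph(H, P, cfg.heads, cfg.key_dim)
    flat = M.reshape(B, n_tokens * cfg.embed_dim)
    z = (flat @ P["w_lat"] + P["b_lat"]).relu()
    dh = (z @ P["w_dec_h"] + P["b_dec_h"]).relu()
    xhat = dh @ P["w_out"] + P["b_out"]
    return z, xhat, attn


def _to_batch(x) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, float)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def vae_forward(x, params, noise=None, rng=None, latent_dim: int = 2):
    """Run the VAE on a vector or batch.

    Returns ``(PosteriorParams, z, x_hat)``.  If ``noise`` is given it is
    used as the reparameterization epsilon; otherwise epsilon is sampled
    standard-normal (from ``rng`` when supplied).
    """
    X, single = _to_batch(x)
    P = _as_tensors(params)
    if noise is None:
        gen = rng if rng is not None else np.random.default_rng()
        eps = gen.standard_normal((X.shape[0], latent_dim))
    else:
        eps = np.asarray(noise, float)
        if eps.ndim == 1:
            eps = np.broadcast_to(eps, (X.shape[0], latent_dim))
        if eps.shape != (X.shape[0], latent_dim):
            raise ValueError(
                f"noise must have shape ({X.shape[0]}, {latent_dim}), got {eps.shape}"
            )
    mu, log_var, z, xhat = _vae_graph(Tensor(X), P, eps, latent_dim)
    post = PosteriorParams(mu.data, log_var.data)
    if single:
        return PosteriorParams(post.mu[0], post.log_var[0]), z.data[0], xhat.data[0]
    return post, z.data, xhat.data


def vae_loss(batch, params, noise=None, latent_dim: int = 2):
    """Evaluate the VAE objective on a standardized batch.

    ``total = mean_i ||x_i - x_hat_i||^2 + mean_i KL_i``; the epsilon
    defaults to zero (evaluation at the posterior mean).  Returns
    ``(total, recon, kl)`` floats.
    """
    X, _ = _to_batch(batch)
    if noise is None:
        noise = np.zeros((X.shape[0], latent_dim))
    P = _as_tensors(params)
    mu, log_var, _, xhat = _vae_graph(Tensor(X), P, np.asarray(noise, float), latent_dim)
    recon = float(np.mean(np.sum((X - xhat.data) ** 2, axis=1)))
    kl = float(np.mean(kl_gaussian(mu.data, log_var.data)))
    return recon + kl, recon, kl


def tae_forward(x, params, cfg: TaeConfig | None = None):
    """Run the transformer autoencoder on a vector or batch.

    Returns ``(z, x_hat)``.
    """
    cfg = cfg or TaeConfig()
    X, single = _to_batch(x)
    z, xhat, _ = _tae_graph(Tensor(X), _as_tensors(params), cfg)
    if single:
        return z.data[0], xhat.data[0]
    return z.data, xhat.data


def mha_forward(tokens: np.ndarray, params, heads: int = 4, key_dim: int = 16):
    """Multi-head self-attention over a (B, T, E) token array.

    Returns ``(output, attention_weights)`` as numpy arrays; exposed for
    direct inspection of the attention layer.
    """
    out, attn = _mha_graph(Tensor(np.asarray(tokens, float)), _as_tensors(params), heads, key_dim)
    return out.data, attn.data


def reconstruction_errors(params, cohort, model_kind: str = "vae",
                          cfg: VaeConfig | TaeConfig | None = None) -> np.ndarray:
    """Per-session reconstruction error ``E_i = ||x_i - x_hat_i||_2``.

    The VAE is evaluated at epsilon = 0 (posterior mean).
    """
    X = cohort.values if isinstance(cohort, CohortMatrix) else np.asarray(cohort, float)
    if model_kind == "vae":
        latent_dim = cfg.latent_dim if cfg is not None else 2
        _, _, xhat = vae_forward(X, params, noise=np.zeros((X.shape[0], latent_dim)),
                                 latent_dim=latent_dim)
    elif model_kind == "tae":
        _, xhat = tae_forward(X, params, cfg if isinstance(cfg, TaeConfig) else None)
    else:
        raise ValueError(f"unknown model kind: {model_kind!r}")
    return np.linalg.norm(X - xhat, axis=1)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _resolve_matrix(endog) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(endog, CohortMatrix):
        if not endog.standardized:
            raise ValueError("cohort must be standardized (use zscore_matrix) before training")
        return endog.values, endog.labels
    return np.asarray(endog, float), None


class _BaseAutoencoder:
    """Shared minibatch Adam training loop."""

    tag = "base"

    def __init__(self, endog, config=None, labels=None):
        self.X, inferred = _resolve_matrix(endog)
        self.labels = labels if labels is not None else inferred
        self.config = config or self._default_config()
        if self.X.ndim != 2 or self.X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected N x {self.config.input_dim} data, got {self.X.shape}"
            )

    def _default_config(self):  # pragma: no cover - overridden
        raise NotImplementedError

    def _init_params(self, rng):
        raise NotImplementedError

    def _batch_loss(self, Xb: np.ndarray, params, rng) -> dict[str, Tensor]:
        raise NotImplementedError

    def fit(self):
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        params = self._init_params(rng)
        opt = Adam(list(params.values()), lr=cfg.learning_rate)
        N = self.X.shape[0]
        rows = []
        for epoch in range(cfg.epochs):
            perm = rng.permutation(N)
            sums: dict[str, float] = {}
            for start in range(0, N, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                terms = self._batch_loss(self.X[idx], params, rng)
                total = terms["total"]
                if not np.isfinite(total.data):
                    raise DivergenceError(
                        f"non-finite loss at epoch {epoch + 1}"
                    )
                opt.zero_grad()
                total.backward()
                opt.step()
                for k, t in terms.items():
                    sums[k] = sums.get(k, 0.0) + len(idx) * t.item()
            rows.append({k: v / N for k, v in sums.items()})
        trace = pd.DataFrame(rows)
        return self._results(params, trace)

    def _results(self, params, trace):
        raise NotImplementedError


class VariationalAutoencoder(_BaseAutoencoder):
    """Baseline VAE over a standardized cohort matrix."""

    tag = "vae"

    def _default_config(self):
        return VaeConfig()

    def _init_params(self, rng):
        return _init_vae(self.config, rng)

    def _batch_loss(self, Xb, params, rng):
        L = self.config.latent_dim
        eps = rng.standard_normal((Xb.shape[0], L))
        mu, log_var, _, xhat = _vae_graph(Tensor(Xb), params, eps, L)
        diff = Tensor(Xb) - xhat
        recon = (diff * diff).sum(axis=1).mean()
        kl_terms = (Tensor(np.ones(L)) + log_var - mu * mu - log_var.exp()).sum(axis=1) * (-0.5)
        kl = kl_terms.mean()
        return {"total": recon + kl, "recon": recon, "kl": kl}

    def _results(self, params, trace):
        post, _, _ = vae_forward(
            self.X, params, noise=np.zeros((self.X.shape[0], self.config.latent_dim)),
            latent_dim=self.config.latent_dim,
        )
        codes = LatentCodes(post.mu, "vae",
                            self.labels.copy() if self.labels is not None else None)
        return VAEResults(self, params, trace, codes)


class TransformerAutoencoder(_BaseAutoencoder):
    """Deterministic self-attention autoencoder over a standardized cohort."""

    tag = "tae"

    def _default_config(self):
        return TaeConfig()

    def _init_params(self, rng):
        return _init_tae(self.config, rng)

    def _batch_loss(self, Xb, params, rng):
        _, xhat, _ = _tae_graph(Tensor(Xb), params, self.config)
        diff = Tensor(Xb) - xhat
        recon = (diff * diff).sum(axis=1).mean()
        return {"total": recon, "recon": recon}

    def _results(self, params, trace):
        z, _ = tae_forward(self.X, params, self.config)
        codes = LatentCodes(z, "tae",
                            self.labels.copy() if self.labels is not None else None)
        return TAEResults(self, params, trace, codes)


class _BaseResults:
    def __init__(self, model, params, trace: pd.DataFrame, codes: LatentCodes):
        self.model = model
        self.params = params
        self.trace = trace
        self.codes = codes
        self.config = model.config

    @property
    def params_arrays(self) -> dict[str, np.ndarray]:
        return params_to_arrays(self.params)

    def reconstruction_errors(self, X=None) -> np.ndarray:
        data = self.model.X if X is None else X
        return reconstruction_errors(self.params, data, self.model.tag, self.config)

    def final_loss(self) -> float:
        return float(self.trace["total"].iloc[-1])

    def summary(self) -> str:
        cfg = self.config
        lines = [
            f"{type(self).__name__}",
            "=" * 46,
            f"Sessions:          {self.model.X.shape[0]}",
            f"Features:          {cfg.input_dim}",
            f"Latent dimension:  {cfg.latent_dim}",
            f"Epochs:            {cfg.epochs}   batch size: {cfg.batch_size}",
            f"Optimizer:         Adam (lr={cfg.learning_rate})",
            f"Seed:              {cfg.seed}",
        ]
        last = self.trace.iloc[-1]
        for k, v in last.items():
            lines.append(f"Final {k:<12}  {v: .6f}")
        err = self.reconstruction_errors()
        lines.append(f"Mean |x - xhat|:   {err.mean(): .6f}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = self.params_arrays
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"model": self.model.tag, "config": asdict(self.config)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


class VAEResults(_BaseResults):
    def encode(self, X=None) -> PosteriorParams:
        data = self.model.X if X is None else np.asarray(X, float)
        post, _, _ = vae_forward(
            data, self.params, noise=np.zeros((np.atleast_2d(data).shape[0],
                                               self.config.latent_dim)),
            latent_dim=self.config.latent_dim,
        )
        return post

    def reconstruct(self, X=None, noise=None):
        data = self.model.X if X is None else np.asarray(X, float)
        if noise is None:
            noise = np.zeros((np.atleast_2d(data).shape[0], self.config.latent_dim))
        _, _, xhat = vae_forward(data, self.params, noise=noise,
                                 latent_dim=self.config.latent_dim)
        return xhat


class TAEResults(_BaseResults):
    def encode(self, X=None) -> np.ndarray:
        data = self.model.X if X is None else np.asarray(X, float)
        z, _ = tae_forward(data, self.params, self.config)
        return z

    def reconstruct(self, X=None):
        data = self.model.X if X is None else np.asarray(X, float)
        _, xhat = tae_forward(data, self.params, self.config)
        return xhat


def train(model_kind: str, cohort, cfg=None):
    """Train a model and return ``(params, LatentCodes, trace)``.

    Functional facade over the model classes; ``cohort`` must be a
    standardized :class:`CohortMatrix` or plain array.
    """
    if model_kind == "vae":
        res = VariationalAutoencoder(cohort, cfg).fit()
    elif model_kind == "tae":
        res = TransformerAutoencoder(cohort, cfg).fit()
    else:
        raise ValueError(f"unknown model kind: {model_kind!r}")
    return res.params, res.codes, res.trace
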