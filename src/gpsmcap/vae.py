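"""Standard variational autoencoder over one-hot encoded sequences.

Architecture: a symmetric encoder/decoder MLP (default three hidden layers of
250 ReLU units each) with a small Gaussian latent bottleneck (default 7
dimensions) and a unit-Normal latent prior.  The decoder head is normalized
per site to a categorical over the q residues, and generation draws one
residue per site — one-hot semantics are thereby guaranteed for every
generated sequence.

Training maximizes the ELBO (categorical reconstruction log-likelihood plus
the analytic Gaussian KL to the prior) with Adam on mini-batches.  Sequence
log-probabilities are estimated by importance sampling from the encoder
posterior; the ELBO is also exposed as a cheaper energy approximation.

The network is implemented directly on numpy arrays with hand-written
backpropagation, which keeps the model dependency-free, deterministic under a
single seed, and fast enough for the desk-scale benchmarks this package runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .alphabet import Alphabet, reduced_alphabet
from .errors import AlignmentError
from .msa import MSA


@dataclass
class VaeConfig:
    """Architecture and training hyperparameters."""

    L: int
    q: int
    hidden_sizes: tuple[int, ...] = (250, 250, 250)
    latent_dim: int = 7
    batch_size: int = 200
    epochs: int = 30
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.batch_size < 1 or min(self.hidden_sizes) < 1:
            raise ValueError("latent_dim, batch_size and hidden sizes must be >= 1")
        if self.L < 1 or self.q < 2:
            raise ValueError("need L >= 1 and q >= 2")


def vae_param_count(config: VaeConfig) -> int:
    """Total trainable parameters (weights + biases) of the architecture."""
    d_in = config.L * config.q
    enc = [d_in, *config.hidden_sizes]
    count = sum(a * b + b for a, b in zip(enc, enc[1:]))
    count += 2 * (enc[-1] * config.latent_dim + config.latent_dim)  # mu and logvar
    dec = [config.latent_dim, *config.hidden_sizes, d_in]
    count += sum(a * b + b for a, b in zip(dec, dec[1:]))
    return count


def _he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))


@dataclass
class VAEModel:
    """Encoder/decoder parameters plus the config that built them."""

    config: VaeConfig
    params: dict[str, np.ndarray]
    alphabet: Alphabet | None = None
    trained: bool = False
    loss_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.alphabet is None:
            self.alphabet = reduced_alphabet(self.config.q)

    @property
    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = dict(
            kind=np.array("vae"),
            format_version=np.array(1),
            symbols=np.array(self.alphabet.symbols),
            L=np.array(self.config.L),
            q=np.array(self.config.q),
            hidden=np.array(self.config.hidden_sizes),
            latent=np.array(self.config.latent_dim),
            batch=np.array(self.config.batch_size),
            epochs=np.array(self.config.epochs),
            lr=np.array(self.config.learning_rate),
            seed=np.array(self.config.seed),
            trained=np.array(self.trained),
            loss_trace=np.array(self.loss_trace),
        )
        np.savez(str(path), **meta, **{f"p_{k}": v for k, v in self.params.items()})

    @classmethod
    def load(cls, path: str | Path) -> "VAEModel":
        with np.load(str(path), allow_pickle=False) as z:
            if str(z["kind"]) != "vae":
                raise ValueError(f"{path} is not a VAE container")
            config = VaeConfig(
                L=int(z["L"]),
                q=int(z["q"]),
                hidden_sizes=tuple(int(x) for x in z["hidden"]),
                latent_dim=int(z["latent"]),
                batch_size=int(z["batch"]),
                epochs=int(z["epochs"]),
                learning_rate=float(z["lr"]),
                seed=int(z["seed"]),
            )
            params = {k[2:]: z[k] for k in z.files if k.startswith("p_")}
            model = cls(config, params, Alphabet(str(z["symbols"])))
            model.trained = bool(z["trained"])
            model.loss_trace = [float(x) for x in z["loss_trace"]]
            return model


def build_vae(config: VaeConfig, alphabet: Alphabet | None = None) -> VAEModel:
    """Initialize a VAE with He-scaled weights, deterministic under the seed."""
    rng = np.random.default_rng(config.seed)
    d_in = config.L * config.q
    sizes = [d_in, *config.hidden_sizes]
    params: dict[str, np.ndarray] = {}
    for k, (a, b) in enumerate(zip(sizes, sizes[1:])):
        params[f"enc_W{k}"] = _he_init(rng, a, b)
        params[f"enc_b{k}"] = np.zeros(b)
    params["mu_W"] = _he_init(rng, sizes[-1], config.latent_dim) * 0.1
    params["mu_b"] = np.zeros(config.latent_dim)
    params["lv_W"] = _he_init(rng, sizes[-1], config.latent_dim) * 0.1
    params["lv_b"] = np.zeros(config.latent_dim)
    dsizes = [config.latent_dim, *config.hidden_sizes, d_in]
    for k, (a, b) in enumerate(zip(dsizes, dsizes[1:])):
        params[f"dec_W{k}"] = _he_init(rng, a, b)
        params[f"dec_b{k}"] = np.zeros(b)
    return VAEModel(config, params, alphabet)


# ---------------------------------------------------------------------------
# forward / backward passes


def _one_hot(data: np.ndarray, q: int) -> np.ndarray:
    eye = np.eye(q)
    return eye[data].reshape(data.shape[0], -1)


def _encode(model: VAEModel, X: np.ndarray):
    p = model.params
    acts = [X]
    a = X
    k = 0
    while f"enc_W{k}" in p:
        a = np.maximum(a @ p[f"enc_W{k}"] + p[f"enc_b{k}"], 0.0)
        acts.append(a)
        k += 1
    mu = a @ p["mu_W"] + p["mu_b"]
    lv = np.clip(a @ p["lv_W"] + p["lv_b"], -10.0, 10.0)
    return mu, lv, acts


def _decode(model: VAEModel, z: np.ndarray):
    """Latent points -> per-site log-categorical probabilities (B, L, q)."""
    p = model.params
    cfg = model.config
    acts = [z]
    a = z
    n_hidden = len(cfg.hidden_sizes)
    for k in range(n_hidden):
        a = np.maximum(a @ p[f"dec_W{k}"] + p[f"dec_b{k}"], 0.0)
        acts.append(a)
    logits = a @ p[f"dec_W{n_hidden}"] + p[f"dec_b{n_hidden}"]
    logits = logits.reshape(-1, cfg.L, cfg.q)
    logp = logits - logsumexp(logits, axis=2, keepdims=True)
    return logp, acts


def _recon_logp(logp: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Per-sequence log p(S|z) under the per-site categorical decoder."""
    B, L, _ = logp.shape
    rows = np.arange(B)[:, None]
    cols = np.arange(L)[None, :]
    return logp[rows, cols, data].sum(axis=1)


def _kl_terms(mu: np.ndarray, lv: np.ndarray) -> np.ndarray:
    """Per-sequence, per-dimension KL( q(z|S) || N(0,1) )."""
    return 0.5 * (mu**2 + np.exp(lv) - 1.0 - lv)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        corr1 = 1.0 - self.b1**self.t
        corr2 = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / corr1) / (
                np.sqrt(self.v[k] / corr2) + self.eps
            )


def _batch_grads(model: VAEModel, batch: np.ndarray, rng: np.random.Generator):
    """Negative-ELBO loss and parameter gradients for one mini-batch."""
    p = model.params
    cfg = model.config
    B = batch.shape[0]
    X = _one_hot(batch, cfg.q)

    mu, lv, eacts = _encode(model, X)
    eps = rng.standard_normal(mu.shape)
    std = np.exp(0.5 * lv)
    z = mu + std * eps
    logp, dacts = _decode(model, z)
    recon = _recon_logp(logp, batch)
    kl = _kl_terms(mu, lv).sum(axis=1)
    loss = float((-recon + kl).mean())

    grads: dict[str, np.ndarray] = {}
    n_hidden = len(cfg.hidden_sizes)

    # decoder backward: d(-logp(s|z))/dlogits = softmax - onehot, scaled 1/B
    probs = np.exp(logp)
    onehot = _one_hot(batch, cfg.q).reshape(B, cfg.L, cfg.q)
    dlogits = (probs - onehot).reshape(B, -1) / B
    delta = dlogits
    for k in range(n_hidden, -1, -1):
        a_prev = dacts[k]
        grads[f"dec_W{k}"] = a_prev.T @ delta
        grads[f"dec_b{k}"] = delta.sum(axis=0)
        if k > 0:
            delta = (delta @ p[f"dec_W{k}"].T) * (a_prev > 0)
    dz = delta @ p["dec_W0"].T

    # latent heads: reparameterization + analytic KL gradients
    dmu = dz + mu / B
    dlv = dz * eps * 0.5 * std + 0.5 * (np.exp(lv) - 1.0) / B

    a_last = eacts[-1]
    grads["mu_W"] = a_last.T @ dmu
    grads["mu_b"] = dmu.sum(axis=0)
    grads["lv_W"] = a_last.T @ dlv
    grads["lv_b"] = dlv.sum(axis=0)
    delta = (dmu @ p["mu_W"].T + dlv @ p["lv_W"].T) * (a_last > 0)
    for k in range(n_hidden - 1, -1, -1):
        a_prev = eacts[k]
        grads[f"enc_W{k}"] = a_prev.T @ delta
        grads[f"enc_b{k}"] = delta.sum(axis=0)
        if k > 0:
            delta = (delta @ p[f"enc_W{k}"].T) * (a_prev > 0)
    return loss, grads


def train_vae(model: VAEModel, msa: MSA, verbose: bool = False) -> VAEModel:
    """Optimize the ELBO with Adam mini-batches; returns the trained model.

    The per-epoch mean loss trace is stored on ``model.loss_trace``.
    Deterministic under ``config.seed``.  Aborts on non-finite loss.
    """
    cfg = model.config
    if msa.L != cfg.L:
        raise AlignmentError(f"MSA length {msa.L} != config L {cfg.L}")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = _Adam(model.params, cfg.learning_rate)
    data = msa.data
    for epoch in range(cfg.epochs):
        order = rng.permutation(msa.N)
        losses = []
        for start in range(0, msa.N, cfg.batch_size):
            batch = data[order[start : start + cfg.batch_size]]
            loss, grads = _batch_grads(model, batch, rng)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch offset {start}"
                )
            opt.step(model.params, grads)
            losses.append(loss)
        model.loss_trace.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1:3d}  -ELBO {model.loss_trace[-1]:.4f}")
    model.trained = True
    return model


# ---------------------------------------------------------------------------
# generation and energies


def sample_vae(model: VAEModel, n_seq: int, seed: int) -> MSA:
    """Draw sequences: z ~ N(0, I), then one categorical draw per site from
    the decoder's per-site probabilities."""
    rng = np.random.default_rng(seed)
    cfg = model.config
    out = np.empty((n_seq, cfg.L), dtype=np.uint8)
    chunk = 4096
    for start in range(0, n_seq, chunk):
        m = min(chunk, n_seq - start)
        z = rng.standard_normal((m, cfg.latent_dim))
        logp, _ = _decode(model, z)
        cdf = np.cumsum(np.exp(logp), axis=2)
        u = rng.random((m, cfg.L, 1))
        out[start : start + m] = (u > cdf).sum(axis=2).clip(0, cfg.q - 1)
    return MSA(out, model.alphabet, [f"vae{k}" for k in range(n_seq)])


def vae_logp(
    model: VAEModel, msa: MSA, n_importance: int = 1000, seed: int = 0
) -> np.ndarray:
    """Importance-sampled statistical energy ``E(S) = -log p(S)``.

    Averages ``p(S|z) p(z) / q(z|S)`` over draws from the encoder posterior
    in the log domain:  E = -logsumexp_k(log w_k) + log K.
    """
    if msa.L != model.config.L:
        raise AlignmentError("sequence length mismatch")
    if n_importance < 1:
        raise ValueError("n_importance must be >= 1")
    rng = np.random.default_rng(seed)
    cfg = model.config
    d = cfg.latent_dim
    out = np.empty(msa.N)
    batch = max(1, 65536 // max(n_importance, 1))
    for start in range(0, msa.N, batch):
        rows = msa.data[start : start + batch]
        B = rows.shape[0]
        X = _one_hot(rows, cfg.q)
        mu, lv, _ = _encode(model, X)
        std = np.exp(0.5 * lv)
        eps = rng.standard_normal((B, n_importance, d))
        z = mu[:, None, :] + std[:, None, :] * eps  # (B, K, d)
        logp, _ = _decode(model, z.reshape(-1, d))
        rep = np.repeat(rows, n_importance, axis=0)
        log_psz = _recon_logp(logp, rep).reshape(B, n_importance)
        log_pz = -0.5 * (z**2).sum(axis=2) - 0.5 * d * np.log(2 * np.pi)
        log_qz = (
            -0.5 * (eps**2).sum(axis=2)
            - 0.5 * d * np.log(2 * np.pi)
            - 0.5 * lv.sum(axis=1)[:, None]
        )
        logw = log_psz + log_pz - log_qz
        out[start : start + B] = -(logsumexp(logw, axis=1) - np.log(n_importance))
    return out


def vae_elbo(
    model: VAEModel, msa: MSA, n_samples: int = 16, seed: int = 0
) -> np.ndarray:
    """ELBO-based energy: Monte-Carlo reconstruction term plus the analytic
    Gaussian KL, negated so larger values mean less probable sequences."""
    if msa.L != model.config.L:
        raise AlignmentError("sequence length mismatch")
    rng = np.random.default_rng(seed)
    cfg = model.config
    d = cfg.latent_dim
    X = _one_hot(msa.data, cfg.q)
    mu, lv, _ = _encode(model, X)
    std = np.exp(0.5 * lv)
    recon = np.zeros(msa.N)
    for _ in range(n_samples):
        z = mu + std * rng.standard_normal(mu.shape)
        logp, _ = _decode(model, z)
        recon += _recon_logp(logp, msa.data)
    recon /= n_samples
    kl = _kl_terms(mu, lv).sum(axis=1)
    return -(recon - kl)


def latent_activity(model: VAEModel, msa: MSA) -> np.ndarray:
    """Mean KL contribution per latent dimension over the MSA (nats).

    Dimensions with activity near zero are collapsed onto the prior and
    carry no information about the input; their sum equals the total KL term
    for the diagonal-Gaussian posterior.
    """
    X = _one_hot(msa.data, model.config.q)
    mu, lv, _ = _encode(model, X)
    return _kl_terms(mu, lv).mean(axis=0)


def collapsed_dimensions(model: VAEModel, msa: MSA, threshold: float = 0.01) -> np.ndarray:
    """Indices of latent dimensions whose mean KL is below ``threshold`` nats."""
    return np.nonzero(latent_activity(model, msa) < threshold)[0]
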