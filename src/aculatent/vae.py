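"""Variational auto-encoder for multichannel EEG samples.

Each time sample (a 19-channel voltage vector) is one observation x.  The
encoder maps x to a diagonal-Gaussian posterior q(z|x) = N(mu(x), sigma(x)^2)
over J latent variables; the decoder maps latent samples back to channel
space.  Training maximises the evidence lower bound

    ELBO = E_q[log p(x|z)] - KL(q(z|x) || N(0, I)),

with a unit-variance Gaussian likelihood on per-channel standardized data,
the reparameterization trick z = mu + sigma * eps for the Monte-Carlo
reconstruction term (L draws), and the closed-form Gaussian KL

    KL = -1/2 sum_j (1 + log sigma_j^2 - mu_j^2 - sigma_j^2).

The network is a small dense MLP (19 -> 32 tanh -> 2J encoder, J -> 32 tanh
-> 19 decoder by default) trained by minibatch stochastic gradient descent
(batch size 20) with hand-written backpropagation; plain SGD, momentum and
Adam update rules are available.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import EpochSet, TrainingError

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class VaeModel:
    """Encoder/decoder parameters and the input standardization affinity."""

    n_channels: int
    J: int
    hidden: tuple[int, ...]
    enc_layers: list[tuple[np.ndarray, np.ndarray]]  # shared hidden stack
    w_mu: np.ndarray
    b_mu: np.ndarray
    w_lv: np.ndarray
    b_lv: np.ndarray
    dec_layers: list[tuple[np.ndarray, np.ndarray]]  # hidden stack + output
    x_mean: np.ndarray = None
    x_std: np.ndarray = None

    def __post_init__(self) -> None:
        if self.x_mean is None:
            self.x_mean = np.zeros(self.n_channels)
        if self.x_std is None:
            self.x_std = np.ones(self.n_channels)

    def parameters(self) -> list[np.ndarray]:
        out = []
        for w, b in self.enc_layers:
            out += [w, b]
        out += [self.w_mu, self.b_mu, self.w_lv, self.b_lv]
        for w, b in self.dec_layers:
            out += [w, b]
        return out


@dataclass
class LatentPosterior:
    """Per-sample posterior N(mu, diag(sigma^2)); sigma parameterized via
    log sigma^2 so it is positive by construction."""

    mu: np.ndarray       # (N, J)
    log_var: np.ndarray  # (N, J)

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.log_var)


@dataclass
class LatentTrajectory:
    """Posterior-mean latent time course, coordinates ordered by variance."""

    times: np.ndarray
    Z: np.ndarray           # (samples, J), columns in descending variance order
    order: np.ndarray       # original latent indices of the columns
    subject_id: str = "s00"
    condition: str = "unknown"
    trial: int = 0

    def top(self, k: int = 3) -> np.ndarray:
        """The k largest-variance latent coordinates (ties broken by index)."""
        if self.Z.shape[1] < k:
            raise ValueError(f"model has J={self.Z.shape[1]} < {k} latent variables")
        return self.Z[:, :k]


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def init_vae(
    n_channels: int,
    J: int,
    hidden: tuple[int, ...] = (32,),
    seed: int = 0,
) -> VaeModel:
    """Deterministic Glorot-initialised model; ``hidden=()`` gives linear
    encoder and decoder."""
    if J < 1:
        raise ValueError("latent dimension J must be >= 1")
    rng = np.random.default_rng([int(seed), 23])

    def layer(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_in, n_out)), np.zeros(n_out)

    enc_layers = []
    d = n_channels
    for h in hidden:
        enc_layers.append(layer(d, h))
        d = h
    w_mu, b_mu = layer(d, J)
    w_lv, b_lv = layer(d, J)
    dec_layers = []
    d = J
    for h in reversed(hidden):
        dec_layers.append(layer(d, h))
        d = h
    dec_layers.append(layer(d, n_channels))
    return VaeModel(n_channels=n_channels, J=J, hidden=tuple(hidden),
                    enc_layers=enc_layers, w_mu=w_mu, b_mu=b_mu,
                    w_lv=w_lv, b_lv=b_lv, dec_layers=dec_layers)


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _standardize(model: VaeModel, x: np.ndarray) -> np.ndarray:
    return (x - model.x_mean) / model.x_std


def _encode_std(model: VaeModel, xs: np.ndarray):
    h = xs
    hiddens = []
    for w, b in model.enc_layers:
        h = np.tanh(h @ w + b)
        hiddens.append(h)
    mu = h @ model.w_mu + model.b_mu
    lv = h @ model.w_lv + model.b_lv
    return mu, lv, hiddens


def _decode_std(model: VaeModel, z: np.ndarray):
    h = z
    hiddens = []
    for w, b in model.dec_layers[:-1]:
        h = np.tanh(h @ w + b)
        hiddens.append(h)
    w, b = model.dec_layers[-1]
    return h @ w + b, hiddens


def encode(model: VaeModel, x: np.ndarray) -> LatentPosterior:
    """Posterior parameters for a batch of channel vectors (N, n_channels)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_channels:
        raise ValueError(f"input width {x.shape[1]} != n_channels {model.n_channels}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in encoder input")
    mu, lv, _ = _encode_std(model, _standardize(model, x))
    return LatentPosterior(mu=mu, log_var=lv)


def decode(model: VaeModel, z: np.ndarray) -> np.ndarray:
    """Map latent vectors (N, J) back to channel space, in original units."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    xs, _ = _decode_std(model, z)
    return xs * model.x_std + model.x_mean


def reparameterize(post: LatentPosterior, L: int = 1, seed: int = 0) -> np.ndarray:
    """L reparameterized draws z = mu + sigma * eps, shape (L, N, J)."""
    if L < 1:
        raise ValueError("need L >= 1 draws")
    rng = np.random.default_rng([int(seed), 37])
    eps = rng.standard_normal((L, *post.mu.shape))
    return post.mu[None] + post.sigma[None] * eps


def kl_gaussian(post: LatentPosterior) -> np.ndarray:
    """Closed-form KL(q || N(0, I)) per sample; always >= 0."""
    s2 = np.exp(post.log_var)
    return -0.5 * np.sum(1.0 + post.log_var - post.mu ** 2 - s2, axis=1)


def elbo(model: VaeModel, batch: np.ndarray, L: int = 1, seed: int = 0) -> float:
    """Monte-Carlo ELBO (nats per sample) on standardized data."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("empty batch")
    xs = _standardize(model, batch)
    mu, lv, _ = _encode_std(model, xs)
    post = LatentPosterior(mu=mu, log_var=lv)
    z = reparameterize(post, L=L, seed=seed)
    recon = 0.0
    for draw in z:
        xhat, _ = _decode_std(model, draw)
        recon += -0.5 * np.sum((xs - xhat) ** 2 + LOG2PI, axis=1)
    recon /= L
    return float(np.mean(recon - kl_gaussian(post)))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def stack_samples(epochs: EpochSet | list[np.ndarray] | np.ndarray,
                  stride: int = 1) -> np.ndarray:
    """Flatten epochs into an (N, n_channels) sample matrix, optionally
    keeping every ``stride``-th time point."""
    if isinstance(epochs, EpochSet):
        mats = list(epochs)
    elif isinstance(epochs, np.ndarray):
        mats = [epochs]
    else:
        mats = list(epochs)
    return np.concatenate([m[:, ::stride].T for m in mats], axis=0)


def _grad_step(model: VaeModel, xb: np.ndarray, L: int,
               rng: np.random.Generator):
    """Loss (negative ELBO without the log 2pi constant) and parameter
    gradients for one minibatch of standardized samples."""
    B = xb.shape[0]
    mu, lv, enc_h = _encode_std(model, xb)
    sigma = np.exp(0.5 * lv)

    d_mu = np.zeros_like(mu)
    d_lv = np.zeros_like(lv)
    grads = {id(p): np.zeros_like(p) for p in model.parameters()}
    recon_loss = 0.0

    for _ in range(L):
        eps = rng.standard_normal(mu.shape)
        z = mu + sigma * eps
        xhat, dec_h = _decode_std(model, z)
        diff = xhat - xb
        recon_loss += 0.5 * np.sum(diff ** 2) / (B * L)

        # decoder backward
        delta = diff / (B * L)
        w_out, b_out = model.dec_layers[-1]
        h_in = dec_h[-1] if dec_h else z
        grads[id(w_out)] += h_in.T @ delta
        grads[id(b_out)] += delta.sum(axis=0)
        delta = delta @ w_out.T
        for li in range(len(model.dec_layers) - 2, -1, -1):
            w, b = model.dec_layers[li]
            h_out = dec_h[li]
            delta = delta * (1.0 - h_out ** 2)
            h_in = dec_h[li - 1] if li > 0 else z
            grads[id(w)] += h_in.T @ delta
            grads[id(b)] += delta.sum(axis=0)
            delta = delta @ w.T
        # through the reparameterization
        d_mu += delta
        d_lv += delta * eps * sigma * 0.5

    # KL gradients (closed form, per sample, averaged over batch)
    kl = 0.5 * np.sum(mu ** 2 + sigma ** 2 - 1.0 - lv) / B
    d_mu += mu / B
    d_lv += 0.5 * (sigma ** 2 - 1.0) / B

    # encoder backward
    h_top = enc_h[-1] if enc_h else xb
    grads[id(model.w_mu)] += h_top.T @ d_mu
    grads[id(model.b_mu)] += d_mu.sum(axis=0)
    grads[id(model.w_lv)] += h_top.T @ d_lv
    grads[id(model.b_lv)] += d_lv.sum(axis=0)
    delta = d_mu @ model.w_mu.T + d_lv @ model.w_lv.T
    for li in range(len(model.enc_layers) - 1, -1, -1):
        w, b = model.enc_layers[li]
        h_out = enc_h[li]
        delta = delta * (1.0 - h_out ** 2)
        h_in = enc_h[li - 1] if li > 0 else xb
        grads[id(w)] += h_in.T @ delta
        grads[id(b)] += delta.sum(axis=0)
        delta = delta @ w.T

    return recon_loss + kl, grads


def train(
    model: VaeModel,
    epochs: EpochSet | list[np.ndarray] | np.ndarray,
    n_epochs: int = 20,
    batch_size: int = 20,
    learning_rate: float = 1e-3,
    seed: int = 0,
    optimizer: str = "sgd",
    momentum: float = 0.9,
    L: int = 1,
    stride: int = 1,
    standardize: bool = True,
) -> tuple[VaeModel, list[float]]:
    """Minimise the negative ELBO by minibatch gradient descent.

    Returns the trained model (updated in place) and the per-pass mean loss
    history.  ``optimizer`` is ``sgd`` (plain, the default), ``momentum`` or
    ``adam``; all are seeded and fully reproducible.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    x = stack_samples(epochs, stride=stride)
    if standardize:
        model.x_mean = x.mean(axis=0)
        sd = x.std(axis=0)
        model.x_std = np.where(sd > 0, sd, 1.0)
    xs = _standardize(model, x)

    rng = np.random.default_rng([int(seed), 11])
    params = model.parameters()
    vel = [np.zeros_like(p) for p in params]
    m1 = [np.zeros_like(p) for p in params]
    m2 = [np.zeros_like(p) for p in params]
    t_step = 0
    history: list[float] = []
    n = xs.shape[0]

    for epoch_i in range(n_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - batch_size + 1, batch_size):
            xb = xs[order[start:start + batch_size]]
            loss, grads = _grad_step(model, xb, L, rng)
            losses.append(loss)
            t_step += 1
            for k, p in enumerate(params):
                g = grads[id(p)]
                if optimizer == "sgd":
                    p -= learning_rate * g
                elif optimizer == "momentum":
                    vel[k] = momentum * vel[k] - learning_rate * g
                    p += vel[k]
                elif optimizer == "adam":
                    m1[k] = 0.9 * m1[k] + 0.1 * g
                    m2[k] = 0.999 * m2[k] + 0.001 * g ** 2
                    mhat = m1[k] / (1 - 0.9 ** t_step)
                    vhat = m2[k] / (1 - 0.999 ** t_step)
                    p -= learning_rate * mhat / (np.sqrt(vhat) + 1e-8)
                else:
                    raise ValueError(f"unknown optimizer {optimizer!r}")
        mean_loss = float(np.mean(losses))
        if not np.isfinite(mean_loss):
            raise TrainingError(f"non-finite loss at training pass {epoch_i}")
        history.append(mean_loss)
    return model, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def reconstruct(model: VaeModel, x: np.ndarray) -> np.ndarray:
    """Deterministic posterior-mean reconstruction, in original units."""
    post = encode(model, x)
    return decode(model, post.mu)


def reconstruction_performance(model: VaeModel,
                               epochs: EpochSet | list[np.ndarray] | np.ndarray) -> float:
    """Mean Pearson correlation between original and reconstructed channel
    traces, averaged over channels and epochs (posterior-mean pass)."""
    if isinstance(epochs, np.ndarray):
        mats = [epochs]
    else:
        mats = list(epochs)
    corrs = []
    for seg in mats:
        xhat = reconstruct(model, seg.T).T
        for c in range(seg.shape[0]):
            s_orig = seg[c].std()
            s_hat = xhat[c].std()
            if s_orig == 0 or s_hat == 0:
                warnings.warn(f"channel {c}: constant trace, skipped in "
                              "reconstruction performance")
                continue
            corrs.append(np.corrcoef(seg[c], xhat[c])[0, 1])
    return float(np.mean(corrs))


def latent_trajectory(
    model: VaeModel,
    segment: np.ndarray,
    fs: float = 256.0,
    subject_id: str = "s00",
    condition: str = "unknown",
    trial: int = 0,
) -> LatentTrajectory:
    """Posterior-mean latent time course of a channels x samples segment,
    coordinates reordered by descending variance (ties broken by index)."""
    post = encode(model, segment.T)
    var = post.mu.var(axis=0)
    order = np.argsort(-var, kind="stable")
    return LatentTrajectory(
        times=np.arange(segment.shape[1]) / fs,
        Z=post.mu[:, order], order=order,
        subject_id=subject_id, condition=condition, trial=trial,
    )
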