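"""The domain-separation network for m5U site prediction, and its losses.

Three architecturally identical encoders map a one-hot window to a
d-dimensional representation: a shared encoder E_c used by both domains
and one private encoder per domain (E_p^s, E_p^t). Per domain, a decoder
reconstructs the input from h_p + h_c, so the two encoders jointly keep
all information; classifiers read ONLY the shared representation. The
training objective combines five terms:

    L = alpha * L_recon + beta * L_difference + gamma * L_similarity
        + L_source + delta * L_target

* L_recon       — reconstruction error per domain (scale-invariant MSE by
                  default, plain MSE selectable);
* L_difference  — soft subspace orthogonality between a domain's shared
                  and private representations (squared Frobenius norm of
                  the cross-product after centering and row
                  normalization), summed over domains;
* L_similarity  — a two-sample distance between the shared
                  representations of the domains: multi-kernel unbiased
                  MMD by default, or an adversarial domain classifier
                  through gradient reversal (DANN);
* L_source / L_target — class negative log-likelihoods. In operating
  mode 1 ("source_only_classifier") there is no target classifier and
  the target stream carries only negatives, providing mRNA sequence
  context without mRNA labels; mode 2 ("dual_classifier") adds a target
  classifier as an extra layer of supervision.

Encoder pipeline: conv(4 -> conv_filters, kernel length 2, symmetric
padding 2) -> batchnorm -> ReLU -> LSTM(hidden 8) final state ->
batchnorm -> dense -> d-vector. Default loss weights alpha=0.02,
beta=0.075, gamma=0.25, delta=1.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor, concat, grad_reverse

__all__ = [
    "ModelConfig", "LossWeights", "LossBreakdown", "ForwardOutputs",
    "DSNModel", "init_model", "reconstruction_loss", "difference_loss",
    "similarity_loss", "classification_loss", "total_loss",
    "save_checkpoint", "load_checkpoint",
]

MODE_SOURCE_ONLY = "source_only_classifier"
MODE_DUAL = "dual_classifier"
_MODES = {1: MODE_SOURCE_ONLY, 2: MODE_DUAL,
          MODE_SOURCE_ONLY: MODE_SOURCE_ONLY, MODE_DUAL: MODE_DUAL}


@dataclass(frozen=True)
class ModelConfig:
    window_length: int = 41
    conv_filters: int = 16
    conv_kernel: int = 2
    conv_padding: int = 2
    lstm_hidden: int = 8
    repr_dim: int = 16
    dropout: float = 0.0
    recon_variant: str = "simse"      # or "mse"
    similarity_variant: str = "mmd"   # or "dann"
    decoder_combine: str = "add"      # or "concat"

    def __post_init__(self):
        for name in ("window_length", "conv_filters", "conv_kernel",
                     "lstm_hidden", "repr_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.recon_variant not in ("simse", "mse"):
            raise ValueError(f"bad recon_variant {self.recon_variant!r}")
        if self.similarity_variant not in ("mmd", "dann"):
            raise ValueError(
                f"bad similarity_variant {self.similarity_variant!r}")
        if self.decoder_combine not in ("add", "concat"):
            raise ValueError(f"bad decoder_combine {self.decoder_combine!r}")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite objective (alpha, beta, gamma, delta)."""

    alpha: float = 0.02
    beta: float = 0.075
    gamma: float = 0.25
    delta: float = 1.0

    def __post_init__(self):
        if min(self.alpha, self.beta, self.gamma, self.delta) < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LossBreakdown:
    recon: float
    difference: float
    similarity: float
    source_cls: float
    target_cls: float | None
    total: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ForwardOutputs:
    h_c_source: Tensor
    h_p_source: Tensor
    h_c_target: Tensor
    h_p_target: Tensor
    recon_source: Tensor
    recon_target: Tensor
    source_logits: Tensor
    target_logits: Tensor | None


class _Encoder(nn.Module):
    """conv -> BN -> ReLU -> LSTM (final state) -> BN -> dense."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv1d(4, cfg.conv_filters, cfg.conv_kernel,
                              cfg.conv_padding, rng)
        self.bn1 = nn.BatchNorm(cfg.conv_filters)
        self.lstm = nn.LSTM(cfg.conv_filters, cfg.lstm_hidden, rng)
        self.bn2 = nn.BatchNorm(cfg.lstm_hidden)
        self.dense = nn.Linear(cfg.lstm_hidden, cfg.repr_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, L, 4) -> conv over sequence axis expects (B, C, L)
        h = self.conv(x.transpose(0, 2, 1))
        h = self.bn1(h).relu()
        h = self.lstm(h.transpose(0, 2, 1))
        h = self.bn2(h)
        return self.dense(h)


class _Decoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        in_dim = cfg.repr_dim * (2 if cfg.decoder_combine == "concat" else 1)
        self.dense = nn.Linear(in_dim, cfg.window_length * 4, rng)
        self.length = cfg.window_length

    def forward(self, h: Tensor) -> Tensor:
        return self.dense(h).reshape(-1, self.length, 4)


class _Classifier(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.dense = nn.Linear(cfg.repr_dim, 2, rng)

    def forward(self, h: Tensor) -> Tensor:
        return self.dense(h).log_softmax(axis=1)


class _DomainDiscriminator(nn.Module):
    """Linear domain classifier used only by the DANN similarity variant."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.dense = nn.Linear(cfg.repr_dim, 2, rng)

    def forward(self, h: Tensor) -> Tensor:
        return self.dense(h).log_softmax(axis=1)


class DSNModel(nn.Module):
    """Shared/private encoders + decoders + classifier(s)."""

    def __init__(self, config: ModelConfig, mode=MODE_SOURCE_ONLY,
                 seed: int = 0):
        super().__init__()
        if mode not in _MODES:
            raise ValueError(f"mode must be 1/2 or one of "
                             f"{sorted(set(_MODES.values()))}")
        self.config = config
        self.mode = _MODES[mode]
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        self.shared_encoder = _Encoder(config, rng)
        self.private_source_encoder = _Encoder(config, rng)
        self.private_target_encoder = _Encoder(config, rng)
        self.decoder_source = _Decoder(config, rng)
        self.decoder_target = _Decoder(config, rng)
        self.source_classifier = _Classifier(config, rng)
        self.target_classifier = (_Classifier(config, rng)
                                  if self.mode == MODE_DUAL else None)
        self.domain_discriminator = (
            _DomainDiscriminator(config, rng)
            if config.similarity_variant == "dann" else None)

    # -- forward -------------------------------------------------------

    def _combine(self, h_p: Tensor, h_c: Tensor) -> Tensor:
        if self.config.decoder_combine == "add":
            return h_p + h_c
        return concat([h_p, h_c], axis=1)

    def forward(self, x_source: Tensor, x_target: Tensor) -> ForwardOutputs:
        # one mixed pass through the shared encoder: its normalization
        # statistics describe the domain mixture, keeping training-time
        # and frozen-statistics evaluation behaviour consistent
        n_s = x_source.shape[0]
        h_c = self.shared_encoder(concat([x_source, x_target], axis=0))
        h_c_s, h_c_t = h_c[:n_s], h_c[n_s:]
        h_p_s = self.private_source_encoder(x_source)
        h_p_t = self.private_target_encoder(x_target)
        recon_s = self.decoder_source(self._combine(h_p_s, h_c_s))
        recon_t = self.decoder_target(self._combine(h_p_t, h_c_t))
        # classifiers read ONLY the shared representation
        src_logits = self.source_classifier(h_c_s)
        tgt_logits = (self.target_classifier(h_c_t)
                      if self.target_classifier is not None else None)
        return ForwardOutputs(h_c_s, h_p_s, h_c_t, h_p_t,
                              recon_s, recon_t, src_logits, tgt_logits)

    def predict_scores(self, x: np.ndarray, classifier: str = "auto",
                       batch_size: int = 256) -> np.ndarray:
        """Positive-class probabilities for encoded windows (n, L, 4).

        ``classifier="auto"`` uses the target classifier in dual mode and
        the source classifier otherwise.
        """
        from .autograd import no_grad
        head = self._resolve_classifier(classifier)
        was_training = self.training
        self.eval()
        outs = []
        with no_grad():
            for lo in range(0, len(x), batch_size):
                h = self.shared_encoder(Tensor(x[lo:lo + batch_size]))
                outs.append(np.exp(head(h).data[:, 1]))
        if was_training:
            self.train()
        return np.concatenate(outs) if outs else np.zeros(0)

    def _resolve_classifier(self, classifier: str):
        if classifier == "auto":
            classifier = ("target" if self.target_classifier is not None
                          else "source")
        if classifier == "source":
            return self.source_classifier
        if classifier == "target":
            if self.target_classifier is None:
                raise ValueError("model has no target classifier (mode 1)")
            return self.target_classifier
        raise ValueError(f"classifier must be auto/source/target, "
                         f"got {classifier!r}")

    def score_fn(self, classifier: str = "auto"):
        """Differentiable positive-class score function for attribution."""
        head = self._resolve_classifier(classifier)

        def f(x: Tensor) -> Tensor:
            return head(self.shared_encoder(x))[:, 1].exp()

        return f


def init_model(config: ModelConfig, mode=MODE_SOURCE_ONLY,
               seed: int = 0) -> DSNModel:
    """Deterministically initialize a model from (config, mode, seed)."""
    return DSNModel(config, mode=mode, seed=seed)


# -- loss terms --------------------------------------------------------


def reconstruction_loss(x: Tensor, x_hat: Tensor,
                        variant: str = "simse") -> Tensor:
    """Per-domain reconstruction error.

    ``mse`` is the mean squared error over all entries; ``simse`` is the
    scale-invariant variant, MSE minus the squared mean error, which
    ignores any constant offset of the reconstruction.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    diff = x_hat - x
    mse = (diff ** 2.0).mean() if diff.ndim == 1 else _flat_mean(diff ** 2.0)
    if variant == "mse":
        return mse
    if variant == "simse":
        return mse - _flat_mean(diff) ** 2.0
    raise ValueError(f"unknown reconstruction variant {variant!r}")


def _flat_mean(t: Tensor) -> Tensor:
    return t.sum() * (1.0 / t.data.size)


def _row_normalize(h: Tensor) -> Tensor:
    sq = (h ** 2.0).sum(axis=1, keepdims=True)
    inv = (sq + 1e-12) ** -0.5
    mask = Tensor((np.asarray(sq.data) > 1e-24).astype(float))
    return h * inv * mask


def difference_loss(h_c: Tensor, h_p: Tensor, center: bool = True,
                    batch_normalized: bool = True) -> Tensor:
    """Soft subspace orthogonality penalty for one domain.

    Both matrices are column-mean-centered and row-L2-normalized
    (all-zero rows stay zero); the loss is the squared Frobenius norm of
    the inter-sample cross-product ``h_c h_p^T`` — the sum of squared
    inner products between every shared row and every private row, which
    is zero exactly when the two representations occupy orthogonal
    subspaces. A single unit-norm sample against itself scores 1. By
    default the sum is divided by the number of row pairs (batch^2), so
    the penalty is comparable to the other loss terms at any batch size;
    ``batch_normalized=False`` gives the raw sum. The model's total
    difference term adds the source-domain and target-domain penalties.
    """
    h_c = h_c if isinstance(h_c, Tensor) else Tensor(h_c)
    h_p = h_p if isinstance(h_p, Tensor) else Tensor(h_p)
    if h_c.shape != h_p.shape:
        raise ValueError(f"shape mismatch: {h_c.shape} vs {h_p.shape}")
    if center:
        h_c = h_c - h_c.mean(axis=0, keepdims=True)
        h_p = h_p - h_p.mean(axis=0, keepdims=True)
    h_c = _row_normalize(h_c)
    h_p = _row_normalize(h_p)
    cross = h_c @ h_p.T
    loss = (cross ** 2.0).sum()
    if batch_normalized:
        loss = loss * (1.0 / h_c.shape[0] ** 2)
    return loss


def _pairwise_sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    aa = (a ** 2).sum(axis=1)[:, None]
    bb = (b ** 2).sum(axis=1)[None, :]
    return np.maximum(aa + bb - 2.0 * a @ b.T, 0.0)


def median_heuristic_bandwidth(a: np.ndarray, b: np.ndarray) -> float:
    """Median pairwise squared distance over the pooled sample."""
    pooled = np.concatenate([np.asarray(a), np.asarray(b)], axis=0)
    d = _pairwise_sq_dists(pooled, pooled)
    upper = d[np.triu_indices_from(d, k=1)]
    med = float(np.median(upper)) if upper.size else 1.0
    return med if med > 1e-12 else 1.0


MMD_BANDWIDTH_SCALES = (1.0, 2.0, 4.0, 8.0, 16.0)


def _mmd2(h_s: Tensor, h_t: Tensor, bandwidth: float) -> Tensor:
    """Unbiased squared MMD with a fixed mixture of RBF kernels."""
    n, m = h_s.shape[0], h_t.shape[0]
    if n < 2 or m < 2:
        raise ValueError("MMD needs at least 2 samples per domain; "
                         "use a larger batch")

    def kernel_mean(a: Tensor, b: Tensor, diag: bool):
        # sum_k exp(-||ai - bj||^2 / (scale * bw))
        aa = (a ** 2.0).sum(axis=1, keepdims=True)
        bb = (b ** 2.0).sum(axis=1, keepdims=True)
        d2 = aa + bb.T - (a @ b.T) * 2.0
        total = None
        for scale in MMD_BANDWIDTH_SCALES:
            k = (d2 * (-1.0 / (scale * bandwidth))).exp()
            total = k if total is None else total + k
        if diag:
            na = a.shape[0]
            off = total.sum() - _trace(total)
            return off * (1.0 / (na * (na - 1)))
        return total.mean()

    return (kernel_mean(h_s, h_s, True) + kernel_mean(h_t, h_t, True)
            - kernel_mean(h_s, h_t, False) * 2.0)


def _trace(t: Tensor) -> Tensor:
    n = t.shape[0]
    return t[np.arange(n), np.arange(n)].sum()


def similarity_loss(h_c_s: Tensor, h_c_t: Tensor, variant: str = "mmd",
                    bandwidth: float | None = None,
                    discriminator: nn.Module | None = None) -> Tensor:
    """Distributional similarity penalty between shared representations.

    ``mmd``: unbiased squared maximum mean discrepancy under a fixed
    mixture of RBF kernels with bandwidths {1,2,4,8,16} x ``bandwidth``
    (median pairwise-distance heuristic when not given; the training
    loop freezes it at the first batch), clamped at zero. ``dann``:
    cross-entropy of a domain discriminator fed through gradient
    reversal, so minimizing it trains the discriminator while pushing
    the shared encoder toward domain confusion.
    """
    h_c_s = h_c_s if isinstance(h_c_s, Tensor) else Tensor(h_c_s)
    h_c_t = h_c_t if isinstance(h_c_t, Tensor) else Tensor(h_c_t)
    if variant == "mmd":
        if bandwidth is None:
            bandwidth = median_heuristic_bandwidth(h_c_s.data, h_c_t.data)
        mmd = _mmd2(h_c_s, h_c_t, bandwidth)
        return mmd.relu()  # unbiased estimate may dip below zero
    if variant == "dann":
        if discriminator is None:
            raise ValueError("dann variant requires a domain discriminator")
        logits = discriminator(concat(
            [grad_reverse(h_c_s), grad_reverse(h_c_t)], axis=0))
        domains = np.concatenate([np.zeros(h_c_s.shape[0], int),
                                  np.ones(h_c_t.shape[0], int)])
        return classification_loss(logits, domains)
    raise ValueError(f"unknown similarity variant {variant!r}")


def classification_loss(log_probs: Tensor, labels) -> Tensor:
    """Mean negative log-likelihood of the true class."""
    labels = np.asarray(labels, dtype=int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    n = log_probs.shape[0]
    if n != len(labels):
        raise ValueError("logits/labels length mismatch")
    picked = log_probs[np.arange(n), labels]
    return -picked.mean()


def total_loss(recon: Tensor, difference: Tensor, similarity: Tensor,
               source_cls: Tensor, target_cls: Tensor | None,
               weights: LossWeights = LossWeights(),
               mode=MODE_SOURCE_ONLY) -> tuple[Tensor, LossBreakdown]:
    """Weighted composite objective; the target term is dropped in mode 1."""
    mode = _MODES[mode]
    _lift = lambda v: v if isinstance(v, Tensor) else Tensor(v)
    recon, difference = _lift(recon), _lift(difference)
    similarity, source_cls = _lift(similarity), _lift(source_cls)
    total = (recon * weights.alpha + difference * weights.beta
             + similarity * weights.gamma + source_cls)
    tgt_val = None
    if mode == MODE_DUAL:
        if target_cls is None:
            raise ValueError("dual mode requires a target classification loss")
        target_cls = _lift(target_cls)
        total = total + target_cls * weights.delta
        tgt_val = float(target_cls.data)
    for name, term in (("recon", recon), ("difference", difference),
                       ("similarity", similarity), ("source", source_cls)):
        if not np.isfinite(term.data):
            raise FloatingPointError(f"non-finite {name} loss")
    breakdown = LossBreakdown(float(recon.data), float(difference.data),
                              float(similarity.data), float(source_cls.data),
                              tgt_val, float(total.data))
    return total, breakdown


# -- checkpoints -------------------------------------------------------


def save_checkpoint(model: DSNModel, path, extra: dict | None = None):
    """Save weights + config + mode + seed as a single ``.npz`` archive
    with a JSON sidecar describing the configuration."""
    import json
    path = Path(path)
    state = model.state_dict()
    meta = {"config": asdict(model.config), "mode": model.mode,
            "seed": model.seed}
    if extra:
        meta.update(extra)
    np.savez(path, **state)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_checkpoint(path) -> DSNModel:
    import json
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    cfg = ModelConfig(**meta["config"])
    model = DSNModel(cfg, mode=meta["mode"], seed=meta["seed"])
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
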