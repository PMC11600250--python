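"""Deep-learning spike sorters.

Four sorters share one front end (63-point gradient features from
:mod:`measort.detect`) and one evaluation convention (optimal
cluster-to-neuron matching in :mod:`measort.evaluate`):

* ``deep_ae_sort`` — deep autoencoder embedding + k-means (DeepAE);
* ``train_dec`` — Deep Embedded Clustering: after pretraining, the
  decoder is discarded and the encoder plus cluster centroids are
  refined by minimizing KL(P‖Q) between the Student-t soft assignment Q
  and a self-sharpening target distribution P;
* ``train_idec`` — Improved DEC: the decoder is kept and the loss is
  L = L_reconstruction + γ·L_clustering, preserving local structure
  while sharpening clusters;
* ``ae_ensemble_sort`` — a reference baseline: several shallow
  autoencoders with different seeds/latent widths, k-means on their
  concatenated latent codes.

Plus an over-clustering artifact filter: sort into 20+ classes, inspect
per-class mean shapes, drop the classes a user marks as noise.

All training runs on a small dense NumPy network (:mod:`measort._nn`);
every source of randomness derives from the single ``TrainConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._nn import Adam, Autoencoder, SGDMomentum

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "ClusterModel",
    "SortResult",
    "ArtifactFilterResult",
    "pretrain_autoencoder",
    "finetune_autoencoder",
    "soft_assign",
    "target_distribution",
    "train_dec",
    "train_idec",
    "deep_ae_sort",
    "ae_ensemble_sort",
    "overcluster_artifact_filter",
]


@dataclass
class NetworkSpec:
    """Autoencoder architecture, input dimension through latent."""

    layer_sizes: tuple[int, ...] = (63, 256, 256, 10)
    activation: str = "relu"

    @property
    def input_dim(self) -> int:
        return self.layer_sizes[0]

    @property
    def latent_dim(self) -> int:
        return self.layer_sizes[-1]

    def validate(self) -> None:
        if any(s < 1 for s in self.layer_sizes):
            raise ValueError("all layer sizes must be >= 1")
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and latent sizes")


@dataclass
class TrainConfig:
    """Training hyperparameters shared by all sorters.

    ``alpha`` is the Student-t degrees of freedom of the soft-assignment
    kernel; ``gamma`` weights the clustering loss in IDEC; ``tol`` is
    the fraction of changed labels below which fine-tuning stops.
    """

    pretrain_epochs: int = 60
    finetune_iterations: int = 2000
    batch_size: int = 256
    learning_rate: float = 1e-3
    alpha: float = 1.0
    gamma: float = 0.1
    update_interval: int = 40
    tol: float = 0.0002
    #: Momentum of the fine-tuning SGD (used by DEC); None selects Adam
    #: instead (used by IDEC and plain continued autoencoder training).
    momentum: float | None = None
    #: Fine-tuning learning rate; None selects the per-method default
    #: (5e-4 for DEC's SGD, ``learning_rate`` for IDEC's Adam).
    finetune_lr: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.tol):
            raise ValueError("tol must be > 0")
        for name in ("pretrain_epochs", "finetune_iterations", "batch_size",
                     "update_interval"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ClusterModel:
    """Trained encoder plus cluster centroids in latent space."""

    autoencoder: Autoencoder
    centroids: np.ndarray
    K: int
    feature_mean: np.ndarray = field(default=None, repr=False)
    feature_scale: np.ndarray = field(default=None, repr=False)

    def embed(self, features: np.ndarray) -> np.ndarray:
        x = features
        if self.feature_mean is not None:
            x = (x - self.feature_mean) / self.feature_scale
        return self.autoencoder.encode(x)


@dataclass
class SortResult:
    """Cluster assignment of every spike plus the trained model."""

    labels: np.ndarray
    soft_assignments: np.ndarray
    model: ClusterModel
    history: dict = field(default_factory=dict)


@dataclass
class ArtifactFilterResult:
    keep_mask: np.ndarray
    labels: np.ndarray
    class_mean_features: np.ndarray  # (K_over, d); rows of empty classes are NaN


# ---------------------------------------------------------------------------
# clustering math

def soft_assign(latent: np.ndarray, centroids: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Student-t soft assignment Q of points to centroids.

    q_ij ∝ (1 + ‖z_i − µ_j‖²/α)^(−(α+1)/2), rows normalized to 1.
    With α = 1 this is the Cauchy kernel used for embedding-space
    cluster membership.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    centroids = np.atleast_2d(centroids)
    if centroids.shape[0] < 2:
        raise ValueError("need at least K=2 centroids")
    d2 = ((latent[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    s = (1.0 + d2 / alpha) ** (-(alpha + 1.0) / 2.0)
    return s / s.sum(axis=1, keepdims=True)


def target_distribution(q: np.ndarray) -> np.ndarray:
    """Self-sharpening auxiliary target P: p_ij ∝ q_ij² / f_j, f_j = Σ_i q_ij.

    Squaring sharpens confident assignments; dividing by the soft cluster
    frequency f_j counteracts large clusters dominating the target.
    Clusters with zero total mass are excluded from the target.
    """
    f = q.sum(axis=0)
    weight = np.zeros_like(q)
    nonzero = f > 0
    weight[:, nonzero] = q[:, nonzero] ** 2 / f[nonzero]
    return weight / weight.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# feature scaling and seeding helpers

def _standardize(features: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column standardization; training runs in float32."""
    mean = features.mean(axis=0)
    scale = features.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return ((features - mean) / scale).astype(np.float32), mean, scale


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


# ---------------------------------------------------------------------------
# pretraining

def pretrain_autoencoder(
    features: np.ndarray, spec: NetworkSpec, config: TrainConfig,
    standardized: bool = False,
) -> tuple[Autoencoder, dict]:
    """Train a symmetric autoencoder on the spike features by MSE.

    Returns the trained network and a history dict with the per-epoch
    reconstruction loss and the untrained (initial) loss.
    """
    spec.validate()
    config.validate()
    if features.ndim != 2 or features.shape[1] != spec.input_dim:
        raise ValueError(
            f"features have dimension {features.shape}, spec expects {spec.input_dim}"
        )
    x = features if standardized else _standardize(features)[0]
    init_seed, batch_seed = _child_seeds(config.seed, 2)
    ae = Autoencoder(list(spec.layer_sizes), np.random.default_rng(init_seed))
    initial = ae.reconstruction_error(x)
    batch = min(config.batch_size, len(x))
    losses = ae.train(x, config.pretrain_epochs, batch,
                      config.learning_rate, np.random.default_rng(batch_seed))
    return ae, {"pretrain_loss": losses, "initial_loss": initial}


# ---------------------------------------------------------------------------
# joint fine-tuning loop (DEC / IDEC / plain continued AE training)

def _joint_train(
    ae: Autoencoder,
    x: np.ndarray,
    config: TrainConfig,
    K: int | None,
    recon_weight: float,
    clu_weight: float,
    use_clustering: bool,
    momentum: float | None = 0.9,
    lr: float | None = None,
    revert_on_nonconvergence: bool = False,
) -> tuple[np.ndarray | None, np.ndarray | None, dict]:
    """Shared fine-tuning loop.

    With ``use_clustering`` the encoder (and, if ``recon_weight`` > 0,
    the decoder) and the centroids minimize
    recon_weight·MSE + clu_weight·KL(P‖Q); without it the loop is plain
    continued autoencoder training consuming the identical batch stream,
    which is what makes IDEC with γ = 0 reduce exactly to autoencoder
    training at equal seeds.
    """
    n = len(x)
    _, batch_seed, kmeans_seed = _child_seeds(config.seed, 3)
    rng = np.random.default_rng(batch_seed + 1)  # fine-tuning batch stream
    batch_size = min(config.batch_size, n)
    alpha = config.alpha

    centroids = None
    labels_prev = None
    p_full = None
    history: dict = {"kl": [], "stopped_at": None}

    params = list(ae.encoder.params)
    if recon_weight > 0:
        params += ae.decoder.params
    if use_clustering:
        z_all = ae.encode(x)
        km = KMeans(n_clusters=K, n_init=10, random_state=kmeans_seed).fit(z_all)
        centroids = km.cluster_centers_.astype(np.float32)
        labels_prev = km.labels_.copy()
        params = params + [centroids]
    # DEC fine-tunes with plain SGD+momentum (pure KL self-training is
    # non-stationary and adaptive step sizes distort the embedding);
    # IDEC keeps Adam (momentum=None), whose reconstruction term anchors
    # the geometry
    lr = config.learning_rate if lr is None else lr
    if momentum is None:
        opt = Adam(params, lr=lr)
    else:
        opt = SGDMomentum(params, lr=lr, momentum=momentum)
    snapshot = [p.copy() for p in params] if revert_on_nonconvergence else None
    converged = False

    order = rng.permutation(n)
    pos = 0
    it = 0
    while it < config.finetune_iterations:
        if use_clustering and it % config.update_interval == 0:
            q_full = soft_assign(ae.encode(x), centroids, alpha)
            labels = q_full.argmax(axis=1)
            p_full = target_distribution(q_full)
            delta = float(np.mean(labels != labels_prev))
            kl = float(np.sum(p_full * (np.log(p_full + 1e-12) - np.log(q_full + 1e-12))) / n)
            history["kl"].append(kl)
            labels_prev = labels
            # tol >= 1 degenerates to "accept the initial assignment":
            # stop before any fine-tuning step.
            if (it > 0 and delta < config.tol) or (it == 0 and config.tol >= 1.0):
                history["stopped_at"] = it
                converged = True
                break
        if pos + batch_size > n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos : pos + batch_size]
        pos += batch_size
        batch = x[idx]

        cache_e: list = []
        z = ae.encoder.forward(batch, cache_e)
        gz = np.zeros_like(z)
        grads_dec = None
        if recon_weight > 0:
            cache_d: list = []
            xhat = ae.decoder.forward(z, cache_d)
            diff = xhat - batch
            g = recon_weight * 2.0 * diff / diff.size
            grads_dec, gz_rec = ae.decoder.backward(cache_d, g)
            gz += gz_rec
        if use_clustering and clu_weight > 0:
            d2 = ((z[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
            base = 1.0 / (1.0 + d2 / alpha)
            s = base ** ((alpha + 1.0) / 2.0)
            q = s / s.sum(axis=1, keepdims=True)
            coeff = ((alpha + 1.0) / alpha) * (p_full[idx] - q) * base
            coeff *= clu_weight / len(batch)
            dz = z[:, None, :] - centroids[None, :, :]
            gz += np.einsum("bk,bkd->bd", coeff, dz)
            gmu = -np.einsum("bk,bkd->kd", coeff, dz)
        grads_enc, _ = ae.encoder.backward(cache_e, gz)
        grads = list(grads_enc)
        if recon_weight > 0:
            grads += grads_dec
        if use_clustering:
            grads = grads + [gmu if clu_weight > 0 else np.zeros_like(centroids)]
        opt.step(grads)
        it += 1

    # without the reconstruction anchor, self-training that never meets
    # the label-change stopping criterion has drifted rather than
    # converged; discard the drifted state and keep the initialization
    if revert_on_nonconvergence and not converged:
        for p, s in zip(params, snapshot):
            p[...] = s
        history["reverted"] = True

    q_final = None
    if use_clustering:
        q_final = soft_assign(ae.encode(x), centroids, alpha)
    return centroids, q_final, history


def finetune_autoencoder(ae: Autoencoder, features: np.ndarray, config: TrainConfig,
                         standardized: bool = False) -> Autoencoder:
    """Continue plain reconstruction training of a pretrained autoencoder.

    Uses the same batch stream as the IDEC fine-tuning loop, so IDEC with
    γ = 0 follows an identical encoder/decoder weight trajectory.
    """
    x = features if standardized else _standardize(features)[0]
    _joint_train(ae, x, config, K=None, recon_weight=1.0, clu_weight=0.0,
                 use_clustering=False, momentum=config.momentum)
    return ae


def _check_k(K: int, n: int) -> None:
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError(f"K={K} exceeds number of spikes n={n}")


def train_dec(
    features: np.ndarray,
    spec: NetworkSpec | None = None,
    config: TrainConfig | None = None,
    K: int = 5,
    pretrained: Autoencoder | None = None,
) -> SortResult:
    """Deep Embedded Clustering.

    Pretrains (or reuses) an autoencoder, discards the decoder,
    initializes centroids by k-means on the latent codes and then
    alternates target-distribution refreshes with gradient steps on
    KL(P‖Q) until fewer than ``config.tol`` of the labels change.
    """
    spec = spec or NetworkSpec()
    config = config or TrainConfig()
    _check_k(K, len(features))
    x, mean, scale = _standardize(features)
    if pretrained is None:
        ae, hist = pretrain_autoencoder(x, spec, config, standardized=True)
    else:
        ae, hist = pretrained, {}
    centroids, q, h2 = _joint_train(
        ae, x, config, K, recon_weight=0.0, clu_weight=1.0, use_clustering=True,
        momentum=config.momentum if config.momentum is not None else 0.9,
        lr=config.finetune_lr if config.finetune_lr is not None else 5e-4,
        revert_on_nonconvergence=True)
    hist.update(h2)
    model = ClusterModel(ae, centroids, K, mean, scale)
    return SortResult(q.argmax(axis=1), q, model, hist)


def train_idec(
    features: np.ndarray,
    spec: NetworkSpec | None = None,
    config: TrainConfig | None = None,
    K: int = 5,
    pretrained: Autoencoder | None = None,
) -> SortResult:
    """Improved Deep Embedded Clustering.

    As :func:`train_dec` but the decoder is retained and the fine-tuning
    loss is L = L_reconstruction + γ·L_clustering (γ = ``config.gamma``),
    preserving the local structure of the data while clusters sharpen.
    """
    spec = spec or NetworkSpec()
    config = config or TrainConfig()
    _check_k(K, len(features))
    x, mean, scale = _standardize(features)
    if pretrained is None:
        ae, hist = pretrain_autoencoder(x, spec, config, standardized=True)
    else:
        ae, hist = pretrained, {}
    centroids, q, h2 = _joint_train(
        ae, x, config, K, recon_weight=1.0, clu_weight=config.gamma,
        use_clustering=True, momentum=config.momentum, lr=config.finetune_lr)
    hist.update(h2)
    model = ClusterModel(ae, centroids, K, mean, scale)
    return SortResult(q.argmax(axis=1), q, model, hist)


def deep_ae_sort(
    features: np.ndarray,
    spec: NetworkSpec | None = None,
    config: TrainConfig | None = None,
    K: int = 5,
    pretrained: Autoencoder | None = None,
) -> SortResult:
    """Deep autoencoder + k-means (DeepAE): embed, then cluster the codes."""
    spec = spec or NetworkSpec()
    config = config or TrainConfig()
    _check_k(K, len(features))
    x, mean, scale = _standardize(features)
    if pretrained is None:
        ae, hist = pretrain_autoencoder(x, spec, config, standardized=True)
    else:
        ae, hist = pretrained, {}
    kmeans_seed = _child_seeds(config.seed, 3)[2]
    z = ae.encode(x)
    km = KMeans(n_clusters=K, n_init=10, random_state=kmeans_seed).fit(z)
    centroids = km.cluster_centers_.astype(float)
    q = soft_assign(z, centroids, config.alpha)
    model = ClusterModel(ae, centroids, K, mean, scale)
    return SortResult(km.labels_.astype(np.int64), q, model, hist)


def ae_ensemble_sort(
    features: np.ndarray,
    n_members: int = 5,
    spec_variants: list[NetworkSpec] | None = None,
    config: TrainConfig | None = None,
    K: int = 5,
) -> SortResult:
    """Autoencoder-ensemble baseline.

    Trains ``n_members`` shallow autoencoders with distinct seeds and
    latent widths, concatenates their latent codes (column-standardized
    so no member dominates) and clusters the concatenation with k-means.
    Serves as the normalization reference in benchmarking.
    """
    config = config or TrainConfig()
    if n_members < 2:
        raise ValueError("an ensemble needs n_members >= 2")
    _check_k(K, len(features))
    d = features.shape[1]
    if spec_variants is None:
        widths = [8, 10, 12, 10, 8]
        spec_variants = [
            NetworkSpec(layer_sizes=(d, 112, widths[i % len(widths)]))
            for i in range(n_members)
        ]
    if len(spec_variants) != n_members:
        raise ValueError("spec_variants length must equal n_members")
    x, mean, scale = _standardize(features)
    seeds = _child_seeds(config.seed, n_members + 1)
    codes = []
    diag = []
    for m in range(n_members):
        member_cfg = TrainConfig(**{**config.__dict__, "seed": seeds[m]})
        ae, hist = pretrain_autoencoder(x, spec_variants[m], member_cfg,
                                        standardized=True)
        z = ae.encode(x)
        codes.append(z)
        diag.append({"latent_dim": z.shape[1],
                     "final_loss": hist["pretrain_loss"][-1]})
    concat = np.hstack(codes)
    sd = concat.std(axis=0)
    concat = (concat - concat.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=K, n_init=10, random_state=seeds[-1]).fit(concat)
    centroids = km.cluster_centers_.astype(float)
    q = soft_assign(concat, centroids, config.alpha)
    model = ClusterModel(None, centroids, K, mean, scale)
    return SortResult(km.labels_.astype(np.int64), q, model,
                      {"members": diag})


def overcluster_artifact_filter(
    features: np.ndarray,
    K_over: int = 20,
    noise_class_ids: set[int] | None = None,
    sorter=None,
    config: TrainConfig | None = None,
) -> ArtifactFilterResult:
    """Over-cluster the spikes and drop user-designated noise classes.

    Sorting into ``K_over`` (20+) classes isolates artifact shapes into
    their own classes; per-class mean feature vectors are returned to
    support the manual decision of which classes are noise.  The keep
    mask excludes spikes whose class is in ``noise_class_ids``.
    """
    noise_class_ids = set() if noise_class_ids is None else set(noise_class_ids)
    if K_over < 2:
        raise ValueError("K_over must be >= 2")
    bad = [c for c in noise_class_ids if not (0 <= c < K_over)]
    if bad:
        raise ValueError(f"noise_class_ids {bad} outside [0, {K_over})")
    sorter = sorter or deep_ae_sort
    result = sorter(features, config=config, K=K_over)
    labels = result.labels
    means = np.full((K_over, features.shape[1]), np.nan)
    for c in range(K_over):
        sel = labels == c
        if sel.any():
            means[c] = features[sel].mean(axis=0)
    if noise_class_ids:
        keep = ~np.isin(labels, sorted(noise_class_ids))
    else:
        keep = np.ones(len(labels), dtype=bool)
    return ArtifactFilterResult(keep_mask=keep, labels=labels,
                                class_mean_features=means)
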