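"""Training protocol: Nadam optimization with projected non-negative mixing.

The optimizer is Adam with Nesterov momentum (Nadam) including the momentum
schedule-decay term, following the Keras formulation the stated defaults
come from:

    mu_t      = beta1 * (1 - 0.5 * 0.96**(t * psi))         (psi = schedule decay)
    mu_{t+1}  = beta1 * (1 - 0.5 * 0.96**((t + 1) * psi))
    m_t       = beta1 * m_{t-1} + (1 - beta1) * g_t
    v_t       = beta2 * v_{t-1} + (1 - beta2) * g_t^2
    m_hat     = mu_{t+1} * m_t / (1 - prod_{i<=t+1} mu_i)
                + (1 - mu_t) * g_t / (1 - prod_{i<=t} mu_i)
    v_hat     = v_t / (1 - beta2^t)
    theta    -= lr * m_hat / (sqrt(v_hat) + eps)

After every optimizer step the mixing-layer weights are clipped at zero
(projected gradient), keeping the reconstruction a non-negative weighted sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor
from .loss import LossConfig, cosine_proximity, reconstruction_loss, activity_regularizer
from .model import Network, project_nonnegative
from .preprocess import PatchSet, augment

__all__ = ["TrainConfig", "TrainingLog", "Nadam", "train", "initialize_mixing_from_data"]


@dataclass
class TrainConfig:
    epochs: int = 80
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    schedule_decay: float = 0.004
    batch_size: int = 1
    seed: int = 0
    alpha: float = 0.0075
    noise_sd: float = 0.05
    scale_sd: float = 0.5
    include_laplacian: bool = True
    mixing_init: str = "data"  # "data" (k-means endmembers) or "keep"
    # epochs during which the mixing layer stays frozen at its endmember
    # initialization while the encoder-decoder learns the abundances; with
    # distinct fixed spectra the per-voxel unmixing is well-posed, which
    # prevents two materials from drifting onto one spectrum
    mixing_freeze_epochs: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingLog:
    """Per-epoch mean loss terms."""

    epochs: list[int] = field(default_factory=list)
    recon: list[float] = field(default_factory=list)
    regularizer: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)

    def append(self, epoch: int, recon: float, reg: float) -> None:
        self.epochs.append(epoch)
        self.recon.append(recon)
        self.regularizer.append(reg)
        self.total.append(recon + reg)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,recon_term,regularizer,total\n")
            for e, r, g, t in zip(self.epochs, self.recon, self.regularizer, self.total):
                fh.write(f"{e},{r:.8f},{g:.8f},{t:.8f}\n")


def _select_endmembers(centroids: np.ndarray, m: int) -> tuple[np.ndarray, float]:
    """Pick the m centroids spanning the largest simplex (N-FINDR style).

    Rare materials (lesions) produce small but spectrally extreme clusters;
    maximizing simplex volume selects them while skipping partial-volume
    clusters that lie between pure signatures.  Exhaustive search when the
    simplex is non-degenerate (m <= C + 1), greedy max-min fallback beyond.
    Returns the selection and its (generalized) simplex volume.
    """
    import itertools

    k, c = centroids.shape
    if m <= c + 1:
        best, best_vol = None, -1.0
        for comb in itertools.combinations(range(k), m):
            pts = centroids[list(comb)]
            a = pts[:-1] - pts[-1]
            vol = abs(np.linalg.det(a @ a.T)) ** 0.5
            if vol > best_vol:
                best_vol, best = vol, comb
        return centroids[list(best)], best_vol
    chosen = [int(np.argmax(np.linalg.norm(centroids, axis=1)))]
    while len(chosen) < m:
        dmin = np.min(
            [np.linalg.norm(centroids - centroids[i], axis=1) for i in chosen], axis=0
        )
        chosen.append(int(np.argmax(dmin)))
    sel = centroids[chosen]
    a = sel[:-1] - sel[-1]
    return sel, abs(np.linalg.det(a @ a.T)) ** 0.5


def initialize_mixing_from_data(
    network: Network, patches: PatchSet, seed: int = 0, max_voxels: int = 20_000
) -> None:
    """Initialize the mixing layer with data-derived endmember spectra.

    Each brain voxel is a C-vector of channel intensities.  The voxels are
    over-clustered with k-means++ (k well above M so that rare materials
    get their own centroid), and the M centroids spanning the largest
    simplex become the initial rows of the mixing matrix (clipped to be
    strictly positive).  Starting the projected optimization from
    data-derived endmembers instead of a random point is standard practice
    in linear spectral unmixing, and matters here because Adam-style
    updates move each mixing weight by roughly the learning rate per step.
    """
    from scipy.cluster.vq import kmeans2

    m = network.config.n_materials
    vox = patches.patches.transpose(0, 2, 3, 4, 1).reshape(-1, network.config.in_channels)
    vox = vox[np.any(vox != 0, axis=1)]
    if len(vox) < m:
        raise ValueError("not enough brain voxels to initialize the mixing layer")
    rng = np.random.default_rng(seed)
    k = min(max(3 * m, m + 4), 16)
    # a single k-means draw occasionally misses a rare material's cluster;
    # take the draw whose selected endmembers span the largest simplex
    best_w, best_vol, best_sub = None, -1.0, None
    for trial in range(3):
        sub = vox
        if len(vox) > max_voxels:
            sub = vox[rng.choice(len(vox), max_voxels, replace=False)]
        sub = sub.astype(float)
        centroids, _ = kmeans2(sub, k, seed=seed + 1000 * trial, minit="++")
        w_trial, vol = _select_endmembers(centroids, m)
        if vol > best_vol:
            best_w, best_vol, best_sub = w_trial, vol, sub
    w = np.maximum(best_w, 1e-3)
    w = _purify_endmembers(w, best_sub)
    w = np.maximum(w, 1e-3)  # (M, C), strictly feasible
    network.mixing.data = w.T.reshape(network.mixing.data.shape).astype(
        network.mixing.data.dtype
    )


def _purify_endmembers(
    w: np.ndarray, vox: np.ndarray, n_iter: int = 2, purity: float = 0.9
) -> np.ndarray:
    """Refine endmembers by averaging near-pure voxels.

    Cluster centroids are biased toward partial-volume mixtures; solving
    non-negative least squares abundances per voxel and re-averaging the
    voxels dominated (>= ``purity``) by one endmember walks each spectrum
    toward its pure-material value.
    """
    from scipy.optimize import nnls

    m = w.shape[0]
    for _ in range(n_iter):
        ab = np.empty((len(vox), m))
        wt = w.T
        for i, v in enumerate(vox):
            ab[i], _ = nnls(wt, v)
        total = ab.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        frac = ab / total
        for j in range(m):
            sel = frac[:, j] >= purity
            if sel.sum() >= 10:
                w[j] = vox[sel].mean(axis=0)
    return w


class Nadam:
    def __init__(self, params: list[Tensor], lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, schedule_decay: float = 0.004, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.psi = schedule_decay
        self.eps = eps
        self.t = 0
        self.m_schedule = 1.0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def _mu(self, t: int) -> float:
        return self.beta1 * (1.0 - 0.5 * 0.96 ** (t * self.psi))

    def step(self) -> None:
        self.t += 1
        t = self.t
        mu_t = self._mu(t)
        mu_next = self._mu(t + 1)
        self.m_schedule *= mu_t
        ms_next = self.m_schedule * mu_next
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            m_hat = mu_next * self.m[i] / (1 - ms_next) + (1 - mu_t) * g / (1 - self.m_schedule)
            v_hat = self.v[i] / (1 - self.beta2**t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    network: Network,
    patches: PatchSet,
    targets: PatchSet,
    config: TrainConfig | None = None,
) -> tuple[Network, TrainingLog]:
    """Optimize the autoencoder on aligned input/target patch sets.

    Inputs and targets must share origins one-to-one; targets differ from
    inputs only by bias correction or enhancement.  Each epoch shuffles the
    patch order (seeded), augments the inputs only (additive noise, then
    per-channel scaling), evaluates the loss of the reconstruction against
    the unaugmented target, steps Nadam, and projects the mixing weights to
    be non-negative.  The patch brainmask is computed from the clean input
    before augmentation so background voxels stay masked.
    """
    config = config or TrainConfig()
    if len(patches) != len(targets) or not np.array_equal(patches.origins, targets.origins):
        raise ValueError("input and target patch sets must be aligned (same origins)")

    if config.mixing_init == "data":
        initialize_mixing_from_data(network, patches, seed=config.seed)
    loss_cfg = LossConfig(alpha=config.alpha, include_laplacian=config.include_laplacian)
    opt = Nadam(
        network.parameters(),
        lr=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        schedule_decay=config.schedule_decay,
    )
    rng = np.random.default_rng(config.seed)
    log = TrainingLog()
    n = len(patches)
    network.train()
    dtype = network.mixing.data.dtype

    for epoch in range(config.epochs):
        frozen = epoch < config.mixing_freeze_epochs
        order = rng.permutation(n)
        recon_sum = 0.0
        reg_sum = 0.0
        for idx in order:
            x = patches.patches[idx].astype(dtype)
            y = targets.patches[idx].astype(dtype)
            mask = np.any(x != 0, axis=0)
            x_aug = augment(x, config.noise_sd, config.scale_sd, rng)
            network.zero_grad()
            _, S, recon = network.forward(x_aug, mask=mask)
            r_term = reconstruction_loss(
                Tensor(y), recon, loss_cfg.epsilon, loss_cfg.include_laplacian
            )
            g_term = activity_regularizer(S, loss_cfg.alpha, loss_cfg.epsilon)
            total = r_term + g_term
            if config.learning_rate > 0:
                total.backward()
                if frozen:
                    network.mixing.grad = None
                opt.step()
                project_nonnegative(network)
            recon_sum += r_term.item()
            reg_sum += g_term.item()
        log.append(epoch, recon_sum / n, reg_sum / n)
    return network, log


def channel_cosines(network: Network, volumes: np.ndarray, maps=None) -> np.ndarray:
    """Per-channel cosine proximity between a volume stack and the
    reconstruction implied by the network's material maps and mixing weights."""
    from .infer import predict_volume  # local import to avoid a cycle

    if maps is None:
        maps = predict_volume(network, volumes, patch_size=volumes.shape[1:], stride=max(volumes.shape))
    recon = np.tensordot(network.mixing_weights.T, maps.maps, axes=1)
    return np.array(
        [cosine_proximity(volumes[c], recon[c]) for c in range(volumes.shape[0])]
    )
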