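"""Losses, GradNorm task balancing, and the adversarial training loop.

The generator optimizes a two-task objective, one task per material map:

    L_VNC = L1(sVNC, VNC) + L_adv1(sVNC)
    L_IOM = L1(sIOM, IOM) + L_adv2(sIOM)
    L_gen = w_VNC * L_VNC + w_IOM * L_IOM

with one discriminator per map providing the adversarial terms.  The task
weights (w_VNC, w_IOM) are adapted every iteration by GradNorm: the gradient
norm of each weighted task loss, measured at the deepest shared encoder
layer, is pulled toward the average norm scaled by that task's relative
inverse training rate.  This matters here because the iodine map is mostly
zero (lesions are sparse) so its raw L1 is an order of magnitude smaller
than the VNC one.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999, initial lr 1e-3) for every
parameter group, with a reduce-on-plateau schedule (factor 0.5, patience 5)
driven by the mean training loss over consecutive 50-iteration windows.
Default batch size 4 and 200 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Discriminator, Generator
from .nn import Adam, Tensor
from .phantom import PairedCase
from .preprocess import augment as augment_case, random_crop

__all__ = ["TrainConfig", "LossBreakdown", "GradNormState", "PlateauScheduler",
           "l1_loss", "adversarial_losses", "task_losses", "gradnorm_step",
           "train"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    loss_window: int = 50
    batch_size: int = 4
    iterations: int = 200
    gradnorm_alpha: float = 1.5
    gradnorm_lr: float = 0.025
    gradnorm_warmup: int = 200
    use_gradnorm: bool = True
    adversarial: bool = True
    gan_mode: str = "nonsaturating"  # or "lsgan"
    crop_size: tuple[int, ...] | None = None
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.lr, self.batch_size, self.iterations, self.loss_window,
               self.gradnorm_alpha, self.gradnorm_lr) <= 0:
            raise ValueError("TrainConfig fields must be positive")
        if not 0.0 < self.scheduler_factor < 1.0:
            raise ValueError("scheduler_factor must lie in (0, 1)")
        if self.gan_mode not in ("nonsaturating", "lsgan"):
            raise ValueError(f"unknown gan_mode {self.gan_mode!r}")


@dataclass
class LossBreakdown:
    """Per-iteration scalar loss terms (generator and discriminator sides)."""

    l1_vnc: float
    adv_vnc: float
    l1_iom: float
    adv_iom: float
    disc_vnc: float
    disc_iom: float

    @property
    def loss_vnc(self) -> float:
        return self.l1_vnc + self.adv_vnc

    @property
    def loss_iom(self) -> float:
        return self.l1_iom + self.adv_iom


@dataclass
class GradNormState:
    """Dynamic task weights; renormalized so they always sum to 2.

    The reference losses L(0) anchor the inverse training rates.  They are
    the mean task losses over the first ``init_window`` updates rather than
    the very first iteration: an untrained generator's first steps are
    dominated by the trivial output-bias error (the VNC task's loss falls
    several-fold while it learns a constant background), and anchoring
    there makes that transient look like runaway training progress, driving
    the task's weight to the floor and shutting the task off.  The default
    warmup (200 updates) spans that transient.  Weights stay at (1, 1)
    during the warmup.
    """

    weights: np.ndarray = field(default_factory=lambda: np.ones(2))
    initial_losses: np.ndarray | None = None
    alpha: float = 1.5
    weight_lr: float = 0.025
    init_window: int = 200
    # stability band: shared-layer gradient norms can differ by orders of
    # magnitude (they scale with downstream weight magnitudes), and literal
    # norm-balancing would then shut one task off entirely; weights adapt
    # freely inside the band but never silence a task
    weight_band: tuple[float, float] = (0.25, 1.75)
    # warmup accumulator and Adam moments for the weight updates
    _accum: np.ndarray = field(default_factory=lambda: np.zeros(2))
    _seen: int = 0
    _m: np.ndarray = field(default_factory=lambda: np.zeros(2))
    _v: np.ndarray = field(default_factory=lambda: np.zeros(2))
    _t: int = 0


def l1_loss(pred: Tensor, target: Tensor) -> Tensor:
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return (pred - target).abs().mean()


def adversarial_losses(disc: Discriminator, fake: Tensor, real: Tensor,
                       mode: str = "nonsaturating") -> tuple[Tensor, Tensor]:
    """Generator and discriminator adversarial terms.

    Non-saturating form: the discriminator minimizes
    -[log σ(D(real)) + log(1 - σ(D(fake)))] and the generator minimizes
    -log σ(D(fake)); the fake is detached for the discriminator term.
    A least-squares variant is available for experimentation.
    """
    fake_logit = disc(fake)
    real_logit = disc(real)
    fake_detached_logit = disc(fake.detach())
    if mode == "nonsaturating":
        gen_term = (-fake_logit).softplus().mean()
        disc_term = ((-real_logit).softplus().mean()
                     + fake_detached_logit.softplus().mean())
    else:  # least squares
        gen_term = ((fake_logit - 1.0) ** 2).mean()
        disc_term = (((real_logit - 1.0) ** 2).mean()
                     + (fake_detached_logit ** 2).mean())
    return gen_term, disc_term


def task_losses(svnc: Tensor, siom: Tensor, yvnc: Tensor, yiom: Tensor,
                disc_vnc: Discriminator | None = None,
                disc_iom: Discriminator | None = None,
                mode: str = "nonsaturating",
                ) -> tuple[Tensor, Tensor, Tensor, Tensor, LossBreakdown]:
    """Assemble (L_VNC, L_IOM, disc_vnc_loss, disc_iom_loss, breakdown)."""
    l1_v = l1_loss(svnc, yvnc)
    l1_i = l1_loss(siom, yiom)
    zero = Tensor(0.0)
    adv_v = adv_i = dv = di = zero
    if disc_vnc is not None:
        adv_v, dv = adversarial_losses(disc_vnc, svnc, yvnc, mode)
    if disc_iom is not None:
        adv_i, di = adversarial_losses(disc_iom, siom, yiom, mode)
    breakdown = LossBreakdown(
        l1_vnc=l1_v.item(), adv_vnc=adv_v.item(),
        l1_iom=l1_i.item(), adv_iom=adv_i.item(),
        disc_vnc=dv.item(), disc_iom=di.item())
    return l1_v + adv_v, l1_i + adv_i, dv, di, breakdown


def gradnorm_step(state: GradNormState, losses: np.ndarray,
                  grad_norms: np.ndarray) -> GradNormState:
    """One GradNorm weight update.

    ``losses`` are the current task losses L_i(t), ``grad_norms`` the raw
    gradient norms g_i = ||∂L_i/∂W_shared|| (unweighted).  The weighted norms
    G_i = w_i * g_i are pulled toward the common target Ḡ * r_i^α, where
    r_i is the inverse training rate L_i(t)/L_i(0) normalized to mean one
    and α the asymmetry exponent.  The gradient of Σ|G_i − target_i| with
    respect to w (targets treated as constants) drives one Adam step, after
    which the weights are renormalized to sum to 2.
    """
    losses = np.asarray(losses, dtype=np.float64)
    grad_norms = np.asarray(grad_norms, dtype=np.float64)
    if state.initial_losses is None:
        state._accum += losses
        state._seen += 1
        if state._seen < state.init_window:
            return state  # warmup: weights remain (1, 1)
        state.initial_losses = np.maximum(state._accum / state._seen, 1e-12)
    w = state.weights
    weighted = w * grad_norms
    rate = losses / state.initial_losses
    rate = rate / max(rate.mean(), 1e-12)
    target = weighted.mean() * rate ** state.alpha
    grad_w = np.sign(weighted - target) * grad_norms
    # Adam on the weights (kept separate from the network optimizers)
    state._t += 1
    state._m += 0.1 * (grad_w - state._m)
    state._v += 0.001 * (grad_w * grad_w - state._v)
    mhat = state._m / (1 - 0.9 ** state._t)
    vhat = state._v / (1 - 0.999 ** state._t)
    w = w - state.weight_lr * mhat / (np.sqrt(vhat) + 1e-8)
    w = np.maximum(w, 1e-3)
    w = 2.0 * w / w.sum()
    lo, hi = state.weight_band
    w[0] = np.clip(w[0], lo, hi)  # two tasks: clamping one fixes the other
    w[1] = 2.0 - w[0]
    state.weights = w
    return state


class PlateauScheduler:
    """Halve the learning rate when windowed mean loss stops improving."""

    def __init__(self, lr: float, factor: float = 0.5, patience: int = 5,
                 threshold: float = 1e-4):
        self.lr = float(lr)
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.best = np.inf
        self.num_bad = 0

    def step(self, mean_loss: float) -> float:
        """Feed one windowed mean; returns the (possibly decayed) lr."""
        if mean_loss < self.best * (1.0 - self.threshold):
            self.best = mean_loss
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad > self.patience:
                self.lr *= self.factor
                self.num_bad = 0
        return self.lr


def _batch_tensors(cases: list[PairedCase], rng: np.random.Generator,
                   config: TrainConfig) -> tuple[Tensor, Tensor, Tensor]:
    picks = rng.integers(0, len(cases), size=config.batch_size)
    sect, vnc, iom = [], [], []
    for i in picks:
        case = cases[int(i)]
        if config.augment:
            case = augment_case(case, rng)
        if config.crop_size is not None:
            case = random_crop(case, config.crop_size, rng)
        sect.append(case.sect)
        vnc.append(case.vnc)
        iom.append(case.iom)
    to_t = lambda vols: Tensor(np.stack(vols)[..., None])
    return to_t(sect), to_t(vnc), to_t(iom)


def train(cases: list[PairedCase], generator: Generator,
          disc_vnc: Discriminator | None, disc_iom: Discriminator | None,
          config: TrainConfig, callback=None) -> pd.DataFrame:
    """Run the adversarial training loop; returns the per-iteration history.

    Each iteration updates both discriminators on (real target, detached
    fake), then the generator on w_VNC*L_VNC + w_IOM*L_IOM with per-task
    gradients combined explicitly so GradNorm can read the per-task gradient
    norms at the shared encoder layer.  Fully replayable from the seed in
    single-threaded mode.
    """
    if not cases:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    adversarial = config.adversarial and disc_vnc is not None
    opt_g = Adam(generator.parameters(), lr=config.lr,
                 beta1=config.beta1, beta2=config.beta2)
    opts_d = []
    if adversarial:
        opts_d = [Adam(d.parameters(), lr=config.lr, beta1=config.beta1,
                       beta2=config.beta2) for d in (disc_vnc, disc_iom)]
    gn_state = GradNormState(alpha=config.gradnorm_alpha,
                             weight_lr=config.gradnorm_lr,
                             init_window=config.gradnorm_warmup)
    scheduler = PlateauScheduler(config.lr, config.scheduler_factor,
                                 config.scheduler_patience)
    shared = generator.shared_layer
    rows: list[dict] = []
    window: list[float] = []

    for it in range(1, config.iterations + 1):
        x, yv, yi = _batch_tensors(cases, rng, config)

        # -- discriminators first, on the current generator output
        if adversarial:
            svnc, siom = generator(x)
            for disc, opt, fake, real in ((disc_vnc, opts_d[0], svnc, yv),
                                          (disc_iom, opts_d[1], siom, yi)):
                _, d_term = adversarial_losses(disc, fake, real, config.gan_mode)
                opt.zero_grad()
                d_term.backward()
                opt.step()

        # -- generator multi-task update
        svnc, siom = generator(x)
        loss_v, loss_i, dv, di, breakdown = task_losses(
            svnc, siom, yv, yi,
            disc_vnc if adversarial else None,
            disc_iom if adversarial else None,
            config.gan_mode)

        generator.zero_grad()
        loss_v.backward()
        g_norm_v = float(np.linalg.norm(shared.grad)) if shared.grad is not None else 0.0
        grads_v = {id(p): p.grad for p in generator.parameters() if p.grad is not None}
        generator.zero_grad()
        loss_i.backward()
        g_norm_i = float(np.linalg.norm(shared.grad)) if shared.grad is not None else 0.0
        w_v, w_i = gn_state.weights
        for p in generator.parameters():
            gv = grads_v.get(id(p))
            gi = p.grad
            if gv is None and gi is None:
                p.grad = None
            else:
                p.grad = ((w_v * gv if gv is not None else 0.0)
                          + (w_i * gi if gi is not None else 0.0))
        opt_g.step()

        if config.use_gradnorm:
            gradnorm_step(gn_state,
                          np.array([breakdown.loss_vnc, breakdown.loss_iom]),
                          np.array([g_norm_v, g_norm_i]))

        total = w_v * breakdown.loss_vnc + w_i * breakdown.loss_iom
        if not np.isfinite(total):
            raise RuntimeError(f"non-finite training loss at iteration {it}: "
                               f"{breakdown}")
        window.append(total)
        if len(window) == config.loss_window:
            new_lr = scheduler.step(float(np.mean(window)))
            window.clear()
            opt_g.lr = new_lr
            for opt in opts_d:
                opt.lr = new_lr

        rows.append({"iteration": it, "l1_vnc": breakdown.l1_vnc,
                     "adv_vnc": breakdown.adv_vnc, "l1_iom": breakdown.l1_iom,
                     "adv_iom": breakdown.adv_iom,
                     "disc_vnc": breakdown.disc_vnc,
                     "disc_iom": breakdown.disc_iom,
                     "loss_vnc": breakdown.loss_vnc,
                     "loss_iom": breakdown.loss_iom,
                     "total": total, "w_vnc": w_v, "w_iom": w_i,
                     "lr": opt_g.lr})
        if callback is not None:
            callback(it, rows[-1])

    return pd.DataFrame(rows)
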