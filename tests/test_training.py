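"""Loss functions, GradNorm balancing, scheduler, and the training loop."""

import numpy as np
import pytest

from sect2mdi.model import Discriminator, Generator
from sect2mdi.nn import Tensor
from sect2mdi.phantom import PhantomConfig, simulate_case
from sect2mdi.training import (GradNormState, PlateauScheduler, TrainConfig,
                               adversarial_losses, gradnorm_step, l1_loss,
                               task_losses, train)

from conftest import TINY_MODEL

LN2 = np.log(2.0)


def _zeroed_disc(shape=(16, 16)):
    """Discriminator clamped to output logit 0 for any input."""
    d = Discriminator(TINY_MODEL, shape, seed=0)
    for p in d.parameters():
        p.data[:] = 0.0
    return d


def test_l1_loss_examples():
    assert l1_loss(Tensor(np.ones((4, 4))), Tensor(np.ones((4, 4)))).item() == 0.0
    assert l1_loss(Tensor(np.full((3, 3), 2.5)),
                   Tensor(np.zeros((3, 3)))).item() == pytest.approx(2.5)
    assert l1_loss(Tensor(np.array([0.0, 2.0])),
                   Tensor(np.array([1.0, 1.0]))).item() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        l1_loss(Tensor(np.zeros(3)), Tensor(np.zeros(4)))


def test_adversarial_losses_at_logit_zero():
    d = _zeroed_disc()
    fake = Tensor(np.zeros((1, 16, 16, 1)))
    real = Tensor(np.ones((1, 16, 16, 1)))
    gen_term, disc_term = adversarial_losses(d, fake, real)
    assert gen_term.item() == pytest.approx(LN2, rel=1e-6)
    assert disc_term.item() == pytest.approx(2 * LN2, rel=1e-6)


def test_disc_term_vanishes_for_confident_discriminator():
    d = _zeroed_disc()
    d.fc.bias.data[:] = 30.0  # strongly "real" on everything
    real = Tensor(np.ones((1, 16, 16, 1)))
    # make the fake side confidently fake by flipping the sign via weights:
    # evaluate the formula directly at large logits instead
    _, disc_term = adversarial_losses(d, real, real)
    # D(real)=+30 contributes ~0; D(fake)=+30 contributes ~30 -> dominated by
    # the fake term; now flip: bias -30 makes the fake term ~0
    d.fc.bias.data[:] = -30.0
    _, disc_term_fakeside = adversarial_losses(d, real, real)
    assert disc_term.item() + disc_term_fakeside.item() == pytest.approx(60.0, rel=0.1)


def test_task_losses_assemble_breakdown():
    rng = np.random.default_rng(0)
    sv, si = Tensor(rng.uniform(0, 1, (1, 16, 16, 1))), Tensor(rng.uniform(0, 1, (1, 16, 16, 1)))
    yv, yi = Tensor(rng.uniform(0, 1, (1, 16, 16, 1))), Tensor(rng.uniform(0, 1, (1, 16, 16, 1)))
    loss_v, loss_i, _, _, bd = task_losses(sv, si, yv, yi)  # no discriminators
    assert bd.adv_vnc == 0.0 and bd.disc_iom == 0.0
    assert loss_v.item() == pytest.approx(bd.l1_vnc)
    d = _zeroed_disc()
    loss_v, loss_i, _, _, bd = task_losses(yv, yi, yv, yi, d, d)
    assert bd.l1_vnc == 0.0
    assert loss_v.item() == pytest.approx(LN2, rel=1e-6)  # perfect pred, D at 0
    assert bd.loss_vnc == pytest.approx(bd.l1_vnc + bd.adv_vnc)
    assert bd.loss_iom == pytest.approx(bd.l1_iom + bd.adv_iom)


def test_gradnorm_symmetric_tasks_keep_equal_weights():
    state = GradNormState()
    for _ in range(25):
        gradnorm_step(state, losses=np.array([3.0, 3.0]),
                      grad_norms=np.array([1.2, 1.2]))
        assert state.weights == pytest.approx([1.0, 1.0])
        assert state.weights.sum() == pytest.approx(2.0)


def test_gradnorm_weight_sum_conserved_and_positive():
    rng = np.random.default_rng(1)
    state = GradNormState()
    for _ in range(200):
        gradnorm_step(state, losses=rng.uniform(0.1, 5.0, 2),
                      grad_norms=rng.uniform(0.01, 2.0, 2))
        assert state.weights.sum() == pytest.approx(2.0)
        assert (state.weights > 0).all()


def test_gradnorm_matches_hand_derived_scalar_oracle():
    """One-parameter model: every quantity known in closed form.

    Tasks L_i = a_i * |w_shared| have shared-layer gradient norms g_i = a_i.
    Step 1 (w = (1,1), r = (1,1)): weighted norms G = (2, 0.5), common
    target mean(G) = 1.25, so dL/dw = (sign(+0.75)*2, sign(-0.75)*0.5)
    = (+2, -0.5).  A first bias-corrected Adam step is exactly
    lr * sign(grad), giving w = (1-0.025, 1+0.025); the shifts cancel so
    renormalization to sum 2 is a no-op.
    Step 2 (L = (2, 0.9), so r = (5/7, 9/7) after mean-normalization):
    G = (1.95, 0.5125), targets mean(G)*r^1.5 = (0.7435, 1.7950), the
    update signs repeat and Adam again steps by lr * sign, giving
    w = (0.95, 1.05) up to the 1e-8 epsilon.
    """
    state = GradNormState(alpha=1.5, weight_lr=0.025, init_window=1)
    gradnorm_step(state, np.array([4.0, 1.0]), np.array([2.0, 0.5]))
    assert state.weights == pytest.approx([0.975, 1.025], abs=1e-6)
    gradnorm_step(state, np.array([2.0, 0.9]), np.array([2.0, 0.5]))
    assert state.weights == pytest.approx([0.95, 1.05], abs=1e-6)


def test_gradnorm_invariant_under_task_relabeling():
    rng = np.random.default_rng(2)
    losses = rng.uniform(0.5, 4.0, (30, 2))
    norms = rng.uniform(0.1, 2.0, (30, 2))
    s_fwd, s_rev = GradNormState(), GradNormState()
    for L, g in zip(losses, norms):
        gradnorm_step(s_fwd, L, g)
        gradnorm_step(s_rev, L[::-1], g[::-1])
    assert s_fwd.weights == pytest.approx(s_rev.weights[::-1], abs=1e-12)


def test_plateau_scheduler_rule_traces():
    s = PlateauScheduler(lr=1e-3, factor=0.5, patience=5)
    for mean in np.linspace(10.0, 5.0, 12):  # strictly improving
        assert s.step(mean) == 1e-3
    s2 = PlateauScheduler(lr=1e-3, factor=0.5, patience=5)
    s2.step(1.0)
    for _ in range(5):
        assert s2.step(1.0) == 1e-3  # within patience
    assert s2.step(1.0) == 0.5e-3  # 6th non-improving mean halves once
    s3 = PlateauScheduler(lr=1e-3, factor=0.5, patience=5)
    s3.step(1.0)
    for _ in range(12):
        s3.step(1.0)
    assert s3.lr == pytest.approx(0.25e-3)  # two plateaus -> lr0 / 4


def _tiny_cases(n, seed):
    cfg = PhantomConfig(grid_shape=(16, 16), voxel_spacing=(1.0, 1.0),
                        radius_range=(2.0, 3.5), lesion_count_range=(1, 1))
    return [simulate_case(cfg, seed=seed + i) for i in range(n)]


def test_train_history_and_determinism():
    cases = _tiny_cases(3, seed=30)
    histories = []
    for _ in range(2):
        gen = Generator(TINY_MODEL, seed=1)
        dv = Discriminator(TINY_MODEL, (16, 16), seed=2)
        di = Discriminator(TINY_MODEL, (16, 16), seed=3)
        cfg = TrainConfig(iterations=12, batch_size=2, seed=4)
        histories.append(train(cases, gen, dv, di, cfg))
    a, b = histories
    assert len(a) == 12
    assert np.allclose(a.total.values, b.total.values)
    assert set(a.columns) >= {"l1_vnc", "adv_vnc", "disc_vnc", "w_vnc", "lr"}


def test_fixed_weights_reproduce_plain_multitask_loss():
    cases = _tiny_cases(2, seed=50)
    runs = []
    for use_gn in (False, False):
        gen = Generator(TINY_MODEL, seed=1)
        cfg = TrainConfig(iterations=8, batch_size=2, adversarial=False,
                          use_gradnorm=use_gn, seed=9)
        runs.append(train(cases, gen, None, None, cfg))
    assert np.allclose(runs[0].total.values, runs[1].total.values)
    assert (runs[0].w_vnc == 1.0).all() and (runs[0].w_iom == 1.0).all()


def test_l1_only_objective_trends_down(memorization_run):
    _, res = memorization_run
    h = res.history
    means = h.total.values.reshape(-1, 50).mean(axis=1)
    assert means[-1] < means[0]
    assert h.l1_vnc.iloc[-1] < 0.1 * h.l1_vnc.iloc[0]
    assert len(h) == 400
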