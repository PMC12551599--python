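"""Conditional latent diffusion: noising, training, DDIM sampling, reuse.

The model operates in the codec's latent space.  The forward process is the
standard fixed Markov chain q(x_t | x_{t-1}) = N(sqrt(1-b_t) x_{t-1}, b_t I)
with closed-form marginal x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps.  A
U-Net predicts the added noise from (x_t, condition, t), trained with the
simplified ELBO objective ||eps - eps_theta(x_t, y, t)||^2; the condition
(the corrupted image's latent) is concatenated to the network input at every
step.  Deterministic DDIM sampling over a uniformly spaced step subset
generates the artifact-reduced latent, and the same trained model is reused
for secondary artifact correction by re-noising an already corrected image
partway and running the remaining trajectory with that image as its own
condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codec import VQCodec
from .geometry import Image2D
from .nn import Adam, UNet

__all__ = [
    "DiffusionSchedule",
    "ConditionPolicy",
    "condition_at",
    "forward_diffuse",
    "training_loss",
    "ddim_sample",
    "secondary_correct",
    "LatentDiffusion",
    "train_ldm",
]


@dataclass(frozen=True)
class DiffusionSchedule:
    """Variance schedule b_t, t = 1..T, with cumulative products abar.

    ``alpha_bars`` has length T+1 with abar_0 = 1 so that step 0 is the
    identity; abar is strictly decreasing.
    """

    betas: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.betas, dtype=np.float64)
        if b.ndim != 1 or b.size < 1:
            raise ValueError("betas must be a 1-D array")
        if np.any(b <= 0) or np.any(b >= 1):
            raise ValueError("betas must lie in (0, 1)")
        object.__setattr__(self, "betas", b)

    @classmethod
    def linear(cls, t_total: int = 200, beta_start: float = 1e-4, beta_end: float = 2e-2):
        return cls(np.linspace(beta_start, beta_end, t_total))

    @property
    def t_total(self) -> int:
        return int(self.betas.size)

    @property
    def alphas(self) -> np.ndarray:
        return 1.0 - self.betas

    @property
    def alpha_bars(self) -> np.ndarray:
        """abar_t for t = 0..T (abar_0 = 1)."""
        return np.concatenate([[1.0], np.cumprod(self.alphas)])


def forward_diffuse(
    x0: np.ndarray, t: int, sched: DiffusionSchedule, noise: np.ndarray
) -> np.ndarray:
    """Closed-form marginal sample x_t = sqrt(abar_t) x0 + sqrt(1-abar_t) eps."""
    if not 0 <= t <= sched.t_total:
        raise ValueError(f"t={t} outside [0, {sched.t_total}]")
    if noise.shape != x0.shape:
        raise ValueError("noise must match x0's shape")
    ab = sched.alpha_bars[t]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * noise


@dataclass
class ConditionPolicy:
    """How the condition latent is presented to the model during sampling.

    ``constant``: the corrupted latent at every step (the default studied
    configuration).  ``weighted``: the condition is faded out linearly with
    the generation step, Condition(t) = ((T - t) * Corrupted - t) / T, so
    generation starts fully guided and ends conditioned on a flat -1 grid.
    """

    corrupted_latent: np.ndarray
    mode: str = "constant"
    t_total: int = 1000

    def __post_init__(self):
        if self.mode not in ("constant", "weighted"):
            raise ValueError(f"unknown condition mode {self.mode!r}")


def condition_at(policy: ConditionPolicy, t: float) -> np.ndarray:
    """Condition grid at generation step t (t counts forward from 0)."""
    if t > policy.t_total or t < 0:
        raise ValueError(f"step {t} outside [0, {policy.t_total}]")
    if policy.mode == "constant":
        return policy.corrupted_latent
    if t == 0:
        return policy.corrupted_latent
    big_t = policy.t_total
    return ((big_t - t) * policy.corrupted_latent - t) / big_t


def training_loss(
    x0: np.ndarray,
    y: np.ndarray,
    t: int,
    sched: DiffusionSchedule,
    model,
    rng: np.random.Generator,
) -> float:
    """Single-sample simplified ELBO term ||eps - eps_theta(x_t, y, t)||^2 (mean)."""
    noise = rng.normal(size=x0.shape)
    xt = forward_diffuse(x0, t, sched, noise)
    inp = np.concatenate([xt, y], axis=0)[None]
    pred = model.forward(inp, np.array([float(t)]))[0]
    return float(np.mean((noise - pred) ** 2))


def _ddim_steps(t_total: int, n_steps: int) -> np.ndarray:
    """Uniformly spaced decreasing step subset T = t_1 > ... > t_n, ending at 0."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if n_steps > t_total:
        raise ValueError("n_steps cannot exceed the schedule length")
    return np.unique(np.round(np.linspace(0, t_total, n_steps + 1)).astype(int))[::-1]


def ddim_sample(
    model,
    policy: ConditionPolicy,
    sched: DiffusionSchedule,
    n_steps: int = 5,
    eta: float = 0.0,
    rng_seed: int | None = 0,
    x_start: np.ndarray | None = None,
    t_start: int | None = None,
    return_trajectory: bool = False,
):
    """Deterministic (eta = 0) DDIM sampling with per-step conditioning.

    Starts from N(0, I) noise at t = T (or from ``x_start`` at ``t_start``
    when resuming partway, as secondary correction does) and applies the
    standard DDIM update over a uniformly spaced subset of steps:

        x0_hat = (x_t - sqrt(1-abar_t) eps_hat) / sqrt(abar_t)
        x_prev = sqrt(abar_prev) x0_hat + sqrt(1-abar_prev - s^2) eps_hat + s z

    with s = eta * DDIM variance (zero by default).
    """
    rng = np.random.default_rng(rng_seed)
    abar = sched.alpha_bars
    t_hi = sched.t_total if t_start is None else int(t_start)
    steps = _ddim_steps(t_hi, min(n_steps, max(t_hi, 1)))
    shape = policy.corrupted_latent.shape
    if x_start is None:
        x = rng.normal(size=shape)
    else:
        x = np.asarray(x_start, dtype=np.float64).copy()
    traj = [x.copy()]
    for t_cur, t_prev in zip(steps[:-1], steps[1:]):
        # generation progress for the condition schedule runs opposite to t
        gen_step = policy.t_total * (1.0 - t_cur / sched.t_total)
        cond = condition_at(policy, gen_step)
        inp = np.concatenate([x, cond], axis=0)[None]
        eps = model.forward(inp, np.array([float(t_cur)]))[0]
        ab_t, ab_p = abar[t_cur], abar[t_prev]
        x0_hat = (x - np.sqrt(1.0 - ab_t) * eps) / np.sqrt(ab_t)
        sigma = 0.0
        if eta > 0:
            sigma = (
                eta
                * np.sqrt((1.0 - ab_p) / (1.0 - ab_t))
                * np.sqrt(1.0 - ab_t / ab_p)
            )
        dir_coeff = np.sqrt(max(1.0 - ab_p - sigma**2, 0.0))
        x = np.sqrt(ab_p) * x0_hat + dir_coeff * eps
        if eta > 0:
            x = x + sigma * rng.normal(size=shape)
        traj.append(x.copy())
    return (x, traj) if return_trajectory else x


@dataclass
class LatentDiffusion:
    """Trained noise estimator with its schedule and latent normalization."""

    model: UNet
    sched: DiffusionSchedule
    codec: VQCodec
    latent_mean: np.ndarray  # per-channel, shape (D, 1, 1)
    latent_std: np.ndarray
    trained: bool = False

    def normalize(self, z: np.ndarray) -> np.ndarray:
        return (z - self.latent_mean) / self.latent_std

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        return z * self.latent_std + self.latent_mean

    def encode_latent(self, image: Image2D) -> np.ndarray:
        return self.normalize(self.codec.encode(image).quantized)

    def generate_prior(
        self,
        corrupted: Image2D,
        n_steps: int = 5,
        rng_seed: int = 0,
        mode: str = "constant",
    ) -> Image2D:
        """Artifact-reduced prior image from a corrupted slice."""
        if not self.trained:
            raise RuntimeError("latent diffusion model is untrained")
        y = self.encode_latent(corrupted)
        policy = ConditionPolicy(y, mode=mode, t_total=self.sched.t_total)
        z = ddim_sample(self.model, policy, self.sched, n_steps=n_steps, rng_seed=rng_seed)
        return self.codec.decode(self.denormalize(z), corrupted.pixel_size)


def secondary_correct(
    initial: Image2D,
    ldm: LatentDiffusion,
    start_fraction: float = 0.2,
    n_steps: int = 2,
    rng_seed: int = 0,
) -> Image2D:
    """Refine an already corrected image by a partial diffusion round trip.

    The image is encoded, noised to the schedule level at ``start_fraction``
    of the trajectory, and the remaining DDIM steps are run with the image's
    own latent as condition; the result is decoded back.  ``start_fraction``
    -> 0 degenerates to the codec round trip.
    """
    if not 0.0 <= start_fraction <= 1.0:
        raise ValueError("start_fraction must lie in [0, 1]")
    if not ldm.trained:
        raise RuntimeError("latent diffusion model is untrained")
    z = ldm.encode_latent(initial)
    t_start = int(round(start_fraction * ldm.sched.t_total))
    if t_start == 0:
        return ldm.codec.decode(ldm.denormalize(z), initial.pixel_size)
    rng = np.random.default_rng(rng_seed)
    xt = forward_diffuse(z, t_start, ldm.sched, rng.normal(size=z.shape))
    policy = ConditionPolicy(z, mode="constant", t_total=ldm.sched.t_total)
    out = ddim_sample(
        ldm.model,
        policy,
        ldm.sched,
        n_steps=n_steps,
        rng_seed=rng_seed + 1,
        x_start=xt,
        t_start=t_start,
    )
    return ldm.codec.decode(ldm.denormalize(out), initial.pixel_size)


def train_ldm(
    codec: VQCodec,
    clean_images: list[np.ndarray],
    corrupted_images: list[np.ndarray],
    t_total: int = 200,
    n_steps: int = 1500,
    batch_size: int = 8,
    lr: float = 2e-3,
    channels: tuple[int, int, int] = (16, 32, 48),
    temb_dim: int = 32,
    seed: int = 0,
    callback=None,
) -> LatentDiffusion:
    """Desk-scale conditional LDM training on paired latents.

    Clean targets and corrupted conditions are encoded once through the
    (frozen) codec, normalized per channel to unit scale, and the U-Net is
    trained to predict the added noise at uniformly drawn timesteps.
    """
    if len(clean_images) != len(corrupted_images) or not clean_images:
        raise ValueError("need matching non-empty clean/corrupted lists")
    rng = np.random.default_rng(seed)
    z0 = np.stack([codec.encode(np.asarray(im)).quantized for im in clean_images])
    zy = np.stack([codec.encode(np.asarray(im)).quantized for im in corrupted_images])
    mean = z0.mean(axis=(0, 2, 3), keepdims=True)[0]
    std = z0.std(axis=(0, 2, 3), keepdims=True)[0] + 1e-6
    z0 = (z0 - mean) / std
    zy = (zy - mean) / std
    d = z0.shape[1]
    sched = DiffusionSchedule.linear(t_total)
    model = UNet(2 * d, d, channels, temb_dim=temb_dim, rng=np.random.default_rng(seed + 1))
    opt = Adam(model.params(), lr=lr)
    abar = sched.alpha_bars
    for step in range(n_steps):
        idx = rng.integers(0, z0.shape[0], size=batch_size)
        t = rng.integers(1, t_total + 1, size=batch_size)
        eps = rng.normal(size=(batch_size,) + z0.shape[1:])
        ab = abar[t][:, None, None, None]
        xt = np.sqrt(ab) * z0[idx] + np.sqrt(1.0 - ab) * eps
        inp = np.concatenate([xt, zy[idx]], axis=1)
        pred = model.forward(inp, t.astype(np.float64))
        model.zero_grad()
        model.backward(2.0 * (pred - eps) / pred.size)
        opt.step()
        if callback is not None and step % 100 == 0:
            callback(step, float(np.mean((pred - eps) ** 2)))
    return LatentDiffusion(
        model=model, sched=sched, codec=codec, latent_mean=mean, latent_std=std, trained=True
    )
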