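"""Cycle-consistent adversarial image translation between staining domains.

Two generator/discriminator pairs are trained so that source-style tiles are
mapped into target-style tiles (and back): G_st translates source→target,
G_ts target→source, and 70×70-PatchGAN discriminators D_t / D_s judge realism
patchwise. A least-squares adversarial loss is combined with an L1 cycle-
consistency loss weighted by λ_cyc, so image content — and therefore the
point annotations — survives the style transfer.

Networks run on the numpy engine in :mod:`nucadapt.nn`. Images are [0, 1]
RGB externally and mapped to [−1, 1] at the network boundary (tanh head).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import nn
from .types import AnnotatedImage


@dataclass(frozen=True)
class GeneratorSpec:
    """Residual translation generator: c7s1 stem, 2 stride-2 downsamplings,
    ``n_blocks`` residual blocks, mirrored upsamplings, tanh head."""

    n_blocks: int = 9
    base_width: int = 64
    downsamples: int = 2

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("generator needs at least one residual block")
        if self.base_width < 1 or self.downsamples < 0:
            raise ValueError("invalid generator spec")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """PatchGAN discriminator as a stack of valid (unpadded) convolutions.

    The default kernels/strides give each output unit a 70×70 receptive
    field; widths double per strided layer from ``base_width``.
    """

    kernels: tuple[int, ...] = (4, 4, 4, 4, 4)
    strides: tuple[int, ...] = (2, 2, 2, 1, 1)
    base_width: int = 64
    use_norm: bool = True

    def __post_init__(self) -> None:
        if len(self.kernels) != len(self.strides) or not self.kernels:
            raise ValueError("kernels and strides must be equal-length, non-empty")
        if any(k < 1 for k in self.kernels) or any(s < 1 for s in self.strides):
            raise ValueError("kernels and strides must be >= 1")

    @property
    def receptive_field(self) -> int:
        rf = 1
        for k, s in zip(reversed(self.kernels), reversed(self.strides)):
            rf = s * (rf - 1) + k
        return rf


@dataclass
class GanTrainConfig:
    """Training hyperparameters for the cycle-consistent GAN pair."""

    iterations: int = 500
    lambda_cyc: float = 10.0
    lambda_identity: float = 0.5  # × lambda_cyc, on G applied to its own output domain
    identity_until: float = 0.5  # fraction of iterations the identity term is active
    lr: float = 2e-4
    batch_size: int = 1
    seed: int = 0
    loss_form: str = "lsgan"

    def __post_init__(self) -> None:
        if self.lambda_cyc <= 0:
            raise ValueError("lambda_cyc must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is implemented")
        if self.loss_form != "lsgan":
            raise ValueError("only the least-squares loss form is implemented")


class ResnetGenerator(nn.Module):
    """Fully convolutional residual generator; spatial dims are preserved."""

    def __init__(self, spec: GeneratorSpec, seed: int) -> None:
        rng = np.random.default_rng(seed)
        w = spec.base_width
        mods: list[nn.Module] = [
            nn.Conv2d(3, w, 7, rng, pad=3, pad_mode="reflect"),
            nn.InstanceNorm2d(w),
            nn.ReLU(),
        ]
        cur = w
        for _ in range(spec.downsamples):
            mods += [
                nn.Conv2d(cur, cur * 2, 3, rng, stride=2, pad=1),
                nn.InstanceNorm2d(cur * 2),
                nn.ReLU(),
            ]
            cur *= 2
        for _ in range(spec.n_blocks):
            mods.append(nn.ResBlock(cur, rng, pad_mode="reflect"))
        for _ in range(spec.downsamples):
            mods += [
                UpConv(cur, cur // 2, rng),
                nn.InstanceNorm2d(cur // 2),
                nn.ReLU(),
            ]
            cur //= 2
        mods += [nn.Conv2d(cur, 3, 7, rng, pad=3, pad_mode="reflect"), nn.Tanh()]
        self.net = nn.Sequential(*mods)
        self.spec = spec
        self.seed = seed

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h, w = x.shape[2], x.shape[3]
        f = 2**self.spec.downsamples
        if h % f or w % f:
            raise ValueError(f"spatial dims must be divisible by {f} for training passes")
        return self.net(x)

    def translate_array(self, image: np.ndarray) -> np.ndarray:
        """Translate one H×W×3 [0,1] image; pads/crops to any size."""
        image = np.asarray(image, dtype=np.float32)
        h, w = image.shape[:2]
        f = 2**self.spec.downsamples
        ph, pw = (-h) % f, (-w) % f
        arr = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        x = nn.Tensor(arr.transpose(2, 0, 1)[None] * 2.0 - 1.0)
        y = self.net(x).data[0].transpose(1, 2, 0)
        return np.clip((y[:h, :w] + 1.0) / 2.0, 0.0, 1.0)

    def __call__(self, x):  # numpy image or Tensor
        if isinstance(x, nn.Tensor):
            return self.forward(x)
        return self.translate_array(x)


class UpConv(nn.Module):
    """Nearest-neighbor ×2 upsampling followed by a 3×3 convolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        self.conv = nn.Conv2d(cin, cout, 3, rng, pad=1)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.conv(nn.upsample_nearest(x, 2))


class PatchDiscriminator(nn.Module):
    """Outputs a spatial map of realism scores, one per receptive patch."""

    def __init__(self, spec: DiscriminatorSpec, seed: int) -> None:
        rng = np.random.default_rng(seed)
        mods: list[nn.Module] = []
        cin = 3
        n = len(spec.kernels)
        for i, (k, s) in enumerate(zip(spec.kernels, spec.strides)):
            last = i == n - 1
            cout = 1 if last else spec.base_width * 2 ** min(i, 3)
            mods.append(nn.Conv2d(cin, cout, k, rng, stride=s))
            if not last:
                if spec.use_norm and i > 0:
                    mods.append(nn.InstanceNorm2d(cout))
                mods.append(nn.LeakyReLU(0.2))
            cin = cout
        self.net = nn.Sequential(*mods)
        self.spec = spec

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.net(x)

    def score_array(self, image: np.ndarray) -> np.ndarray:
        x = nn.Tensor(np.asarray(image, np.float32).transpose(2, 0, 1)[None] * 2.0 - 1.0)
        return self.net(x).data[0, 0]

    def __call__(self, x):
        if isinstance(x, nn.Tensor):
            return self.forward(x)
        return self.score_array(x)


def build_generator(spec: GeneratorSpec, seed: int) -> ResnetGenerator:
    return ResnetGenerator(spec, seed)


def build_discriminator(spec: DiscriminatorSpec, seed: int) -> PatchDiscriminator:
    return PatchDiscriminator(spec, seed)


def desk_discriminator_spec(base_width: int = 8) -> DiscriminatorSpec:
    """A 22×22-patch discriminator for small tiles.

    The full-size configuration judges 70×70 patches, which exceeds a 64×64
    training tile (a valid-convolution stack would emit an empty score map);
    three strided layers give a receptive field that fits desk-scale images.
    """
    return DiscriminatorSpec(kernels=(4, 4, 4), strides=(2, 2, 1), base_width=base_width)


# ---------------------------------------------------------------------------
# losses (numpy level, shared with training)
# ---------------------------------------------------------------------------


def cycle_loss(x: np.ndarray, x_reconstructed: np.ndarray) -> float:
    """Mean absolute reconstruction error; zero iff the images are identical."""
    x = np.asarray(x, dtype=np.float64)
    xr = np.asarray(x_reconstructed, dtype=np.float64)
    if x.shape != xr.shape:
        raise ValueError("cycle_loss requires identical shapes")
    return float(np.mean(np.abs(x - xr)))


def adversarial_losses(
    d_out_real: np.ndarray, d_out_fake: np.ndarray
) -> tuple[float, float]:
    """Least-squares GAN losses.

    The discriminator is perfect (loss 0) when real scores are 1 and fake
    scores are 0; the generator is perfect when fake scores reach 1.
    """
    real = np.asarray(d_out_real, dtype=np.float64)
    fake = np.asarray(d_out_fake, dtype=np.float64)
    if not (np.all(np.isfinite(real)) and np.all(np.isfinite(fake))):
        raise ValueError("score maps must be finite")
    loss_d = 0.5 * (np.mean((real - 1.0) ** 2) + np.mean(fake**2))
    loss_g = float(np.mean((fake - 1.0) ** 2))
    return float(loss_d), loss_g


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class CycleGanResult(NamedTuple):
    G_st: ResnetGenerator
    G_ts: ResnetGenerator
    trace: list[dict]


def _to_tensor(image: AnnotatedImage) -> nn.Tensor:
    return nn.Tensor(image.pixels.transpose(2, 0, 1)[None] * 2.0 - 1.0)


def train_cyclegan(
    source: list[AnnotatedImage],
    target: list[AnnotatedImage],
    config: GanTrainConfig,
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
) -> CycleGanResult:
    """Train the two generator/discriminator pairs on unpaired image sets.

    Annotations are ignored — translation is unsupervised. Each iteration
    draws one source and one target tile in a fixed seeded order, updates
    both generators jointly (adversarial + λ_cyc · cycle terms), then updates
    both discriminators on real vs detached fake tiles. Deterministic for a
    given config seed.
    """
    if not source or not target:
        raise ValueError("source and target sets must be non-empty")
    gen_spec = gen_spec or GeneratorSpec()
    disc_spec = disc_spec or DiscriminatorSpec()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(5)]
    g_st = ResnetGenerator(gen_spec, seeds[0])
    g_ts = ResnetGenerator(gen_spec, seeds[1])
    d_t = PatchDiscriminator(disc_spec, seeds[2])
    d_s = PatchDiscriminator(disc_spec, seeds[3])
    order_rng = np.random.default_rng(seeds[4])

    opt_g = nn.Adam(g_st.parameters() + g_ts.parameters(), lr=config.lr)
    opt_d = nn.Adam(d_t.parameters() + d_s.parameters(), lr=config.lr)

    src_order = order_rng.permutation(len(source))
    tgt_order = order_rng.permutation(len(target))

    trace: list[dict] = []
    for it in range(config.iterations):
        xs = _to_tensor(source[src_order[it % len(source)]])
        xt = _to_tensor(target[tgt_order[it % len(target)]])

        # generator update
        fake_t = g_st(xs)
        fake_s = g_ts(xt)
        rec_s = g_ts(fake_t)
        rec_t = g_st(fake_s)
        adv_st = nn.mse_loss(d_t(fake_t), 1.0)
        adv_ts = nn.mse_loss(d_s(fake_s), 1.0)
        cyc = nn.l1_loss(rec_s, xs.data) + nn.l1_loss(rec_t, xt.data)
        loss_g = adv_st + adv_ts + config.lambda_cyc * cyc
        if config.lambda_identity > 0 and it < config.identity_until * config.iterations:
            # anchors the color mapping early on (a generator shown an image
            # already in its output domain should leave it unchanged); dropped
            # later so large palette shifts are not held back
            ident = nn.l1_loss(g_st(xt), xt.data) + nn.l1_loss(g_ts(xs), xs.data)
            loss_g = loss_g + (config.lambda_identity * config.lambda_cyc) * ident
        opt_g.zero_grad()
        opt_d.zero_grad()
        loss_g.backward()
        opt_g.step()

        # discriminator update on detached fakes
        fake_t_det = nn.Tensor(fake_t.data)
        fake_s_det = nn.Tensor(fake_s.data)
        loss_dt = 0.5 * (nn.mse_loss(d_t(xt), 1.0) + nn.mse_loss(d_t(fake_t_det), 0.0))
        loss_ds = 0.5 * (nn.mse_loss(d_s(xs), 1.0) + nn.mse_loss(d_s(fake_s_det), 0.0))
        loss_d = loss_dt + loss_ds
        opt_d.zero_grad()
        loss_d.backward()
        opt_d.step()

        trace.append(
            {
                "iteration": it,
                "loss_G_adv": adv_st.item() + adv_ts.item(),
                "loss_cycle": cyc.item(),
                "loss_G": loss_g.item(),
                "loss_D": loss_d.item(),
            }
        )
    return CycleGanResult(g_st, g_ts, trace)


def translate(g_st, images: list[AnnotatedImage]) -> list[AnnotatedImage]:
    """Apply a trained generator; annotations and case ids pass through unchanged."""
    out = []
    for im in images:
        if callable(getattr(g_st, "translate_array", None)):
            pixels = g_st.translate_array(im.pixels)
        else:
            pixels = np.clip(np.asarray(g_st(im.pixels), dtype=np.float32), 0.0, 1.0)
        out.append(
            AnnotatedImage(
                pixels=np.clip(pixels, 0.0, 1.0),
                annotations=list(im.annotations),
                case_id=im.case_id,
            )
        )
    return out


# ---------------------------------------------------------------------------
# receptive-field measurement
# ---------------------------------------------------------------------------


def measure_receptive_field(spec: DiscriminatorSpec, seed: int = 0) -> tuple[int, int]:
    """Measure the discriminator's receptive field by single-pixel probing.

    Builds the convolutional stack with normalization disabled (instance
    norm couples every pixel globally and is conventionally excluded from
    receptive-field analysis), replaces weights by their absolute values and
    zeroes the biases so that a perturbation propagates iff a structural
    path exists, then perturbs pixels one at a time along a row and a column
    through output unit (0, 0) and records the extent of pixels that change
    its score.
    """
    probe_spec = DiscriminatorSpec(
        kernels=spec.kernels,
        strides=spec.strides,
        base_width=spec.base_width,
        use_norm=False,
    )
    disc = PatchDiscriminator(probe_spec, seed)
    for p in disc.parameters():
        p.data = np.abs(p.data)
        if p.data.ndim == 1:  # bias
            p.data[:] = 0.0
    rf = probe_spec.receptive_field
    size = rf + 4  # unit (0,0) sees input [0, rf); leave slack beyond it
    base = np.zeros((1, 3, size, size), dtype=np.float32)
    out0 = disc.forward(nn.Tensor(base)).data[0, 0, 0, 0]
    mid = rf // 2

    def probed(r: int, c: int) -> bool:
        x = base.copy()
        x[0, :, r, c] = 1.0
        return disc.forward(nn.Tensor(x)).data[0, 0, 0, 0] != out0

    rows = [r for r in range(size) if probed(r, mid)]
    cols = [c for c in range(size) if probed(mid, c)]
    return (rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
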