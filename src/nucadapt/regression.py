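"""Proximity-map regression for joint nucleus detection and classification.

Supervision is a 3-channel proximity map: around each annotated center a
Gaussian bump (peak 1.0, scale σ, truncated at 3σ) is stamped into the
channel of its class (IPT, INT, NT), overlapping bumps combining by
pixelwise maximum so every nucleus keeps a strict local maximum. The
regressor R is a U-Net-like residual encoder-decoder — 4 stacked residual
blocks on each side by default, long-range skip connections, multi-level
feature fusion, and a 2-convolution output head with a rectifying activation
so the η·max(ŷ) suppression rule downstream is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .types import CLASS_INDEX, AnnotatedImage, PointAnnotation, validate_output_map


@dataclass(frozen=True)
class TargetMapConfig:
    """Shape of the proximity bump stamped around each annotation."""

    sigma: float = 4.0
    truncate: float = 3.0  # bump radius in units of sigma
    peak: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.peak <= 0 or self.truncate <= 0:
            raise ValueError("sigma, peak and truncate must be positive")

    @property
    def radius(self) -> float:
        return self.truncate * self.sigma


@dataclass(frozen=True)
class RegressorSpec:
    """Architecture of the regressor R."""

    encoder_blocks: int = 4
    decoder_blocks: int = 4
    base_width: int = 16
    skip_connections: bool = True
    fusion: bool = True
    instance_norm: bool = True

    def __post_init__(self) -> None:
        if self.encoder_blocks < 1 or self.decoder_blocks < 1:
            raise ValueError("encoder/decoder need at least one block")
        if self.encoder_blocks != self.decoder_blocks:
            raise ValueError("encoder and decoder depths must match")

    @property
    def downsampling(self) -> int:
        return 2**self.encoder_blocks


@dataclass
class RegressorTrainConfig:
    """Optimization settings for :func:`train_regressor`."""

    epochs: int = 30
    lr: float = 1e-3
    seed: int = 0
    shuffle: bool = True
    lr_decay: float = 0.3  # multiplier applied after 60% of the epochs
    lr_decay_at: float = 0.6
    augment: bool = False  # add flipped/rotated copies of each training image
    step_budget: int | None = None  # cap total update steps (≤ epochs × set size)
    clip_norm: float | None = 1.0  # global gradient-norm clip


# ---------------------------------------------------------------------------
# target construction
# ---------------------------------------------------------------------------


def build_target_map(
    annotations: list[PointAnnotation],
    dims: tuple[int, int],
    config: TargetMapConfig = TargetMapConfig(),
) -> np.ndarray:
    """Stamp per-class Gaussian proximity bumps; combine by pixelwise max."""
    h, w = dims
    out = np.zeros((h, w, 3), dtype=np.float32)
    rad = int(np.ceil(config.radius))
    offs = np.arange(-rad, rad + 1, dtype=np.float64)
    d2 = offs[:, None] ** 2 + offs[None, :] ** 2
    bump = config.peak * np.exp(-d2 / (2.0 * config.sigma**2))
    bump[d2 > config.radius**2] = 0.0
    bump = bump.astype(np.float32)
    for a in annotations:
        if not (0 <= a.row < h and 0 <= a.col < w):
            raise ValueError(f"annotation {a} outside {h}×{w} map")
        r0, r1 = max(0, a.row - rad), min(h, a.row + rad + 1)
        c0, c1 = max(0, a.col - rad), min(w, a.col + rad + 1)
        br0, bc0 = r0 - (a.row - rad), c0 - (a.col - rad)
        ch = CLASS_INDEX[a.label]
        patch = bump[br0 : br0 + (r1 - r0), bc0 : bc0 + (c1 - c0)]
        np.maximum(out[r0:r1, c0:c1, ch], patch, out=out[r0:r1, c0:c1, ch])
    return out


def regression_loss(prediction: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error over all pixels and channels."""
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("prediction and target shapes must match")
    return float(np.mean((p - t) ** 2))


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------


def _widths(base: int, n: int) -> list[int]:
    # double per stage, capped at 4× to keep desk-scale CPU training viable
    return [base * min(2**i, 4) for i in range(1, n + 1)]


class Regressor(nn.Module):
    """Residual encoder-decoder with skips and multi-level fusion."""

    def __init__(self, spec: RegressorSpec, seed: int) -> None:
        rng = np.random.default_rng(seed)
        w = spec.base_width
        self.spec = spec
        norm = spec.instance_norm
        self.stem = nn.Sequential(
            nn.Conv2d(3, w, 3, rng, pad=1, init="he"),
            nn.InstanceNorm2d(w) if norm else nn.Identity(),
            nn.ReLU(),
        )
        widths = _widths(w, spec.encoder_blocks)
        self.enc_down: list[nn.Module] = []
        self.enc_res: list[nn.Module] = []
        cin = w
        for wi in widths:
            self.enc_down.append(
                nn.Sequential(
                    nn.Conv2d(cin, wi, 3, rng, stride=2, pad=1, init="he"),
                    nn.InstanceNorm2d(wi) if norm else nn.Identity(),
                    nn.ReLU(),
                )
            )
            self.enc_res.append(nn.ResBlock(wi, rng, pad_mode="zero", init="he", norm=norm))
            cin = wi
        self.dec_up: list[nn.Module] = []
        self.dec_fuse: list[nn.Module] = []
        self.dec_res: list[nn.Module] = []
        dec_widths = list(reversed([w] + widths[:-1]))
        skip_widths = list(reversed([w] + widths[:-1]))
        for wi, ws in zip(dec_widths, skip_widths):
            self.dec_up.append(
                nn.Sequential(
                    UpConv(cin, wi, rng, norm=norm),
                )
            )
            fuse_in = wi + (ws if spec.skip_connections else 0)
            self.dec_fuse.append(
                nn.Sequential(
                    nn.Conv2d(fuse_in, wi, 3, rng, pad=1, init="he"),
                    nn.InstanceNorm2d(wi) if norm else nn.Identity(),
                    nn.ReLU(),
                )
            )
            self.dec_res.append(nn.ResBlock(wi, rng, pad_mode="zero", init="he", norm=norm))
            cin = wi
        if spec.fusion:
            self.fuse_proj: list[nn.Module] = [
                nn.Conv2d(wi, w, 1, rng, init="he") for wi in dec_widths[:-1]
            ]
            head_in = w + len(self.fuse_proj) * w
        else:
            self.fuse_proj = []
            head_in = w
        self.head1 = nn.Sequential(
            nn.Conv2d(head_in, w, 3, rng, pad=1, init="he"), nn.ReLU()
        )
        self.head2 = nn.Conv2d(w, 3, 1, rng, init="he")

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h, w = x.shape[2], x.shape[3]
        f = self.spec.downsampling
        pad_h, pad_w = (-h) % f, (-w) % f
        if pad_h or pad_w:
            raise ValueError(
                f"input dims must be a multiple of {f} inside forward(); "
                "use predict() for arbitrary sizes"
            )
        feats = [self.stem(x)]
        y = feats[0]
        for down, res in zip(self.enc_down, self.enc_res):
            y = res(down(y))
            feats.append(y)
        skips = feats[:-1][::-1]  # resolutions matching each decoder stage output
        level_feats = []
        for up, fuse, res, skip in zip(self.dec_up, self.dec_fuse, self.dec_res, skips):
            y = up(y)
            if self.spec.skip_connections:
                y = nn.concat([y, skip], axis=1)
            y = res(fuse(y))
            level_feats.append(y)
        top = level_feats[-1]
        if self.spec.fusion:
            fused = [top]
            for proj, feat in zip(self.fuse_proj, level_feats[:-1]):
                p = proj(feat)
                # smooth progressive upsampling avoids blocky side maxima
                while p.shape[2] < top.shape[2]:
                    p = nn.smooth3(nn.upsample_nearest(p, 2))
                fused.append(p)
            top = nn.concat(fused, axis=1)
        # softplus keeps outputs nonnegative without dead-gradient collapse
        return nn.softplus(self.head2(self.head1(top)))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Predict the H×W×3 proximity map for one [0,1] RGB image."""
        image = np.asarray(image, dtype=np.float32)
        h, w = image.shape[:2]
        f = self.spec.downsampling
        ph, pw = (-h) % f, (-w) % f
        arr = np.pad(image, ((0, ph), (0, pw), (0, 0)), mode="reflect")
        x = nn.Tensor(arr.transpose(2, 0, 1)[None] * 2.0 - 1.0)
        y = self.forward(x).data[0].transpose(1, 2, 0)
        return validate_output_map(y[:h, :w])


class UpConv(nn.Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, norm: bool = True) -> None:
        self.conv = nn.Conv2d(cin, cout, 3, rng, pad=1, init="he")
        self.norm = nn.InstanceNorm2d(cout) if norm else nn.Identity()

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return nn.relu(self.norm(self.conv(nn.upsample_nearest(x, 2))))


def build_regressor(spec: RegressorSpec, seed: int) -> Regressor:
    return Regressor(spec, seed)


def count_parameters(model: nn.Module) -> int:
    return sum(p.data.size for p in model.parameters())


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_regressor(
    train_images: list[AnnotatedImage],
    val_images: list[AnnotatedImage],
    target_config: TargetMapConfig,
    spec: RegressorSpec,
    train_config: RegressorTrainConfig,
) -> Regressor:
    """Fit R by per-image Adam steps on the MSE proximity-map loss.

    Returns the model restored to the weights with the best validation loss
    (training loss if no validation images are given). Per-epoch losses are
    kept on ``model.history``. Deterministic for a given seed: the seed
    drives both initialization and the per-epoch image order. An image
    without annotations contributes an all-zero target.

    With ``augment`` each training image also contributes its left-right,
    up-down and 180°-rotated copies (targets transformed identically). A
    ``step_budget`` bounds the number of update steps so differently sized
    training pools receive comparable optimization; the epoch count is
    reduced accordingly (never below 1, never above ``epochs``).
    """
    if not train_images:
        raise ValueError("training set must be non-empty")
    ss = np.random.SeedSequence(train_config.seed)
    init_seed, order_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    model = Regressor(spec, init_seed)
    opt = nn.Adam(
        model.parameters(),
        lr=train_config.lr,
        betas=(0.9, 0.999),
        clip_norm=train_config.clip_norm,
    )
    order_rng = np.random.default_rng(order_seed)

    def target_for(im: AnnotatedImage) -> np.ndarray:
        return build_target_map(im.annotations, im.shape, target_config)

    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for im in train_images:
        t = target_for(im)
        pairs.append((im.pixels, t))
        if train_config.augment:
            pairs.append((im.pixels[:, ::-1], t[:, ::-1]))
            pairs.append((im.pixels[::-1, :], t[::-1, :]))
            pairs.append((im.pixels[::-1, ::-1], t[::-1, ::-1]))

    n_epochs = train_config.epochs
    if train_config.step_budget is not None:
        n_epochs = min(
            n_epochs, max(1, round(train_config.step_budget / len(pairs)))
        )
    history: dict[str, list[float]] = {"train": [], "val": []}
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    for epoch in range(n_epochs):
        if epoch == int(train_config.lr_decay_at * n_epochs):
            opt.lr *= train_config.lr_decay
        idx = np.arange(len(pairs))
        if train_config.shuffle:
            idx = order_rng.permutation(idx)
        epoch_loss = 0.0
        for i in idx:
            pixels, tmap = pairs[i]
            x = nn.Tensor(np.ascontiguousarray(pixels.transpose(2, 0, 1))[None] * 2.0 - 1.0)
            t = np.ascontiguousarray(tmap.transpose(2, 0, 1))[None]
            loss = nn.mse_loss(model.forward(x), t)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
        history["train"].append(epoch_loss / len(pairs))
        if val_images:
            val_loss = float(
                np.mean(
                    [
                        regression_loss(model.predict(im.pixels), target_for(im))
                        for im in val_images
                    ]
                )
            )
        else:
            val_loss = history["train"][-1]
        history["val"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
    if best_state is not None:
        model.load_state_dict(best_state)
    model.history = history
    return model
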