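"""Experimental orchestration: case-level splits, training regimes, sweeps.

Four regimes mirror the experimental design: ``baseline_source_only``
(regressor trained on source images alone), ``adapted`` (cycle-consistent
translation first, regressor trained on converted + original source images),
``mixed`` (adapted plus k real annotated target training images) and
``target_supervised`` (the ceiling: regressor trained on real target
annotations). Every regime evaluates on the target test fold; an audit log
records which case annotations each stage consumed so label hygiene — target
test labels touched only at evaluation — is assertable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .evaluation import EvalConfig, MetricsReport, evaluate_maps
from .postprocess import PostprocessConfig
from .regression import (
    RegressorSpec,
    RegressorTrainConfig,
    TargetMapConfig,
    train_regressor,
)
from .translation import (
    DiscriminatorSpec,
    GanTrainConfig,
    GeneratorSpec,
    train_cyclegan,
    translate,
)
from .types import AnnotatedImage

REGIMES = ("baseline_source_only", "adapted", "mixed", "target_supervised")


@dataclass(frozen=True)
class SplitSpec:
    """Case-level twofold split: 50/50 train/test, 20% of train as validation."""

    train_fraction: float = 0.5
    val_fraction: float = 0.2
    n_folds: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must lie in (0, 1)")
        if not 0 < self.val_fraction < 1:
            raise ValueError("validation fraction must lie in (0, 1)")
        if self.n_folds != 2:
            raise ValueError("the protocol is twofold cross-validation")


@dataclass(frozen=True)
class RegimeSpec:
    """One training condition of the adaptation experiment."""

    regime: str = "adapted"
    source_fraction: float = 1.0
    k_target: int = 0
    include_original_source: bool = True

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if not 0 < self.source_fraction <= 1:
            raise ValueError("source fraction must lie in (0, 1]")
        if self.k_target < 0:
            raise ValueError("k_target must be >= 0")
        if self.regime in ("baseline_source_only", "adapted") and self.k_target:
            raise ValueError(f"{self.regime} uses no real target labels (k_target=0)")


class Fold(NamedTuple):
    train: list[str]
    validation: list[str]
    test: list[str]


def split_cases(case_ids: list[str], spec: SplitSpec) -> list[Fold]:
    """Deterministic twofold case-level split; folds swap train/test roles."""
    unique = list(dict.fromkeys(case_ids))
    if len(unique) < 5:
        raise ValueError("need at least 5 cases for a case-level split")
    rng = np.random.default_rng(spec.seed)
    order = [unique[i] for i in rng.permutation(len(unique))]
    n_train = int(round(spec.train_fraction * len(order)))
    halves = [order[:n_train], order[n_train:]]
    folds = []
    for train_pool, test in (tuple(halves), tuple(halves[::-1])):
        n_val = max(1, int(round(spec.val_fraction * len(train_pool))))
        folds.append(
            Fold(
                train=list(train_pool[:-n_val]),
                validation=list(train_pool[-n_val:]),
                test=list(test),
            )
        )
    return folds


class AuditLog:
    """Chronological record of which cases (and whose labels) each stage used."""

    def __init__(self) -> None:
        self.entries: list[dict] = []

    def record(self, event: str, cases: list[str], labels_used: bool) -> None:
        self.entries.append(
            {"event": event, "cases": sorted(set(cases)), "labels_used": labels_used}
        )

    def labeled_cases_before_evaluation(self) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            if e["event"] == "evaluation":
                break
            if e["labels_used"]:
                out.update(e["cases"])
        return out


def assert_label_hygiene(audit: AuditLog, test_cases: list[str]) -> None:
    leaked = audit.labeled_cases_before_evaluation() & set(test_cases)
    if leaked:
        raise AssertionError(f"target test labels consumed during training: {sorted(leaked)}")


class RegimeResult(NamedTuple):
    report: MetricsReport
    audit: AuditLog
    regressor: object
    translator: object | None


def _strip_labels(images: list[AnnotatedImage]) -> list[AnnotatedImage]:
    return [AnnotatedImage(im.pixels, [], im.case_id) for im in images]


def _carve_validation(
    images: list[AnnotatedImage], seed: int
) -> tuple[list[AnnotatedImage], list[AnnotatedImage]]:
    if len(images) < 2:
        return images, []
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(images))
    n_val = max(1, int(round(0.2 * len(images))))
    val = [images[i] for i in idx[:n_val]]
    train = [images[i] for i in idx[n_val:]]
    return train, val


def run_regime(
    source: list[AnnotatedImage],
    target: list[AnnotatedImage],
    regime: RegimeSpec,
    seed: int = 0,
    fold: int = 0,
    split_spec: SplitSpec | None = None,
    gen_spec: GeneratorSpec | None = None,
    disc_spec: DiscriminatorSpec | None = None,
    gan_config: GanTrainConfig | None = None,
    reg_spec: RegressorSpec | None = None,
    target_config: TargetMapConfig | None = None,
    reg_train_config: RegressorTrainConfig | None = None,
    eval_config: EvalConfig | None = None,
    postprocess_config: PostprocessConfig | None = None,
    translator=None,
    sweep: bool = False,
) -> RegimeResult:
    """Train one regime and evaluate it on the target test fold.

    Target test annotations are consumed only by the final evaluation; the
    returned audit log proves it. ``translator`` injects a pre-trained (or
    identity) source→target generator, skipping GAN training.
    """
    split_spec = split_spec or SplitSpec(seed=seed)
    target_config = target_config or TargetMapConfig()
    reg_spec = reg_spec or RegressorSpec()
    eval_config = eval_config or EvalConfig()
    postprocess_config = postprocess_config or PostprocessConfig()
    audit = AuditLog()

    ss = np.random.SeedSequence(seed)
    gan_seed, reg_seed, sub_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )

    folds = split_cases([im.case_id for im in target], split_spec)
    f = folds[fold]
    t_train = [im for im in target if im.case_id in set(f.train)]
    t_val = [im for im in target if im.case_id in set(f.validation)]
    t_test = [im for im in target if im.case_id in set(f.test)]

    rng = np.random.default_rng(sub_seed)
    src = list(source)
    if regime.source_fraction < 1.0:
        n = max(1, int(round(regime.source_fraction * len(src))))
        src = [src[i] for i in sorted(rng.permutation(len(src))[:n])]

    trained_translator = translator
    if regime.regime == "baseline_source_only":
        train_imgs, val_imgs = _carve_validation(src, sub_seed)
        audit.record("regressor_training", [im.case_id for im in train_imgs + val_imgs], True)
    elif regime.regime in ("adapted", "mixed"):
        if trained_translator is None:
            gan_config = gan_config or GanTrainConfig(seed=gan_seed)
            audit.record("gan_training_source", [im.case_id for im in src], False)
            audit.record("gan_training_target", [im.case_id for im in t_train], False)
            result = train_cyclegan(
                src, _strip_labels(t_train), replace(gan_config, seed=gan_seed),
                gen_spec=gen_spec, disc_spec=disc_spec,
            )
            trained_translator = result.G_st
        converted = translate(trained_translator, src)
        pool = converted + (src if regime.include_original_source else [])
        audit.record("regressor_training", [im.case_id for im in pool], True)
        if regime.regime == "mixed" and regime.k_target > 0:
            if regime.k_target > len(t_train):
                raise ValueError("k_target exceeds available target training images")
            extra = t_train[: regime.k_target]
            pool = pool + extra
            audit.record("regressor_training_target", [im.case_id for im in extra], True)
        train_imgs, val_imgs = _carve_validation(pool, sub_seed)
    elif regime.regime == "target_supervised":
        train_imgs, val_imgs = t_train, t_val
        audit.record(
            "regressor_training", [im.case_id for im in train_imgs + val_imgs], True
        )
    else:  # pragma: no cover - guarded by RegimeSpec
        raise ValueError(regime.regime)

    reg_train_config = reg_train_config or RegressorTrainConfig()
    model = train_regressor(
        train_imgs, val_imgs, target_config, reg_spec,
        replace(reg_train_config, seed=reg_seed),
    )

    audit.record("evaluation", [im.case_id for im in t_test], True)
    maps = [model.predict(im.pixels) for im in t_test]
    report = evaluate_maps(
        maps,
        [im.annotations for im in t_test],
        eval_config,
        postprocess_config,
        sweep=sweep,
    )
    assert_label_hygiene(audit, [im.case_id for im in t_test])
    return RegimeResult(report, audit, model, trained_translator)


def desk_scale_settings(gan_iterations: int = 400, step_budget: int = 640) -> dict:
    """Network and training sizes for CPU-scale experiments on 64×64 tiles.

    Generator: 2 residual blocks, width 12; discriminator: 22×22 patches,
    width 16 (a 70×70 patch exceeds a 64×64 tile); regressor width 12 with
    flip/rotation augmentation under a fixed step budget so every regime
    receives the same optimization effort; gold-standard radius 8 px, matched
    to the tile scale.
    """
    return dict(
        gen_spec=GeneratorSpec(n_blocks=2, base_width=12),
        disc_spec=DiscriminatorSpec(kernels=(4, 4, 4), strides=(2, 2, 1), base_width=16),
        gan_config=GanTrainConfig(iterations=gan_iterations),
        reg_spec=RegressorSpec(base_width=12),
        reg_train_config=RegressorTrainConfig(
            epochs=30, augment=True, step_budget=step_budget
        ),
        eval_config=EvalConfig(radius=8.0),
    )


def sweep_source_fraction(
    source: list[AnnotatedImage],
    target: list[AnnotatedImage],
    fractions: list[float],
    k_target: int = 0,
    regime: str = "adapted",
    **kwargs,
) -> pd.DataFrame:
    """One regime run per source fraction; returns an F1-vs-fraction table."""
    if not fractions:
        raise ValueError("fraction list must be non-empty")
    rows = []
    for frac in fractions:
        spec = RegimeSpec(
            regime="mixed" if k_target else regime,
            source_fraction=frac,
            k_target=k_target,
        )
        res = run_regime(source, target, spec, **kwargs)
        rows.append(
            {
                "source_fraction": frac,
                "k_target": k_target,
                "detection_f1": res.report.detection["f1"],
                "classification_f1": res.report.weighted["f1"],
            }
        )
    return pd.DataFrame(rows)


def sweep_target_count(
    source: list[AnnotatedImage],
    target: list[AnnotatedImage],
    ks: list[int],
    source_fraction: float = 0.4,
    **kwargs,
) -> pd.DataFrame:
    """One regime run per target-image count k at a fixed source fraction.

    The k = 0 row is exactly the adapted regime. A trained translator can be
    passed through ``kwargs`` to share one GAN fit across all k.
    """
    rows = []
    for k in ks:
        spec = RegimeSpec(
            regime="mixed" if k else "adapted",
            source_fraction=source_fraction,
            k_target=int(k),
        )
        res = run_regime(source, target, spec, **kwargs)
        rows.append(
            {
                "k_target": int(k),
                "source_fraction": source_fraction,
                "detection_f1": res.report.detection["f1"],
                "classification_f1": res.report.weighted["f1"],
            }
        )
    return pd.DataFrame(rows)
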