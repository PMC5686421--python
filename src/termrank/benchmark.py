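"""Desk-scale transfer-learning benchmark on the synthetic shift world.

Bundles the steps shared by the test suite, the acceptance script and the
CLI: generate a world, mine candidates, assemble features, build the
balanced distantly-labeled source set, and run the repeated-split protocol
for a set of systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import EvalReport, LabelingConfig, SplitProtocol, TransferConfig
from .evaluation import average_precision, evaluate_systems, make_splits
from .labeling import build_source_set
from .synth import SyntheticConfig, SyntheticWorld, generate_world

ALL_SYSTEMS = ("SourceOnly", "TargetOnly", "ADS-fsa", "ADS-sds")


@dataclass
class BenchmarkConfig:
    """Study conditions for the scaled-down benchmark: 600 balanced source
    examples, 30 repeated splits of 1600 annotated terms into a pool of 1000
    and an evaluation set of 600."""

    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    n_source_pos: int = 300
    n_source_neg: int = 300
    n_repeats: int = 30
    target_pool_size: int = 1000
    L_values: tuple[int, ...] = (100, 200, 500, 1000)
    systems: tuple[str, ...] = ALL_SYSTEMS
    ablate: tuple[str, ...] = ()
    seed: int = 0


def prepare_benchmark(
    cfg: BenchmarkConfig, world: SyntheticWorld | None = None
) -> tuple[SyntheticWorld, dict[str, np.ndarray], list[tuple[str, int]]]:
    """World, raw features for every term the protocol touches, and the
    balanced source training pairs."""
    if world is None:
        world = generate_world(cfg.synth)
    builder = world.feature_builder(ablate=cfg.ablate)
    annotated_terms = {t for t, _ in world.annotated}
    lab_cfg = LabelingConfig(
        familiarity_threshold=cfg.synth.familiarity_threshold,
        n_pos=cfg.n_source_pos,
        n_neg=cfg.n_source_neg,
        seed=cfg.seed,
    )
    source_train = build_source_set(world.candidates, annotated_terms, world.lexicon, lab_cfg)
    needed = list(dict.fromkeys([t for t, _ in source_train] + [t for t, _ in world.annotated]))
    raw = {t: builder.raw(t) for t in needed}
    return world, raw, source_train


def run_shift_benchmark(
    cfg: BenchmarkConfig, world: SyntheticWorld | None = None
) -> tuple[EvalReport, SyntheticWorld]:
    """Run the repeated-split protocol for ``cfg.systems`` at every L."""
    world, raw, source_train = prepare_benchmark(cfg, world)
    protocol = SplitProtocol(
        n_repeats=cfg.n_repeats,
        target_pool_size=cfg.target_pool_size,
        L_values=cfg.L_values,
        seed=cfg.seed,
    )
    splits = make_splits(world.annotated, protocol)
    transfer_cfg = TransferConfig(seed=cfg.seed)
    report = evaluate_systems(
        systems=list(cfg.systems),
        splits=splits,
        raw_features=raw,
        source_train=source_train,
        transfer_cfg=transfer_cfg,
        L_values=cfg.L_values,
    )
    return report, world


def bayes_ap(world: SyntheticWorld, split_eval: list[tuple[str, int]]) -> float:
    """Average precision of the generative Bayes-optimal ranking on one
    evaluation set — the ceiling any learned ranker can be compared to."""
    terms = [t for t, _ in split_eval]
    labels = np.array([l for _, l in split_eval])
    return average_precision(labels, world.bayes_scores(terms), tie_keys=np.array(terms))
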