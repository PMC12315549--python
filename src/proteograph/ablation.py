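"""Ablation harness: which model component earns its keep.

Variants drop network propagation, trained cluster aggregation, or both,
while sharing the training loop and evaluation protocol:

* ``full`` - propagation + trained softmax aggregation
* ``AM1``  - propagation + fixed uniform aggregation (lambda frozen)
* ``AM2``  - propagation only; heads act on the p protein signals
* ``AM3``  - trained aggregation of the raw signals (no propagation)
* ``AM4``  - plain multi-task logistic heads on the raw signals
"""

from __future__ import annotations

from .crossval import CVResult, cross_validate
from .estimator import PropagationClassifier, TrainingConfig

VARIANTS = {
    "full": dict(use_propagation=True, aggregation="trained"),
    "AM1": dict(use_propagation=True, aggregation="uniform"),
    "AM2": dict(use_propagation=True, aggregation="none"),
    "AM3": dict(use_propagation=False, aggregation="trained"),
    "AM4": dict(use_propagation=False, aggregation="none"),
}


def variant_estimator(
    variant: str,
    network=None,
    clusters=None,
    config: TrainingConfig | None = None,
) -> PropagationClassifier:
    """Configure a :class:`PropagationClassifier` for an ablation variant."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown ablation variant {variant!r}; choose from {sorted(VARIANTS)}")
    config = config or TrainingConfig()
    opts = VARIANTS[variant]
    return PropagationClassifier(
        network=network if opts["use_propagation"] else None,
        clusters=clusters if opts["aggregation"] != "none" else None,
        delta=config.delta,
        learning_rate=config.learning_rate,
        max_iter=config.max_iters,
        tol=config.tol,
        phi_floor=config.phi_floor,
        init_phi=config.init_phi,
        **opts,
    )


def run_ablation(
    x,
    net,
    clusters,
    y,
    test_x,
    test_y,
    config: TrainingConfig | None = None,
    variant: str = "full",
    n_repeats: int = 20,
    n_folds: int = 5,
) -> CVResult:
    """Run one variant through the repeated-CV evaluation protocol."""
    est = variant_estimator(variant, network=net, clusters=clusters, config=config)
    return cross_validate(
        x, net, clusters, y, test_x, test_y,
        config=config, n_repeats=n_repeats, n_folds=n_folds, estimator=est,
    )
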