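"""Two-step intermediate fusion of data modalities.

Feature counts differ wildly across modalities (a handful of clinical scores
vs. thousands of SNPs), which biases joint embedded selection. The two-step
strategy first trains a separate boosted Cox model per modality and keeps the
features with nonzero relative influence, then joins the selected features
and trains one final model on the union.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gbm import BoostedCoxEnsemble, fit_gbm

log = logging.getLogger(__name__)


@dataclass
class FusionResult:
    model: BoostedCoxEnsemble
    selected: dict[str, list[str]]                 # modality -> step-1 kept features
    modality_models: dict[str, BoostedCoxEnsemble] = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(X[self.model.feature_names])

    def importance(self, normalize: bool = True) -> dict[str, float]:
        return self.model.importance(normalize=normalize)


def two_step_fusion(
    modalities: dict[str, pd.DataFrame],
    times,
    events,
    seed: int = 0,
    keep_modality_models: bool = False,
    **gbm_params,
) -> FusionResult:
    """Train per-modality models, join nonzero-importance features, retrain.

    ``modalities`` maps block name (clinical / snps / pathways / components)
    to a feature frame; all blocks must share one patient index and disjoint
    column names. A modality contributing no features is logged and excluded
    from the join. The final model is trained with ``seed`` itself, so a
    single-modality call reproduces a plain ``fit_gbm`` on that block.
    """
    names = list(modalities)
    if not names:
        raise ValueError("at least one modality is required")
    index = modalities[names[0]].index
    seen: set[str] = set()
    for nm in names:
        if not modalities[nm].index.equals(index):
            raise ValueError(f"modality {nm!r} does not share the patient index")
        overlap = seen & set(modalities[nm].columns)
        if overlap:
            raise ValueError(f"duplicate feature names across modalities: {sorted(overlap)[:5]}")
        seen |= set(modalities[nm].columns)

    selected: dict[str, list[str]] = {}
    mod_models: dict[str, BoostedCoxEnsemble] = {}
    for i, nm in enumerate(names):
        m_seed = int(np.random.SeedSequence([int(seed), 101, i]).generate_state(1)[0] % (2**31))
        model = fit_gbm(modalities[nm], times, events, seed=m_seed, **gbm_params)
        kept = [c for c, v in model.importance(normalize=False).items() if v > 0]
        selected[nm] = kept
        if keep_modality_models:
            mod_models[nm] = model
        if not kept:
            log.info("modality %r selected no features; excluded from the join", nm)

    joined_cols: list[str] = [c for nm in names for c in selected[nm]]
    if not joined_cols:
        raise ValueError("no modality selected any feature")
    joined = pd.concat([modalities[nm][selected[nm]] for nm in names if selected[nm]], axis=1)
    final = fit_gbm(joined, times, events, seed=int(seed), **gbm_params)
    return FusionResult(model=final, selected=selected, modality_models=mod_models)
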