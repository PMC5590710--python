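"""Summary tables: optimal weights and sample sizes across trial durations."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import EffectSpec, PopulationParams, TrialDesign, gamma_covariance_unit
from .power import PowerRequest, bonferroni_sample_size, sample_size
from .weights import equal_weights, optimal_weights_c, optimal_weights_jc, unit_weight
from .weights import weight_table as optimal_weight_table

__all__ = ["optimal_weight_table", "sample_size_table"]

_STRATEGY_ORDER = ("unit_1", "unit_2", "unit_3", "equal", "optimal_jc", "optimal_c")


def _strategies(params, effect, design):
    j = params.n_components
    g = effect.gamma_for(params)
    sg1 = gamma_covariance_unit(params, design).sigma_gamma1
    out = {f"unit_{k + 1}": unit_weight(j, k) for k in range(j)}
    out["equal"] = equal_weights(j)
    out["optimal_jc"] = optimal_weights_jc(g, sg1)
    out["optimal_c"] = optimal_weights_c(g, params, design)
    return out


def sample_size_table(
    params: PopulationParams,
    effect: EffectSpec,
    durations: Sequence[float] = (2, 3, 4, 5, 6),
    base_design: Optional[TrialDesign] = None,
) -> pd.DataFrame:
    """Required total N per statistic, weight strategy and trial duration.

    Rows: the joint test Xi_J; Xi_JC(w) and Xi_C(w) under each weight
    strategy (unit vectors, equal weights, both optima); and the Bonferroni
    comparator (each component powered separately at alpha/J via Xi_C, the
    maximum N taken).  Columns: durations in years.
    """
    base = base_design if base_design is not None else TrialDesign(duration_years=2)
    cols = {}
    j = params.n_components
    strat_names = [s for s in _STRATEGY_ORDER if not s.startswith("unit_") or int(s[5:]) <= j]
    for dur in durations:
        design = base.with_duration(float(dur))
        strategies = _strategies(params, effect, design)
        col = [
            sample_size(
                PowerRequest("J", alpha=design.alpha, target_power=design.target_power),
                params,
                effect,
                design,
            ).n_required
        ]
        for stat in ("JC", "C"):
            for name in strat_names:
                req = PowerRequest(
                    stat,
                    weights=strategies[name],
                    alpha=design.alpha,
                    target_power=design.target_power,
                )
                col.append(sample_size(req, params, effect, design).n_required)
        col.append(bonferroni_sample_size(params, effect, design).n_required)
        cols[f"{float(dur):g}y"] = col
    index = pd.MultiIndex.from_tuples(
        [("Xi_J", "-")]
        + [("Xi_JC", name) for name in strat_names]
        + [("Xi_C", name) for name in strat_names]
        + [("Bonferroni", "-")],
        names=["statistic", "weights"],
    )
    return pd.DataFrame(cols, index=index)
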