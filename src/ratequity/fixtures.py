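"""Packaged example data and fixture generation.

Two published worked examples ship as in-memory constants: a hypothetical
five-study toy comparison of the sample ATE against subgroup effects, and the
subgroup analysis of the Moving to Opportunity (MTO) housing-voucher
experiment's effect on child psychological distress (standardized score),
stratified by child gender and family health vulnerability.
``generate_fixtures`` writes these, plus a seeded synthetic trial, as CSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import SummaryRow
from .simulation import EffectDistributionSpec, SimulationConfig, sample_effects, simulate_trial

__all__ = [
    "TOY_REPRESENTATION",
    "toy_multistudy_table",
    "mto_summary_rows",
    "MTO_PHI",
    "MTO_MAX_DIFF",
    "generate_fixtures",
]

# Hypothetical multi-study example: three subgroups A/B/C at fixed 70/20/10%
# representation; each row is one study's true subgroup effects.
TOY_REPRESENTATION = np.array([0.7, 0.2, 0.1])

_TOY_TAU = [
    (-3.51, -2.96, 4.04),
    (-4.39, -0.13, 4.62),
    (-1.84, -1.08, -0.26),
    (-1.16, -4.71, -4.22),
    (-1.75, 0.85, -1.38),
]


def toy_multistudy_table() -> pd.DataFrame:
    """Five-study toy example: true subgroup effects for groups A, B, C."""
    return pd.DataFrame(_TOY_TAU, columns=["tau_A", "tau_B", "tau_C"],
                        index=pd.RangeIndex(1, 6, name="study"))


# MTO subgroup analysis of psychological distress: published intention-to-treat
# estimates (SD units) with 95% CIs and sample representation, for
# nonvulnerable girls (NVG), vulnerable girls (VG), nonvulnerable boys (NVB)
# and vulnerable boys (VB).
_MTO_ROWS = [
    ("NVG", -0.21, -0.34, -0.07, 0.309),
    ("VG", 0.02, -0.15, 0.18, 0.195),
    ("NVB", 0.04, -0.09, 0.17, 0.269),
    ("VB", 0.26, 0.09, 0.44, 0.227),
]

# heterogeneity hyperparameter used in the MTO analysis: subgroup effects
# assumed to differ by at most 0.25 SD, so phi <= 0.25/2 by Popoviciu's bound
MTO_MAX_DIFF = 0.25
MTO_PHI = 0.125


def mto_summary_rows() -> list[SummaryRow]:
    """Published MTO subgroup results as summary rows."""
    return [SummaryRow(label=l, estimate=e, ci_low=lo, ci_high=hi, representation=p)
            for l, e, lo, hi, p in _MTO_ROWS]


def generate_fixtures(out_dir, seed: int = 1) -> dict[str, Path]:
    """Write the packaged example CSVs plus one seeded synthetic trial.

    Returns a mapping of fixture name to written path. The synthetic trial is
    fully determined by the seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    toy = toy_multistudy_table().reset_index()
    for lab, p in zip(("A", "B", "C"), TOY_REPRESENTATION):
        toy[f"p_{lab}"] = p
    paths["toy_multistudy"] = out / "toy_multistudy.csv"
    toy.to_csv(paths["toy_multistudy"], index=False)

    mto = pd.DataFrame(_MTO_ROWS,
                       columns=["label", "estimate", "ci_low", "ci_high", "representation"])
    paths["mto_summary"] = out / "mto_summary.csv"
    mto.to_csv(paths["mto_summary"], index=False)

    config = SimulationConfig(effect_spec=EffectDistributionSpec(), seed=seed)
    ss = np.random.SeedSequence(seed)
    effect_seed, trial_seed = ss.spawn(2)
    effects = sample_effects(config.effect_spec, config.n_groups, effect_seed)
    trial = simulate_trial(config, effects, trial_seed)
    paths["synthetic_trial"] = out / "synthetic_trial.csv"
    trial.to_dataframe().to_csv(paths["synthetic_trial"], index=False,
                                float_format="%.10g")
    return paths
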