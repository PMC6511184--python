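"""Shared Monte-Carlo cohort simulations, cached so that the property tests
and the acceptance tests reuse one set of runs within a session.

Simulations are run at a reduced 3 mm / 120 px grid to keep the suite
inside its time budget; the contracts under test are resolution-free.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from octaperf import EffectModel, ScanGeometry, generate_cohort, wilcoxon_signed_rank

GEOMETRY = ScanGeometry(3.0, 120)
TRUE_SHIFT = -0.014


def scp_paired_diffs(seed: int, effect: EffectModel) -> np.ndarray:
    """Measured month1-baseline SCP density differences of a 16-eye cohort."""
    cohort = generate_cohort(
        16,
        GEOMETRY,
        effect,
        seed=seed,
        include_controls=False,
        plexuses=("SCP",),
    )
    wide = cohort.measure().pivot_table(
        index="eye_id", columns="timepoint", values="density"
    )
    return (wide["month1"] - wide["baseline"]).to_numpy()


@lru_cache(maxsize=None)
def null_scp_pvalues(n_seeds: int = 200) -> tuple[float, ...]:
    """Paired Wilcoxon p-values of cohorts simulated under the null."""
    effect = EffectModel.null()
    return tuple(
        wilcoxon_signed_rank(scp_paired_diffs(seed, effect)).p_value
        for seed in range(n_seeds)
    )


@lru_cache(maxsize=None)
def shift_recovery(n_seeds: int = 100) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """(mean paired SCP change, its standard error) per simulated cohort."""
    effect = EffectModel(scp_shift=TRUE_SHIFT)
    means = []
    ses = []
    for seed in range(n_seeds):
        d = scp_paired_diffs(seed, effect)
        means.append(float(d.mean()))
        ses.append(float(d.std(ddof=1) / np.sqrt(len(d))))
    return tuple(means), tuple(ses)
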