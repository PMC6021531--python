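"""Shared fixtures: planted ground truth and seeded synthetic study runs."""

from __future__ import annotations

import numpy as np
import pytest

from emgsyn import (
    SimConfig,
    default_ground_truth,
    match_synergies,
    run_fatigue_study,
    run_multidirectional_study,
)

N_REPLICATES = 20


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def multidirectional_replicates(ground_truth):
    """Twenty seeded replicates of the full multidirectional pipeline.

    Each replicate simulates a 26-direction session at 30 dB SNR, selects the
    synergy count by the dual VAF criteria over the full 1..13 sweep, and
    records planted-W recovery similarities and preferred-direction errors.
    """
    out = []
    for rep in range(N_REPLICATES):
        seed = 100 + rep
        study = run_multidirectional_study(
            ground_truth, SimConfig(), seed=seed, k_range=range(1, 14)
        )
        entry = {"study": study, "order": study.selection.order}
        res3 = study.selection.results_by_k.get(3)
        if res3 is not None:
            perm, sims = match_synergies(res3.weights, ground_truth.weights)
            entry["recovery_sims"] = sims
            # PD error per planted synergy, via the matched tuning entries
            from emgsyn.tuning import tuning_curve

            tun = tuning_curve(res3.coefficients, study.directions)
            errs = []
            for j in range(ground_truth.n_synergies):
                s = tun.synergies[perm[j]]
                errs.append(
                    s.angle_to(ground_truth.preferred_directions[j])
                    if s.defined else np.inf
                )
            entry["pd_errors_deg"] = np.array(errs)
        out.append(entry)
    return out


@pytest.fixture(scope="session")
def fatigue_study(ground_truth):
    """One full fatigue study at the default study conditions (270 s trials)."""
    return run_fatigue_study(ground_truth, SimConfig(), seed=11)
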