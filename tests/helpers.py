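"""Shared simulation helpers for the statistical tests.

The epoch-level cohort path mirrors the pipeline's per-trial processing
(detrend, baseline) on artifact-free simulated epochs and extracts the
scan's input: subject × condition × electrode × grid-window means.
"""

import numpy as np

from erpwp import synth
from erpwp.io_core import CONDITIONS
from erpwp.preprocess import baseline_epochs, detrend_epochs
from erpwp.stats import WINDOW_GRID_MS


def cohort_window_means(spec, cohort_seed, covariates=None,
                        n_subjects=17, preprocess=True):
    """Simulate one cohort at the epoch level and return the scan input
    (n_subjects, 3, 2, 19) plus the covariate table used."""
    if covariates is None:
        covariates = synth.default_covariates(n_subjects, seed=cohort_seed)
    usage = covariates.values("usage_frequency")
    ss = np.random.SeedSequence(cohort_seed)
    wm = np.empty((n_subjects, len(CONDITIONS), 2, len(WINDOW_GRID_MS)))
    for i, child in enumerate(ss.spawn(n_subjects)):
        ep = synth.simulate_epochs(spec, float(usage[i]), seed=child)
        if preprocess:
            ep = baseline_epochs(detrend_epochs(ep))
        slices = [ep.time_slice(*w) for w in WINDOW_GRID_MS]
        for j, c in enumerate(CONDITIONS):
            avg = ep.data[ep.conditions == c].mean(axis=0)
            for w, sl in enumerate(slices):
                wm[i, j, :, w] = avg[:, sl].mean(axis=1)
    return wm, covariates


def null_cohort_spec(seed=0):
    """Cohort spec with all ERP amplitudes zeroed (pure noise)."""
    import dataclasses

    base = synth.CohortSpec(seed=seed)
    comps = tuple(
        synth.ComponentSpec(c.center_ms, c.width_ms,
                            {k: 0.0 for k in c.amplitude_uv},
                            c.channel_gains, 0.0)
        for c in base.components)
    return dataclasses.replace(base, components=comps)


def window_mean_from_grid(wm, cond_idx, elec_idx, start_ms, end_ms):
    """Mean of grid-window means whose windows tile [start, end] ms."""
    idx = [i for i, (a, b) in enumerate(WINDOW_GRID_MS)
           if a >= start_ms and b <= end_ms]
    return wm[:, cond_idx, elec_idx, :][:, idx].mean(axis=1)
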