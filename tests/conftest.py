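"""Shared fixtures: cached desk-scale micromotion runs.

Scenario solutions are expensive, so every acceptance-tier test draws from
one session-scoped cache of runs.  Ordering properties are probed under a
monotone quarter-period respiration ramp (vascular ripple off), which
preserves the material / friction / geometry orderings of the full
two-tone waveform at a fraction of the cost; the full waveform itself is
exercised by the baseline quantitative runs.
"""

import warnings

import numpy as np
import pytest

from probemech import fe_solver as fes
from probemech import postprocess as post

warnings.filterwarnings("ignore")

RAMP = fes.BoundaryLoad(vascular_amplitude=0.0)
RAMP_TIME = 0.15  # s; monotone rise to 9.2 um, enough to rank conditions


def _summarize(bundle):
    d, v = bundle["path_profiles"]["tip"]
    return {
        "peak_roi_max": bundle["peak_roi_max"],
        "peak_roi_mean": bundle["peak_roi_mean"],
        "critical_volume": bundle["critical_volume"],
        "tip_path_peak": float(np.max(v)),
    }


@pytest.fixture(scope="session")
def ramp_run():
    """Factory returning cached summaries of ramp-load scenario runs."""
    cache = {}

    def _run(material="hydrogel", cof=0.3, kind="ellipse", ratio=1,
             preset="tiny", total_time=RAMP_TIME):
        key = (material, cof, kind, ratio, preset, total_time)
        if key not in cache:
            sc = fes.Scenario(
                name="ramp", material=material, cof=cof, section_kind=kind,
                section_ratio=ratio, preset=preset, load=RAMP,
                total_time=total_time,
            )
            cache[key] = _summarize(fes.run_scenario(sc))
        return cache[key]

    return _run


@pytest.fixture(scope="session")
def baseline_full_run():
    """Full two-tone waveform, hydrogel baseline, quarter period."""
    sc = fes.Scenario(name="baseline", material="hydrogel", preset="tiny",
                      total_time=0.25)
    return fes.run_scenario(sc)


@pytest.fixture(scope="session")
def full_cof_runs(baseline_full_run):
    """Friction sweep end points under the full waveform, quarter period."""
    runs = {0.3: baseline_full_run}
    for cof in (0.1, 0.9):
        sc = fes.Scenario(name=f"cof{cof}", material="hydrogel", cof=cof,
                          preset="tiny", total_time=0.25)
        runs[cof] = fes.run_scenario(sc)
    return runs
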