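import warnings

import numpy as np
import pytest

from startlekit import analysis, protocol, response, simulate
from startlekit.stimulus import ClippingWarning


@pytest.fixture(autouse=True)
def _silence_clipping():
    """Levels above the calibration reference legitimately exceed digital
    full scale; the warning is tested explicitly where it matters."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClippingWarning)
        yield


@pytest.fixture
def platform():
    """Noiseless platform: round-trip identities hold exactly."""
    return simulate.VirtualPlatform(noise_rms=0.0)


@pytest.fixture
def skewed_platform():
    """Unequal axis gains, still noiseless."""
    return simulate.VirtualPlatform(gx=1.2, gy=0.8, gz=1.5, noise_rms=0.0)


def simulate_amplitude_table(proto, animal, plat):
    """Render a session and extract per-trial amplitudes (ground truth
    table augmented with an `amplitude` column)."""
    recs, truth = simulate.simulate_session(proto, animal, plat)
    truth = truth.copy()
    truth["amplitude"] = [
        response.extract_asr(r, plat.calibration()).value for r in recs]
    return truth


def gpias_estimate(run_seed, gpias_true=0.5, n_repeats=15, n_bootstrap=500,
                   noise_rms=0.02):
    """One end-to-end GPIAS measurement: protocol -> simulate -> render ->
    extract -> full-combinatorial statistic with bootstrap SE."""
    plat = simulate.VirtualPlatform(noise_rms=noise_rms)
    proto = protocol.build_gpias_protocol([8000.0], n_repeats=n_repeats, seed=run_seed)
    animal = simulate.VirtualAnimal(gpias_true=gpias_true, seed=run_seed + 5000)
    tbl = simulate_amplitude_table(proto, animal, plat)
    blk = tbl[~tbl.habituation]
    return analysis.bootstrap_se(
        blk.loc[blk.kind == "gap", "amplitude"].to_numpy(),
        blk.loc[blk.kind == "nogap", "amplitude"].to_numpy(),
        n_bootstrap, seed=run_seed)


def threshold_estimate(run_seed, threshold_dbspl=10.0, n_repeats=15,
                       rendered=True, noise_rms=0.02):
    """One end-to-end threshold measurement; returns the fitted threshold."""
    proto = protocol.build_threshold_protocol(
        2000.0, 2000.0, 0.5, 2.0, 26.0, 2.0, n_repeats=n_repeats, seed=run_seed)
    animal = simulate.VirtualAnimal(
        threshold_dbspl=threshold_dbspl, slope=0.05, saturation=0.8,
        seed=run_seed + 9000)
    if rendered:
        plat = simulate.VirtualPlatform(noise_rms=noise_rms)
        tbl = simulate_amplitude_table(proto, animal, plat)
    else:
        import pandas as pd

        tbl = pd.DataFrame([
            {"kind": s.kind, "tone_level_dbspl": s.tone_level_dbspl,
             "habituation": i < protocol.N_HABITUATION,
             "amplitude": simulate.draw_trial_amplitude(animal, s, i)}
            for i, s in enumerate(proto.trials)])
    blk = tbl[~tbl.habituation]
    base = blk.loc[blk.kind == "notone", "amplitude"].to_numpy()
    levels, ppi = [], []
    for level, sub in blk[blk.kind == "tone"].groupby("tone_level_dbspl"):
        r = analysis.full_combinatorial_ratios(sub["amplitude"].to_numpy(), base)
        levels.append(level)
        ppi.append(analysis.inhibition_statistic(r))
    return analysis.fit_hard_sigmoid(np.asarray(levels), np.asarray(ppi))
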