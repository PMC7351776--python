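import numpy as np
import pytest

from hippopred import design, simulate


@pytest.fixture(scope="session")
def default_schedule():
    return design.generate_schedule(design.DesignSpec(seed=11))


@pytest.fixture(scope="session")
def small_spec():
    # 6 rooms x 9 types = 54 trials over 2 scans (27 per scan, one per task)
    return design.DesignSpec(n_rooms=6, n_scans=2, seed=7)


@pytest.fixture(scope="session")
def small_schedule(small_spec):
    return design.generate_schedule(small_spec)


@pytest.fixture(scope="session")
def rsa_schedule():
    # 8 rooms over 4 scans: two scans per task, so cue/intact-image pairs
    # can satisfy the different-scan + same-task eligibility rules
    return design.generate_schedule(design.DesignSpec(n_rooms=8, n_scans=4,
                                                      seed=13))


@pytest.fixture(scope="session")
def small_sim(small_schedule):
    params = simulate.SimulationParams(seed=21)
    runs, truth = simulate.simulate_participant(small_schedule, params)
    return small_schedule, params, runs, truth


def make_single_scan_schedule(trial_specs, spec=None, start_s=10.0,
                              gap_s=4.0, task="Furniture"):
    """Hand-build a one-scan schedule from (room, furniture, layout) tuples."""
    spec = spec or design.DesignSpec()
    trials = []
    t = start_s
    for i, (room, f, l) in enumerate(trial_specs):
        trials.append(design.Trial(
            trial_index=i, room_id=room, task=task, furniture_changes=f,
            layout_changes=l, scan_index=0, cue_onset_s=t,
            image_onset_s=t + spec.cue_to_image_s))
        t += spec.cue_to_image_s + spec.image_duration_s + gap_s
    return design.TrialSchedule(spec=spec, trials=tuple(trials))
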