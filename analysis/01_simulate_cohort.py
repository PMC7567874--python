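#!/usr/bin/env python
"""Generate the synthetic study materials: the rhythmic amplitude-modulated
noise stimulus, a supratemporal electrode cohort with planted ground truth,
and the listening + articulation recordings.

Bulky binary containers (WAV, HDF5) go under scratch/; the electrode table,
event table, and ground-truth parameters are written as TSV/JSON under
results/data/. Downstream analysis scripts regenerate the same cohorts
deterministically from the library seeds, so they can run independently.
"""

import json
from pathlib import Path

from audiopred.containers import write_recording, write_table_tsv
from audiopred.simulate import (
    make_electrode_table,
    make_ground_truth,
    simulate_articulation_response,
    simulate_neural_response,
)
from audiopred.stimuli import StimulusSpec, make_am_noise_stimulus, write_wav

SCRATCH = Path("scratch/cohort")
OUT = Path("results/data")

def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    OUT.mkdir(parents=True, exist_ok=True)

    spec = StimulusSpec(sample_rate_hz=4000.0, seed=0)
    stimulus = make_am_noise_stimulus(spec)
    write_wav(SCRATCH / "am_noise_3hz.wav", stimulus.waveform, spec.sample_rate_hz)

    electrodes = make_electrode_table(n_sustained=10, n_transient=6, n_null=4, seed=0)
    truth = make_ground_truth(electrodes)
    write_table_tsv(electrodes, OUT / "electrodes.tsv")
    write_table_tsv(truth.electrodes, OUT / "ground_truth.tsv")

    listening = simulate_neural_response(stimulus, electrodes, truth, n_trials=24, seed=1)
    articulation = simulate_articulation_response(electrodes, truth, n_trials=24, seed=2)
    write_recording(listening, SCRATCH / "listening.h5")
    write_recording(articulation, SCRATCH / "articulation.h5")
    write_table_tsv(listening.events, OUT / "listening_events.tsv")

    summary = {
        "stimulus": {"mod_freq_hz": 3.0, "mod_depth": 0.8, "n_pulses": spec.n_pulses,
                     "edge_times_s": stimulus.edge_times.tolist()},
        "cohort": truth.electrodes["archetype"].value_counts().to_dict(),
        "n_trials": 24,
        "listening_duration_s": listening.duration_s,
    }
    with open(OUT / "simulation_summary.json", "w") as f:
        json.dump(summary, f, indent=2)
    print(f"stimulus: {spec.n_pulses} pulses, edges at {[round(t, 3) for t in stimulus.edge_times]}")
    print(f"cohort: {summary['cohort']}; recordings in {SCRATCH}/")


if __name__ == "__main__":
    main()
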