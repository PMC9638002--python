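#!/usr/bin/env python
"""Generate the synthetic recording sessions the downstream analyses use.

Writes two session directories under results/sessions/ plus their ground
truth: a 200-unit session with gains sampled 3-6x (the population whose
response categories the scoring stage must recover) and a 40-unit gain-5
session with 4 presentations per class (the strong-effect session used for
decoding and temporal dynamics).
"""

import json
from pathlib import Path

from ethospike.io_core import write_session
from ethospike.synthetic import SimConfig, simulate_session

OUT = Path(__file__).resolve().parent.parent / "results" / "sessions"


def dump(name, cfg):
    session, gt = simulate_session(cfg)
    dest = OUT / name
    write_session(session, dest)
    with open(dest / "ground_truth.json", "w") as fh:
        json.dump(
            dict(category=gt.category, baseline_rate=gt.baseline_rate,
                 event_gain=gt.event_gain, aftereffect=gt.aftereffect,
                 trial_onsets=gt.trial_onsets),
            fh, indent=1, default=float,
        )
    n_resp = len(gt.responsive_units())
    print(f"{name}: {cfg.n_units} units ({n_resp} responsive), "
          f"{len(session.events)} events, {session.duration/60:.0f} min")


def main():
    dump("mixed_gain", SimConfig(n_units=200, events_per_class=2, seed=0))
    dump("gain5", SimConfig(n_units=40, events_per_class=4, event_gain=5.0,
                            seed=0))


if __name__ == "__main__":
    main()
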