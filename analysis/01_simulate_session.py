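#!/usr/bin/env python
"""Simulate one default behavioral session + movie and write its artifacts.

Generates a 150-trial pole-detection session at 4 fps, renders the 128 x 128
movie with the default 20-dendrite population, and writes the event log,
whisker trace, movie, and ground truth under results/session/.  Prints the
session's basic statistics (outcome counts, random rewards, duration).
"""

import json
from collections import Counter
from pathlib import Path

from tuftpipe import pipeline

OUT = Path("results/session")


def main():
    cfg = pipeline.load_config(Path(__file__).parent.parent / "configs" / "default.yaml")
    paths = pipeline.simulate_stage(cfg, OUT)
    from tuftpipe.io_formats import read_events
    session = read_events(OUT / "events.csv", OUT / "whisker.h5")
    outcomes = Counter(t.outcome for t in session.trials)
    stats = {
        "n_trials": len(session.trials),
        "outcomes": dict(outcomes),
        "n_random_rewards": len(session.random_reward_times_s),
        "n_licks": len(session.lick_times_s),
        "duration_min": round(session.duration_s / 60, 1),
    }
    (OUT / "session_stats.json").write_text(json.dumps(stats, indent=2))
    print("simulated session:", json.dumps(stats))
    print("artifacts:", {k: str(v) for k, v in paths.items()})


if __name__ == "__main__":
    main()
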