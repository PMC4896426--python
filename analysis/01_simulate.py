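"""Simulate the planted twin-session cohort and write its ground truth.

Emits the atlas table, the planted static labels, and one example subject's
signal matrix so downstream readers can see the raw data format.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import COHORT, results_dir
from dynfc.io import save_signals
from dynfc.simulate import make_atlas, simulate_cohort


def main() -> None:
    out = results_dir()
    sessions = simulate_cohort(COHORT, n_subjects=20, sessions=2)
    atlas = make_atlas(COHORT)
    atlas.to_csv(out / "atlas.csv", index=False)
    pd.DataFrame(
        {
            "node_id": list(COHORT.node_ids),
            "native_community": COHORT.native_labels(),
            "static_truth": COHORT.static_truth_labels(),
            "flexible": [i in COHORT.flexible_nodes for i in range(COHORT.n_nodes)],
        }
    ).to_csv(out / "planted_truth.csv", index=False)
    example = sessions[0]
    save_signals(
        type(example)(example.subjects[:1], example.data[:1], example.node_ids, example.dt),
        out / "example_signals",
    )
    print(f"cohort: {len(sessions)} sessions x {sessions[0].n_subjects} subjects, "
          f"{sessions[0].n_nodes} nodes x {sessions[0].n_frames} frames")
    print(f"flexible coalition: nodes {COHORT.flexible_nodes}")
    print(f"wrote atlas, planted truth and one example subject under {out}")


if __name__ == "__main__":
    main()
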