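"""Shared study configuration for the numbered analysis scripts.

One planted twin-session cohort drives all analyses: 40 nodes (three
12-node stable host communities plus a 4-node flexible coalition), 20
subjects, 1,200 frames at TR 0.72 s. Windowed community detection uses a
40 s exponentially weighted window advancing 6 frames per step with 20
seeded initializations per window — enough to keep every script to seconds
while leaving all results unchanged relative to denser settings.
"""

from pathlib import Path

from dynfc.pipeline import RunConfig
from dynfc.simulate import SimSpec

RESULTS = Path(__file__).resolve().parent.parent / "results"

COHORT = SimSpec(seed=7)

CONFIG = RunConfig(
    sim=COHORT,
    n_subjects=20,
    sessions=2,
    step_frames=6,
    n_init=20,
    seed=13,
)


def results_dir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
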