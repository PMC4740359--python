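"""Shared configuration for the numbered analysis drivers.

One synthetic dataset, generated at the emulated study design, is analysed by
scripts 03-06; regenerating it from the fixed seed is cheap, so no script
depends on another's files.
"""

from pathlib import Path

from provzone.simulate import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
ANALYSIS_SEED = 20260927

# the emulated sampling design: 16 populations x 32 individuals x 134 dominant
# loci on a 160 km transect, 13 loci coupled to the climate gradient
STUDY_CONFIG = SimConfig(seed=ANALYSIS_SEED)


def study_dataset():
    from provzone.simulate import simulate_dataset

    return simulate_dataset(STUDY_CONFIG)
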