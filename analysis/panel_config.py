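"""Shared configuration for the numbered analysis scripts.

One demonstration panel — smaller than the full study geometry so every
script runs in seconds — regenerated deterministically by each script
instead of being passed around as bulky intermediates. The full study
conditions (12 samples, 200 compounds, 87 min runs) are exercised by the
test suite and scripts/acceptance.py.
"""

from pathlib import Path

from ventree.synthetic import PanelDesign, default_sample_meta, make_compound_library

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"

PANEL_SEED = 2024
LIBRARY_SEED = 5


def demo_library():
    return make_compound_library(10, seed=LIBRARY_SEED, rt_range=(2.0, 38.0))


def demo_design() -> PanelDesign:
    return PanelDesign(
        n_samples=6,
        sample_meta=default_sample_meta(6),
        shared_fraction=0.3,
        rt_range=(1.0, 40.0),
    )


def demo_panel():
    from ventree.synthetic import simulate_panel

    lib = demo_library()
    design = demo_design()
    runs, truth = simulate_panel(design, lib, seed=PANEL_SEED)
    return lib, design, runs, truth


def deconvolute_panel(runs):
    from ventree.deconvolution import process_run

    return {run.sample_id: process_run(run) for run in runs}
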