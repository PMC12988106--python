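"""Deconvolute every run of the demonstration panel into purified spectra.

Re-simulates the panel deterministically, runs two-axis peak spotting and
NNLS/ALS spectral deconvolution per run, scores recovery against the
generator truth, and writes the per-run spectrum table plus an MGF of the
first run's purified spectra.
"""

import pandas as pd
from panel_config import RESULTS, deconvolute_panel, demo_panel

from ventree.evaluation import match_spectra_to_truth
from ventree.io import spectrum_table, write_mgf


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    lib, design, runs, truth = demo_panel()
    by_id = {c.id: c for c in lib}
    per_run = deconvolute_panel(runs)

    tables = []
    for run in runs:
        spectra = per_run[run.sample_id]
        rec = match_spectra_to_truth(spectra, truth.placements[run.sample_id],
                                     by_id)
        print(f"{run.sample_id}: {len(spectra)} purified spectra, "
              f"{rec.n_recovered}/{rec.n_truth} placed compounds recovered "
              f"at cosine >= 0.95 ({rec.rate:.1%})")
        tables.append(spectrum_table(spectra, run.sample_id))
    pd.concat(tables).to_csv(RESULTS / "spectrum_table.csv", index=False)
    write_mgf(per_run[runs[0].sample_id], RESULTS / "run1_spectra.mgf",
              sample_id=runs[0].sample_id)
    print(f"wrote {RESULTS/'spectrum_table.csv'} and {RESULTS/'run1_spectra.mgf'}")


if __name__ == "__main__":
    main()
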