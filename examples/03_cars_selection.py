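"""CARS wavelength selection on the calibration partition.

Runs the Monte-Carlo elimination for the total-adulterant target and prints
the RMSECV trace minimum, the number of surviving wavelengths and where they
sit on the wavenumber axis — the informative bands of the mixture problem.
"""

from nirquant import (
    CARSConfig, ks_split, run_cars, sg_filter, simulate_default_study, train_size,
)

spectra = sg_filter(simulate_default_study(seed=1, n_points=800,
                                           replicates_per_level=8))
split = ks_split(spectra, train_size(spectra.n_samples, 0.7))
cal = spectra.take(split.train_indices)

res = run_cars(cal, "C", CARSConfig(n_runs=50, seed=1))
print(f"best run: {res.best_run} of 50 "
      f"(RMSECV {res.rmsecv_trace[res.best_run - 1]:.4f}%)")
print(f"selected {res.selected_indices.size} of {res.n_variables_total} "
      f"variables ({100 * res.selected_fraction:.1f}%)")
wn = spectra.wavenumbers[res.selected_indices]
print(f"selected wavenumbers span {wn.min():.0f}-{wn.max():.0f} cm^-1")
print("first ten:", ", ".join(f"{w:.0f}" for w in sorted(wn)[:10]))
# a small RMSECV with a few percent of the variables means the calibration
# information is concentrated in a handful of absorption bands
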