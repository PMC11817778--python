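"""Generate the synthetic adulteration study and inspect its structure.

Builds the default mixture design (15 total-adulteration levels from 40% down
to 0%, five sweet-potato:corn ratios, 15 replicates each = 225 samples),
renders FT-NIR-like spectra on a 1,557-point grid with realistic scatter and
noise, and writes them as a wide CSV.
"""

from nirquant import build_design, simulate_default_study, write_spectra_csv

design = build_design()
print(design.table.drop_duplicates("level").to_string(index=False))
# each row above is one recipe: fA/fB are the sweet-potato and corn starch
# mass percentages, fC their sum; 15 replicate samples share each recipe

spectra = simulate_default_study(seed=1)
print(f"\n{spectra.n_samples} samples x {spectra.n_points} wavenumbers "
      f"({spectra.wavenumbers[0]:.0f} -> {spectra.wavenumbers[-1]:.0f} cm^-1)")
print(f"absorbance range: {spectra.absorbance.min():.3f} "
      f"to {spectra.absorbance.max():.3f} AU")

path = write_spectra_csv(spectra, "scratch_spectra.csv")
print(f"wrote {path}")
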