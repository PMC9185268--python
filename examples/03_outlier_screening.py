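"""Screen spectral outliers with the standardized Mahalanobis (GH) distance.

Plants three corrupted spectra in a clean synthetic population and shows
that the GH > 3 rule finds exactly those samples.
"""

from podnirs import (MathTreatment, apply_treatment, average_replicates,
                     generate_dataset, fit_pca, gh_distances,
                     remove_spectral_outliers)

spectra, _ = generate_dataset(n=144, replicates=6, seed=1)
averaged = average_replicates(spectra, "sample")
corrected = apply_treatment(averaged, MathTreatment(scatter="snv_dt"))

# corrupt three samples with a gross spectral shift
planted = ["S010", "S077", "S140"]
rows = [corrected.sample_ids.index(s) for s in planted]
corrected.absorbance[rows] += 8 * corrected.absorbance.std()

space = fit_pca(corrected, k=0.99)
h = gh_distances(space, corrected)
print(f"PCA subspace: {space.k} components; "
      f"in-sample mean GH = {h.mean():.3f} (expected (n-1)/n = "
      f"{(len(h) - 1) / len(h):.3f})")

kept, report = remove_spectral_outliers(corrected, h_limit=3.0)
print(f"removed at GH > 3: {report.removed_ids}")
print(f"surviving samples: {kept.n_samples}")
# The three planted samples are flagged; the clean population keeps a
# mean GH near 1, the scale the H > 3 limit is calibrated for.
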