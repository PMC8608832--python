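"""Train the cine fingerprint extractor and look at what the latent encodes.

Trains the probabilistic encoder-decoder unsupervised on 30 phantom
sequences, then shows that the posterior means linearly predict the LV
end-diastolic area — a structural feature the extractor was never told
about.
"""

import numpy as np

from cinerisk import ExtractorConfig, crop_and_resample, extract_fingerprint, sample_cohort, train_extractor

cohort = sample_cohort(30, seed=2, spacing_mm=8.8, size_px=32, n_frames=8)
seqs = [crop_and_resample(s, out_size=32, out_spacing_mm=8.8) for _, _, s in cohort]

config = ExtractorConfig(latent_dim=4, hidden_dim=32, pca_dim=32, epochs=80, seed=0)
model = train_extractor(seqs, [s.subject_id for s in seqs], config)
print(f"reconstruction L2: {model.history[0]['l2']:.4f} -> {model.history[-1]['l2']:.4f} "
      f"over {config.epochs} epochs")

fps = [extract_fingerprint(model, s) for s in seqs]
print(f"fingerprint dimension: {fps[0].mean.size} "
      f"({config.latent_dim} per frame x {seqs[0].n_frames} frames)")

# linear probe: latent means -> LV end-diastolic area
F = np.stack([fp.mean for fp in fps])
area = np.array([p.lv_edv_area for _, p, _ in cohort])
A = np.column_stack([F, np.ones(len(F))])
beta, *_ = np.linalg.lstsq(A, area, rcond=None)
r2 = 1 - (area - A @ beta).var() / area.var()
print(f"linear R^2 of LV end-diastolic area from the fingerprint: {r2:.2f}")
print("(the latent encodes chamber geometry without any labels)")
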