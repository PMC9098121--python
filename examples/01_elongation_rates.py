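"""Estimate transcription elongation rates from synthetic wavefront data.

Generates DRB-release (advancing) and flavopiridol-runoff (receding) waves
moving at a known 2 kb/min, then recovers the rate with both estimators:
the spline-peak meta-profile method and the per-gene half-height method.
"""

import numpy as np

from ttquant.profiles import tss_reference_profile
from ttquant.synthetic_data import (
    SyntheticConfig,
    make_wave_gene_set,
    simulate_drb_wave_tracks,
    simulate_fp_clearance_tracks,
)
from ttquant.wavefront import (
    call_drb_wave_positions,
    fit_elongation_rate,
    fit_smooth_curve,
    fp_half_height_series,
    mean_rate_one_decimal,
)

cfg = SyntheticConfig(seed=0, wave_speed=2.0)
genes, chrom_lengths = make_wave_gene_set(cfg, n_genes=3)

# --- DRB release: wave peaks on the meta-profile, then an OLS rate fit
timepoints = [0, 10, 20, 30, 40]  # minutes after release
tracks, _ = simulate_drb_wave_tracks(genes, chrom_lengths, cfg, timepoints)
curves = {}
for t, track in tracks.items():
    prof = tss_reference_profile(track, genes, downstream=200_000, upstream=2000,
                                 bin_size=100, trim=0.0)
    curves[t] = fit_smooth_curve((prof.positions + 50) / 1e3, prof.means)
series = call_drb_wave_positions(curves)
fit = fit_elongation_rate(series)
print("DRB wave peaks (kb):", np.round(series.positions_kb, 1))
print(f"DRB elongation rate: {fit.rate:.2f} kb/min (true 2.0)")

# --- FP runoff: per-gene half-height rear-edge positions
tracks, _ = simulate_fp_clearance_tracks(genes, chrom_lengths, cfg,
                                         [10, 20, 30, 40, 50])
rates = []
for gene in genes:
    s = fp_half_height_series(tracks, gene)
    r = fit_elongation_rate(s).rate
    rates.append(r)
    print(f"FP {gene.gene_id}: rear edge {np.round(s.positions_kb, 1)} kb "
          f"-> {r:.2f} kb/min")
print(f"FP mean rate over {len(rates)} genes: {mean_rate_one_decimal(rates)} kb/min")
print("Both estimators read the wavefront displacement per minute; agreement "
      "with the planted speed validates the calling rules.")
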