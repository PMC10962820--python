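"""Full PRM verification chain: transition-level peak QC (ppm, points across
peak, minimum fragments, truncation), calibration, LOQ-censored
quantification, replicate averaging, and paired statistics at FDR < 0.05."""

from deltaprot.prm import determine_linear_range, qc_peaks, quantify, verify_differential
from deltaprot.simulate import default_spike_design, simulate_calibration, simulate_prm_export

peptides = {"SSEDPNEDIVER": -1.3, "ALQDQLVLVAAK": 0.9, "TPENFPADGK": 0.0}
design = default_spike_design(sorted(peptides), spike_fmol_per_ul=1.0)

calibration = simulate_calibration(design, slope=1.0, intercept=0.0, cv=0.05, seed=3)
manifest, export_rows, truth = simulate_prm_export(design, peptides, n_patients=20,
                                                   cv=0.15, seed=3)

measurements, qc_report = qc_peaks(export_rows, min_fragments=3, min_points=8, max_ppm=10)
print(f"QC: {qc_report['n_rows']} transition rows -> {qc_report['n_accepted']} accepted "
      f"measurements ({qc_report['n_fragments_high_ppm']} high-ppm fragments dropped, "
      f"{qc_report['n_dropped_truncated']} truncated replicates superseded)")

quant_frames = []
for pep in sorted(peptides):
    curve, _ = determine_linear_range(
        calibration[calibration["peptide_sequence"] == pep], peptide=pep
    )
    quant_frames.append(quantify(measurements, curve, spike_fmol_per_ul=1.0))

import pandas as pd
quant = pd.concat(quant_frames, ignore_index=True)
results = verify_differential(quant, manifest, alpha=0.05, seed=3)

print("\npeptide            true   median log2 FC  [95% CI]          FDR     %changed")
for pep, row in results.iterrows():
    print(f"{pep:18s} {peptides[pep]:+.1f}   {row['median_log2_fc']:+.2f}           "
          f"[{row['ci_lo']:+.2f}, {row['ci_hi']:+.2f}]   {row['fdr']:.1e}  "
          f"{row['pct_changed']:.0f}%")
# The injected shifts are recovered in sign and magnitude; the null peptide's
# FDR stays high and its confidence interval straddles zero.
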