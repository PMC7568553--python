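# Default study configuration: acquisition-method constants, controlled-sample
# compositions, and full-scale system-suitability acceptance criteria.
dia_method:
  mz_start: 400.0
  mz_end: 1210.0
  window_width: 15.0
  scans_per_subcycle: 18
  ms1_cycle_time: 1.7
  ms2_cycle_time: 5.2

design:
  composition_A: {human: 0.65, yeast: 0.15, ecoli: 0.20}
  composition_B: {human: 0.65, yeast: 0.30, ecoli: 0.05}
  composition_QC: {human: 1.0}

qc_criteria:
  peak_width_band: [14.0, 20.0]
  ms1_points_band: [8, 11]
  ms2_points_band: [3, 4]
  min_precursors: 48000
  min_proteins: 5000
  max_median_cv: 15.0
  fdr_q: 0.01

organism_patterns:
  fasta:
    human: [sapiens, human]
    yeast: [cerevisiae, yeast]
    ecoli: [coli]
  accession_suffix:
    human: _HUMAN
    yeast: _YEAST
    ecoli: _ECOLI

report_columns:
  peak_width: EG.PeakWidth
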