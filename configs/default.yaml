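# Full default configuration for the cfdeconv pipeline.
# Any subset may be overridden in a user config; CLI flags override both.

paths:
  regions: null      # BED3+1 cluster definitions
  atlas: null        # atlas CSV prefix ({prefix}.csv + {prefix}.columns.csv)
  manifest: null     # samples manifest CSV

thresholds:
  cfdna_min: 0.40            # cfDNA/total-DNA gate (inclusive, exploratory default)
  etf_min: 0.30              # estimated-tumor-fraction gate (inclusive)
  min_depth_per_cpg: 1       # reads required for a CpG to contribute
  min_cpgs_per_cluster: 3    # CpGs required for a cluster beta
  min_clusters: 50           # floor on clusters shared by sample and atlas
  cnv_z: 3.0                 # |z| threshold for aberrant bins
  cnv_min_bins: 5            # consecutive aberrant bins per called segment
  min_panel_median: 10.0     # mask bins with lower panel median (scaled counts)

binsize: 400000              # bp, CNV bin grid
seed: 0

simulate:
  n_tumor_entities: 8
  n_regions: 2000
  markers_per_entity: 40
  margin: 0.5
  mean_coverage: 30
  cpgs_per_region: 4
  fractions: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
  samples_per_fraction: 10
  total_mass_ng: 10.0
  seed: 0
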