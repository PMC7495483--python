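{
  "_comment": [
    "Reference parameter table for the single-cell clock network, transcribed from the",
    "published ensemble summaries. Columns: 'det' = deterministic (macroscopic) ensemble",
    "means; 'counts' = the same values converted to molecular-number units; 'pt_mean'/'pt_se'",
    "= parallel-tempering ensemble (D/D experiment, 1591 cells); 'ga_mean'/'ga_se' =",
    "genetic-algorithm (PSO) + Metropolis-Hastings ensemble over all four experiments",
    "(D/D + 6 h, 12 h, 36 h L/D days). The 'ga' column is the canonical parameter set used",
    "throughout this package. Entries listed under '_ambiguous' could not be transcribed",
    "unambiguously from the source typography (run-together digit columns); the stored value",
    "is the reading most consistent with the surrounding rows and the source's prose, and",
    "none of the flagged cells other than the ga means of u_r0, S1 and D1 are consumed",
    "numerically by this package."
  ],
  "_ambiguous": ["u_r0.pt_se", "u_r0.ga_se", "u_r1.pt_se", "u_p.pt_se", "f_p.pt_se",
                 "w.counts", "g_r.pt_se", "S1.counts", "S1.ga_mean", "D1.ga_mean",
                 "D6.ga_mean", "Sc.ga_mean"],
  "parameters": {
    "u_r0": {"det": 3.99924113, "counts": 2156.7057, "pt_mean": 2868.1460, "pt_se": 32.54, "ga_mean": 2491.944, "ga_se": 9.3283},
    "u_r1": {"det": 0.44244118, "counts": 22.46137677, "pt_mean": 0.872953544, "pt_se": null, "ga_mean": 266.5025, "ga_se": 1.24742302},
    "u_p":  {"det": 4.24e-07, "counts": 459.0, "pt_mean": 2144.149238, "pt_se": 68.74768856, "ga_mean": 267.75, "ga_se": 1.41999973},
    "f_0":  {"det": 0.3563651, "counts": 0.0, "pt_mean": 0.465055176, "pt_se": 0.01143672, "ga_mean": 0.33333333, "ga_se": 0.00785783},
    "f_1":  {"det": 0.0824576, "counts": 0.0, "pt_mean": 0.534944824, "pt_se": 0.01143672, "ga_mean": 0.6666667, "ga_se": 0.00785783},
    "f_r":  {"det": 4.9e-06, "counts": 3.0, "pt_mean": 159.15869679, "pt_se": 2.637452857, "ga_mean": 263.66667, "ga_se": 1.53551295},
    "f_p":  {"det": 3.0804345, "counts": 2534.3363, "pt_mean": 1177.7211, "pt_se": 43.25, "ga_mean": 258.83333, "ga_se": 0.96610217},
    "w":    {"det": 9.24126, "counts": 10.0, "pt_mean": 155.40042039, "pt_se": 1.674320488, "ga_mean": 280.11306, "ga_se": 1.34419102},
    "g_0":  {"det": 0.00661951, "counts": 0.0, "pt_mean": 0.71623752, "pt_se": 0.010337149, "ga_mean": 0.5, "ga_se": 0.00833449},
    "g_1":  {"det": 2.59e-06, "counts": 0.0, "pt_mean": 0.28376248, "pt_se": 0.010337149, "ga_mean": 0.5, "ga_se": 0.00833449},
    "g_r":  {"det": 1.17e-06, "counts": 2.0, "pt_mean": 635.6784025, "pt_se": 21.030258983, "ga_mean": 234.41667, "ga_se": 1.45223506},
    "g_p":  {"det": 1.37e-05, "counts": 10.0, "pt_mean": 259.1907514, "pt_se": 4.920903774, "ga_mean": 283.93833, "ga_se": 1.01849186},
    "A":    {"det": 0.000658482, "counts": 6.06e-13, "pt_mean": 2.56e-10, "pt_se": 7.31e-12, "ga_mean": 2.24e-10, "ga_se": 1.1e-11},
    "Abar": {"det": 0.546986, "counts": 0.546986, "pt_mean": 1.589532708, "pt_se": 0.035661845, "ga_mean": 0.6046986, "ga_se": 0.01326434},
    "S1":   {"det": 0.061594783, "counts": 83.70771546, "pt_mean": 80.12566921, "pt_se": 0.302471515, "ga_mean": 82.372323, "ga_se": 1.03259487},
    "S3":   {"det": 0.00146575, "counts": 3.569116497, "pt_mean": 0.400641074, "pt_se": 0.036565894, "ga_mean": 13.491623, "ga_se": 0.42722599},
    "S4":   {"det": 2.2396, "counts": 5453.449297, "pt_mean": 8316.020583, "pt_se": 100.285218, "ga_mean": 877.524423, "ga_se": 1.13421469},
    "D1":   {"det": 0.723678, "counts": 0.723678, "pt_mean": 1.294999006, "pt_se": 0.0302896167, "ga_mean": 1.2760416, "ga_se": 2.63473865},
    "D3":   {"det": 0.299703, "counts": 0.299703, "pt_mean": 4.382612039, "pt_se": 0.181101578, "ga_mean": 6.16109147, "ga_se": 0.17691415},
    "C1":   {"det": 0.0428595, "counts": 4.81e-05, "pt_mean": 0.000932789, "pt_se": 2.47e-05, "ga_mean": 9.22e-05, "ga_se": 4.25e-06},
    "L1":   {"det": 31.7758, "counts": 4.244678204, "pt_mean": 4.777735371, "pt_se": 0.106626479, "ga_mean": 2.60684774, "ga_se": 0.04948995},
    "L3":   {"det": 3.02387, "counts": 0.485087349, "pt_mean": 0.665600817, "pt_se": 0.011127036, "ga_mean": 0.09315913, "ga_se": 0.00269597},
    "D4":   {"det": 0.00323262, "counts": 0.00323262, "pt_mean": 0.08474029, "pt_se": 0.004700587, "ga_mean": 0.05674687, "ga_se": 0.00194278},
    "D6":   {"det": 0.15183, "counts": 0.15183, "pt_mean": 0.193685712, "pt_se": 0.002236097, "ga_mean": 12.0326238, "ga_se": 0.28052851},
    "D7":   {"det": 0.138387, "counts": 0.138387, "pt_mean": 2.130911791, "pt_se": 0.090030385, "ga_mean": 0.11260178, "ga_se": 0.00432734},
    "D8":   {"det": 0.00248668, "counts": 0.00248668, "pt_mean": 0.007744621, "pt_se": 0.000182717, "ga_mean": 0.00014153, "ga_se": 3.61e-06},
    "C2":   {"det": 0.162687246, "counts": 0.162687246, "pt_mean": 1.515554675, "pt_se": 0.077548547, "ga_mean": 95.9668318, "ga_se": 3.1203002},
    "P":    {"det": 19.5648, "counts": 3.12e-11, "pt_mean": 2.72e-09, "pt_se": 4.83e-11, "ga_mean": 3.46e-08, "ga_se": 6.82e-10},
    "Ac":   {"det": 4.06813, "counts": 7.82e-09, "pt_mean": 1.86e-08, "pt_se": 2.55e-09, "ga_mean": 3.44e-05, "ga_se": 1.89e-06},
    "Bc":   {"det": 2.52197, "counts": 2.52197, "pt_mean": 2.581096866, "pt_se": 0.040197442, "ga_mean": 0.88230334, "ga_se": 0.0199371},
    "Sc":   {"det": 1.01e-06, "counts": 73.80414613, "pt_mean": 61.51499414, "pt_se": 1.10962971, "ga_mean": 311.0853255, "ga_se": 0.25892314},
    "Lc":   {"det": 1.15e-08, "counts": 2.231095711, "pt_mean": 1.61524392, "pt_se": 0.017335914, "ga_mean": 0.01161864, "ga_se": 0.00012954},
    "Dcr":  {"det": 0.219758, "counts": 0.219758, "pt_mean": 0.150810052, "pt_se": 0.00291715, "ga_mean": 0.27129774, "ga_se": 0.00638981},
    "Dcp":  {"det": 0.696903, "counts": 0.696903, "pt_mean": 0.54063952, "pt_se": 0.006141903, "ga_mean": 0.0224811, "ga_se": 0.00035852},
    "fIL":  {"det": null, "counts": null, "pt_mean": null, "pt_se": null, "ga_mean": 16.4900328, "ga_se": 0.38777036}
  },
  "measured_ratios": {"rna_dna": 128.7, "prot_dna": 412.0}
}
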