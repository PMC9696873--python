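# Example analysis configuration for `retestkit analyze --config ...`.
# Every key is optional; defaults shown are the package defaults.

trials_path: data/trials.csv        # long-format trial CSV
hops_path: data/hops.csv            # hop-level CSV (reactive hops only)

# map canonical column names to your file's headers (canonical: yours)
schema:
  subject_id: athlete
  value: measurement

session_order: [S1, S2, S3]         # default: lexical sort of labels

# which variables/rules to analyse; default: everything present,
# Avg + Hv (Avg + Lv for hop_contact_time)
variables: [peak_torque, grip_force, jump_height, peak_power,
            hop_peak_force, hop_contact_time]
rules:
  peak_torque: [avg, highest]
  hop_contact_time: [avg, lowest]

# session comparisons; default: all sessions plus every pair
comparisons:
  - [S1, S2, S3]
  - [S1, S2]
  - [S1, S3]
  - [S2, S3]

alpha: 0.05                 # significance level for gates, bias test, ICC CI
swc_multiplier: 0.2         # smallest worthwhile change = multiplier * SD_pooled
cv_method: per_subject      # or: pooled
levene_center: mean         # or: median
sd_pool_method: per_session # or: centered_cells
seed: 0
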