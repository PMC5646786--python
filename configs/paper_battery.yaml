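# Published comparison battery: every row with printed (a, b, v) sizes.
# a = comparison pool, b = counterpart pool, v = observed overlap,
# universe_n = assumed shared protein-coding gene count.
# Domesticate-pool rows use a = 691 (cat+dog+cattle+horse union);
# wolf/wisent rows are tested against the AMH pool (a = 742).
universe_n: 19500
mc_reps: 0
seed: 20171018

comparisons:
  - label: dom_vs_amh
    a: 691
    b: 742
    v: 41
  - label: dom_vs_amh_prufer
    a: 691
    b: 108
    v: 9
  - label: dom_vs_amh_prufer_racimo
    a: 691
    b: 419
    v: 24
  - label: dom_vs_chimp
    a: 691
    b: 415
    v: 16
  - label: dom_vs_orangutan
    a: 691
    b: 500
    v: 20
  - label: dom_vs_gorilla
    a: 691
    b: 426
    v: 12
  - label: amh_vs_wolf_stronen_t2
    a: 742
    b: 32
    v: 3
  - label: amh_vs_wolf_stronen_s3
    a: 742
    b: 70
    v: 0
  - label: amh_vs_wolf_stronen_s5
    a: 742
    b: 33
    v: 1
  - label: amh_vs_wolf_pilot
    a: 742
    b: 32
    v: 1
  - label: amh_vs_wisent_gautier
    a: 742
    b: 425
    v: 11
  - label: amh_vs_wisent_wang
    a: 742
    b: 72
    v: 3
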