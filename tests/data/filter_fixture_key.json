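{
 "n_records": 50,
 "final_kept": [
  108,
  118,
  126,
  134,
  224,
  304,
  354,
  362,
  574,
  584,
  834,
  846,
  878,
  930,
  940,
  955,
  1155,
  1355,
  1595,
  1795,
  1885,
  2295,
  2797,
  2812,
  2852
 ],
 "strict_kept": [
  108,
  126,
  134,
  224,
  304,
  354,
  362,
  584,
  794,
  834,
  866,
  878,
  930,
  940,
  955,
  1355,
  1555,
  1795,
  1835,
  2585,
  2597,
  2797,
  2812,
  2852,
  2860,
  2875,
  2900
 ],
 "final_then_cluster_kept": [
  224,
  304,
  354,
  362,
  574,
  584,
  834,
  846,
  878,
  1155,
  1355,
  1595,
  1795,
  1885,
  2295,
  2797,
  2812,
  2852
 ]
}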