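{
  "shank_dc": {
    "channel_id": "shank_dc",
    "I": 8.964627403200394,
    "J": 6.007839119076163,
    "m": 1,
    "n": 1
  },
  "shank_ac": {
    "channel_id": "shank_ac",
    "I": 5.959120656113432,
    "J": 2.2017941524412916,
    "m": 2,
    "n": 1
  },
  "thigh_dc": {
    "channel_id": "thigh_dc",
    "I": 11.970331050022903,
    "J": 8.006761085223529,
    "m": 1,
    "n": 1
  },
  "thigh_ac": {
    "channel_id": "thigh_ac",
    "I": 7.962714040707129,
    "J": 3.0021414768858166,
    "m": 2,
    "n": 3
  }
}
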