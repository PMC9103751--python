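{
  "model": {
    "embedding_dim": 32,
    "recurrent_hidden": 32,
    "conv_channels_per_width": 16,
    "dropout": 0.0
  },
  "training": {
    "batch_size": 32,
    "strategy": "gradnorm"
  }
}
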