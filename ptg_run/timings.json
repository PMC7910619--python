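{
  "step1_gibbs_s": 0.023311126999942644,
  "step2_expand_s": 0.0003389640000932559,
  "step3_finetune_s": 0.0031741250002141896
}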