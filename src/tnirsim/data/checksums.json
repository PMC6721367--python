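{
 "chromophores.csv": "81bfcee2e8fc51d20f27b8a96a382f40ebdc82bacbe7e9254c63533ceb25b5d9",
 "optical.csv": "4763b203921c6df38e9accdbc02852a977fb7f7eba95f971002197cd86484c8e",
 "perfusion.csv": "e052eb46e7c143a3b6d0d6d334f0449328565df1fc2e45afdee5c9d50462ff75",
 "thermal.csv": "efafb414200e3a1c73d2506a0f9cc29180e37f6cc68cab5a73ab9edf6b03b91a",
 "whole_tissue.csv": "d8b4f16f0ba9d2cc53b72c5d0d81f4628b78d30ec119d78acf26d8313aeb835b"
}
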