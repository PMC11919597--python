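# Full-scale configuration: 64x64 FCGR input, two 32-dimensional digit
# capsules, 3 routing iterations, Adam lr 0.001 for 100 epochs.
# Training at this scale is a long single-CPU run; use configs/scaled.yaml
# for desk-scale experiments.
input_size: 64
conv_channels: [64, 256]
conv_kernel: [9, 9]
conv_stride: [1, 2]
primary_capsule_dim: 8
num_digit_capsules: 2
digit_capsule_dim: 32
routing_iterations: 3
margin_upper: 0.9
margin_lower: 0.1
margin_lambda: 0.5
reconstruction_weight: 0.0005
decoder_hidden: [512, 1024]
epochs: 100
lr: 0.001
batch_size: 32
seed: 0
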