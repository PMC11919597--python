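# Desk-scale configuration: 32x32 FCGR input and a small conv stack.
# Trains in well under a minute on a few hundred windows while keeping
# every architectural ingredient (primary capsules, routing, margin +
# reconstruction loss) intact.
input_size: 32
conv_channels: [8, 32]
conv_kernel: [5, 5]
conv_stride: [2, 2]
primary_capsule_dim: 8
num_digit_capsules: 2
digit_capsule_dim: 16
routing_iterations: 3
margin_upper: 0.9
margin_lower: 0.1
margin_lambda: 0.5
reconstruction_weight: 0.0005
decoder_hidden: [64, 128]
epochs: 25
lr: 0.001
batch_size: 32
seed: 0
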