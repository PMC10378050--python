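# Desk-scale training run on the synthetic fundus-like dataset produced by
#   drmargin synth --out-dir data/synth --counts 40,15,25,10,10 --size 64 --seed 0
data_dir: data/synth
label_csv: labels.csv
output_dir: runs/synthetic
dataset_tag: synthetic
task: multiclass
loss: angular_margin

epochs: 5
batch_size: 16
lr: 2.0e-4
tau: 0.05
m_u: 0.2
m_v: 0.1
lam: 1.0

image_size: 64
encoder: small_cnn
d_e: 64
proj_hidden: 128
d_p: 128

seed: 0
log_cadence: 10
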