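# Named culture presets for the synthetic generator.
#
# Preset parameters are *planted* quantities; the `targets` tables hold the
# observable means +/- SEM that the full analysis chain is expected to measure
# on cultures generated with the preset (used by round-trip recovery tests).
#
# Calibration notes
# -----------------
# burst_participation and independent_rate are derived jointly from the target
# global rate R, independent fraction q, mean IBI and duration T:
#   burst spikes  S_b = (1 - q) * R * T   spread over ~T/IBI bursts,
#   background    B   = q * R * T         placed as an isolated-spike process.
# The measured per-burst participation additionally includes background spikes
# captured inside the detected burst window, so the planted participation sits
# below the measured target.  Striatal presets use one spike per participant
# per burst, which is what the burst-spike budget allows.

["WT-STR"]
n_rois = 1000
frac_active = 0.14
frac_glia = 0.10
duration = 600.0
frame_rate = 20.0
mean_ibi = 17.0
burst_participation = 0.214   # 27 of 126 active; measured participation ~26%
burst_duration = 0.2
spikes_per_burst_neuron = 1.0
independent_rate = 0.0379     # ~2860 background spikes per recording
n_modules = 4
p_intra = 0.30
p_inter = 0.01
kernel_amplitude = 1.0
kernel_decay = 3.0
noise_sd = 0.05
drift_amplitude = 0.15
intra_weight = 20.0
seed = 0

["WT-STR".targets.percent_active]
mean = 14.0
sem = 2.0
["WT-STR".targets.percent_in_bursts]
mean = 26.0
sem = 2.0
["WT-STR".targets.mean_ibi]
mean = 17.0
sem = 2.0
["WT-STR".targets.global_rate]
mean = 6.3
sem = 1.0
["WT-STR".targets.independent_fraction]
mean = 76.0
sem = 2.0
["WT-STR".targets.global_efficiency]
mean = 0.23
sem = 0.02
["WT-STR".targets.community_q]
mean = 0.52
sem = 0.01
["WT-STR".targets.community_size]
mean = 26.0
sem = 3.0
["WT-STR".targets.n_connector_hubs]
mean = 20.0
sem = 3.0

["HD-STR"]
n_rois = 1000
frac_active = 0.08
frac_glia = 0.10
duration = 600.0
frame_rate = 20.0
mean_ibi = 24.0
burst_participation = 0.153   # 11 of 72 active; clears the >=10 participant floor
burst_duration = 0.1
spikes_per_burst_neuron = 1.0
independent_rate = 0.0286     # ~1240 background spikes per recording
n_modules = 4
p_intra = 0.30
p_inter = 0.01
kernel_amplitude = 1.0
kernel_decay = 3.0
noise_sd = 0.05
drift_amplitude = 0.15
intra_weight = 4.0
seed = 0

["HD-STR".targets.percent_active]
mean = 8.0
sem = 1.0
["HD-STR".targets.percent_in_bursts]
mean = 29.0
sem = 2.0
["HD-STR".targets.mean_ibi]
mean = 24.0
sem = 3.0
["HD-STR".targets.global_rate]
mean = 2.5
sem = 0.4
["HD-STR".targets.independent_fraction]
mean = 84.0
sem = 2.0
["HD-STR".targets.global_efficiency]
mean = 0.18
sem = 0.02
["HD-STR".targets.community_q]
mean = 0.57
sem = 0.02
["HD-STR".targets.community_size]
mean = 16.0
sem = 2.0
["HD-STR".targets.n_connector_hubs]
mean = 11.0
sem = 3.0

["WT-CTX"]
n_rois = 1000
frac_active = 0.31
frac_glia = 0.10
duration = 600.0
frame_rate = 20.0
mean_ibi = 10.0
burst_participation = 0.37
burst_duration = 0.3
spikes_per_burst_neuron = 1.0
independent_rate = 0.0348
n_modules = 4
p_intra = 0.30
p_inter = 0.01
kernel_amplitude = 1.0
kernel_decay = 3.0
noise_sd = 0.05
drift_amplitude = 0.15
intra_weight = 3.0
seed = 0

["WT-CTX".targets.percent_active]
mean = 31.0
sem = 4.0
["WT-CTX".targets.mean_ibi]
mean = 10.0
sem = 1.0
["WT-CTX".targets.global_rate]
mean = 20.0
sem = 4.0

["HD-CTX"]
n_rois = 1000
frac_active = 0.29
frac_glia = 0.10
duration = 600.0
frame_rate = 20.0
mean_ibi = 9.4
burst_participation = 0.36
burst_duration = 0.3
spikes_per_burst_neuron = 1.0
independent_rate = 0.0383
n_modules = 4
p_intra = 0.30
p_inter = 0.01
kernel_amplitude = 1.0
kernel_decay = 3.0
noise_sd = 0.05
drift_amplitude = 0.15
intra_weight = 3.0
seed = 0

["HD-CTX".targets.percent_active]
mean = 29.0
sem = 3.0
["HD-CTX".targets.mean_ibi]
mean = 9.4
sem = 0.6
["HD-CTX".targets.global_rate]
mean = 20.0
sem = 2.0

# Disinhibition-like dynamical preset: more active neurons, larger and denser
# bursts, fewer isolated spikes.  Parameter preset only, no pharmacodynamics.
["BIC-like"]
n_rois = 1000
frac_active = 0.30
frac_glia = 0.10
duration = 600.0
frame_rate = 20.0
mean_ibi = 25.0
burst_participation = 0.50
burst_duration = 0.5
spikes_per_burst_neuron = 2.0
independent_rate = 0.02
n_modules = 4
p_intra = 0.30
p_inter = 0.01
kernel_amplitude = 1.0
kernel_decay = 3.0
noise_sd = 0.05
drift_amplitude = 0.15
intra_weight = 3.0
seed = 0

# NMDA-like dynamical preset: coherent network bursts disabled (mean_ibi =
# inf), raised active fraction and background rate.
["NMDA-like"]
n_rois = 1000
frac_active = 0.25
frac_glia = 0.10
duration = 600.0
frame_rate = 20.0
mean_ibi = "inf"
burst_participation = 0.0
burst_duration = 0.2
spikes_per_burst_neuron = 1.0
independent_rate = 0.10
n_modules = 4
p_intra = 0.30
p_inter = 0.01
kernel_amplitude = 1.0
kernel_decay = 3.0
noise_sd = 0.05
drift_amplitude = 0.15
intra_weight = 3.0
seed = 0
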