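# Frozen reference configuration: the published-methods constants.
# Every stage of the pipeline defaults to these values.

[acquisition]
frame_rate = 20.0        # frames/s
duration = 600.0         # s (10-min recordings)

[roi_detection]
normalize_percentiles = [20.0, 30.0]
blur_sigma = 7.0         # px
threshold = 0.08
opening_size = 4         # px, square structuring element
min_pixels = 10
connectivity = 8

[trace_normalization]
boxcar = 5               # frames, causal square window
block_s = 50.0           # baseline reference block
baseline_percentile = 10.0
spline_lam = 1e6         # smoothing-spline stiffness

[spike_reconstruction]
kernel_amplitude = 1.0   # %dF/F0
kernel_decay = 3.0       # s
rise_lag = 3             # frames
rise_frac = 0.35         # of kernel amplitude
max_rate = 10.0          # spikes/s sustained cap

[burst_detection]
window_s = 1.0
hi_frac = 0.10
lo_frac = 0.05
merge_gap_s = 0.5
min_participants = 10
bursty_ibi_cutoff_s = 45.0
theta_active = 2         # spikes per recording to call a neuron active

[network_inference]
markov_order = 2
instant_feedback = true
significance_sd = 2.0    # mean + 2 SD of the joint row/column distribution
min_active_neurons = 25  # inference refused at or below this count

[topology]
louvain_resolution = 1.0
louvain_restarts = 10
z_hub = 1.5
p_hub = 0.3

[statistics]
outlier_iqr_multiplier = 1.5
alpha = 0.05
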