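# Settings for the large-scale female-wolverine application: scat-based
# noninvasive genetic sampling on a 2-km search grid across Norway,
# analysed with local state-space evaluation.  The detection data
# themselves are an external deposit (DRYAD doi:10.5061/dryad.42m96c8) and
# must be converted by the user to the package's generic CSV schema
# (detectors: detector_id,x,y ; detections: individual_id,detector_id).
#
# All lengths are in km (the unit declaration is metadata only; the model
# is unit-agnostic).
unit: km
sigma: 6.0                 # half-normal scale for female wolverines, ~6 km
detector_resolution: 2.0   # searched 2-km grid cells are the detectors
ac_width_in_sigma: 5.0     # AC evaluation window width = 5 sigma = 30 km
extension_in_sigma: 2.0    # detector window extends 2 sigma = 12 km beyond
buffer_width: 12.0         # 2 sigma habitat buffer around the searched area
n_chains: 3
n_iter: 3000
n_adapt: 1000
thin: 3
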