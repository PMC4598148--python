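# Study-replica cohort: 9 MMP-ACPP + 8 thrombin-ACPP rabbits, 286 aortic
# segments of which exactly 47 are disrupted.  FER and open-view plaque
# distributions follow the published group means +- SD; RR is moderately
# informative and GdR deliberately uninformative (identical class
# distributions).  Segment counts: 17 per rabbit, last rabbit trimmed to 14
# so the cohort totals 286.
arms:
  - probe: MMP_ACPP
    n_rabbits: 9
    segments_per_rabbit: 17
    fer_disrupted: [4.5, 1.0]
    fer_nondisrupted: [2.2, 1.0]
    fer_openview_plaque: [4.0, 1.1]
    thrombus_to_plaque_signal_ratio: 0.5
    rr_disrupted: [1.08, 0.12]
    rr_nondisrupted: [1.00, 0.08]
    gdr_disrupted: [1.3, 0.25]
    gdr_nondisrupted: [1.3, 0.25]
  - probe: THROMBIN_ACPP
    n_rabbits: 8
    segments_per_rabbit: 17
    fer_disrupted: [5.0, 1.1]
    fer_nondisrupted: [2.5, 1.1]
    fer_openview_plaque: [6.8, 2.0]
    thrombus_to_plaque_signal_ratio: 0.5
    rr_disrupted: [1.08, 0.12]
    rr_nondisrupted: [1.00, 0.08]
    gdr_disrupted: [1.3, 0.25]
    gdr_nondisrupted: [1.3, 0.25]
axial_segment_length_mm: 4.0
mri_slice_pitch_mm: 4.0
replica_mode: true
n_disrupted: 47
total_segments: 286
seed: 1
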