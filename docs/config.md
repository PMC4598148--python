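# Cohort configuration schema

A cohort configuration is a YAML (or JSON) mapping loaded by
`plaqrisk.load_config`.  The shipped study-replica calibration lives at
`configs/study_replica.yaml`.

## Top level (`CohortConfig`)

| key | type | default | meaning |
|---|---|---|---|
| `arms` | list of arm mappings | required | one entry per probe arm |
| `axial_segment_length_mm` | float > 0 | 4.0 | axial segment length |
| `mri_slice_pitch_mm` | float > 0 | 4.0 | MRI slice pitch (3 mm slice + 1 mm gap) |
| `seed` | int | 0 | root RNG seed; fixed (config, seed) ⇒ byte-identical output |
| `replica_mode` | bool | false | exact-count vs per-segment-probability disruption |
| `n_disrupted` | int ≥ 0 | — | replica mode: exact disrupted count, drawn uniformly among targeted-arm segments |
| `total_segments` | int | — | replica mode: trims the last rabbit so the cohort totals exactly this many segments |
| `disruption_probability` | float in [0, 1] | — | probability mode: independent per-segment coin |

Exactly one of `n_disrupted` (with `replica_mode: true`) or
`disruption_probability` (with `replica_mode: false`) must be given.

## Per arm (`ArmConfig`)

| key | type | default | meaning |
|---|---|---|---|
| `probe` | `MMP_ACPP` \| `THROMBIN_ACPP` \| `PEG_ACPP` | required | probe identity; `PEG_ACPP` arms are excluded from the replica disrupted draw |
| `n_rabbits` | int ≥ 1 | required | rabbits in the arm |
| `segments_per_rabbit` | int ≥ 1 | 17 | aortic segments per rabbit |
| `fer_disrupted` | [mean, sd] | [4.5, 1.0] | closed-view FER, disrupted segments |
| `fer_nondisrupted` | [mean, sd] | [2.2, 1.0] | closed-view FER, non-disrupted segments |
| `fer_openview_plaque` | [mean, sd] | [4.0, 1.1] | open-view underlying-plaque FER at disrupted sites |
| `thrombus_to_plaque_signal_ratio` | float in (0, 1) | 0.5 | detached-thrombus signal as a fraction of the plaque's |
| `rr_disrupted` / `rr_nondisrupted` | [mean, sd] | [1.08, 0.12] / [1.00, 0.08] | remodeling-ratio multipliers |
| `gdr_disrupted` / `gdr_nondisrupted` | [mean, sd] | [1.3, 0.25] / [1.3, 0.25] | Gd enhancement ratios |

All `[mean, sd]` quantities are sampled from normals truncated to (0, ∞);
means must be positive and SDs non-negative.
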