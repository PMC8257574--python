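# File formats

All tabular/structural data travel as versioned JSON documents; volumes as
NIfTI. Coordinates are world-frame millimetres throughout; voxel indices are
0-based with voxel centres at `origin + index · spacing`.

## Coronary tree — `corflow-tree/1`

```json
{
  "schema": "corflow-tree/1",
  "artery_label": "LAD",
  "branches": [
    {
      "branch_id": "LAD",
      "parent_id": null,
      "attach_index": null,
      "label": "LAD",
      "points": [[x, y, z], ...],
      "radii": [r0, r1, ...]
    }
  ]
}
```

* Exactly one branch has `parent_id: null` (the root) and must carry a
  main-artery label (`LAD`, `LCx` or `RCA`); other branches are labelled
  `SIDE` (or a main label for the main vessel's continuation).
* `attach_index` indexes into the parent's `points` (1 … n−1) where the
  branch originates.
* `points` and `radii` have equal length ≥ 2; all radii positive;
  consecutive points distinct.

A bundle of the three main trees uses `corflow-trees/1`:
`{"schema": "corflow-trees/1", "trees": {"LAD": <tree>, ...}}`.

## Lesions — `corflow-lesions/1`

```json
{"schema": "corflow-lesions/1",
 "lesions": [{"branch_id": "LAD", "s_start": 12.0, "s_end": 22.0,
              "severity": 55.0, "profile": "cosine"}]}
```

`s_start`/`s_end` are arc-length positions (mm) on the branch; `severity`
is percent diameter reduction at the lesion midpoint, in [0, 100).

## Patient record — `corflow-patient/1`

```json
{"schema": "corflow-patient/1", "patient_id": "p1",
 "sbp_mmhg": 120.0, "dbp_mmhg": 80.0,
 "measured_ffr": {"LAD": 0.78}, "frame_counts": {"LAD": 20},
 "vessel_lengths_mm": {"LAD": 95.5}, "myocardial_mass_g": null}
```

`measured_ffr`, `frame_counts`, `vessel_lengths_mm` are optional per-vessel
maps; `myocardial_mass_g`, when present, bypasses the mask-derived mass.

## Masks and territory labels — NIfTI

The LV mask is any 3-D NIfTI volume; nonzero voxels are occupied. Spacing
and origin are taken from the affine. Territory label volumes use integer
codes 0 = none, 1 = LAD, 2 = LCx, 3 = RCA on the mask grid.

## Evaluation pairs — CSV

Columns `vessel_id, ffr_s, ffr_m` (simulated and measured/reference FFR).

## Pipeline config — JSON

Keys mirror `corflow.config.RunConfig` fields; unknown keys are rejected.
Either `phantom_seed` (the case is generated) or explicit
`mask_path`/`trees_path`/`patient_path` (+ optional `lesions_path`).
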