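# gapdvh

Isoeffective, DVH-based compensation of radiotherapy treatment gaps.

`gapdvh` converts the physical dose-volume histograms (DVHs) of a treatment
plan into repopulation-corrected BED / EQD₂ histograms per structure, builds
and validates gap-compensation schedules under RCR/NCCP constraints (≤ 6
fractions per week, no consecutive twice-daily days, ≥ 6 h between same-day
fractions), and compares intended, uncompensated, and revised courses both
as scalar accounting tables and per-bin DVHs. A 1-D gamma analysis validates
DVH curves against a reference, and a phantom factory generates synthetic
DICOM RT Dose / RT Structure Set pairs with analytically known DVHs for
end-to-end testing without clinical data.

## Model

For a schedule of `N` fractions of `d` Gy finishing at overall time `T`
(calendar days):

    BED  = N·d·(1 + d·(1 + h)/(α/β)) − max(0, K·(T − T_delay))   (tumor)
    BED  = N·d·(1 + d·(1 + h)/(α/β))                              (OAR)
    EQD₂ = BED / (1 + 2/(α/β))

`h = 2^(−m/T½)` is the incomplete-repair factor for two same-day fractions
`m` hours apart (0 when `m` > 8 h; 0 for tumors at the recommended ≥ 6 h
interval). The per-bin DVH conversion replaces `d` with the variable dose
per fraction `D_i/N` in each dose bin, optionally splitting the course into
session groups with different `h` (twice-daily versus single-fraction days).
Repopulation loss is attributed to segments cumulatively, so a small
post-gap segment can legitimately carry a negative BED.

## CLI

```sh
# synthesize a phantom (DICOM RT Dose + RT Structure + expected DVH tables)
gapdvh phantom --config phantom.yaml -o phantom_out/

# physical DVHs -> EQD2 DVHs + statistics table for each contoured structure
gapdvh convert phantom_out/rtdose.dcm phantom_out/rtstruct.dcm \
    --config convert.yaml -o converted/

# scalar plan comparison (intended vs uncompensated vs revised)
gapdvh compare --config plans.yaml -o comparison/

# gamma analysis between two DVH tables (reference first)
gapdvh gamma ref_dvh.csv eval_dvh.csv --delta-d 0.01 --delta-v 0.01 -o gamma/
```

Example `plans.yaml`:

```yaml
tissue: {preset: tumor_c1}          # alpha/beta=10, K=0.9 Gy/day, T_delay=28 d
reference: intended
plans:
  intended:
    segments:
      - {label: full, n: 35, d: 2.0, t_end: 50}
  uncompensated:
    segments:
      - {label: pre-gap, n: 6, d: 2.0, t_end: 9}
      - {label: post-gap, n: 29, d: 2.0, t_end: 63}
```

Tissue presets (`tumor_c1`, `oar_generic`, `spinal_cord`) live in
`src/gapdvh/data/tissue_presets.yaml` and can be overridden with
`--presets`.

## Layout

- `src/gapdvh/radiobiology.py` — LQ conversions, repopulation, `h`, per-bin
  DVH conversion, tissue presets
- `src/gapdvh/dvh.py` — DVH construction from dose grids, statistics
  (Dmean, D_x%, D_xcc, V_xGy), relative/absolute rescaling
- `src/gapdvh/dicom_io.py` / `_dicom.py` — RT Dose / RT Structure Set
  read/write, contour rasterization, plain-text DVH tables
- `src/gapdvh/phantom.py` — synthetic phantoms with closed-form DVHs and the
  five interrupted-course case studies
- `src/gapdvh/planner.py` — calendars, schedule validation/building, plan
  evaluation, 1-D point-dose method
- `src/gapdvh/gamma.py` — DVH gamma analysis
- `src/gapdvh/cli.py` — the `gapdvh` command
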