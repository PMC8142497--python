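# greyblood

Simulation and reconstruction pipeline for free-breathing 3D **grey-blood
PSIR** late gadolinium enhancement (LGE) cardiac MRI with dual-echo Dixon
water/fat separation and image-navigator respiratory motion correction.

## The problem

LGE imaging detects myocardial scar as bright tissue on T1-weighted
inversion-recovery images. Conventional "bright-blood" LGE nulls healthy
myocardium, but subendocardial scar then borders an equally bright blood
pool and can be missed. Choosing the inversion time to null the **blood**
instead renders blood mid-grey on a phase-sensitive (PSIR) reconstruction —
myocardium dark, scar bright — and sharpens the scar-blood interface.
Doing this in free-breathing 3D requires: a variable-density Cartesian
spiral-like phase-encode schedule (VD-CASPR) acquired over interleaved
IR-prepared / reference heartbeats, per-heartbeat 2D image navigators
(iNAVs) to track translational respiratory motion, k-space phase-shift
motion correction with 100% scan efficiency (no data rejection), iterative
(CG) SENSE reconstruction of the four echo/volume images, two-point Dixon
water/fat separation with B0 estimation and unwrapping, and transfer of the
PSIR signal polarity onto the separated water image.

This package implements that full chain against its own Bloch-simulated
digital phantoms, so every stage is tested against a known ground truth:

- `greyblood.phantom` — vial and cardiac-like phantoms, synthetic coil
  maps, respiratory motion traces
- `greyblood.trajectory` — golden-angle VD-CASPR schedule generation
- `greyblood.sequence` — Mz recursion of the interleaved segmented IR/
  reference spoiled-GRE Dixon sequence, null-TI search
  (`find_null_ti` ≈ T1·ln 2 in the ideal limit), k-space acquisition
  simulator with iNAVs, motion, coils, noise
- `greyblood.motion` — iNAV reconstruction, NCC template-matching motion
  estimation, linear-phase k-space correction
- `greyblood.sense` — coil-map estimation, CG-SENSE, rigid inter-echo
  registration
- `greyblood.dixon` — magnitude-cue B0 estimation with region-growing
  unwrapping, algebraic two-point separation
- `greyblood.psir` — intermediate in-phase PSIR, polarity transfer,
  grey-blood assembly
- `greyblood.metrics` — ROI contrast ratio / CNR, Bland-Altman
- `greyblood.pipeline`, `greyblood.cli` — end-to-end orchestration and a
  `greyblood` command-line tool

The core reconstruction identity is `psir_water = polarity × water`, where
`polarity = sign(Re(IR·e^{-iθ})/(B+ε))` comes from the intermediate PSIR
between the in-phase IR and reference volumes (θ: low-pass reference phase;
B: low-pass reference magnitude for surface-coil normalization), computed
*before* Dixon separation because separation discards the sign.

## Worked example

Null the blood pool and reconstruct a motion-corrupted grey-blood volume:

```python
import greyblood as gb
from greyblood.pipeline import PipelineConfig, run_pipeline

seq = gb.SequenceParams(ti=300.0)          # protocol timing, placeholder TI
ti_blood = gb.find_null_ti(384.0, seq, search=(150.0, 500.0, 0.5))
print(ti_blood)                            # 260.9 ms (blood T1 = 384 ms)

cfg = PipelineConfig(
    phantom=gb.cardiac_spec(shape=(48, 48, 24), blood_radius_mm=16.0,
                            wall_thickness_mm=10.0),
    seq=dict(ti=float(ti_blood)),
    seed=1,
)
res = run_pipeline(cfg)
print(res.efficiency_percent)              # 100.0
for name, rep in res.reports.items():
    print(name, round(rep.cr, 2), round(rep.cnr, 1))
```

Output of the metrics loop (display-normalized PSIR, nulled tissue at 0.5):

```
scar_vs_blood 1.75 9.2
scar_vs_myocardium 5.65 17.6
blood_vs_myocardium 3.23 8.4
```

Compartment display means land where grey-blood contrast puts them:
myocardium 0.15 (dark, inverted), blood 0.50 (grey, nulled), scar 0.87
(bright) — so the scar-blood border is carried by a 0.37 display-level step
instead of the bright-blood regime where both are high. Every acquired shot
contributed to the reconstruction (100% respiratory scan efficiency); the
estimated per-shot displacements, all volumes, field maps and a provenance
log with checksums are written when `out_dir` is set, or from the shell:

```bash
greyblood pipeline --config config.yaml --seed 1 --out results/
```

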