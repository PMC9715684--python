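# ttmkit

Single-photon time-tagging data path and analysis toolkit: a bit-exact
codec for an FPGA time-tagger's 16-bit word stream, sliding-scale TDC
calibration, event-table pre-processing, and the two downstream
applications — super-resolved fluorescence-lifetime image scanning
microscopy (FLISM) and fluorescence-lifetime fluctuation spectroscopy
(FLFS) — plus a physics simulator that generates synthetic word streams
with known ground truth, so the whole pipeline is testable without
hardware.

## Layout

| module               | role                                                            |
|----------------------|-----------------------------------------------------------------|
| `ttmkit.words`       | 16-bit word codec, event-filter semantics, `.ttm` stream files  |
| `ttmkit.simulate`    | decay/SYLAP/scan/diffusion simulators, TDL model, stream builder|
| `ttmkit.calibrate`   | code-density calibration, DNL/INL, start–stop reconstruction, SSP, channel alignment |
| `ttmkit.tables`      | counter unwrapping, reverse start–stop matching, scan coordinates, HDF5 tables |
| `ttmkit.flism`       | 4D binning, adaptive pixel reassignment, lifetime maps, phasors, FRC |
| `ttmkit.flfs`        | weighted timestamp correlator, FLCS filters, point/circular FCS fits, diffusion law |

### Data path

```
simulate (ground truth) ──► .ttm word stream ──► decode ──► event tables (HDF5)
                                                    │
                                   calibration (code density) ──► calibrated tables
                                                    │
                                 ┌──────────────────┴──────────────────┐
                              FLISM (images, τ maps, FRC)         FLFS (G(τ), fits)
```

Word format: each 16-bit word is a 7-bit identifier, a 1-bit valid flag
and an 8-bit payload.  A frame is 5 header words (ids 123–127 in order:
REF flags + sync-valid, SYNC tap code, STEP low byte, STEP high byte,
spare) followed by one word per channel hit, zero-suppressed.  Stream
files carry a 4-byte `TTM1` preamble and little-endian words.

## CLI

```sh
ttm simulate scene.yaml -o run.ttm --truth truth.h5   # synthetic stream
ttm decode run.ttm -o tables.h5                       # stream -> event tables
ttm calibrate tables.h5 -o calib.h5                   # code-density calibration
ttm flism tables.h5 --calib calib.h5 --nx 64 --ny 64 -o flism.h5
ttm flfs tables.h5 --calib calib.h5 --mode circular --radius 0.5 -o flfs.h5
```

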