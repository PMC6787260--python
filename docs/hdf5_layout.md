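# Photon-data HDF5 container

The native container for photon-event streams and decoded images. All
datasets are written with `track_times=False`, so identical data produce
byte-identical files. Field names are bit-exact as listed.

## Photon stream (`write_stream` / `read_stream`)

```
/events/macro_time   int64   photon arrival, clock ticks (20 MHz default)
/events/micro_time   int32   TCSPC bin index; -1 where absent (CW detection)
/events/channel      int16   detector / router channel id
/markers/kind        int8    0 = pixel, 1 = line, 2 = frame
/markers/macro_time  int64   marker arrival, clock ticks
/meta@clock_hz       float   macro-time clock frequency
/meta@metadata       str     JSON-encoded free-form acquisition descriptors
```

`macro_time` is non-decreasing within `/events` and within `/markers`.
A file missing any of the three groups, or `clock_hz`, is rejected with a
`FormatError` naming the missing field.

## Line-scan matrix (`write_linescan` / `read_linescan`)

```
/counts                      int     [n_lines x n_pixels] photon counts
/counts@line_period_s        float
/counts@pixel_size_um        float
/counts@dropped_photons      int     photons outside all line intervals
```

## FLIM decay stack (`write_flim_image` / `read_flim_image`)

```
/decay                       int     [ny x nx x n_bins]
/decay@pixel_size_um         float
/decay@bin_width_ns          float
/decay@dropped_photons       int     out-of-gate photons
/decay@metadata              str     JSON
```

## CSV export (small fixtures)

`stream_to_csv` writes one row per record with columns
`record` (`event`|`marker`), `macro_time`, `micro_time`, `channel`,
`marker_kind`; intended for tiny human-readable fixtures, not bulk data.
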