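# puretone

Air-conduction pure-tone audiometry for smartphone-class hardware, as a
Python library with a small CLI. The package implements the complete
test/calibrate/evaluate loop of a self-administered hearing test — the kind
of tool that lets people screen their own hearing thresholds with a phone
and a wired earphone — and pairs it with a virtual-listener simulator so
the whole pipeline can be exercised, validated and calibrated without
human subjects or audio hardware.

It is aimed at audiology and psychoacoustics researchers prototyping
mobile audiometry, and at engineers who need a reference implementation of
the clinical threshold-seeking procedure and its calibration arithmetic.

## What it implements

**Threshold tracking.** The modified Hughson-Westlake adaptive staircase:
start at 30 dB HL, ascend in 10 dB steps until first heard, then descend
10 dB after every heard response and ascend 5 dB after every miss. The
hearing threshold is the level of the first heard response in an ascending
run once three reversals have occurred. Levels span −10 to 80 dB HL
(75 dB HL at 250 Hz, limited by transducer output); a miss at the ceiling
records a NO_RESPONSE sentinel. Six octave frequencies (0.25–8 kHz) are
tested per ear.

**Level conversion.** Hearing level and sound pressure level are linked by
the per-frequency, per-transducer reference equivalent threshold sound
pressure level (RETSPL):

```
dB SPL = dB HL + RETSPL(f)
```

RETSPL tables for ER-3A insert earphones (the ANSI S3.6 reference) and for
a smartphone-earphone combination before and after calibration are
packaged.

**Calibration.** Given paired thresholds from a reference audiometer and
the device on the same ears, the device's RETSPL table is corrected by the
per-frequency median difference:

```
RETSPL_new(f) = RETSPL_old(f) − median_ears(HL_audiometer − HL_device)
```

The median is used because threshold differences are not normally
distributed and it resists outliers. Agreement is quantified by pooled
Spearman rank correlation and per-frequency mean absolute error.

**Session rules.** Masking: a tone at L dB SPL can cross to the non-test
ear at L − IA (interaural attenuation, minimum clinical assumption 40 dB),
so masking noise of at least that level is required there. Ambient noise:
the test pauses when the background level exceeds 40 dB SPL. Audiograms
are labelled with the ASHA severity bands (normal ≤ 25 dB HL, mild 26–40,
moderate 41–55, moderately severe 56–70, severe 71–90, profound > 90).

**Signals.** Calibrated continuous pure tones and one-third-octave masking
noise, rendered against measured full-scale device output levels
(2-cc-coupler values for three iPhone models are packaged), plus an
unweighted RMS level meter. Audio is written as uncompressed WAV.

**Virtual listeners.** Subjects with per-ear, per-frequency true
thresholds and either deterministic or logistic psychometric response
models (threshold, steepness, guess and lapse rates), with cohort builders
for simulation studies.

## Worked example

```python
from puretone import (packaged_retspl_tables, hl_to_spl, run_session,
                      VirtualListener, TEST_FREQUENCIES)
from puretone.listeners import EARS

tables = packaged_retspl_tables()
print(hl_to_spl(30, 2000, tables["HearTest v2"]).value)
# 37.3  -> a 30 dB HL tone at 2 kHz must be emitted at 37.3 dB SPL

listener = VirtualListener(
    thresholds={(ear, f): 40.0 for ear in EARS for f in TEST_FREQUENCIES},
    model="step",
)
audiogram = run_session(listener)
entry = audiogram.entries[("right", 1000)]
print(entry.threshold_dbhl, entry.category)
# 40.0 mild  -> the staircase recovers the 40 dB HL threshold exactly,
#               which falls in the ASHA "mild" band (26-40 dB HL)
print([level for level, _ in audiogram.histories[("right", 1000)]])
# [30.0, 40.0, 30.0, 35.0, 40.0, 30.0, 35.0, 40.0]
#   the classic track: miss at 30, heard at 40, two descend/ascend
#   sweeps confirming 40 dB HL on ascending runs
```

The same workflows are available from the shell:

```
puretone simulate-test --n-listeners 20 --seed 1 --out runs/b1
puretone calibrate --pairs pairs.csv --transducer "HearTest v1" --out cal/
puretone report runs/b1/audiogram_L000.json --plot audiogram.png
puretone device-spread
puretone render-tone --freq 1000 --level-spl 80 --out tone.wav
```

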