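# radiofix

Computation stack for **automated VHF wildlife radiotracking** with
four-antenna amplitude-comparison stations, plus a synthetic RF scene
simulator so the whole pipeline can be exercised and validated without
hardware or field data.

It is aimed at movement ecologists and engineers working with networks of
fixed receiving stations that listen for pulsed telemetry transmitters
(the classical "beep" tags glued to bats, birds or small mammals): each
station multiplexes four directional antennas pointing N/E/S/W, detects
the pulse train of each tag, converts the four per-antenna signal
strengths into a bearing and a range estimate, and time-coincident
bearings from several stations are triangulated into positions.

## The method

Signal strengths are handled in **dBa** (dB referenced to one attowatt,
= dBm + 150); azimuths are degrees clockwise from north.

1. **Pulse detection.** The four antenna streams (round-robin sampled,
   ~4 ms per antenna, ~15 ms per cycle) are averaged per cycle and the
   mean-subtracted series is correlated against a periodic rectangular
   comb built from the known pulse timing (period searched over a ±3 %
   tolerance window). The match yields on-pulse and off-pulse RSSI
   means; their difference is the signal-to-noise ratio S/N and a
   reading is accepted when S/N exceeds the acceptance threshold
   (default 3.3 dB, calibrated per deployment).
2. **Bearing.** Each antenna's gain is sinusoidal in dB,
   G(Δ) = C + S·cosΔ. Relabelling the four on-pulse values about the
   strongest antenna (F front, L/R neighbours, Re rear, K = front
   antenna rotation) and reconstructing the unreliable rear lobe as
   Re = L + R − F gives the exact inversion

       ΔBRG = atan2(R − L, F − Re),       BRG = K + ΔBRG

   and the boresight strength RSSImax = C̄ + (F − C̄)/cos ΔBRG with
   C̄ = (L+R)/2. A tabulated per-station calibration vector (from a
   rotation experiment) is subtracted from every bearing.
3. **Ranging.** DIST = A·B^RSSImax, with A and B fitted per deployment
   from beacon transmitters at known distances (ordinary least squares
   in log space). Readings above 100 dBa (receiver overload) are
   excluded; 45–100 dBa is the stable performance band.
4. **Localisation.** Fixes of one channel falling in the same tumbling
   time window (default 60 s) are combined: every station pair
   contributes the intersection of its two bearing rays and the position
   is the centre of gravity (area centroid) of the convex hull of all
   mutual intersections. Lone fixes become single-station positions via
   the range model. Post-processing offers the 100 % minimum convex
   polygon and a feeding/search activity budget.

The scene simulator (`radiofix.scene`) provides ground-truthed inputs
for all of this: free-space + Fresnel-obstruction propagation,
sinusoidal antenna patterns with optional tabulated distortion, antenna
multiplexing, duty-cycled pulsed transmitters, moving trajectories and
seeded Gaussian receiver noise in dB.

## Worked example

Describe a deployment in YAML (two noisy stations 2 km apart, one tag
pulsing 0.2 s every 1 s at (700, 900) m — see
`tests/test_schedule_io.py` for the full schema), then run the chain:

```sh
radiofix simulate --config deployment.yaml --station north \
    --transmitter bat01 --duration 10 --out rec.csv --truth-out truth.csv
# INFO radiofix: wrote 2664 samples, 10 pulses
radiofix detect --in rec.csv --period 1.0 --pulse-duration 0.2 --out det.csv
# INFO radiofix: snr=83.73 dB valid=True
radiofix bearing --in det.csv --config deployment.yaml --out fixes.csv
cat fixes.csv
# station_id,time_s,channel_khz,bearing_deg,delta_brg_deg,rssi_max_dba,snr_db,valid
# north,0.001875,150000.0,36.586,36.586,113.722,83.728,True
```

The S/N of 83.7 dB says the pulse train sits far above the noise floor,
so the fix is valid; the estimated bearing 36.6° compares with the true
azimuth 37.9° recorded in `truth.csv` — about a degree of error from the
2 dB receiver noise. RSSImax ≈ 113.7 dBa is the strength an antenna
aimed straight at the tag would have read, the input to ranging.

The `pipeline` command chains every stage over the scan schedule and
triangulates across stations:

```sh
radiofix pipeline --config deployment.yaml --duration 120 --window-s 60 \
    --out positions.csv
cat positions.csv
# time_s,channel_khz,east_m,north_m,n_stations,method
# 50.0,150000.0,711.18,916.15,2,triangulated
# 110.0,150000.0,714.01,881.74,2,triangulated
```

Both positions land within ~20 m of the true (700, 900) m under 2 dB of
per-sample noise.

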