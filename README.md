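# epiclim

Space-time structure analysis for disease case series, with a synthetic
data generator that makes every stage testable against ground truth.

Given a case table (onset date, home coordinates, clinical covariates) the
package provides:

- **Temporal clusters** (`epiclim.clusters`) — two-stage construction: a day
  is a *cluster day* when any 7-day moving window containing it holds ≥ 4
  onsets; clusters are maximal unbroken runs of cluster days with their
  member cases. Significance of the cluster count comes from a Monte Carlo
  null that redistributes the same number of cases over the period with the
  observed monthly seasonality (t-based and empirical rank p-values).
- **Excess Knox statistic** (`epiclim.knox`) — for every threshold pair
  (τ days, δ km), the count X of case pairs close in both time and space is
  compared with the independence expectation E = N_T·N_S/M; excess =
  (X − E)/E. The permutation null shuffles case locations against fixed
  onset dates; p-values are upper-tail.
- **Climate anomaly composites** (`epiclim.composites`) — day-of-year
  climatology (running-mean smoothed, multi-year), daily anomalies, and
  event-lagged composite maps (lag bins around the date of onset) for four
  event-date groups (no-case days, all case days, non-cluster case days,
  cluster case days) and three seasons (ALL, DJFMA, MJJA), with per-cell
  t-statistic significance masks.
- **Clinical trait structure** (`epiclim.traits`) — forward-window
  conditional medians (the median trait value among cases with onset in the
  10 days strictly after a reference case) regressed on the reference
  value, binned medians, and a spatial label-permutation test for binary
  traits (mean pairwise distance among positives, lower tail).
- **Synthetic data** (`epiclim.simulate`) — seasonal inhomogeneous
  background cases plus episodic bursts (clumped in time and space, with
  burst-shared trait shifts and an optional binary-trait spatial hotspot),
  and gridded climate fields (seasonal cycle + AR(1) noise + additive
  anomaly coupled to event days). Fully seeded and deterministic.

Input formats: cases as CSV (`case_id, onset_date, lat, lon` plus optional
`age, sex, esr, anc, crp, ggt_elevated, illness_day`; ISO dates, empty
string = missing); gridded fields as CF-style NetCDF with (time, lat, lon)
daily axes.

## Command line

```sh
# synthetic bundle: cases.csv (+ ground-truth burst_id) and climate.nc
epiclim simulate --out-dir demo --n-expected 300 --burst-rate 3 --seed 1

# temporal clusters + seasonal Monte Carlo test
epiclim clusters --cases demo/cases.csv --window 7 --min-cases 4 \
    --null-reps 500 --seed 1 --out-dir demo

# excess Knox grid with permutation p-values (optional heatmap)
epiclim knox --cases demo/cases.csv --reps 999 --seed 1 \
    --out demo/knox.csv --plot demo/knox.png

# event-lagged anomaly composites per case group
epiclim composites --cases demo/cases.csv --fields demo/climate.nc \
    --variable tmax --season ALL --confidence 0.95 --out-dir demo

# trait autocorrelation and spatial label test
epiclim traits --cases demo/cases.csv --trait age --window 10 --out-dir demo
epiclim spatial-label --cases demo/cases.csv --label ggt_elevated \
    --reps 999 --seed 1 --out demo/spatial_label.json

# everything at once from a YAML config (see RunConfig fields)
epiclim run --config run.yaml
```

`epiclim run` writes a `manifest.json` recording parameters, seeds, input
digests and every output file; reruns with the same config are
deterministic.

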