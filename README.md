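# compchip

Estimation of transcription-factor chromatin **residence times** from
competition ChIP time courses, using a physical model of competitive
binding, plus the downstream transcription-efficiency statistics.

## The problem

In a competition ChIP experiment an inducible, alternatively tagged copy of
a transcription factor (the *competitor*, B) is switched on at *t* = 0 and
competes with the constitutively expressed endogenous copy (A) for the same
chromatin sites.  Two-color arrays report the competitor/endogenous ChIP
ratio at each probe over a series of induction times.  Because a site can
only change its occupant when the bound protein dissociates, the rate at
which the ChIP ratio follows the rising soluble concentration ratio encodes
the dissociation rate k_d — equivalently the residence time
t<sub>1/2</sub> = ln2 / k_d — at every binding site.  The canonical design
is TBP (TATA-binding protein) in budding yeast, where residence times from
about 1.3 to 53 minutes are resolvable.

## The model

Soluble induction is described by a Hill sigmoid
ρ(t) = ρ<sub>∞</sub> · tⁿ/(tⁿ + t<sub>ind</sub>ⁿ) with n = 4; the fitted
constants for the TBP design are ρ<sub>∞</sub> = 2.23 and
t<sub>ind</sub> = 22 min.  Fractional occupancies obey mass-action
competitive binding with shared rates (the two copies are the same
protein):

    dθ_A/dt = k_a (1 − θ_A − θ_B) − k_d θ_A
    dθ_B/dt = k_a ρ(t) (1 − θ_A − θ_B) − k_d θ_B

with the endogenous concentration absorbed into k_a (both rates in 1/min).
The observable θ_B/θ_A always saturates at ρ<sub>∞</sub> and, in the dilute
regime, is nearly insensitive to k_a, so only k_d is estimated.

Per locus, estimation proceeds through: array preprocessing (dye-swap
geometric averaging, background normalization against a truncated-normal
fit of the unenriched probes, BH-FDR signal-probe selection, peak-level
aggregation); sigmoid scaling that removes the locus background B and the
antibody-affinity scale α so the series satisfies the model's boundary
conditions; then a three-stage kinetic fit — a closed-form *ideal
induction* fit, bias correction through a pre-generated lookup table, and
one-dimensional Newton refinement against the exact ODE — finished by a
joint variable-projection refinement of (k_d, B, α).  Downstream,
transcriptional efficiency TR·t<sub>1/2</sub> (RNA molecules per binding
event), KS contrasts between promoter classes, Spearman correlations and
label-permutation tests with BH-FDR control reproduce the comparative
statistics.

A synthetic-data module generates complete probe-level datasets with known
ground truth, so every stage is testable without any external download.

## Worked example

```sh
python examples/02_estimate_residence_time.py
```

```
true residence time: 9.0 min

noiseless:
  ideal-induction fit  t1/2 =  20.00 min (biased)
  final estimate       t1/2 =   9.00 min (k_d = 0.0770/min, stages: ideal -> lookup -> newton)
sigma_log2 = 0.1:
  ideal-induction fit  t1/2 =  20.30 min (biased)
  final estimate       t1/2 =   9.30 min (k_d = 0.0745/min, stages: ideal -> lookup -> newton)
```

The ideal-induction fit alone overestimates the residence time badly (20 vs
9 min) because the competitor actually needs ~60 min to reach steady state;
the lookup-table correction and Newton refinement recover the true value
exactly on noiseless data and to ~3% under realistic array noise.  The
other scripts in `examples/` show the forward model
(`01_simulate_occupancy.py`), the full probe-to-residence-time pipeline on
synthetic arrays (`03_full_pipeline.py`, median error ~11%, rank
correlation 0.98 with truth), and the downstream statistics
(`04_downstream_stats.py`, e.g. median Pol II efficiency ≈ 0.2 molecules,
i.e. ~5 binding events per RNA).

## Command-line pipeline

Every stage is also a subcommand exchanging TSV artifacts, which makes runs
reproducible and resumable:

```sh
compchip all --out run/ --seed 1 --n-loci 200
# or stage by stage:
compchip simulate   --out run/data --seed 1
compchip preprocess --probes run/data/probes.tsv --peaks run/data/peaks.bed --out run/series.tsv
compchip scale      --series run/series.tsv --induction run/data/induction.tsv --out-dir run/
compchip fit        --series run/series.tsv --induction-fit run/induction_fit.tsv \
                    --bias-table run/bias_table.tsv --out run/kinetic_fits.tsv
compchip stats      --fits run/kinetic_fits.tsv --annotations run/data/annotations.tsv \
                    --tf-table run/data/tf_presence.tsv --out-dir run/
```

Outputs carry provenance headers (version, config hash, seed) and are
byte-identical across reruns with the same seed.

## Layout

- `src/compchip/` — the library: `induction`, `preprocess`, `scaling`,
  `kinetics`, `pipeline`, `stats`, `synthetic`, `io`, `cli`
- `examples/` — narrative scripts, one per capability
- `tests/` — pytest suite (unit, property and model-level acceptance tests)
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
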