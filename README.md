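# fearsemble

Analysis pipeline for studying **fear generalization** in prefrontal
neuronal ensembles and in human psychophysiology. Fear generalization —
responding to neutral or novel stimuli as if they predicted threat — is a
hallmark of trauma-related disorders. This package implements the
single-neuron and population-level analyses used to ask how prelimbic (PL)
cortex ensembles distinguish a threat-predictive conditioned tone (CS⁺)
from a neutral tone (NT), how that distinction degrades under
endocannabinoid (2-AG) depletion, and how plasma 2-AG relates to
fear-potentiated startle generalization in humans.

It is written for systems-neuroscience users who have neuron × time
calcium activity matrices (e.g. CNMF-E output), tone/shock event
schedules, freezing series, two-channel fiber-photometry recordings, or
trial tables of startle EMG amplitudes — and for methodologists who want
every stage testable against synthetic data with planted ground truth.

## What it computes

**Peri-tone z-scoring** (`fearsemble.align`). Traces sampled at 10 Hz are
aligned to tone onset, averaged into 1-s bins over a 15-s pre-tone
baseline plus the 15-s tone, averaged into blocks of 2 presentations, and
z-transformed per neuron × block against that block's own baseline
(unbiased SD):

    z[b] = (x[b] − mean(baseline)) / sd(baseline)

**Responsive-neuron taxonomy** (`fearsemble.respond`). A neuron is
(+)responsive to a tone if z exceeds +3 for any 2 consecutive bins during
the tone, (−)responsive below −3; with 3 patterns {+, −, 0} per stimulus
and 2 stimuli there are 3² = 9 response types. Dual-responsive = both
labels non-zero. Group differences in type proportions use Fisher's exact
test.

**Stimulus preference** (`fearsemble.prefer`). Per neuron, with Z_NT and
Z_CS⁺ the average whole-session-normalized tone-period z-scores,

    |Z_NT − Z_CS⁺| / (|Z_NT| + |Z_CS⁺|)

signed positive when |Z_NT| > |Z_CS⁺| and negative otherwise; group
distributions compared by two-sample Kolmogorov–Smirnov test.

**Response clustering** (`fearsemble.cluster`). Concatenated NT/CS⁺
z-traces are rescaled ([−5, 5] saturating onto [−3, 3]), Ward-linked with
Euclidean metric, cut at 5% of the maximum linkage height, and cluster
profiles are remapped to the unscaled z-traces.

**Population geometry** (`fearsemble.popgeo`). Time-binned population
vectors (neurons as features, size-matched across treatment groups by
seeded subsampling) are reduced by PCA; NT-vs-CS⁺ trajectory separation
is measured per bin by the Mahalanobis distance of each NT point to the
CS⁺ point cloud (shrinkage-regularized covariance) and by the
instantaneous Euclidean distance over the first 15 components.

**Behavior and photometry** (`fearsemble.behavior`, `.photometry`).
Freezing percent per interval, blocks of 2 tones, neutral/reference
generalization index; isosbestic-corrected ΔF/F, per-trial z against the
2-s pre-tone baseline, and pooling of trials that elicited > 75% vs < 25%
freezing.

**Human startle/endocannabinoids** (`fearsemble.human`). Peak-to-peak
startle EMG standardized by each subject's mean ITI startle, CS
generalization = (CS⁻) − (CS⁺) over the first 4 recall trials per cue,
log-transformed 2-AG baselines (mean of two time points), and the
Pearson association with a 1,000-resample bootstrap CI on the regression
slope.

**Synthetic ground truth** (`fearsemble.synthdata`). Sessions with
neurons drawn from known archetypes (NT-only, CS⁺-only, dual, suppressed,
mixed, non-responsive), photometry with transient amplitude planted as a
decreasing function of trial freezing, and human cohorts with a planted
correlation between log 2-AG and generalization — so every stage above
has a parameter-recovery test.

## Worked example

```python
from fearsemble import align, prefer, respond, synthdata
from fearsemble.io import EventType

pop = synthdata.PopulationSpec(
    n_neurons=200,
    archetype_fractions={"cs_plus": 0.25, "dual_plus": 0.10, "none": 0.65},
    response_amplitude=6.0,
    seed=42,
)
sess = synthdata.SessionSpec(n_nt_tones=2, n_cs_tones=2)
traces, schedule, truth = synthdata.generate_session(pop, sess)

t_nt = align.peri_tone_tensor(traces, schedule, EventType.NT)
t_cs = align.peri_tone_tensor(traces, schedule, EventType.CS_PLUS)
taxonomy = respond.response_taxonomy(
    respond.classify_tensor(t_nt), respond.classify_tensor(t_cs), traces.neuron_ids
)
props = respond.taxonomy_proportions(taxonomy)
print(f"dual-responsive: {100*props['dual_proportion']:.1f}%")
print(f"CS+-only (+):    {100*props['proportions']['NONE/PLUS']:.1f}%")
print(f"non-responsive:  {100*props['proportions']['NONE/NONE']:.1f}%")
```

prints

```
dual-responsive: 10.0%
CS+-only (+):    25.5%
non-responsive:  64.5%
```

— the classifier recovers the planted composition (10% dual, 25%
CS⁺-only, 65% none) from raw noisy traces. Continuing with the preference
index separates single-stimulus from dual archetypes:

```python
z_nt, _ = align.ztransform_whole_session(traces, schedule, EventType.NT)
z_cs, _ = align.ztransform_whole_session(traces, schedule, EventType.CS_PLUS)
table = prefer.preference_table(z_nt, z_cs, traces.neuron_ids).merge(truth, on="neuron_id")
```

gives a median |preference| of 1.00 for CS⁺-only neurons (fully
selective) versus 0.11 for dual-responsive neurons (near-complete
generalization of the response).

A command-line interface mirrors the library
(`fearsemble simulate session|photometry|cohort`, `fearsemble align`,
`fearsemble respond`, `fearsemble behavior`, `fearsemble photometry`,
`fearsemble human`, `fearsemble run --config cfg.yaml`); see
`fearsemble --help` and `fearsemble init-config` for a starting
configuration.

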