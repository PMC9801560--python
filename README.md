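# pbdtss

**DNA-breathing statistics fused with string kernels for transcription start
site (TSS) prediction.**

Double-stranded DNA is not static: thermal fluctuations transiently open
single base pairs and runs of adjacent pairs ("denaturation bubbles"), and
these openings are implicated in transcription initiation.  `pbdtss` turns a
base sequence into equilibrium opening and bubble probabilities under the
Peyrard–Bishop–Dauxois (PBD) mesoscopic model, and uses those physical
profiles — on their own or averaged with a weighted-degree string kernel on
the raw sequence — as precomputed kernels for a soft-margin SVM that
separates true TSS windows from gene-body decoys.

It is aimed at researchers in regulatory genomics and DNA biophysics who
want (a) an exact, fast transfer-integral engine for PBD opening/bubble
statistics of arbitrary sequences, and (b) a reproducible
imbalance-aware benchmark pipeline that fuses the physical and sequence
views of a candidate site.

## The model in brief

Each base pair `n` carries one stretching coordinate `y_n` (Å) with energy

```
U = V₁(y₁) + Σᵢ [ Vᵢ(yᵢ) + W(yᵢ, yᵢ₋₁) ]
V(y) = D (e^{−αy} − 1)²  +  Θ(y) · b y³ / cosh²[c(αy − d ln 2)]
W(y, y′) = ½ K (1 + ρ e^{−δ(y+y′)}) (y − y′)²
```

— a Morse well plus re-closing barrier per pair (AT vs GC constants) and an
anharmonic stacking coupling per ordered dimer whose stiffness collapses from
`K(1+ρ)` to `K` on opening.  Because the chain is one-dimensional, every
constrained partition function is an iterated one-dimensional integral: the
probability that pair `j` is closed in the double-stranded ensemble is

```
P(j closed) = Z(j closed) / (Z_I − Z_II)
```

and the engine likewise yields the exact-size bubble matrix `P_bub(k, m)` and
the participation profile `P_part(k, m)` (the probability of sitting inside a
bubble of ≥ m pairs).  A classifier instance is a 201-base sequence window
plus the 200 central values of `P_part(k, m)` over a 300-base physics window;
kernels: weighted-degree (sequence), RBF (profile), and their equal-weight
unit-diagonal-normalized average (hybrid).  See `docs/methods.md` for the
complete account.

## Worked example

Breathing profiles at 345 K — an AT-rich repeat against homopolymers:

```python
from pbdtss import TransferIntegrator, QuadratureGrid, profile_for_window

engine = TransferIntegrator(temperature=345.0, grid=QuadratureGrid(n_points=600))
seq = "TATAAAAGGC" * 30                     # a 300-base physics window
prof1 = profile_for_window(seq, 345.0, m=1, integrator=engine)   # opening
prof8 = profile_for_window(seq, 345.0, m=8, integrator=engine)   # bubbles >= 8
print(round(float(prof1.values.mean()), 4))   # 0.3557
print(round(float(prof8.values.mean()), 4))   # 0.3334

at = profile_for_window("A" * 300, 345.0, m=1, integrator=engine)
gc = profile_for_window("G" * 300, 345.0, m=1, integrator=engine)
print(round(float(at.values.mean()), 4))      # 0.978
print(round(float(gc.values.mean()), 4))      # 0.001
```

Each call returns the 200 central per-base probabilities (the 50 boundary
values on each side are trimmed).  The AT-rich repeat breathes heavily
(mean opening 0.36), poly(AT) at 345 K is close to melting (0.98), and
poly(GC) stays shut (0.001) — the compositional contrast the classifier
exploits.

A small synthetic classification run (50 positives / 500 negatives train,
50/500 held-out test; positives carry a degenerate TATA-like motif *and*
elevated central AT content):

```python
from pbdtss.pipeline import ExperimentConfig, SyntheticSpec, run_experiment

config = ExperimentConfig(
    temperatures=(345.0,), replicates=3, folds=5, seed=7,
    synth=SyntheticSpec(n_pos=50, n_neg=500, test_n_pos=50, test_n_neg=500),
)
summary, detail = run_experiment(config)
print(summary[["kernel", "auROC_mean", "auROC_ci95", "G_mean_mean",
               "Sn_mean", "Sp_mean"]].round(4).to_string(index=False))
```

```
     kernel  auROC_mean  auROC_ci95  G_mean_mean  Sn_mean  Sp_mean
sequence-WD      0.9835      0.0057       0.8935   0.8067   0.9907
profile-RBF      0.8882      0.0177       0.8219   0.8533   0.7927
     hybrid      0.9479      0.0063       0.8812   0.9067   0.8573
```

The sequence kernel reads the planted motif, the profile kernel reads the
physics (no sequence alignment involved), and the hybrid fuses both views.
auROC is the threshold-free ranking quality; G-mean = √(Sn·Sp) summarises the
thresholded classifier on the imbalanced test split; ± values are 95 %
intervals over undersampling replicates.

The same pipeline is scriptable from the shell:

```
pbdtss synth --out-dir data/ --n-pos 200 --n-neg 2000 --seed 1
pbdtss profile data/windows300.fasta --out profiles.tsv -t 345 -m 8
pbdtss experiment --out report.tsv -t 345 --seed 1
```

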