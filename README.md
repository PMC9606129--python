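# bbphi — Gaussian integrated information for body–brain time series

`bbphi` treats a small set of simultaneously recorded physiological signals —
respiration (RES), heartbeat (ECG), skin conductance (EDA) and four midline
EEG channels (Fz, Cz, Pz, Oz) — as **one** stochastic system, and quantifies
how irreducible that system is to its parts using integrated information
under mismatched decoding (the Gaussian, continuous-variable formulation
often called IIT 2.0).  It is written for experiments such as the rubber
hand illusion, where the scientific question is whether a body-ownership
manipulation changes the *interaction structure* between body and brain
rather than any single signal.

## The quantities it computes

For a channel set *S* with lagged state pair (X(t−τ), X(t)) modelled as
jointly Gaussian:

* **Mutual information**  I(X(t−τ); X(t)) — everything the past says about
  the present.
* **Mismatched-decoding information**  Ĩ(β) for a bipartition π of *S*: the
  information that survives when the decoder q(X(t)|X(t−τ)) is forced to
  factorise across the blocks of π, maximised over the decoding
  "temperature" β.  Its maximum I* never exceeds I.
* **Integrated information**  Φ\*(π) = I − I\*: the information lost by
  cutting π.
* **MIP / Φ_MIP** — the bipartition minimising Φ\* (the system's weakest
  link) and its value:  π_MIP = argmin_π Φ\*(π),  Φ_MIP = Φ\*(π_MIP).
* **Complexes and main complexes** — subsets T with Φ_MIP(T) > 0 exceeding
  every superset (complexes), and complexes containing no smaller complex
  (main complexes, the information cores).  ΣΦ over main complexes measures
  subsystem integrity.
* **Subject score**  s(Φ_MIP): per subject, the sum over stimulus-phase
  windows of the baseline-subtracted SYNC-minus-ASYNC difference in ΣΦ over
  main complexes — the quantity correlated with questionnaire ratings.

The sliding-window pipeline turns a 900 s, 250 Hz, 7-channel recording into
900 per-second Φ/complex results (window 250 frames, shift 250 frames,
lag τ = 50 frames by default), labels them pre/stim/post by thirds,
detrends, and feeds the group statistics: Welch phase contrasts, MIP-cut and
main-complex frequency shifts, and Pearson correlations with the
questionnaire-based illusion index (mean of items Q1–Q3 per condition).

Because no public recordings exist for this paradigm, the package ships a
first-class synthetic cohort generator: stable vector-autoregressive
dynamics over the seven channels with cross-channel interactions at a 50
frame delay, stimulus-phase coupling changes (occipital decoupling,
body↔brain decoupling, EDA↔RES strengthening) scaled per subject and per
condition, and ratings tied to each subject's effect size.

## Worked example

```python
import numpy as np
from bbphi import estimate_lagged_model, mip_search, summarize_complexes
from bbphi.synthetic import SimConfig, simulate_recording
from bbphi.pipeline import WindowConfig, run_subject

cfg = SimConfig(n_subjects=2, frames=9000, seed=0)
rec = simulate_recording(cfg, 0, "SYNC")          # 36 s toy block

model = estimate_lagged_model(rec.data[1000:1250], tau=50, labels=rec.labels)
res = mip_search(model)
print(f"I = {res.mutual_info:.3f} nats, Phi_MIP = {res.phi_mip:.3f}, "
      f"cut = {res.mip.key(rec.labels)}")

rep = summarize_complexes(model)
print(f"complexes: {rep.n_complexes}, sum Phi over main complexes = "
      f"{rep.sum_main_phi:.3f}")
```

Output:

```
I = 0.490 nats, Phi_MIP = 0.066, cut = Cz
complexes: 3, sum Phi over main complexes = 0.254
```

Read: the window carries 0.49 nats of past→present information; the weakest
cut (here the vertex channel against the rest) loses only 0.066 nats, so
the system is weakly but genuinely integrated; its main complexes together
hold 0.254 nats of internal integration.

The same flow from the shell:

```bash
bbphi simulate --subjects 2 --frames 25000 --out cohort/
bbphi analyze cohort/recordings/*.csv --stride 10 --out results/
bbphi stats --series-dir results/ --ratings cohort/ratings.csv --out results/
bbphi report --results-dir results/
```

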