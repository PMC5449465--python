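# statebmi

State-dependent spike-count decoding and closed-loop simulation of a
bidirectional brain–machine interface (BMI).

Cortical responses to a fixed stimulus vary from trial to trial, and a large
part of that variability tracks the *network state* — endogenous fluctuations
of excitability visible in the ongoing activity just before the stimulus.
`statebmi` implements and evaluates decoders that exploit this: a
bidirectional BMI in which the position of a simulated point mass is encoded
as one of four intracortical-microstimulation patterns (s₁…s₄), the evoked
cortical response is decoded back into a force, and decoding optionally
conditions on pre-stimulus ongoing activity. The package targets
methodologists who want a fully synthetic, reproducible testbed for
state-dependent decoding: no animal data are required — a calibrated
generator produces spike sessions with the statistical structure the method
assumes.

## The method

For each trial *m*, spike trains are binned into a pre-stimulus count matrix
Θᵐ (adaptive schedule: 39 bins, coarse far from onset down to 5 ms at onset)
and a post-stimulus response matrix Rᵐ (uniform 5 ms bins starting after the
30 ms stimulation-artifact blank). Three feature variants are decoded:

* **SI** (state-independent): aᵐ = vec(Rᵐ);
* **SD-TA**: Rᵐ plus each unit's time-averaged pre-stimulus activity;
* **SD-TD**: Rᵐ plus the full pre-stimulus time course Θᵐ.

The decoder is PCA (k components, fit on the training fold) followed by
multiclass LDA with a shrinkage-regularized shared covariance; posteriors
P(s_d | aᵐ) are sharpened by a winner-take-all rule when max_d P > P_thr.
Performance is the mutual information of the soft confusion matrix
Q(s_d | s_i) (columns = mean posterior per presented stimulus),

    I(S; D) = Σ_{d,i} P(s_i) Q(s_d|s_i) log₂ [ Q(s_d|s_i) / Q(s_d) ],

estimated by leave-one-out cross-validation and bias-corrected by
subtracting the mean information over label-shuffled reruns of the entire
pipeline. In the closed loop, the decoded force F = Σ_d P̃(s_d|a) F_d (the
four force fields sit at the quadrant centroids of a 36 × 36 cm workspace,
pointing at the central target) drives a point mass through a viscous
medium, m dv/dt = F − b v, integrated exactly; trajectories stop on target
entry or after 100 steps.

## Worked example

```python
import statebmi as sb
from statebmi.pipeline import variant_information

session = sb.generate_session(sb.SimParams(seed=0))
for variant in ("SI", "SD-TA", "SD-TD"):
    r = variant_information(session, variant, n_shuffles=20, seed=1)
    print(f"{variant:6s} {r.corrected_bits:.3f} bits "
          f"(raw {r.raw_bits:.3f}, bias {r.bias_bits:.3f})")
```

prints (seed 0, 400 trials, 14 units):

```
SI     0.962 bits (raw 0.971, bias 0.009)
SD-TA  0.976 bits (raw 0.986, bias 0.010)
SD-TD  1.166 bits (raw 1.175, bias 0.009)
```

The state-independent decoder extracts just under one bit about the four
stimulation patterns; adding the time-averaged pre-stimulus activity helps
a little, and adding the full pre-stimulus time course (SD-TD) recovers a
further ~0.2 bits by predicting — and discounting — the excitability
fluctuation that corrupts each single-trial response.

The same comparison can be run from the shell:

```
statebmi simulate-session --seed 0 --out runs/session
statebmi fit-decode --session runs/session --variant sd-td --out runs/sdtd
statebmi run-bmi --session runs/session --variant sd-td --target-radius 1 \
    --reps 20 --out runs/bmi-sdtd
statebmi report --bmi-dir runs/bmi-sdtd --out runs/report
```

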