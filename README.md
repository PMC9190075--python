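# antescreen

A decision-tree cost-effectiveness model of screening for depression at
the first antenatal appointment, for health economists and perinatal
mental-health researchers. It compares four identification strategies —
the two Whooley questions, the Edinburgh Postnatal Depression Scale
(EPDS), the Whooley followed by the EPDS for Whooley positives, and
routine midwife assessment without a screening tool — on expected costs
(2015/16 GBP, health-and-social-care perspective) and quality-adjusted
life years (QALYs) over a nine-month horizon from booking appointment
to three months post-birth.

## The model

Each strategy classifies a woman as true positive, false positive, true
negative or false negative. For a single-stage screen with probability
of a positive result *p*₊, positive predictive value *PPV* and negative
predictive value *NPV*:

    P(TP) = p₊ · PPV          P(FP) = p₊ · (1 − PPV)
    P(TN) = (1 − p₊) · NPV    P(FN) = (1 − p₊) · (1 − NPV)

(the two-stage strategy pools stage-1 negatives with stage-1 positives
who are EPDS-negative, each stratum with its own NPV). A common
treatment pathway attaches an expected QALY *Q*ᵢ and cost *C*ᵢ to each
class: screen positives receive facilitated self-help or high-intensity
psychological therapy and respond with probability 1 − RR × AR;
depressed screen negatives may recover spontaneously (0.33) or be
identified later (0.1025) and treated. Arm value per woman is

    E[Q] = Σᵢ P(i) · Qᵢ ,   E[C] = c_screen + Σᵢ P(i) · Cᵢ .

Strategies are compared by incremental cost-effectiveness ratios
(ICER = ΔC/ΔQ) under the rules of strict and extended dominance, and by
net monetary benefit NMB(λ) = λ·Q − C. Probabilistic sensitivity
analysis samples every parameter (betas for probabilities from their
weighted event counts, gammas for costs with SE = 30% of the mean) and
summarises 5,000 Monte-Carlo iterations as cost-effectiveness
acceptability curves — the probability each arm maximises NMB across a
willingness-to-pay grid. Thirteen one-way scenarios probe the main
structural assumptions, and a synthetic-cohort microsimulation provides
a brute-force check of the analytic tree. See `docs/methods.md` for the
full specification.

## Worked example

```python
from antescreen import ScreeningModel

model = ScreeningModel()          # built-in base-case parameters
print(model.fit().summary())
```

```
Screening strategy comparison (per woman, 9-month horizon)

strategy         QALYs   cost £  status
epds            0.7305     1798  on_frontier
whooley         0.7302     1772  extended_dominated
whooley_epds    0.7302     1747  on_frontier
no_screen       0.7255     1764  dominated

Incremental analysis vs no_screen:
  whooley        ΔQALY +0.0047  Δcost £+8  ICER £1,615/QALY
  epds           ΔQALY +0.0050  Δcost £+34  ICER £6,801/QALY
  whooley_epds   ΔQALY +0.0046  Δcost £-17  ICER £-3,610/QALY
Frontier: whooley_epds -> epds
```

Reading this: all three screening strategies gain roughly 0.005 QALYs
per woman over no screening. The two-stage Whooley–EPDS is *cheaper*
than not screening (its extra false negatives avoid expensive treatment,
a saving that outweighs the second screen) and dominates it; the Whooley
alone is removed by extended dominance; EPDS buys the most health at the
highest cost. The probabilistic analysis shows how little separates the
three screening arms:

```python
print(model.fit_psa(n_iterations=5000, seed=1).summary(25000))
```

```
PSA with 5000 iterations (probability cost-effective at £25,000/QALY):
  whooley       0.253
  epds          0.262
  whooley_epds  0.263
  no_screen     0.223
```

At the conventional £20,000–£30,000/QALY threshold each screening arm
has a similar probability of being the cost-effective choice, and each
beats no screening — the practical conclusion is that the choice among
the three instruments can rest on clinical burden rather than economics.

The same analyses are available from the shell:

```sh
antescreen basecase --out results/
antescreen psa --seed 1 --iterations 5000 --plot --out results/psa
antescreen scenarios --ids all --seed 1 --iterations 2000 --out results/scenarios
antescreen simulate --n-women 200000 --seed 1 --out results/cohort
antescreen dump-defaults > params.yaml   # edit and pass back via --config
```

Each run writes CSV tables and a `manifest.json` (command, configuration
hash, seed, version) sufficient to reproduce it byte-for-byte.

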