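# registrysim

Discrete-event simulation of the hospital-level cancer-registry reporting
workflow, for public-health informatics and surveillance-timeliness
research.

US hospitals report every newly diagnosed reportable tumor to their state
cancer registry through certified tumor registrars (CTRs). The process has
three steps — case finding, abstraction, batch submission — but most of the
elapsed time is *waiting*: after a case is found it sits in a **suspense
file** for a fixed three-to-six months so that treatment data can
accumulate before abstraction. `registrysim` models that pipeline as a
discrete-event simulation and quantifies how much reporting latency is
removed by replacing the fixed wait with an EHR **treatment-completion
notification** (release each case as soon as its first treatment is
recorded, with a 6-month fallback timeout), alongside ePath case
identification.

## Model

Per case, the diagnosis-to-submission reporting time decomposes as

```
T = (t_identified − t_diagnosis)      case finding (daily pathology scan /
                                      monthly ICD disease-index scan)
  + (t_released  − t_identified)      queue policy (the intervention target)
  + (t_done      − t_released)        abstraction (U(45, 90) minutes)
  + (t_submitted − t_done)            batch residence (caseload-tiered
                                      submission boundaries)
```

The queue-release policies are

* **existing**: `t_released = t_identified + W_h`, with `W_h` a
  facility-wide constant wait in the 3–6-month band;
* **redesigned**: `t_released = max(t_identified, t_treat)` when treatment
  completes within 180 days of diagnosis, else `t_diagnosis + 180`.

Treatment waits `t_treat − t_diagnosis` are triangular per cancer type,
built from published (mean; min–max) summaries — breast (24; 14–40),
colorectal (37; 20–63), lung (26; 13–46) days — with
`mode = 3·mean − min − max` so the analytic mean matches the summary.
Case arrivals are homogeneous Poisson at the facility's annual caseload;
batch submission fires at multiples of the tier interval (annual /
quarterly / every-other-month / monthly for ≥300 cases a year).

## Worked example

```bash
registrysim --workflow both --horizon-days 365 --replicates 20 --seed 1 \
    --out runs/demo
```

prints (seed 1, shipped calibrated configuration):

```
variant       horizon       n      min     mean      max      p25      p75      sd
existing          365   40543    105.8    137.4    229.4    127.1    146.5    15.0
redesigned        365   54815     14.5     50.7    151.7     40.3     59.3    14.9
mean improvement (existing - redesigned): 86.7 days (Welch p = 9.18e-28)
```

Reading this: under the existing process a case takes on average ~137 days
from diagnosis to arrival at the state registry, ~120 of which are the
suspense-file wait; the notification redesign cuts the mean to ~51 days —
an ~87-day improvement — because most cases are released at their actual
treatment-completion time (~35 days after diagnosis under the calibrated
case mix) instead of a fixed four months. The redesigned arm submits more
cases within the year (larger `n`) for the same generated caseload.
`runs/demo/` contains per-case outcome CSVs, `summary.json`,
`comparison.json` and a run manifest.

Library use mirrors the CLI:

```python
from registrysim import calibrated_config, run_experiment

result = run_experiment(calibrated_config(seed=1))
print(result.arms["existing"].summary.mean)      # ~137.4
print(result.comparison.mean_difference)         # ~86.7
```

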