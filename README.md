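# catcad

Adaptive mental-health assessment toolkit with two engines sharing one
ordinal item bank:

- **CAT** — a computerized adaptive *severity* test. The bank is calibrated
  under the bifactor graded-response IRT model (each item loads on one
  primary dimension plus one subdomain factor). The test administers the
  most informative item at the current severity estimate, re-scores by EAP
  after every response, and stops once the posterior uncertainty drops to
  5 points on a 0–100 reporting scale (plus remaining-information,
  minimum/maximum-length and exhaustion rules). Severity categories
  (none / mild / moderate / severe) are cut at 35 / 47 / 60 by default.
- **CAD** — a computerized adaptive *diagnostic screener*. Small
  extremely-randomized-trees ensembles (2 trees, depth ≤ 3, linearly
  combined) are trained against a binary criterion diagnosis and
  administered by traversing the trees, asking each distinct item only
  once — at most 6 items per session.

Supporting modules provide validation statistics (cross-validated ROC/AUC
with DeLong intervals, sensitivity/specificity, severity-threshold
selection, Pearson correlation), a synthetic-data generator that emulates
the target study geometry (211 items over 5 subdomains, ~713 respondents,
~28% diagnosis prevalence), plain-text file formats and a CLI.

## Command line

All stages are subcommands of one entry point (`catcad --help`):

```sh
# generate a synthetic bank + responses + diagnosis labels
catcad --seed 1 --out-dir data synth

# calibrate (bifactor + unidimensional, LR test), then filter weak items
catcad --out-dir fit calibrate --bank data/bank.csv --responses data/responses.csv
catcad --out-dir fit filter    --bank data/bank.csv --responses data/responses.csv --min-loading 0.3

# simulated CAT from complete response patterns; tuning grid search
catcad --out-dir sim cat-simulate --bank fit/calibrated_bank.csv --responses data/responses.csv
catcad --out-dir sim cat-tune     --bank fit/calibrated_bank.csv --responses data/responses.csv --max-sims 50

# one interactive (or scripted) adaptive test
catcad cat-run --bank fit/calibrated_bank.csv

# train screener forms and administer one
catcad --out-dir cad cad-train --responses data/responses.csv --labels data/labels.csv
catcad cad-run --model cad/cad_form_01.json

# cross-validated AUC + severity-threshold selection for a score column
catcad --out-dir val validate --scores scores.csv --labels data/labels.csv
```

Global flags `--seed`, `--config` (strict YAML, unknown keys rejected) and
`--out-dir` come before the subcommand. Every artifact embeds a
provenance line (tool version, seed, config hash); CAT session logs are
replayable with `catcad.io.replay_session`.

## Layout

```
src/catcad/bank.py        item bank / response matrix types
src/catcad/bifactor.py    bifactor graded-response EM calibration, EAP, information
src/catcad/cat.py         adaptive severity testing, stopping rules, tuning
src/catcad/cad.py         extra-trees screening ensembles
src/catcad/evaluation.py  ROC/AUC, operating points, threshold policies
src/catcad/synthetic.py   seeded generators for banks/responses/labels
src/catcad/io.py          plain-text formats + provenance
src/catcad/config.py      strict YAML run configuration
src/catcad/cli.py         the `catcad` command
tests/                    unit, property (hypothesis) and acceptance suites
```
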