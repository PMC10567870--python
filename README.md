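# methylfluid

Forensic body-fluid identification from targeted DNA-methylation profiles.

In casework it often matters *which* secretion a DNA trace came from —
vaginal secretion versus skin cells, menstrual versus peripheral blood,
nasal secretion versus saliva — information STR typing cannot give.
`methylfluid` implements a rule-based workflow that identifies seven body
fluids (nasal secretion, nasal blood, peripheral blood, menstrual blood,
saliva, vaginal secretion, sperm secretion) and mixtures thereof, from
bisulfite-pyrosequencing methylation percentages at a six-CpG marker panel,
combined with conventional rapid pre-tests for blood, saliva and sperm.

The package is aimed at forensic geneticists who want to apply, audit or
re-calibrate the workflow, and includes everything needed to exercise it
without real samples: a synthetic-stain generator, duplicate QC, gap-based
cutoff calibration and confusion-matrix validation.

## The method

Each marker carries tiered, strictly compared thresholds on percent
methylation $m$; a tier may be conditioned on confirmed-negative pre-tests
(a pre-test that was not done never activates a conditional tier):

| marker | CpG | call |
|---|---|---|
| NB21 | cg16518142 | $m < 67$ → nasal secretion or nasal blood |
| B7 | cg13763232 | $m > 80$ → pure peripheral blood |
| MB4 | cg04255276 | $m > 21$ → menstrual blood; $m > 18$ given sperm −; $18 < m < 21$ given sperm + → menstrual blood + sperm mixture |
| SA4 | cg21597595 | $m > 35$ → saliva; $m > 18$ → saliva as partial component |
| V2 | cg26079753 | $m > 50$ → vaginal secretion; $m > 40$ given saliva −; $m > 25$ → vaginal-tract secretion present |
| N27SE | cg20864568 | $m > 75$ → sperm; nasal band $m < 70$ with lower bound 40 given sperm −, 30 also blood −, 22 also saliva − |

Classification first excludes fluids ruled out by negative pre-tests, then
applies each measured marker's tiers most-specific-first, then adds
pre-test-supported components where the methylation evidence does not
contradict them. Exclusions always win; irreducible ambiguities (e.g.
menstrual blood versus a peripheral-blood/vaginal mixture) are reported as
flags, not guesses.

The synthetic generator draws single-source values from per-(fluid, marker)
normal distributions with the reference cohort's means and SDs (clipped to
[0, 100] with the mean preserved), injects the documented outliers, models
mixtures as DNA-mass-weighted means, and emits duplicate measurements with
bounded noise so duplicates agree within the 5-point QC rule.

## Worked example

```python
from methylfluid import classify, PreTestPanel

result = classify(
    {"NB21": 90, "B7": 38, "MB4": 20, "N27SE": 51},
    PreTestPanel.from_strings("positive", "negative", "positive"),
    sample_id="handkerchief",
)
print(result.narrative())
```

prints

```
Sample handkerchief:
  Pre-tests excluded: saliva.
  NB21 = 90% (no tier fired) -> no call
  B7 = 38% (no tier fired) -> no call
  MB4 = 20% (18% < value < 21% [given sperm positive]) -> menstrual_sperm_mixture
  N27SE = 51% (no tier fired) -> no call
  Conclusion: mixture of menstrual_blood, sperm_secretion.
  Warning: markers not evaluated: SA4, V2
```

A reddish stain, blood- and sperm-positive on the rapid tests: NB21 at 90%
rules out nasal blood (nasal samples sit below 67%) and B7 at 38% rules out
pure peripheral blood (above 80%). MB4 inside the 18–21% band with a
positive sperm test identifies a menstrual-blood/sperm mixture, consistent
with N27SE at 51% (pure sperm exceeds 75%; sperm mixtures run lower). The
stain is a mixture of menstrual blood and sperm secretion.

The same pipeline is scriptable from the shell:

```sh
methylfluid simulate saliva "saliva:0.5+vaginal_secretion:0.5" --count 20 --seed 7 --out sheet.csv
methylfluid qc sheet.csv
methylfluid classify sheet.csv --narrative
methylfluid validate sheet.csv   # labeled cohorts only
```

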