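# spatialcog

Cognitive models of **spatial relational reasoning**, evaluated at the level
of the individual reasoner.

People read premises such as *"Frankfurt is south-west of Amsterdam.
Amsterdam is north-east of Paris."* and draw (or verify) a conclusion about
the outer pair of terms.  Mental-model theories hold that reasoners build a
spatial arrangement of the terms — a *mental model* — inspect it, and
sometimes search for alternatives.  This package implements the main
computational instantiations of that family and the apparatus needed to test
how well each one predicts the responses of a *specific* person rather than
an aggregate:

* **SpatialReasoner** — incremental 3-D coordinate models.  Integrating a
  putative assertion yields one of four outcomes (*truth*, *falsity*,
  *weak falsification*, *weak truthification*), and four predictive variants
  interpret them: *skeptical* (accept only necessary conclusions), *initial*
  (accept what the first model shows), *credulous* (accept anything
  possible), and *adapted* (fit the variant per participant).
* **PRISM** — a spatial focus writes terms into a discrete array, counting
  focus operations as cognitive cost.  First-fit (`ff`) vs first-free-fit
  (`fff`) insertion and bounded model variation produce the *preferred
  mental model* and explain systematic preferences among logically
  equivalent answers.
* **VerbalReasoner** — an ordered queue of terms with directed, cost-weighted
  links (breaking a link costs more than creating one), extended to cardinal
  directions with per-axis direction encodings and a >90° insertion rule.
* **Baselines** — Random, most-frequent-answer (MFA), a transitive-closure
  logic oracle, per-participant BestModel selection, and the union-oracle
  Optimal model.
* **Benchmarks** — seeded synthetic generators for four classic designs
  (figural effect, continuity effect, cardinal-direction preference,
  small/large-scale arrangement verification) plus simulated responders with
  a configurable generating model and error rate.
* **Coverage evaluation** — the individual-level protocol in which a model
  sees each participant's own problem-response pairs (plus everyone else's)
  before predicting them, scoring whether that person's behavior lies inside
  the model's parameter space.

## Worked example

```python
from spatialcog.relations import parse_assertions
from spatialcog import prism, verbal

premises = parse_assertions(
    "left;pear;apricot/left;fig;pear/left;kiwi;pear/left;cherry;kiwi"
)
for strategy in ("ff", "fff"):
    model, cost = prism.construct_preferred(premises, strategy)
    print(strategy, [t.capitalize() for t in model.axis_order()], "cost", cost.total)
print("mix", [t.capitalize() for t in prism.mix_arrangements(premises)[0].axis_order()])
```

prints

```
ff ['Fig', 'Cherry', 'Kiwi', 'Pear', 'Apricot'] cost 13
fff ['Cherry', 'Kiwi', 'Fig', 'Pear', 'Apricot'] cost 10
mix ['Cherry', 'Fig', 'Kiwi', 'Pear', 'Apricot']
```

The four premises place four fruits to the left of previously placed ones;
premises 3 and 4 collide with occupied cells.  First-fit squeezes the new
fruit in next to its reference term and shifts the occupants (2 relocations,
hence the higher operation cost of 13); first-free-fit scans outward to the
nearest empty cell (cost 10); the mix construction (ff on the first
collision, fff afterwards) yields the third arrangement.  These are exactly
the three qualitative models this premise set admits, and which one a person
finds "consistent" reveals their construction strategy.

A full evaluation from the shell:

```bash
spatialcog generate --design smalllarge --participants 30 --seed 7 \
    --responder prism --error-rate 0.1 --out data.csv
spatialcog evaluate --data data.csv \
    --models random,mfa,closure,prism,verbal,sr-adapted,best,optimal \
    --seed 7 --out results/
spatialcog report --results results/ --plots
```

`results/summary.json` then holds per-model medians/MADs of participant
accuracies and `co_optimality.csv` the asymmetric matrix of how often one
model is correct when another is.

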