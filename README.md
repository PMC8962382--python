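# mpcscreen

Ligand-based pharmacophore screening and assay analytics for discovering
inhibitors of the mitochondrial pyruvate carrier (MPC), the MPC1/MPC2
inner-membrane heterodimer that gates pyruvate entry into mitochondria.

The package is aimed at computational chemists and assay scientists working
on the α-cyanocinnamate inhibitor series. It re-implements, as a tested and
reusable pipeline, the computational chain behind the discovery of non-indole
MPC inhibitors:

1. **Compound registry** — curated structures of the reference inhibitor
   UK-5099 (2-cyano-3-(1-phenyl-1H-indol-3-yl)acrylic acid), the cyanoacrylic
   acid actives BE1976–BE2623 with their measured potencies and ESI-MS
   masses, and their ester/des-cyano negative controls.
2. **Pharmacophore hypothesis** — three features read off a 3D conformer of
   UK-5099: a negative-ionizable site **N** on the carboxylate, a hydrogen-bond
   acceptor **A** on the nitrile, and an aromatic ring **Ar** on the indole.
3. **Fitness-scored screening** — deck conformers that match *all* three
   sites are superposed onto the hypothesis and ranked by

   ```
   S = W_site (1 − S_align/C_align) + W_vec S_vec + W_vol S_vol + W_ivol S_ivol
   ```

   with `S_align` the RMS site-point deviation after optimal rigid
   superposition (Å), `S_vec` the mean cosine between matched feature
   direction vectors, `S_vol` the intersection-over-union of heavy-atom van
   der Waals volumes against the reference conformer, and defaults
   `W_site = W_vec = W_vol = 1`, `W_ivol = 0`, `C_align = 1.2 Å`. A perfect
   self-match scores `S = 3`.
4. **Assay analytics** — BRET ratio computation (acceptor/donor, donor-only
   subtraction, pre-injection baseline normalization), oxygen-consumption
   rates and respiratory control ratios from oxygraph traces, and
   four-parameter log-logistic IC50 fits with fold-potency and
   Rule-of-Five reporting.
5. **Synthetic data** — seeded generators for a desk-scale screening deck
   (actives + ester negatives + scaffold-decorated decoys with or without
   the cyanoacrylate warhead) and for simulated BRET plates, O2 traces and
   dose–response points, so the whole chain runs end to end without
   proprietary software or instrument data.

## Worked example

Screen a 50-decoy deck (with the reference in it) against the UK-5099
hypothesis:

```python
from mpcscreen.pharmacophore import build_hypothesis
from mpcscreen.screening import screen_deck, hits_to_frame
from mpcscreen.synthetic_data import DeckSpec, generate_deck

deck, manifest = generate_deck(DeckSpec(n_decoys=50, seed=17, include_reference=True))
ref = next(e for e in deck if e.provenance == "reference")
hits = screen_deck(deck, build_hypothesis(ref.conformers[0]), top_k=7)
print(hits_to_frame(hits).to_string(index=False))
```

```
      id  rank  conformer        S  S_align    S_vec    S_vol
 UK-5099     1          0 3.000000 0.000000 1.000000 1.000000
DEC00000     2          4 2.626563 0.031074 0.998493 0.653964
DEC00013     3          4 2.579091 0.012546 0.993491 0.596056
DEC00011     4          3 2.567919 0.030237 0.997823 0.595293
DEC00001     5          1 2.561252 0.016353 0.941350 0.633530
DEC00004     6          0 2.560894 0.039848 0.996290 0.597810
  BE1980     7          0 2.534017 0.037933 0.952846 0.612781
```

The reference matches its own hypothesis exactly (`S_align = 0`,
`S_vec = S_vol = 1`, total `S = 3`); the best decoys are close cyanoacrylate
analogs whose volume overlap tops out around 0.65. Ester negatives carry no
negative-ionizable feature, fail the all-feature match, and never appear.

Fold-potency over the registry's measured IC50s (`mpcscreen report`):

```
     id  ic50_nM  fold_vs_reference         fold_label
 BE1976     33.0             0.1375 7-fold more potent
 BE2617     39.0             0.1625 6-fold more potent
 BE1978    117.0             0.4875 2-fold more potent
 BE1980    162.0             0.6750 1-fold more potent
UK-5099    240.0             1.0000         comparable
 BE1985    638.0             2.6583           >=2-fold
 BE2623    731.0             3.0458           >=3-fold
 BE1984   1533.0             6.3875           >=6-fold
```

BE1976 is 7-fold and BE2617 6-fold more potent than the canonical inhibitor
UK-5099; BE2623 is ~19-fold less potent than BE2617. Of the five
BRET-validated actives, four are nanomolar (BE1984, at 1533 nM, is not).

A full run (deck → hypothesis → screen → simulate → fit → report) is one
command:

```sh
mpcscreen run-all --seed 17 --out-dir out/
```

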