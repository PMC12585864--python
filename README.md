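# enameliso

Serial tooth-enamel stable-isotope palaeoecology: from raw intra-tooth
δ¹³C/δ¹⁸O measurements to diet reconstruction, weaning-signal detection and
cross-taxa niche comparison.

## The scientific problem

Herbivore enamel carbonate records the isotopic composition of diet and
drinking water at the time each increment of the tooth mineralized. Sampling
a molar in serial grooves along its growth axis (~1 mm spacing ≈ monthly
resolution at typical proboscidean extension rates of 8–21 mm yr⁻¹) yields a
time series across tooth formation. Two classic signals live in such
profiles:

* **Diet.** C₄ grasses are strongly enriched in ¹³C relative to C₃
  vegetation, so enamel δ¹³C separates grazers from browsers. Enamel is
  enriched by ~14.1 ‰ relative to diet, and fossil values must additionally
  be corrected for the secular drift of atmospheric CO₂ δ¹³C, giving the
  *modern-equivalent diet* value

  δ¹³C_diet-meq = δ¹³C_enamel − 14.1 + (δ¹³C_atm(epoch) − δ¹³C_atm(modern)),

  with δ¹³C_atm = −6.3 ‰ (Pliocene), −6.5 ‰ (Pleistocene), −8.0 ‰
  (post-industrial). The C₄ dietary fraction then follows from a linear
  two-end-member mixing model, f = (δ − δ_C3)/(δ_C4 − δ_C3), with end
  members −34.6 ‰ (C₃) and −7.6 ‰ (C₄) on the diet-meq scale.

* **Weaning.** Milk fat is ¹³C-depleted (~1.5 ‰) relative to maternal
  forage and milk water is ¹⁸O-enriched relative to drinking water, so the
  earliest-formed enamel of a nursing juvenile shows a paired excursion —
  low δ¹³C, high δ¹⁸O — that decays as solid food replaces milk.

The package implements the full analysis chain: scale conversions
(δ-notation, VSMOW↔VPDB, diet-meq), a five-class vegetation scheme, the
mixing model, per-specimen and pooled profile statistics, a two-window
shift detector plus a ramp-model weaning-position estimator, cross-taxa
Wilcoxon rank-sum comparisons with Holm adjustment and rank-biserial effect
sizes (bootstrap CIs), and a forward simulator of serial profiles for
validation. It ships a reference dataset: serial measurements from three
Pleistocene *Palaeoloxodon* molars dredged from the Taiwan Strait (a
juvenile, a subadult and an adult) and one extant *Elephas maximus* molar.

## Worked example

```python
import enameliso as ei

profiles = ei.read_serial_table(ei.bundled_serial_table_path())
juvenile = profiles[0]          # NTUM-VP 210127, ~5 yr old at death

s = ei.summarize_profile(juvenile, "d13C_diet_meq")
print(round(s.mean, 1), round(s.sd, 2))       # -15.2 1.09  (n = 9 grooves)

r = ei.specimen_c4_range(juvenile)
print(round(r.min_percent, 1), round(r.max_percent, 1))   # 63.3 77.1

rep = ei.detect_ontogenetic_shift(juvenile, "d13C_enamel")
print(rep.detected, rep.direction, round(rep.effect, 2))  # True rising 3.82

print(ei.estimate_weaning_position(juvenile))  # 4  (non-missing sample axis)
```

Reading: the juvenile's diet averaged −15.2 ‰ on the modern-equivalent
scale (63–77 % C₄ grasses), and its profile starts 3.8 tail-standard
-deviations below the later grooves, rising monotonically — the δ¹³C
weaning signature. The estimator places the end of the transition at the
fourth measured groove (groove 6 of the tooth, the first two grooves having
yielded no enamel powder). The same calls on the adult profile return
`detected=False` (effect 0.70).

The same pipeline is scriptable from the shell:

```sh
enameliso convert -- -4.92          # -17.52  (Pleistocene diet-meq)
enameliso mix -- -17.52             # 63.3    (% C4)
enameliso run src/enameliso/data/taiwan_strait_serial.csv --out report/
enameliso simulate --seed 3 --out sim.csv
```

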