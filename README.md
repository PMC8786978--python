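# invadosim

A 3D mechanochemical simulator of cancer-cell **invadopodia** — the
actin-rich membrane protrusions invasive cells use to degrade and
penetrate the extracellular matrix (ECM). It is built for computational
cell-mechanics work: testing how branched-actin force generation,
crosslinker mechanics, integrin adhesion and MT1-MMP/MMP-2 proteolysis
combine into cycles of protrusion, retraction and severing, and what
in-silico knockouts (α-actinin, filamin, fascin, MT1-MMP, Arp2/3) do to
invasion.

The model couples:

* **five viscoelastic cell surfaces** (invadopodial membrane, force
  transduction layer, actin cortex, and a double nuclear envelope), all
  Kelvin–Voigt triangulated shells linked by vertical springs;
* a **branched actin network**: polyline filaments with stretch
  (κ = A·E/L₀, E = 1.8 GPa, r = 3.5 nm → 0.46 N/m at the 150-nm initial
  element) and bending (κ_b = E·I) elasticity, Arp2/3 branches at 70°,
  a seven-state lifecycle (nucleated → growth → adhesion → detach →
  ratchet → capped → uncapped), Brownian-ratchet polymerization forces
  F_p·log(v₀/|n̂·Δv|), and load-dependent growth
  v_g = v₀·exp(−f/(n_F·f₀));
* **crosslinkers and motors**: fascin, filamin, α-actinin springs at
  fractional positions on filament pairs, and bipolar myosin
  minifilaments sliding toward barbed ends at the Hill rate
  v = v₀(F_s − F)/(F_s + c_m F);
* a **discrete collagen fiber network** (⌀41 nm fibers, 3-µm pores)
  with Bell slip-bond integrin adhesions
  (k_off = k_off⁰·e^{κ(L_b−λ)x_b/k_BT}) and volume exclusion;
* a **six-species reaction–diffusion field** (MMP-2, TIMP-2, MT1-MMP,
  ternary complex, ligand, ECM) with protrusive-phase tip secretion and
  irreversible fiber degradation where ECM concentration falls below
  threshold.

See `docs/methods.md` for the full model description, numerical choices
and limitations.

## Worked example

```python
import numpy as np
from invadosim import make_fixture, engine, average_speed

state = make_fixture("tiny", seed=3, protrusive=30.0,
                     retractile=10.0, severing=5.0)
tips = []
engine.run(state, 135.0, sample_interval=1.0,
           on_sample=lambda s: tips.append(s.tip_position()))
tips = np.asarray(tips)
adv = tips[-1, 2] - tips[0, 2]
print(f"tip advance over 3 cycles: {adv:.0f} nm")
print(f"degraded fiber elements: {int((~state.net.intact).sum())}")
print(f"tip speed: {average_speed(np.arange(len(tips)), tips, 45.0):.1f} nm/s")
```

prints (seed 3, miniature 20-filament fixture in a dense 1.2-µm-pore
gel, three 45-s cycles):

```
tip advance over 3 cycles: 633 nm
degraded fiber elements: 21
tip speed: 6.9 nm/s
```

The tip ratchets forward during each protrusive phase while MT1-MMP
secreted at the tip activates MMP-2 and clears the fibers in front of
it; re-running with `ko_mt1mmp=True` leaves the fiber network intact
and reduces the advance. The miniature fixture reproduces the trends
(protrusive-duration dependence, knockout orderings), not the absolute
published speeds; those belong to the full-scale configuration
(500 + 500 filaments, 45×30×20 µm box, 240/60/20-s phases) run
overnight.

There is also a CLI:

```bash
invadosim fixture tiny --seed 1 --out-dir out/
invadosim run config.yaml --seed 1 --out-dir out/
invadosim stretch-test --pore 3000 --seeds 5
invadosim analyze out/trajectory.csv --window 60
```

`invadosim run` writes `trajectory.csv` (tip and nucleus positions,
traction and intracellular force at the tip, adhered-filament counts),
legacy-VTK snapshots of membrane, filaments and the MMP-2 field, and a
JSON-lines style event log (nucleation, capping, severing, adhesion,
focal-complex events, phase switches).

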