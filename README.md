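# marrowsim

A hybrid cellular-automaton (HCA) simulator of the trabecular bone-marrow
ecosystem and its takeover by multiple myeloma. The model couples discrete
cell agents on a single-occupancy lattice -- preosteoclasts, osteoclasts,
mesenchymal stem cells (MSCs), preosteoblasts, osteoblasts, bone-lining
cells, and myeloma cells -- to reaction-diffusion cytokine fields (RANKL and
a bone-derived factor, BDF/TGF-beta) and a continuous per-site bone-density
field. It is written for computational biologists studying bone remodeling,
the myeloma "vicious cycle", and environment-mediated drug resistance
(EMDR) under bortezomib (BTZ) and zoledronate (ZOL).

## The model in brief

Normal remodeling proceeds through basic multicellular units (BMUs):
bone-lining cells express RANKL (production alpha_R per cell), recruiting
preosteoclasts that chemotax up grad(R_L) and fuse (>= 5 precursors) into an
osteoclast, which resorbs a trench of bone over its ~14-day lifespan,
releasing stored BDF (alpha_T per unit density resorbed). BDF recruits an
MSC whose asymmetric divisions supply preosteoblasts; these proliferate
while BDF is high and differentiate when it falls, each osteoblast
rebuilding its site with lifespan proportional to the local resorbed depth
(~90 days per unit) -- coupling formation to resorption. Cytokines obey

    dR_L/dt    = D_R lap(R_L)    + alpha_R B_ij          - delta_R R_L
    dT_beta/dt = D_T lap(T_beta) + alpha_B + alpha_T B_ij C_ij - delta_T T_beta

solved by forward-time centered-space stepping with periodic boundaries.

Myeloma cells divide and survive better on BDF and near stroma, trigger
remodeling when clustered against bone, and block osteoblast
differentiation within 80 um -- the feed-forward vicious cycle of osteolysis
and growth. Treatment starts at 10% marrow burden and relapse is declared
at 20%; after treatment starts, dividing sensitive cells acquire heritable
resistance with probability p_omega (with a proliferation cost), and EMDR
shields sensitive cells near MSCs/preosteoblasts or on high BDF from the
BTZ kill. See `docs/methods.md` for the full parameterization.

## Worked example

```python
from marrowsim import make_simulation, area_fractions

sim = make_simulation("homeostasis", seed=1, horizon=365.0)
ts = sim.run()                       # tidy per-frame DataFrame
print(f"BA/TA after 1 y: {ts.ba_ta.iloc[-1]:.4f}")
print(f"cumulative osteoclasts: {int(ts.cum_oc.iloc[-1])}")
print(f"remodeling events: {len(sim.events)}")
```

prints (seed 1):

```
BA/TA after 1 y: 0.1216
cumulative osteoclasts: 86
remodeling events: 100
```

i.e. after one simulated year the bone area fraction is still within ~6% of
the initial 12.9% while 100 remodeling events have initiated and 86
osteoclasts have resorbed bone since replaced by new formation --
homeostatic turnover. A tumor run:

```python
sim = make_simulation("mm_progression", seed=31, horizon=400.0)
ts = sim.run()
print(f"myeloma burden: {100 * ts.mm_fraction.iloc[-1]:.1f}% of marrow, "
      f"BA/TA {ts.ba_ta.iloc[-1]:.4f}")
```

```
myeloma burden: 40.3% of marrow, BA/TA 0.0931
```

-- the vicious cycle: tumor expansion with concurrent bone destruction.

The command line mirrors the library:

```bash
marrowsim run homeostasis --seed 1 --horizon 365 --outdir out/
marrowsim run treatment_cohort --seed 7 --replicates 5 --outdir cohort/
marrowsim summarize cohort/cohort.csv
```

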