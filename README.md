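# karyoevo

Ancestral karyotype reconstruction on phylogenies under a chromosomal
rearrangement event model, built around the comparative cytogenetics of the
Neotropical dwarf cichlid clade *Nannacara* – *Ivanacara* – *Cleithracara*
(five species, diploid numbers 2n = 44–50).

## The problem and the model

Fish karyotypes are commonly summarised by the diploid number 2n and a
formula such as `18m-sm+26st-a`: counts of **biarmed** chromosomes
(metacentric + submetacentric, `m-sm`) and **uniarmed** chromosomes
(subtelocentric + acrocentric, `st-a`). Working in homologous-pair units,
a karyotype is a lattice point (M, A) and evolution moves through the
lattice by discrete events:

| event | effect (ΔM, ΔA) | Δ2n |
|---|---|---|
| centric (Robertsonian) fusion | (+1, −2) | −2 |
| fission | (−1, +2) | +2 |
| pericentric inversion, m-sm → st-a | (−1, +1) | 0 |
| pericentric inversion, st-a → m-sm | (+1, −1) | 0 |

The number of CMA3-positive signal pairs (GC-rich, NOR-associated sites) is
carried as an independent ordered character with unit-cost gains and
losses.

The distance between two karyotypes is the minimal number of events
separating them. With ΔN the change in pair number and ΔM the change in
biarmed pairs it has the closed form

    d = |ΔN| + |ΔM + ΔN|

(fusions/fissions are the only events changing N, inversions absorb the
residual arm-class change), backed by a breadth-first-search oracle over
the lattice for the boundary cases. Ancestral states are inferred by
**Sankoff (generalized) parsimony** with this distance as the transition
cost: the reconstruction minimises the total number of rearrangement
events the tree history requires, reports *all* most-parsimonious states
per node, and decomposes every branch into its unique minimal event
multiset (x fusions, y fissions, u/v inversions).

When several root states are exactly tied, the tie is broken toward a
reference karyotype — by default the ancestral cichlid karyotype of 48
uniarmed chromosomes (`48st-a`) — mirroring how outgroup context is used
in comparative cytogenetics. The tie-break never changes the parsimony
score.

A forward simulator of the same event model (Poisson event counts per
branch on Yule trees, feasibility-checked application, full event logs)
provides ground truth for recovery experiments.

## Worked example

The packaged inputs are the rooted ingroup topology
`((((anomala,aureocephalus),taenia),adoketa),maronii);` and the
five-species karyotype table. Running

```sh
python analysis/01_reconstruct_ancestral_karyotype.py
```

prints

```
Root ancestral karyotype: 2n=48 (16m-sm+32st-a); root CMA3 signal pairs: 1
Parsimony cost: 5 rearrangements + 2 CMA3 events
Root states tied at minimal cost: ['14m-sm+36st-a', '16m-sm+32st-a']; selected by proximity
to the ancestral cichlid karyotype (0m-sm+48st-a)

Ancestral karyotype at root: 2n=48 (16m-sm+32st-a); CMA3 signal pairs: 1
Total parsimony cost: 5 rearrangement + 2 CMA3 events
Branch to clade N2: no events; karyotype 2n=48 (16m-sm+32st-a), CMA3 pairs 1
Branch to clade N3: 2 fusions + 1 inversion (m-sm -> st-a); karyotype 2n=44 (18m-sm+26st-a), CMA3 pairs 1
Branch to clade N4: no events; karyotype 2n=44 (18m-sm+26st-a), CMA3 pairs 1
Branch to anomala: no events; karyotype 2n=44 (18m-sm+26st-a), CMA3 pairs 1
Branch to aureocephalus: 2 CMA3 gains; karyotype 2n=44 (18m-sm+26st-a), CMA3 pairs 3
Branch to taenia: 1 inversion (m-sm -> st-a); karyotype 2n=44 (16m-sm+28st-a), CMA3 pairs 1
Branch to adoketa: no events; karyotype 2n=48 (16m-sm+32st-a), CMA3 pairs 1
Branch to maronii: 1 fission; karyotype 2n=50 (14m-sm+36st-a), CMA3 pairs 1
```

Reading: the clade ancestor had 2n = 48 (16 biarmed + 32 uniarmed
chromosomes) and one CMA3 signal pair. One fission produced the
*Cleithracara maronii* karyotype (2n = 50); *Ivanacara adoketa* kept the
ancestral karyotype unchanged; two fusions plus a pericentric inversion
produced the 2n = 44 *Nannacara* karyotypes, with a second inversion on
the *N. taenia* branch and a CMA3 multiplication (1 → 3 pairs) in
*N. aureocephalus*. Five rearrangements in total — the parsimony minimum.

The same run is available as a CLI (`karyoevo reconstruct --out DIR`,
plus `karyoevo simulate` and `karyoevo distance F1 F2`), e.g.

```sh
$ karyoevo distance "16m-sm+32st-a" "18m-sm+26st-a"
distance=3 events=fusion:2,inv_m_to_a:1
```

The simulation study (`python analysis/02_recovery_simulation.py`, 200
replicates on 20-leaf Yule trees at 0.5 expected events per branch)
reports root-2n recovery 0.93, exact root-state recovery 0.86, mean branch
event-multiset agreement 0.80, and zero violations of the parsimony lower
bound.

## Layout

- `src/karyoevo/` — the library: `model` (event algebra, distances),
  `io` (Newick/TSV, fixtures), `reconstruct` (Sankoff, MPR enumeration),
  `simulate` (forward model, recovery experiments), `cli`.
- `analysis/` — numbered drivers that run the study analyses and write
  tables under `results/`.
- `docs/methods.md` — modelling assumptions, parameter choices, numerical
  details and limitations.
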