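# chemspace

Element-substitutability networks over an evolving chemical space.

`chemspace` is a pipeline for a computational-history question: as the set
of known substances (the *chemical space*) grows year by year, how do the
similarity and ordering relationships among chemical elements — the raw
material of a periodic system — emerge, stabilize, and converge?  It is
aimed at researchers in cheminformatics and history of science who have a
substance table (identifier, molecular formula, first-report year) and
want to reconstruct yearly *systems of chemical elements* (SCEs) from it,
or to stress-test such reconstructions on synthetic data with known ground
truth.

## The model

**Similarity as substitutability.**  Every substance containing element
*x* contributes one *arranged formula* to *x*'s profile F*x*: its canonical
formula with *x* replaced by the placeholder X and the symbols
lexicographically re-sorted (C₂H₂Br₂ contributes C₂H₂X₂ to F_Br).  F*x* is
a multiset — isomers are distinct records sharing one formula.  The
similarity of *x* toward *y* is

    s(x→y) = |{entries of Fx whose arranged formula occurs in Fy}| / |Fx|

counted with F*x* multiplicity against F*y* membership: the probability
that replacing *x* by *y* in a randomly chosen compound of *x* yields a
known compound.  The measure is asymmetric — s(x→y) and s(y→x) share
neither numerator nor denominator.

**SCE networks.**  For each year's cumulative snapshot, a directed network
draws an edge from each element to its most similar element(s) (ties kept,
no edge when the maximum is 0), with nodes ranked by atomic weight.
Cross-year convergence is measured by the edge-set overlap
|N_x ∩ N_y| / |N_x|; the *backbone* collects edges present in more than a
threshold share (default 60%) of the yearly networks over the window in
which both elements existed; *ubiquity* asks how small a random fraction
of the space still reveals each edge, by repeated subsampling.

**Retrodiction.**  A historical atomic-weight table A reinterprets modern
formulae: each coefficient of element *e* is multiplied by the simplest
Farey fraction approximating (W/A)(e) = (W(e)/W(H)) / (A(e)/A(H)) within a
relative tolerance τ (swept over 1%…20%).  The SCE of the rescaled space
is scored against a reference-year SCE by true-positive rate
|P_τ ∩ P_ref| / |P ∩ P_ref| and false-positive rate |P_τ \ P_ref| / |P_τ|.

**Synthetic spaces.**  The generator emits study-shaped spaces —
exponential growth, staged element introduction, declining combination
diversity, isomers, combination sizes ≤ 8 — with *planted families* whose
members substitute for each other by construction, so every analysis stage
can be validated against known ground truth.

## Worked example

The shipped 13-substance toy space (HCl, HBr, H₂O, O₂, NaCl, NaBr, CO₂,
KCl, Na₂O, C₂H₂Cl₂, K₂O, and two C₂H₂Br₂ isomer records):

```python
from fractions import Fraction
import chemspace as cs

space = cs.toy_space()
s1 = cs.similarity(space, 1804, "Br", "Cl")
s2 = cs.similarity(space, 1804, "Cl", "Br")
print(f"s(Br->Cl) = {s1.numerator}/{s1.denominator} = {float(s1.value):.2f}")
print(f"s(Cl->Br) = {s2.numerator}/{s2.denominator} = {float(s2.value):.2f}")
g = cs.sce_network(space, 1804)
print("SCE edges:", sorted(g.edges()))

table = cs.synthetic.iron_doubled_table()   # A(Fe) doubled on the H scale
f = cs.parse_formula("Fe2O3")
print("Fe2O3 ->", cs.rescale_formula(f, table, Fraction(5, 100)).render())
```

prints

```
s(Br->Cl) = 4/4 = 1.00
s(Cl->Br) = 3/4 = 0.75
SCE edges: [('Br', 'Cl'), ('Cl', 'Br'), ('H', 'Na'), ('K', 'H'), ('K', 'Na'), ('Na', 'H')]
Fe2O3 -> FeO3
```

Every bromine compound stays a known compound when Br is replaced by Cl
(4/4), but not conversely (KBr is unknown here, so 3/4): substitutability
is asymmetric.  The SCE pairs the halogens, pairs Na with H, and leaves C
and O isolated — their arranged formulae are shared with no one.  K ties
between H and Na, so both edges are kept.  Under a weight table in which
iron's hydrogen-relative weight is doubled, the Farey multiplier for Fe is
exactly 1/2 at any tolerance and Fe₂O₃ is re-read as FeO₃.

The same analyses run from the shell:

```sh
chemspace generate --out space.csv --seed 4 --truth-out truth.json
chemspace all --substances space.csv --out results --seed 4
```

`results/manifest.json` then lists the per-stage artifacts (year stats,
combination counts, yearly GraphML/JSON networks, similarity matrix,
overlap matrix, backbone, ubiquity profiles, and — when weight tables are
supplied — retrodiction scores).

## Layout

- `chemspace.formula` — formula parsing/canonicalization, combinations, arranged formulae
- `chemspace.space` — cumulative spaces, growth/diversity/coverage statistics
- `chemspace.similarity` — profiles, substitutability similarity, SCE networks
- `chemspace.convergence` — overlap matrices, backbone, subsampling ubiquity
- `chemspace.retrodiction` — weight tables, Farey rescaling, retro-SCE scores
- `chemspace.synthetic` — planted-family generator, toy space, weight perturbations
- `chemspace.pipeline` / `chemspace.cli` — orchestration, manifests, command line

See `docs/methods.md` for the methods note (model assumptions, parameter
defaults, numerical choices, limitations).
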