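# aquarisk

Antibiotic residues (ARs) in aquatic products do not stay where they are
produced: they move through supply chains dominated by small, often
untraceable intermediaries — the "hidden middle" — from production
provinces to consumption provinces.  `aquarisk` is a Python toolkit for
analysing routine food-safety sampling records in that setting.  It is
aimed at food-safety modellers and surveillance planners who have
long-format test records (where a sample was tested, where it came from,
whether it failed, and which compounds exceeded their legal limits) plus
trade and consumption tables, and who want to answer four questions:

1. **Where does contamination come from?**  For each flow from source
   province *i* to monitoring province *j*, the conditional contamination
   probability of antibiotic *k* is estimated as

   `ProbC(i,j,k) = (NSC_ij / NST_ij) × (NSC_ijk / Σ_h NSC_ijh)`

   — the flow's failure rate times compound *k*'s share of hazard
   occurrences.  Flows are classified internal (i = j), external
   (traceable, i ≠ j) or unknown (untraceable).

2. **How much food is lost to contamination?**  Net trade volume
   `TV = PV − EV + IV` (production − exports + imports, tons) times the
   destination's pooled failure rate gives the contamination-attributable
   loss `CTV`, overall and per antibiotic.

3. **What is the dietary risk?**  The standard veterinary-residue chain:
   estimated daily intake `EDI = CL × DI / BW`, hazard quotient
   `HQ = EDI / ADI`, probability-corrected quotient `CHQ = ProbC × HQ`,
   and the cumulative hazard index `HI_j = Σ_{i,k} CHQ`, flagged when it
   exceeds 1.

4. **Where should limited sampling go?**  With per-flow prevalence *a*
   and *x* sampling batches, a source is caught with probability
   `d = 1 − (1 − s·a)^x` (assay sensitivity *s*).  The allocator
   maximizes the joint detection `h_j = Π_i d_i` per province subject to
   the batch budget, a floor on post-removal trade volume, a cap on
   residual hazard index, and integrality.  The log objective is
   separable concave, so greedy marginal allocation is exact for the
   budget-only problem; active side constraints are handled by an exact
   dynamic program (small instances) or greedy repair, and everything is
   verifiable against an enumeration oracle.

A synthetic-data generator (`aquarisk.synthetic`) produces sampling,
trade, consumption, and reference tables with known ground truth at the
scale of the real surveillance setting (31 provinces × 2015–2022,
~300,000 samples), so every stage is testable without any data download.

## Worked example

```python
import aquarisk as aq

ds = aq.paper_scale_preset(seed=1)          # 31 provinces, 2015-2022
cfg = aq.StudyConfig(seed=1)
res = aq.run_pipeline(ds.records, ds.trade, ds.consumption, ds.reference,
                      cfg,
                      budgets={j: 1200 for j in ds.truth.provinces},
                      baseline_alloc=aq.baseline_allocation(ds.truth, 1200))

print(res.streams)
print("provinces with HI > 1:", int(res.risk.hi["exceeds_standard"].sum()))
print("annual AR loss per province (tons):",
      round(aq.annual_average_loss(res.loss, national=True)))
```

prints

```
     stream  mean_a_ant    mean_a  n_cells
0  internal    0.006116  0.007254       31
1  external    0.018720  0.022266      149
2   unknown    0.016645  0.019773       31
provinces with HI > 1: 6
annual AR loss per province (tons): 19943
```

Reading: the mean any-antibiotic contamination probability is 0.61 % for
internal (local) flows, 1.87 % for external (trans-provincial) flows and
1.66 % for untraceable flows — traceable cross-province trade carries the
highest per-flow risk, and the hidden middle sits close behind.  Six
provinces accumulate a hazard index above 1 (a potential health
concern), and the average province loses ~20,000 tons of product per
year to antibiotic exceedances.  `res.comparison` then quantifies how an
optimized allocation of the same 1,200 batches per province improves
joint detection, saved food loss and saved health risk over the
baseline scheme that spends ~78 % of batches on untraceable sources.

A CLI mirrors the stages (`aquarisk simulate | estimate | loss | risk |
evaluate | optimize | sensitivity`); each command reads the documented
CSV schemas and writes its output tables plus a run manifest.

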