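# regulatome

Screening analysis of the **cell-death regulatome** — a curated set of
299 genes regulating 13 cell-death modalities (apoptosis, MPT-driven
necrosis, necroptosis, ferroptosis, pyroptosis, parthanatos, entotic
cell death, NETotic cell death, lysosome-dependent, autophagy-dependent
and immunogenic cell death, mitotic death, anoikis) — across
two-condition expression datasets, plus a chromatin long-range
interaction (CLRI) signed-distance analysis. It is aimed at anyone
mining public two-group expression data (e.g. ultrasound-, heat- or
shear-stress-treated cells) for coordinated shifts in cell-death
regulator expression and for the chromatin-interaction geometry of the
genes that move.

## What it computes

**Screening layer.** Per-gene signed fold changes use the
reciprocal-negative convention (ratio r ≥ 1 ⇒ +r; r < 1 ⇒ −1/r). A gene
is called *up* when FC > T and *down* when FC < −T, with T = 1.5 by
default and a strict comparison. Calls are annotated per cell-death
modality (a multi-type gene appears under each of its types), dataset
quality is checked by requiring housekeeping genes (CHMP2A, PSMB4,
ACTB, GAPDH) to stay inside (−T, T), and conditions are compared by
shared / discordant call sets. Auxiliary panels (ROS-generating vs
antioxidant enzymes; insulator-, promoter- and non-promoter-binding
chromatin-conformation factors) run through the same rule.

**CLRI layer.** For a gene set, each cis chromatin interaction
involving a member gene yields a signed distance
`partner_anchor − promoter_TSS` (positive = partner downstream).
Distributions are summarized as upstream/downstream fractions plus a
signed decade histogram (edges at 10³…10⁸ bp), and two gene sets are
compared with a two-sample Kolmogorov–Smirnov test: D is the supremum
ECDF difference; the asymptotic p evaluates the Kolmogorov distribution
at λ = √(n₁n₂/(n₁+n₂))·D; pooled samples of ≤ 14 get an exact
permutation p by full enumeration.

**Synthetic data.** Generators produce replicated two-group expression
matrices with planted multiplicative effects under log-normal noise,
and interaction tables with a controllable downstream-placement
probability β and log-uniform distance magnitudes — with ground truth,
so every stage is testable without downloads.

Packaged fixtures transcribe the published per-condition fold-change
tables (LIUS in lymphoma and pre-osteoblast cells, mild hyperthermia,
oscillatory shear stress, TP53/SRF perturbations, housekeeping values,
redox and chromatin-factor screens), making the published counts
reproducible offline. See `docs/methods.md` for conventions and
curation decisions.

## Worked example

Registry arithmetic and a condition screen from the command line:

```sh
$ regulatome qc
{
  "n_values": 35,
  "min_value": -1.271,
  "max_value": 1.284,
  "threshold": 1.5,
  "missing_cells": 1,
  "pass": true
}
```

Housekeeping fold changes across all nine packaged series span
[−1.271, 1.284] — well inside the ±1.5 band, so the datasets pass QC
(one series lacks its CHMP2A probe; the cell is counted, not imputed).

```python
>>> import regulatome as rt
>>> reg = rt.load_regulatome()
>>> reg.total_memberships, reg.unique_genes, reg.multi_type_genes
(390, 299, 91)
>>> sorted(reg.memberships_of("TP53"))
['ADCD', 'MPT-driven necrosis', 'apoptosis', 'ferroptosis', 'mitotic death']

>>> from regulatome.fixtures import load_condition_table
>>> calls = rt.classify(load_condition_table("lius_cancer"), reg.all_genes)
>>> len(calls.up), len(calls.down)
(13, 12)
```

The LIUS-treated lymphoma screen calls 13 regulatome genes up (among
them TP53 at +2.723) and 12 down (among them CD47 at −15.995).
Comparing the two non-cancer conditions:

```python
>>> hyper = rt.classify(load_condition_table("hyperthermia_noncancer"), reg.all_genes)
>>> lius = rt.classify(load_condition_table("lius_noncancer"), reg.all_genes)
>>> sorted(rt.compare(lius, hyper).shared_down)
['CD47', 'GCLC', 'NLRP3']
```

Both mild hyperthermia and ultrasound downregulate GCLC, NLRP3 and
CD47 in non-cancer cells — the shared inflammatory-cell-death
signature. A synthetic CLRI comparison:

```python
>>> from regulatome.synthetic import SyntheticInteractionSpec, gen_interactions
>>> spec = lambda b, s: SyntheticInteractionSpec(genes=("A",), interactions_per_gene=500,
...                                              downstream_prob=b, seed=s)
>>> a, pa = gen_interactions(spec(0.5, 1)); b, pb = gen_interactions(spec(0.8, 2))
>>> da = rt.build_distance_set(("A",), a, pa); db = rt.build_distance_set(("A",), b, pb)
>>> ks = rt.ks_two_sample(da.distances, db.distances)
>>> round(ks.D, 3), ks.p_asymptotic < 0.001
(0.304, True)
```

Two interaction sets whose partners fall downstream with probability
0.5 vs 0.8 are sharply distinguishable at n = 500 distances each.

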