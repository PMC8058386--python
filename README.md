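# tmmpsf — topology-based telomere maintenance mechanism phenotyping

Cancer and stem cells escape replicative telomere shortening through one of
two telomere maintenance mechanisms (TMM): the telomerase-dependent pathway
(**TEL** — hTERT, the RNA template hTR/TERC and the dyskerin complex
assembling into active telomerase) or the recombination-based alternative
lengthening of telomeres (**ALT** — a break-induced-repair-like process
involving APB bodies, strand invasion and Holliday-junction processing).
Experimental TMM assays (TRAP, C-circle, APB staining) are laborious and
individually unreliable; `tmmpsf` infers the TMM phenotype of each sample
directly from gene expression by propagating expression fold changes through
curated TEL and ALT pathway topologies.

The package is aimed at computational biologists analysing microarray or
RNA-seq cohorts (cell lines, tumours, healthy tissues) who want per-sample
TMM activity scores, quadrant phenotype calls, and gene-level explanations
of why a pathway is on or off.

## Method

**Pathway signal flow (PSF).** Each pathway is a typed DAG of gene, complex,
operator ("linker") and process nodes converging on a single sink. For a
sample with fold changes *FC(g)* (relative to the per-gene cohort mean, or
the mean of non-zero TPM for RNA-seq), node signals are computed in
topological order:

    S(v) = FC(v) · W(v)

where *W(v)* combines the parent signals arriving on incoming edges — an
activating edge contributes *S(u)*, an inhibiting edge *1/S(u)* — using the
node's rule: declared operator (min / max / sum) for linkers, min for
complexes (the weakest subunit limits the complex), product otherwise.
Pathway activity is reported as

    activity_log2 = log2( S(sink) / S0(sink) )

with *S0* the sink signal of the all-neutral (FC ≡ 1) vector, so 0 is always
the neutral threshold.

**Partial influence (PI).** The influence of gene *g* on a target node is
the log2 ratio of the target signal before versus after forcing *FC(g) = 1*.
Ranked PI profiles identify the genes that limit or drive a pathway, and
multi-gene neutralization answers what-if questions ("does TEL switch on if
these suppressors return to baseline?").

**Phenotyping.** Each sample's (TEL, ALT) activity pair is classified into
one of four quadrants (TEL−/ALT−, TEL+/ALT−, TEL−/ALT+, TEL+/ALT+) using
independent per-axis thresholds: the 1-D max-margin separator fitted on
experimentally annotated samples, or the neutral threshold 0 without labels.

The packaged topologies (TMM v2.0) contain 37 ALT genes and 26 TEL genes
(63 unique symbols), each with signed effects and literature citation keys;
they ship as JSON under `src/tmmpsf/data/` and export to XGMML/GraphML.

## Worked example

Score a simulated cohort with planted phenotypes (4× effect, log2 noise
SD 0.2, 5 samples per quadrant):

```python
from tmmpsf import TMMModel, SimulationDesign, simulate_expression
from tmmpsf.phenotype import QUADRANTS

design = SimulationDesign(n_per_quadrant={q: 5 for q in QUADRANTS}, seed=7)
matrix, labels = simulate_expression(design)
results = TMMModel(matrix, annotations=labels.to_dict()).fit()
print(results.summary())
```

```
TMM pathway activity phenotyping
========================================
samples:            20
pathway version:    TMM v2.0
fold-change ref:    mean
TEL threshold:      -1.5545 (margin 4.6596, max_margin)
ALT threshold:      -0.4593 (margin 6.4128, max_margin)
quadrant counts:
  TEL-/ALT-    5
  TEL+/ALT-    5
  TEL-/ALT+    5
  TEL+/ALT+    5
overall agreement:  100.0%
```

Every sample lands in its planted quadrant; the fitted max-margin
thresholds sit between the well-separated positive and negative activity
clusters (large margins because the planted effect dwarfs the noise).

Gene-level dissection of an hTR-maturation bottleneck — a sample whose
TERT-activation branch is induced 2-fold while the hTR maturation factors
(TERC, PARN, WRAP53) are at a quarter of their baseline:

```python
from tmmpsf import load_tmm, compute_psf, pi_profile, neutralize_and_score

tel = load_tmm("TEL")
fc = {g: 1.0 for g in tel.gene_ids()}
fc.update({g: 0.25 for g in ("TERC", "PARN", "WRAP53")})
fc.update({g: 2.0 for g in ("TERT", "KPNA1", "RAN", "IPO7",
                            "RANBP2", "HSP90AA1", "HSP90AB1", "PTGES3")})
print(compute_psf(tel, fc).activity_log2)            # -0.198  -> TEL-negative
for r in pi_profile(tel, fc)[:3]:                    # strongest suppressors
    print(r.gene, round(r.pi_log2, 3))               # TERC -0.749, PARN -0.515, WRAP53 -0.515
print(neutralize_and_score(tel, fc,
      ["TERC", "PARN", "WRAP53"]).activity_log2)     # +1.229  -> TEL-positive
```

Despite the induced TERT branch, the suppressed hTR branch keeps overall
TEL activity below the neutral threshold; the PI profile pinpoints the
responsible genes, and neutralizing them flips the call — the "bottleneck"
behaviour the topology is designed to expose.

The same analyses are available from the shell:

```sh
tmm simulate --effect 4 --n 20 --seed 7 --out sim/
tmm run --expr sim/expression.tsv --annotations sim/labels.tsv --out report/
tmm pi --pathway TEL --expr sim/expression.tsv --genes NAF1,WRAP53,PARN --out pi/
```

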