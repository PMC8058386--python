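# Methods

## Pathway model

A pathway is a directed acyclic graph with five node types: **gene**
(carries expression), **complex** (a protein complex with listed member
genes), **linker** (combines parallel inputs with a declared operator:
`min`, `max` or `sum`), **process** (an event node) and a single **sink**
whose propagated signal summarises pathway activity. Edges are signed
(activation / inhibition), self-loops are forbidden, and every source node
must reach the sink. Validation reports all violations as data
(`validate_pathway`) so malformed files can be diagnosed in one pass;
readers (`XGMML`, `GraphML`, JSON) reject files that violate the model and
name the offending element. Writers emit elements sorted by node id, so two
writes of the same pathway are byte-identical.

## The packaged TMM topologies (v2.0)

The ALT (37 genes) and TEL (26 genes) encodings transcribe the curated
gene tables: every gene carries its net activating/inhibiting sign and at
least one citation key, complexes carry their member lists, and genes are
grouped into the event blocks of the pathway schematics.

Wiring follows a block scheme: within each block, genes and complexes feed
a `sum` linker (parallel lines of evidence add), complex members feed their
complex by activation edges and the complex joins its block with the
table's sign, and each block's evidence linker activates a process node.
ALT is a serial chain of seven blocks (DDR/G4 handling → telomere bridge
formation → APB recruitment → strand invasion → template-directed
synthesis → Holliday-junction dissolution → resolution). TEL has three
parallel component branches (nuclear TERT activation; hTR maturation;
dyskerin complex) that converge on telomerase assembly and then on
recruitment/synthesis; TERT, TERC and DKC1 feed both their own maturation
branch and the assembly block.

Two deliberate choices:

* **Serial/convergent blocks combine by product, not min.** Evidence
  linkers are sums, so blocks of different sizes have different neutral
  signals (e.g. 8 inputs in the TERT block vs 2 in the recruitment block).
  A `min` across such blocks would always be pinned by the smallest block
  and deviations elsewhere could not propagate; the product rule keeps
  every block's relative deviation visible after neutral-baseline
  normalization, while the biological "weakest component limits the
  output" behaviour is retained where it is well-defined — inside
  complexes, which combine members by `min`.
* **POLA1 completes the TEL synthesis block.** The curated table text
  yields 25 unique TEL symbols while the pathway is described with 26;
  DNA polymerase alpha is named throughout the narrative as the final
  synthesis actor stimulated by CST/STN1, so POLA1 is included in the
  "recruitment to telomeres and synthesis" block.
* **NuRD** is published without a subunit list and is encoded as an
  unmeasured complex node (neutral signal) unless the user extends the
  topology with members.
* Canonical HGNC symbols are used, with printed aliases preserved as
  annotations (e.g. NBN/NBS1, PSMC3IP/HOP2, TENT4B/PAPD5, MTREX/MTR4,
  ZCCHC7/AIR2); the printed SLX1 rows map to SLX1A and SLX1B and the
  doubled HSP90 row to the HSP90AA1/HSP90AB1 pair.

## Preprocessing

* **Probe collapsing**: for genes measured by several probes, the probe
  with the largest population (ddof 0) standard deviation across samples is
  kept; SD ties break by ascending probe id. GCT 1.2 files with duplicate
  gene symbols are collapsed by the same rule.
* **Capping**: optionally, all values above the global `q`-quantile
  (linear-interpolation definition over every entry of the matrix; default
  `q = 0.9` when enabled) are replaced by that quantile. Note that
  re-computing the quantile on already-capped data yields a slightly lower
  cap — capping is idempotent at a fixed cap value, not under quantile
  re-computation.
* **Fold changes**: `FC(g, s) = x(g, s) / ref(g)` with `ref` the per-gene
  mean over all samples (microarray) or over non-zero values (TPM).
  Results are clipped to `[1e-6, 1e6]` — the lower bound keeps reciprocals
  finite when inhibition edges invert a zero — and all-zero genes are set
  to FC 1 with a logged warning. Technical replicates (ids suffixed
  `_1`/`_2`) are scored separately, never averaged; replicate concordance
  is reported alongside agreement.

## Signal propagation

Nodes are visited in a deterministic topological order (ties by node id).
The contribution of parent *u* through edge *e* is `S(u)` for activation
and `1/S(u)` for inhibition, with signals pre-clipped to `[1e-6, 1e6]`.
Parent contributions combine by the node-type rule (linker operator /
complex min / product), and the result is multiplied by the node's own fold
change (1 for non-gene nodes and for pathway genes missing from the data,
which are also reported). Activity is `log2(sink_raw / sink_neutral)`
against the all-ones baseline; this normalization makes the neutral sample
score exactly 0 even though `sum` linkers give the raw neutral signal a
topology-dependent value. Natural invariants — exact neutrality,
monotonicity in a gene's fold change with fixed inhibition parity, order
invariance, the product closed form on pure activation chains, and
agreement with an independent recursive evaluator — are property-tested on
random DAGs.

## Partial influence

`PI(g → t) = log2 S_t(observed) − log2 S_t(g neutralized)`, computed by two
full propagations. The "difference of log signals" and "log of the signal
ratio" readings coincide by construction; log base 2 is used everywhere.
Genes inside complexes are neutralized through the complex with no special
casing, genes with no path to the target have PI exactly 0, and profiles
are sorted ascending (strongest suppressor first) with deterministic
id tie-breaks. The cohort-level profile uses a "mean sample": the per-gene
arithmetic mean of fold changes across samples.

## Phenotyping

The 2-D decision boundary is two axis-parallel lines, so the classifier is
two independent 1-D max-margin fits rather than a kernel machine. For
separable data the threshold is the midpoint of the innermost
opposite-label pair (margin = half the gap); otherwise the cut minimising
misclassifications, preferring larger margin and then smaller threshold.
Orientation is fixed (positive = strictly greater than the threshold; a
value exactly on the line counts negative). Without annotations both
thresholds default to 0, the neutral activity. The fit is verified against
exhaustive search over all candidate midpoints.

## Synthetic data

The simulator emulates a phenotyped expression cohort: per-gene baselines
`2^N(7, 1)` (arbitrary intensity scale), planted multiplicative shifts —
activating genes of an active pathway multiplied by the effect size,
inhibiting genes divided by it, so the planted signal is coherent with
pathway semantics — and independent log2-normal noise per entry. Defaults
(effect 4×, noise SD 0.2 log2 units, 20 samples per quadrant, 100
background genes) describe a clearly phenotyped cohort of cell-line-panel
size. The generator does **not** emulate probe-level artifacts, correlated
gene modules, cohort covariates or mixed-cell-type tissues, so passing
recovery tests demonstrate the pipeline's correctness and sensitivity
under clean planted signal, not expected accuracy on real tumours. The
end-to-end harness (`phenotype_recovery`) runs fold changes → both
pathways → threshold fit on true labels → classification and reports the
fraction of correctly recovered quadrants; recovery is perfect without
noise, near-chance without effect, and monotone in effect size.

## Numerical choices

* Signal and fold-change clipping to `[1e-6, 1e6]` bounds reciprocals.
* Exact-zero neutrality is guaranteed structurally (observed and baseline
  runs share one code path), not by tolerance.
* All random generation funnels through seeded generators; simulation
  designs record their seed.
* Problem sizes in the verification harness (hundreds of random DAGs of
  ≤ 12 nodes, 50 random fold-change vectors per pathway, 200 labelled
  sets, one 80-sample simulated cohort) were chosen to exercise every
  code path while keeping the whole suite in seconds.

## Known limitations

* The packaged topologies encode one defensible reading of the curated
  tables; the exact operator placement of the original curation is not
  published in reusable form, so branch-level numbers are
  encoding-dependent even where sink-level behaviour is robust.
* TERC is absent from common microarray platforms; the engine then treats
  it as neutral and reports it in `missing_genes`, which dampens TEL
  sensitivity exactly as it does in practice.
* Activity scores are relative to the cohort used to form fold changes;
  scores are not comparable across data sets processed separately.
* No significance estimates are attached to PSF or PI values.
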