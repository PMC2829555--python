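# Methods

This note documents the models, rules and numerical choices behind mipkit,
what the synthetic-data generator does and does not emulate, and the known
limits of each stage.

## Sequence features

**Transmembrane segments.** MIP channels cross the membrane six times.
mipkit predicts TM segments from Kyte–Doolittle hydropathy: the mean over a
sliding window (default 19 residues, a common choice for helical TM
detection) is assigned to the window centre; maximal runs of centres at or
above the cutoff (default 1.6) are merged when separated by fewer than 3
residues, expanded by half a window on each side (clipped at the midpoint
where two expansions would overlap), and discarded below a 15-residue
minimum span.  The centre-run formulation was chosen over unions of raw
window extents because extents bleed half a window into flanking loops and
spuriously merge helices across the short intracellular loops B and D.
This is a deliberately simple offline stand-in for dedicated topology
predictors; externally produced TM annotations can be supplied as a TSV
(`read_tm_annotations`) and the count is not used as a hard gate anywhere —
Aqp8-like channels in particular are known to show only five predictable
helices in some in-silico analyses, and the classifier tolerates that.

**NPA boxes.** Both pore hemi-helices end in an Asn-Pro-Ala motif whose
third (and occasionally second) position varies across the family; mipkit
scans for `N-[PA]-[APSTV]`, which covers the observed variants (NAA, NPP,
NPS, NPT, NPV).  When reference-mapped expected positions are available,
the candidate closest to each expected centre within 15 residues is
labelled B or E (ties to the leftmost); otherwise the first two matches
are taken in order.  A sequence with no motif match and a reference
alignment score below 50 is flagged non-MIP.

**Anchored residue mapping.** The ar/R constriction tetrad and the Froger
P1–P5 residues are located by globally aligning the query against an
annotated reference frame (BLOSUM62, gap open 10, gap extend 0.5, end gaps
penalised — standard practice for full-length homologs) and reading the
query residue in each anchor column; a gap in the query yields a missing
marker.  Two reference frames are packaged (a water-channel frame and a
glycerol-facilitator frame, both synthetic generator roots labelled as
such); each frame's mapping is scored by how many of its NPA anchors land
exactly on scanned NPA motifs, and the better-corroborated mapping wins,
with ties going to the higher alignment score.  When both NPA anchors are
corroborated at one consistent offset, all anchors are snapped to that
register.  Rationale: at 40–50% identity a global alignment occasionally
buys a spurious local bulge that shifts a single anchor column even though
the two sequences are colinear; the NPA boxes are locatable without any
alignment and therefore serve as independent register landmarks.  With
real insertions or deletions the two offsets disagree and the method falls
back to pure alignment-column bookkeeping, so indel handling is unchanged.

**Froger discriminants.** The P1–P5 residue sets that separate
water-selective channels from glycerol facilitators ship as an editable
TSV (version-stamped into every profile): aquaglyceroporins carry an
aromatic P1, Asp P2, Lys/Arg P3, Pro P4 and a non-aromatic P5, while
water-selective channels carry small residues at P1–P3 and aromatics at
P4–P5.  Labs using different curations can swap the table without touching
code.

**Mercury flag.** A Cys within 15 residues upstream of the loop-E NPA Asn
is flagged as a candidate mercurial-inhibition site.  The flag is
descriptive only: mercury sensitivity is known to be imperfectly predicted
by this residue.

## Subfamily classification

Rules are evaluated in fixed precedence and the first fully satisfied
class wins:

1. **aqp8-like** — His at the aromatic slot, Val/Ile at the His slot, Arg
   at the Arg slot.  Tested first because this tetrad is a strict variant
   that would otherwise partially satisfy the water-selective rules.
2. **water-selective** — aromatic slot 1, His slot 2, Arg slot 4, and at
   least as many aquaporin-set as Glp-set P1–P5 matches.
3. **glp** — no His at slot 2, an aromatic (or Tyr) at the Cys slot, and
   ≥4 Glp-set P1–P5 matches.
4. **unorthodox** — a tetrad atypical for all of the above and ≤3
   aquaporin-set matches.

If no class matches fully, the best-scoring class is reported when it
satisfies at least half of its rules (the violated rules are listed in the
evidence field); below that floor the call is `unclassified`.  The floor
is a package choice — there is no community-standard threshold — and the
partial path mainly rescues profiles with a single missing anchor.
Substrate prediction is class-level by design: known intra-class
exceptions (an Aqp8-like duplicate passing only water, weak urea transport
in some Glps) are surfaced by the concordance table rather than special-
cased in the predictor.

**Hybrid genes.** Each translated exon peptide (≥10 aa) is scored by
local-alignment percent identity against every labelled reference family;
an exon is assigned to the best family only when it beats the runner-up by
a margin (default 10 identity points — a package default, chosen because
no numeric margin is standard), else it is ambiguous.  The gene is called
hybrid iff two or more non-ambiguous contiguous blocks carry different
labels, and the breakpoint indices are reported.  Local rather than global
alignment is used because a short exon against a full-length reference
would otherwise be dominated by end gaps.

## Identity, distance and trees

Gapped-global identity uses every column of the pairwise alignment between
the first and last column where both sequences have residues: internal
gaps count in the denominator, terminal overhangs do not.  "Similarity"
counts identical pairs plus substitutions with a positive BLOSUM62 score.
The gapless positional mode compares equal-length sequences column by
column, the convention used when quoting identity over complete peptides
of equal length.  Identity-to-distance conversion defaults to p-distance
(1 − identity/100, the natural "changes per residue" scale); a Poisson
correction (−ln of fractional identity) is available.

Neighbor joining follows Saitou–Nei: join the pair minimising
`Q(i,j) = (n−2)·d(i,j) − r_i − r_j`, with branch lengths
`l_i = d(i,j)/2 + (r_i − r_j)/(2(n−2))`, matrix reduction by
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`, and the unrooted three-taxon closure.
Ties take the smallest index pair under current order, so output is
deterministic; negative branch-length estimates are clamped to zero and
counted on the returned tree (`negative_branches_clamped`).  On any
additive matrix this recovers the generating topology and branch lengths
exactly, which the tests verify against forward-constructed trees
(n = 4–8) and, for five taxa, against exhaustive least-squares fits of all
15 unrooted topologies; an independent library implementation is used as a
cross-check on non-additive input.

## Assay quantification

The osmotic water permeability of one oocyte is
`Pf = V0·[d(V/V0)/dt] / (S·Vw·(Osm_in − Osm_out))` in cm/s, with
osmolarities converted from mOsm to mol/cm³ (factor 1e-6) and the molar
volume of water Vw = 18 cm³/mol (the value is sometimes misprinted with
volume-per-ml units; dimensional analysis of the formula requires molar
volume, and the constant used is recorded in the output).  The slope is an
ordinary least-squares fit of V/V0 against time over the first 20 s
(2-s imaging interval), the initial linear regime of the swelling
response; no exponential model is fitted.  When only a diameter is given
the oocyte is treated as a sphere (V0 = πd³/6, S = πd²); explicit V0/S
columns override.  Hypo-osmotic swelling yields a positive Pf by sign
convention.

Group comparisons use the classical pooled-variance unpaired Student's
t test, two-sided, significant at p < 0.01 (Welch's form available via
`welch=True`); SEM = SD/√n; fold-change is the expressing-group mean over
the control mean.  Uptake counts are corrected per oocyte by subtracting
the zero-time baseline (signal from externally bound solute), floored at
zero with a flag.  Percent inhibition is `(1 − mean_treated/mean_baseline)
× 100`, and a block is called reversible when the recovered group is
statistically indistinguishable from baseline while the treated group is
not.

## Synthetic-data model and its limits

All class roots descend from one deterministic 263-residue ancestral fill
(hydrophobic alphabet inside six TM blocks, hydrophilic elsewhere; Asn and
Cys excluded from fills so the only NPA motifs and mercury-candidate Cys
are implanted ones).  Each class substitutes 25% of non-signature sites
within the same hydropathy category and implants its signature: NPA
triplets, ar/R tetrad (1-based 56/180/189/195), P1–P5.  That places
inter-class identity near 55–63% — comfortably inside the range real MIP
paralog families span — so reference-anchored mapping is exercised in a
realistic regime.  Family variants substitute non-signature sites
uniformly over the 19 alternative residues at the requested divergence
(≤0.6); signature sites are frozen; no indels are introduced by default so
anchor-mapping tests isolate column bookkeeping from gap placement (an
indel-free model is the generator's main idealisation on the sequence
side, together with the absence of rate heterogeneity and tree-structured
descent).

Swelling curves are forward-simulated from the same Pf formula the
estimator inverts, with i.i.d. Gaussian noise on V/V0 (default SD 0.005
per point, a realistic video-densitometry jitter) and the standard assay
geometry (1.2 mm oocyte, 200 → 20 mOsm transfer, 11 points over 20 s).
Simulated true Pf values span 0.01–0.03 cm/s, the range of strongly
expressing oocytes; water-injected controls are simulated near
0.0015 cm/s.  Uptake counts are negative-binomial with variance 1.5× the
mean (mild over-dispersion typical of per-oocyte scintillation counts),
10 oocytes per group, with the recorded zero-time baseline drawn
independently of the bound-solute component actually added to the counts.

Because the swelling generator is the estimator's exact forward model,
passing recovery tests demonstrates correct inversion, units and fitting —
not robustness to model violations such as early-phase curvature,
photobleaching drift or oocyte-to-oocyte geometry error.  Similarly, the
sequence generator shows that feature extraction and classification
recover implanted signatures through realistic divergence, not that the
rule set is complete for natural sequences outside the four encoded
classes.

## Defaults that matter

| Parameter | Default | Where |
| --- | --- | --- |
| Alignment | BLOSUM62, open 10, extend 0.5, global | all identity/mapping |
| TM window / cutoff / merge / min span | 19 / 1.6 / 3 / 15 | `predict_tm_segments` |
| Mercury-Cys window | 15 residues upstream of loop-E NPA | `extract_feature_profile` |
| Frame-ambiguity margin | 5 score units | `extract_feature_profile` |
| Classification score floor | 0.5 | `classify_subfamily` |
| Hybrid identity margin | 10 points | `detect_hybrid_gene` |
| Pf fit window / Vw | 0–20 s / 18 cm³/mol | `compute_pf` |
| Significance level | p < 0.01 | all assay tests |
| Generator: class divergence / swelling noise / uptake dispersion | 0.25 / 0.005 / 1.5 | `simulate` |

All of these are function arguments or config fields and are echoed in the
run manifest, so any run can be reproduced byte-identically from its
manifest alone.
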