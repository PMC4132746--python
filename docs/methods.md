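# Methods

## Thermodynamic model

All melting temperatures come from the two-state nearest-neighbor
model with the unified DNA/DNA parameter set (ΔH in kcal/mol, ΔS in
cal/mol·K per stack, plus terminal initiation terms):

Tm(K) = 1000·ΔH / (ΔS + 0.368·(N−1)·ln[Na⁺] + R·ln(C_T/4))

with defaults [Na⁺] = 50 mM, total strand concentration C_T = 50 nM
(equimolar strands), R = 1.987 cal/mol·K. The entropic salt
correction and the C_T/4 convention match the common oligo-design
implementations; the test suite pins the whole calculation against
Biopython's independent `Tm_NN` (unified table, `saltcorr=5`) to
~1e-6 °C on random 8–40-mers.

Secondary-structure metrics are computed by exhaustive enumeration of
ungapped complementary stems, exact at oligo length (≤ ~60 nt):

- **hairpin_tm** — max duplex Tm over intramolecular stems with a loop
  of ≥ 3 unpaired bases;
- **self_any_tm** — max duplex Tm over stems between two copies of the
  oligo (self-dimer);
- **self_end_tm** — as above but the stem must pair the 3′-terminal
  base (a dimer the polymerase/ligase could act on);
- **end_stability_dg** — |ΔH − T·ΔS| of the 3′-terminal pentamer
  duplex at the 37 °C reference, initiation included.

Because the NN Tm is not monotone under stem extension (initiation
terms change, weak stacks dilute a strong core), every contiguous
sub-stem of each maximal complementary run is scored. When no stem of
≥ 2 bp exists the metric reports the physical floor −273.15 °C; a Tm
whose entropy denominator would be non-negative (no stable duplex) is
floored the same way. All metrics are deterministic.

## Probe design

Candidates are 36-nt windows inside the 3′-terminal 1-kb region
(shorter transcripts use their whole length), kept when the antisense
oligo's Tm ∈ [60, 85] °C and GC ∈ [30, 70] %; the penalty is
|Tm − 68| + 0.5·|GC − 50| (weights configurable), and up to 20
candidates are retained preferring low penalty then poly(A)
proximity. Coordinates are 0-based half-open on the sense strand;
dist_to_polyA = transcript_length − window_end.

Each candidate is extended 4 nt in the probe's 5′ direction — the
transcript's 3′ direction, toward the poly(A) tail — so candidates
must end ≥ 4 nt before the transcript 3′ end. The antisense 40-mer is
split at the midpoint: the acceptor is the 5′ half (its 3′-OH at the
ligation junction), the donor the 3′ half (5′-PO₄ at the junction);
this orientation is forced by the ligation chemistry and by the read
layout AD1 → probe → RCAD2.

QC applies the five strict thresholds (see README) to the
**adaptor-appended** oligos — AD1 + acceptor half and donor half +
RCAD2 — since that is what gets synthesized. The off-target screen
indexes 8-mers of the background transcriptome (both strands via the
query's reverse complement), extends each seed to the maximal exact
run, estimates the off-target Tm as the NN duplex Tm of that matched
run only, and drops a probe set when either half's off-target Tm comes
within 10 °C of that half's on-target Tm. An empty background keeps
everything. Pass rates on real transcriptomes are data-dependent; the
suite asserts only boundedness and monotonicity under threshold
loosening.

Selection is a non-parametric rank sum: rank(dist_to_polyA ascending)
+ rank(penalty ascending), ties by smaller poly(A) distance then
window coordinates; greedy acceptance requires ≥ 10 nt between
selected footprints; at most two sets per transcript. The acceptor's
two 3′-terminal bases are annotated as ribonucleotides (lowercase in
text output) — the ligase requires RNA at exactly those positions.

## Barcodes

Well (8 nt) and plate (7 nt) sets are built by a seeded shuffle of all
k-mers with greedy accept-if-compatible: GC ∈ [25, 75] %, homopolymer
runs ≤ 3 (synthesizability), pairwise **Levenshtein** distance ≥ 2
(edit distance, not Hamming — indels are in scope). Assignment is
exact-match first, then unique-within-distance-1 rescue; any tie is
UNASSIGNED, which guarantees no misassignment for corruptions within
⌊(d_min−1)/2⌋ substitutions. The plate barcode is read as the first
7 bases of the 8-base index read (the trailing base is a filler; both
lengths are configurable).

## Read simulation

Reads follow the fixed anatomy 8 + 17 + 40 + 34 = 99 nt padded with
'A' to 100. Counts per (probe, sample) cell are one multinomial draw
over the expected-abundance matrix divided by each probe's predicted
decoy fold reduction. A read is chimeric with probability
`off_target_rate`, replacing its donor with a uniformly drawn other
probe's donor. Errors are i.i.d. per-base substitutions (uniform over
the three alternatives) on read and index read alike; indels are off
by default. Identical config + seed reproduces byte-identical output.

The generator emulates pooled screening data (shared anatomy, decoy
response, chimera rate, substitution noise). It does **not** model
base-quality structure, PCR duplicates, indel-rich error modes, or the
sequence-composition biases of real libraries, so passing round-trips
demonstrates correctness of the deconvolution logic under the stated
error model, not performance on any particular instrument run.

## Deconvolution

Stage order: plate demultiplex → collapse to unique sequences (counts
preserved) → anatomy parse → well assignment → probe mapping. AD1 is
located by exact string match with a single-substitution rescue at the
expected offset ± 2; the probe region ends at the exact tail match
(full 34-mer, then the RCAD2 prefix) or the read end. Observed well
barcodes must have length in (6, 10) exclusive.

Mapping mimics blastn-short: match +1, mismatch −3, gap open 5, gap
extend 2, word size 8, plus strand only. Word seeds select candidate
references among all acceptor×donor concatenations; each candidate is
scored by an **exact** affine-gap Smith–Waterman (references are
40-mers, so the full DP is cheap and strictly dominates the x-drop
heuristic it replaces; the x-drop setting is accepted in the config
for compatibility). The single best score wins, ties resolved to the
lowest (acceptor, donor) index; the hit is kept only if alignment
length > 30 and query start < 6 (0-based — the BLAST convention is
1-based, which shifts the cutoff by one position; the filters replace
E-value thresholds, which would need a database-size model). A hit
with acceptor index ≠ donor index is an off-target ligation event.
Per-stage tallies (plate-unassigned, unparsed, length-filtered,
well-unassigned, no-hit, mapped on/off) always sum to the input read
count, and the pipeline asserts this.

### Analytic retention

For round-trip tests at nonzero error rate, the expected mapped
fraction is computed by exhaustive enumeration of substitution
patterns through the actual pipeline policies, exploiting that errors
hit disjoint read segments independently: ≤ 2 errors per barcode
segment (all 3^e substitution choices, via the real assignment
function), the closed form P₀+P₁ for the 17-nt AD1 (the rescue accepts
exactly ≤ 1 mismatch), and ≤ 3 error positions in the 40-nt probe
region (deterministic base rotation; the substituted identity only
matters through rare cross-probe matches). Heavier patterns are
bracketed all-fail/all-pass, so tests compare the observed fraction to
[lo − 3σ, hi + 3σ] — an honest band, not a fitted one.

## Decoy model and analytics

mix_ratio = 1/authentic fraction. Predicted fold reduction: acceptor
decoys track the dilution (ratio *m* → *m*-fold); donor decoys are
amplified by the empirical factor *f* (default 3.5, the midpoint of
the observed ~3–4× band — treated as a purely empirical multiplier,
configurable); decoying both multiplies the components. Planning
(`recommend_mix_ratios`) caps each probe's expected read share at a
target; because shares renormalize after decoying, the naive ratio
share/target undershoots, so by default ratios are solved in closed
form (iterated water-filling over the set of capped probes) so
decoyed probes land exactly on the target share in expectation; the
naive rule is available via `correct_renormalization=False`. A target
below 1/n_probes is rejected as infeasible.

Fold change: fc = ((a+1)/ΣA) / ((b+1)/ΣB) — pseudocount 1 on the
numerators, raw library totals as denominators (display convention for
log–log comparisons). Clustering: rows are z-scored (population sd,
ddof 0; constant rows excluded with a warning), then average-linkage
hierarchical clustering on Euclidean distances, samples first, then
probe sets; leaf order is scipy's deterministic ordering and
dendrograms are emitted as Newick.

## Problem sizes and numerical choices

Test simulations use a 6-probe panel designed on 6 random 800-nt
transcripts, 8 wells × 2 plates, and 10k–50k reads — large enough
that 3σ binomial bands are a few tenths of a percent while the whole
suite stays fast. The 50 × 1.5-kb design exercise and the 384-barcode
generation run at full published scale. Oracle-equivalence checks use
≤ 30-mers (thermo) and 5-probe instances (mapper), where exhaustive
enumeration is exact. All randomness is seeded; reruns are
bit-identical.

## Known limitations

- Thermodynamics covers perfect DNA/DNA duplexes only: no mismatch or
  dangling-end parameters, no RNA/DNA hybrids (probe–template binding
  is approximated by the DNA duplex of the probe).
- The designer targets 3′-proximal windows; splice-junction and
  isotype-junction probe placement is out of scope.
- The off-target screen scores exact matched runs; a long imperfect
  duplex interrupted by single mismatches is underestimated.
- Retention enumeration assumes substitution-only errors; indel modes
  are simulated but not covered by the analytic expectation.
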