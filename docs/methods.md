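# Methods

## Junction model

A loxPsym locus `i` on the parental genome defines two flanks: `U_i`, the
`flank_len` bases ending immediately before the 34-bp motif, and `D_i`, the
bases starting immediately after it. A junction is an unordered pair of
*ends* — `(i, u)` or `(i, d)` — and its reference sequence is
`left + loxPsym + right`, where an end contributes `U_i` (for `u`) or
`revcomp(D_i)` (for `d`) on the left and symmetrically on the right. Because
loxPsym equals its own reverse complement, a junction sequence and its
reverse complement are one object, which is also why reads are scanned on
the forward strand only. For `L` usable loci the pool holds `L` parental
entries and `4·C(L,2)` recombinant ones; self-pair (foldback) entries such
as `{u_i,u_i}` exist behind a flag but are excluded by default so that the
pair accounting matches the `C(L,2)` convention. Co-located tandem copies of
the motif at one locus are collapsed: at flank resolution a junction between
two copies of the same locus is indistinguishable from the parental
junction.

Cre-mediated events map onto end pairs as follows (derived on explicit
sequence and enforced by a truth-completeness test that re-discovers every
junction in the emitted genome by exhaustive motif scanning):

| event | junctions created |
|---|---|
| deletion i..j | `{u_i, d_j}` |
| inversion i..j | `{u_i, u_j}`, `{d_i, d_j}` |
| tandem duplication i..j | `{u_j, d_i}` |
| reciprocal translocation i/j | `{u_i, d_j}`, `{u_j, d_i}` |
| non-reciprocal translocation i/j | `{u_i, d_j}` (+ copy-number changes) |
| circularization i..j | `{u_j, d_i}`, topology circular |
| inverted duplication i..j | `{u_j, u_j}` (foldback self-pair), `{d_i, d_j}` |

Events are applied sequentially; site positions are re-resolved by id
against the current genome state, so multi-event simulations compose (an
inversion after a translocation acts on the moved site). Later events can
destroy earlier junctions; the acceptance truth is therefore the junction
set of the *final* genome, which the event log derives from the final state
rather than by unioning per-event contributions.

## Classification

Motif occurrences are found by iterated best-first infix search (edlib) with
masking, reporting all non-overlapping occurrences within `max_lox_edits`
(default 3) edits. For each occurrence, the read context on each side (up to
`flank_len`, motif excluded) is aligned against every locus flank in both
left/right roles, anchored at the motif boundary (prefix-mode alignment of
the reversed left context, forward right context). The affine score
(match +1, mismatch −1, gap open −2, gap extend −1) is recomputed from the
alignment path; an entry's score is the better of its two orientations. A
call requires the best entry to lead the runner-up by `min_score_margin`
(default 20 score units — the internal analogue of a mapping-quality
uniqueness filter) and both flanks to be covered to `min_flank_cov` (default
0.5); occurrences closer than `min_flank_cov·flank_len` to a read end, and
exact ties, are left unclassified rather than assigned arbitrarily. Each
occurrence contributes at most one count; a read spanning two motifs
contributes two independent counts.

With 1 kb flanks of essentially random sequence, the correct entry at 5 %
read error typically scores hundreds of units above any entry differing in
either flank, so the margin filter costs little sensitivity; the
flank-length robustness study confirms identical event sets at flank lengths
500/1000/1500/2500 on zero-error reads.

## Rate statistics

`RR_i = Nre_i/(2·Nnorm_i + Nre_i)`: a normal read covers both flanks of one
locus, a rearranged read covers one flank each of two loci, hence the factor
2 in the observation depth `Nall_i`. `RW_ij = Nre_ij/√(Nall_i·Nall_j)` is
invariant under uniform rescaling of all counts (sequencing depth), which
the test suite checks on 1 000 random count tables.

ARR admits more than one reading of "normalised to the total number of
rearranged sites"; the default here divides the class-restricted rate by the
number of possible partner loci of that class
(`ARR_{i,cls} = (Nre_{i,cls}/Nall_i)/P_{i,cls}`), which makes intra and
inter values comparable per partner opportunity and gives both classes
identical expectations under uniform recombination. A `normalization=
"global"` switch divides by the number of rearranged loci instead. One
caveat found while validating the null: per-locus ARR values are mutually
dependent (loci share pair counts), so a rank test between the intra and
inter collections is anticonservative even under a uniform null — the null
study asserts equality of pooled means and absence of consistent separation
rather than a nominal rejection rate. The analytic null for event classes is
the pair fraction `Σ_c C(n_c,2) / C(L,2)` (7.6 % intra for the 83-site
layout), to which simulated uniform-recombination event mixes converge.

Outliers use the upper Tukey fence (Q3 + 1.5·IQR, interpolated quartiles).
The distance regression is OLS of RW on 1/d over pairs whose loci lie
strictly on one side of the centromere interval; centromere-spanning pairs
are excluded. Group tests are the two-sided Mann–Whitney (intra vs inter
ARR) and the unpaired two-tailed t-test (open vs closed chromatin,
membership by motif-position overlap with any interval). Contact-map
utilities provide the Spearman correlation of RW with binned contact counts
over inter-chromosomal pairs and the median-normalised log2 ratio of two
maps with non-positive cells masked.

## Copy number and LOH

Depth is computed over the 2 000-bp windows on each side of each locus on
the parental reference. Reads are placed by exact 21-mer seeds indexed over
the windows (both strands), taking the median seed offset per read/window
pair with at least 3 seed votes — a deliberate replacement for an external
aligner that is robust at the ≤10 % error rates simulated here. Depth is
mean aligned bases per window position, so clipped junction reads contribute
exactly the part of the window they cover. Each covering read is classified
lox-containing *at that locus* when one of its motif occurrences maps within
80 bp of the locus position; reads spanning the motif position (±50 bp) with
and without a lox there are counted separately, because that spanning count
is the LOH signal.

Copy number per window follows an iterative median re-scaling: with ratio
`r = depth_sample/depth_parent`, a scale `s` (initially `median(r)`) gives
`CN = round(ploidy·r/s)` (half away from zero), and `s` is re-estimated as
the median ratio over windows currently at `CN == ploidy`, until stable
(fallback to the global median, with a warning, if no window sits at the
modal ploidy). Calls further than 0.35 from their integer are flagged
low-confidence. The procedure is scale-invariant by construction. This
re-anchoring scheme is the package's own reconstruction of the iterative
depth-correction idea; no external specification of it was available.

Lox states are assigned with priority absent (CN 0 both flanks) →
rearranged (a supported novel junction touches the locus) → lox_lost (the
parent carried lox, flank depth persists, but no spanning read carries a lox
— LOH) → wildtype_only (parent lox-free) → intact_lox. SV hypotheses
combine junctions with the four flank-window copy numbers of the two loci:
uniform chromosome-wide shifts are aneuploidy; an intra up/down junction
with reduced interior is a deletion; gained plus lost flanks mean a
non-reciprocal translocation; gain without loss a duplication insertion; two
complementary junctions with balanced copy number a reciprocal
translocation.

## Deconvolution

A chromosome's lox sites cut it into segments 1..N+1; site `k`'s upstream
flank is segment `k`'s tail and its downstream flank segment `k+1`'s head,
so junction calls translate directly into segment-end adjacencies. Reads
are first partitioned by marker (recoded-tag) sequences: a read goes to the
variant whose markers strictly outnumber the other's (approximate match,
≤2 edits, both strands); ties and zero hits stay unassigned. Occurrences
whose sides match no segment end are reported as unassigned junctions
(e.g. homologous-recombination fusions) rather than dropped.

Reconstruction builds a multigraph on segment ends — each copy of a segment
an obligatory head–tail edge, each accepted junction observation (support ≥
2 reads by default, 1 in zero-error settings) an edge to traverse exactly
once — and searches for Eulerian traversals that alternate segment and
junction edges: linear when junction edges number one less than segment
copies, circular when they are equal and the last edge closes the loop.
Edges are explored in sorted order, solutions are canonicalised modulo
global flip (and rotation for circles) with an optional anchor segment kept
in + orientation, and enumeration stops at a configurable cap (default 16)
with an ambiguity flag. Inconsistent observations raise an error listing
the end-degree imbalance instead of guessing. An exhaustive signed-
permutation oracle validates the search for small segment counts, and the
acceptance sweep rebuilds all ~25 000 canonical arrangements of up to six
segments exactly.

## Synthetic data: what it does and does not emulate

The generator produces uniform-composition random genomes at a configurable
GC fraction (default 0.38), splices one motif per locus, and simulates reads
with lognormal lengths (default median ~10 kb), uniform strand, and i.i.d.
per-base substitution/insertion/deletion errors (default 3 %/1 %/1 %).
The 83-site layout ships per-chromosome locus counts chosen so that every
site id named in published analyses of the strain exists, the 75 distinct
loci give exactly 210 intra-chromosomal pairs of 2 775, and even spacing
between ~74 kb telomeric margins reproduces the ~145 kb mean adjacent-site
distance; the true per-site coordinates are not public, so this layout is
synthetic and is labelled as such. Not modelled: homopolymer-dependent or
strand-dependent ONT error structure, chimeric library artefacts,
repeat-induced mapping ambiguity, fitness/selection during SCRaMbLE, and
real chromatin landscapes. Passing the round-trip studies therefore
demonstrates correctness of the pipeline's logic under calibrated noise,
not performance on arbitrary real libraries.

## Study problem sizes

The reference studies are sized for single-CPU verification: the junction
round trip uses a 5×0.5 Mb genome, 20 loci, 10 events and 20× reads at 5 %
error; the zero-error oracle uses ≤10 loci on ≤1 Mb. The diploid CNV/LOH
study uses 5×80 kb chromosomes with two loci each and deeper sequencing
(100× per copy, 200× parent, ~4.5 kb reads): mean depth over a 2 kb window
has near-Poisson sampling variance for multi-kilobase reads
(CV ≈ 1/√depth), so these depths keep the CN 2 vs 3 separation at several
standard deviations, the regime the window-depth method needs regardless of
genome size. Marker partitioning uses one marker pair per ~1.7 kb,
mirroring recoded-tag density on synthetic chromosomes.

## Known limitations

- Junctions between two copies of one locus (normal-vs-self) and foldback
  self-pairs are not separable from parental junctions at flank resolution;
  foldback entries are off by default.
- LOH calling needs the parent to be heterozygous for the motif; it cannot
  distinguish conversion direction when both haplotypes carry lox.
- The seed-anchored placement assumes flank windows are locally unique;
  heavily repetitive flanks would need a true aligner.
- Arrangements whose junction coverage is incomplete are reported as errors,
  not imputed; duplicated segments can make several arrangements consistent,
  in which case all (up to the cap) are returned and flagged.
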