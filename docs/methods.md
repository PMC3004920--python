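# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Gene architecture assumed throughout

An intron-containing double-homeobox (DUX-type) gene is modelled with five
exons: exon 1 (N-terminal coding), exons 2/3 carrying homeodomain 1 and
exons 4/5 carrying homeodomain 2, with both introns interrupting the
60-codon homeobox at the same codon. The intra-homeobox splice codon is a
free parameter (`hd_splice_codon`, default 47, valid 1–59): the family's
splice positions are equivalent across paralogues, but the exact residue is
not fixed by any observation we rely on, so nothing downstream may depend
on its particular value — the scanner, classifier and simulators all take
it as configuration. All splice sites are canonical GT..AG.

Coordinates are 0-based half-open everywhere in memory; GFF3 on disk keeps
1-based inclusive coordinates, converted exactly once per direction.

## Synthetic family evolution (`family_sim`)

Sequences evolve along a user-supplied Newick species tree (branch lengths
in substitutions/site) under JC69 (default) or K2P(κ), substitutions only.
Insertions, deletions, gaps, retro-insertions and duplications enter
exclusively through explicit, branch-addressed events, so every truth label
is unambiguous. Events are applied at the end of their branch
(evolve-then-edit), and planted lesions (e.g. a nonsense codon) are frozen
against reversion on descendant branches.

Rate structure: introns and spacers evolve at the nominal rate; DUX exons
at `exon_rate` (default 0.5×) and anchor genes at `anchor_rate` (default
0.3×), reflecting purifying selection and the requirement — which motivated
anchor-based synteny mapping in the first place — that anchors stay
alignable at divergences where the gene of interest degrades.

Two deviations from a purely neutral model are deliberate:

* **Nonsense protection.** In coding segments of genes the truth set calls
  intact, a substitution creating a stop codon is locally repaired
  (minimal reversion within the codon). Real intact genes persist under
  selection against nonsense alleles; without this, an "intact" gene at
  0.25 substitutions/site pairwise divergence would carry several spurious
  stops and the truth labels would be meaningless. The public
  `evolve_sequence` API is unprotected; protection is applied only by the
  genome-level simulator.
* **Frozen splice dinucleotides.** The GT/AG termini of introns are held
  fixed, for the same reason: losing a splice signal is a gene-inactivating
  mutation that selection removes from intact lineages.

The ancestral homeodomains are fixed: HD2 differs from HD1 at 14 positions,
so the domain duplication predates the root of every simulated tree — the
history the duplication-timing test must recover. The single-domain
outgroup used for rooting carries a third-state residue at each of those 14
positions plus 8 private ones, making it exactly equidistant (22
substitutions) from both domain ancestors, which is what "diverged before
the domain duplication" implies; an outgroup closer to one domain than the
domains are to each other would attach inside that domain's radiation and
cannot root the test.

What the generator does **not** emulate: indel evolution in the background,
repeat landscapes, rate heterogeneity across sites, codon-usage bias,
segmental rearrangements beyond single deletions. Benchmarks passed on this
generator therefore demonstrate the correctness of the inference logic
under its stated model, not performance on raw vertebrate assemblies.

## Homeodomain scanning (`hd_scan`)

The profile is a 60 × 20 log-odds matrix,
`score(r) = log2(((count_r + τ·bg_r)/(n + τ)) / bg_r)` with pseudocount
τ = 1 and uniform background by default, built from a seed alignment of
known homeodomains (the simulator seeds it with the two ancestral domains).
Scanning sums column scores over every 60-residue window of all six
conceptual translations; any codon containing an ambiguous base translates
to X (scored 0), and a stop anywhere in the window vetoes the full-length
hit. Hits are greedy non-overlapping local maxima above `threshold_bits`
(default 25 — calibrated on the i.i.d. null so a 10 kb window is expected
to yield far fewer than 0.01 false hits; a planted homeodomain scores
~180 bits even at benchmark divergence).

Split homeoboxes are found via the two sub-profiles flanking the splice
codon. Half thresholds are **per column** (`half_bits_per_col`, default
1.7): with the splice at codon 47 the 3′ half has only 13 columns, and a
linear share of the full threshold (0.42 bits/col) would admit on the
order of ten random hits per window, whereas at 1.7 bits/col a false hit
needs ≥ 8/13 identities to the consensus (expected count ≪ 0.1 per window)
while genuine diverged halves score ≥ ~2.4 bits/col. Halves shorter than 8
residues are not searched. Colinear 5′/3′ halves on one strand, separated
by ≤ `max_intron` (default 10 kb) with GT..AG at the boundaries, merge into
a full hit whose score is the sum of its parts; merging is restricted to
halves assigned to the same homeodomain (HD1 vs HD2, by the per-domain
sub-profiles), because a 5′ half whose true partner fell below threshold
would otherwise capture the next domain's 3′ half across a chance GT..AG.

Unsplit full-profile hits are validated half-by-half: the 60-column window
reads straight through a splice junction into the intron, and a stop-free
in-frame intron stretch (probability ≈ 0.54 for 13 codons) otherwise fakes
a complete domain on the strength of the exonic half alone. A full hit
whose 5′ or 3′ half scores below the (relaxed, see below) half bar is
demoted to the passing half.

## Ortholog calling (`ortholog_call`)

Hits in a (coding-strand-normalised) window are partitioned into candidate
array units — a new unit opens when an HD1-class hit follows an HD2-class
hit or after a gap of `max_gene_span` (default 8 kb) — so tandem arrays are
called per copy and copy counts reported.

For a domain represented by a single half, the classifier probes for the
other half: first a **splice-anchored** search (donor/acceptor consistent
with the present half, candidate region translated and scored leniently,
stops allowed), then an unconstrained lenient scan of the neighbourhood in
all three frame offsets. The anchored search examines only ~50
donor–acceptor candidates rather than ~3 × 10⁴ window positions, so it may
accept at `anchored_relax` (default 0.6) times the genome-wide half bar
without raising the false-positive rate; the unconstrained scan keeps the
full bar. Probes never accept a span overlapping hits assigned to the other
homeodomain. Probe outcomes map to evidence: residues with `*` →
`premature_stop`; a hit in an incompatible frame → `frameshift`; nothing →
`missing_exon`.

Frameshifts hidden inside apparently complete domains are detected by a
shifted-frame scan: per codon-aligned part, per-column profile scores in
the claimed frame are compared with the two shifted frames, and a maximal
contiguous segment (Kadane) where a shifted frame wins by
`frameshift_margin_bits` (default 25 — about six consecutive columns
decoding better out of frame) marks the lesion. Clean domains essentially
never trigger this, since shifted frames decode garbage everywhere.

Status rules: **intact** requires both domains complete and stop-free plus
an in-frame, stop-free coding path between them — either direct
read-through (which, with unsplit domains, also raises the retrocopy flag)
or a single GT..AG intron found by donor/acceptor enumeration
(`max_linker_exon` 300 bp of coding tail per side, intron length within
[`min_intron` = 40, `max_intron`]). **pseudogene** requires observed lesion
evidence. **unclear** is assigned when an N-run ≥ `gap_min` (default 50 bp)
overlaps the expected locus and no intact model exists — including the case
where the only lesion is a missing exon whose expected location is gapped.
**absent** is the residual. Precedence across array units: an intact copy
anywhere makes the family cell intact.

## Phylogenetics (`phylo_infer`)

Distances are computed with pairwise deletion of undefined columns
(gap/X/*): p-distance or Poisson correction d = −ln(1 − p). Tree search is
neighbor joining with the standard Q criterion, deterministic tie-breaking
by smallest original-taxon-index pair, and negative branch lengths clamped
to zero; on any additive matrix NJ returns the generating topology with
exact branch lengths (verified against an exhaustive least-squares
topology oracle in the tests). Maximum-likelihood search is deliberately
out of scope: the quantities consumed downstream are topology and support,
which the distance/NJ route reproduces at a fraction of the cost, and this
substitution is documented rather than hidden — published ML branch scores
are not expected to match bit-for-bit.

Bootstrap: columns resampled with replacement, default 100 replicates; the
support of a bipartition is its replicate percentage; majority-rule
consensus keeps bipartitions above 50% (all mutually compatible by
construction) and branch lengths are refit on the consensus topology from
the original matrix by non-negative least squares.

Duplication timing: the tree is rooted at the outgroup; if the HD1 taxa of
all genes form one supported clade and the HD2 taxa another, the verdict is
`pre_speciation`; if every gene's HD1+HD2 pair is a clade,
`post_speciation`; anything else — polytomies, mixed clustering, or
configurations whose defining nodes carry support below `support_floor`
(default 70) — is `unresolved`. Long-branch artefacts are a known failure
mode of distance methods; the floor exists so that weakly supported
configurations are not over-interpreted.

## dN/dS (`selection_dnds`)

Site counting, difference counting and correction follow the unweighted
NG86 pathway method: per codon position the synonymous fraction is
(synonymous changes)/(changes not creating a stop); differences average
synonymous/nonsynonymous steps over all k! orderings, excluding orderings
that pass through a stop (if all are excluded the codon falls back to
per-position counting and is flagged); pS = Sd/S and pN = Nd/N receive the
Jukes–Cantor correction, which is undefined at p ≥ 3/4 and raises rather
than extrapolating. ω is reported as 0 when dN = 0 and as undefined (never
infinity) when dS = 0; gapped codon columns are dropped pairwise with a
count. Family means are arithmetic means over all unordered pairs. The
implementation is checked against an independent brute-force enumerator on
hundreds of random codon pairs to 10⁻⁹.

The benchmark for selection inference evolves a four-tip star from one
ancestor with nonsynonymous substitutions accepted at probability ω
(rejection sampling, stop-gains always rejected) and verifies the NG86 mean
recovers the target regime (ω < 1, within sampling error of the nominal
0.3). C-terminal-domain analyses on real orthologue sets are supported by
supplying the codon alignment and span directly.

## Fusion by deletion (`fusion_sim`)

The tandem locus carries two identically oriented single-homeobox copies:
exon 1 = upstream coding (default 30 codons) + homeobox 5′ part; intron
(default 300 bp); exon 2 = homeobox 3′ part + long ORF (total exon-2 length
default 989 bp, the observed mean for such copies); intergenic spacer
default 5 kb. A deletion draws its left breakpoint uniformly in copy 1's
exon-2 ORF downstream of the homeodomain and its right breakpoint uniformly
upstream of copy 2's homeobox (breakpoints inside the homeobox violate the
model's constraint that HD2 survive, and are rejected as input errors);
original splice signals are retained by construction. The junction is in
frame iff the two coding offsets agree mod 3 — probability exactly 1/3 for
interval lengths divisible by 3, independent of geometry, and that
independence is itself tested. `stop_free` and `hd2_intact` are evaluated
on the translation of the spliced fused transcript; the
`new_intron_len` field measures the junction material stranded between the
two homeoboxes (the raw material of the short intron 3 such a fusion
predicts), and shrinks stochastically as the right breakpoint interval
moves toward the homeobox.

## Benchmark problem sizes

The default study conditions are: 6 species (maximum pairwise divergence
0.25 substitutions/site), 4 families, ~11 kb per locus window, with seven
event types planted on named branches; 100 random additive matrices of 4–8
taxa for NJ; 100 independently seeded 4-species families for the
duplication-timing rate; 10⁴ deletion draws for frame retention; 200 random
codon pairs of ≤ 30 codons for the NG86 cross-check. These sizes keep a
complete verification run in minutes on one core while leaving each
statistic's sampling error well inside the margins it is judged against.

## Known limitations

* The classifier is tuned to the simulator's gene architecture (one intron
  per homeobox, canonical splice sites, single-deletion lesions); real
  assemblies add noise sources (sequencing error, fragmented contigs,
  repeat interference) that the generator does not model.
* Distance/NJ trees can misplace long branches where ML might not; the
  support floor mitigates but does not remove this.
* The linker search considers at most one intron between the domains, so
  exotic multi-intron linkers would be scored as ORF discontinuities.
* `user_fasta` pipeline mode is limited to the library API
  (`ortholog_call.analyze_window` on user windows); the orchestrated CLI
  path is synthetic-first.
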