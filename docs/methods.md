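# Methods

## The inference problem

Three C3 panicoid grasses are represented only by long-read consensus
transcripts; eight grass species have annotated reference CDS sets and a
sorghum-anchored table of syntenic orthologs.  The pipeline joins the two
data types into per-gene codon alignments over up to eleven taxa
(`Oryza`, `Brachypodium`, `Oropetium`, `Eragrostis`, `Pennisetum`,
`Setaria`, `Sorghum`, `Zea` from annotation; `Dichanthelium`,
`Chasmanthium`, `Hymenachne` from transcripts), builds one tree per
alignment, and counts rooted topologies.  Rice and brachypodium (the BOP
clade) are the fixed outgroup pair.

## CDS calling

Consensus transcripts from oligo-dT libraries are polyA-oriented but may
lack their 5' end.  Each forward frame is partitioned into segments
bounded by stop codons; every segment that *ends* in a stop is a
candidate ORF and the longest candidate is the CDS.  An in-frame ATG
anywhere within the segment sets `has_start` but is not required, which
can prepend a few untranslated codons to the CDS; requiring a start would
instead truncate real coding sequence on 5'-damaged transcripts.  Length
ties prefer the 5'-most segment, then the lowest frame index.  Codons
containing ambiguity codes translate to `X` and do not disqualify a
segment.  A separate six-frame stop scan (forward and reverse frames) is
used only for quality triage: a transcript with no stop anywhere is
unusable and feeds the discard ledger.  A CDS is "complete" when it has
start and stop and covers ≥ 60% of its transcript.

## Similarity search and orthology

Hits are local alignments (match +1, mismatch −1, gap open −2, extend −1;
`Bio.Align.PairwiseAligner` behind the module surface) kept when
alignment identity ≥ 0.70 and query coverage ≥ 0.50.  Coverage is defined
on the query; each direction of the bidirectional search applies the
thresholds on its own query.  Identity counts matches over all alignment
columns, gap columns included.  Two shortcuts keep the all-vs-all scan at
desk scale without changing results on homologous pairs: byte-identical
query sequences (redundant isoforms) are aligned once, and only subjects
sharing an exact 12-mer with the query are aligned (at most four, ranked
by shared-seed count) — the same seed-and-extend assumption every seeded
DNA search tool makes.  The tiny set of transcripts with no callable CDS
is instead assigned to loci by an exhaustive raw-sequence scan at looser
thresholds (identity ≥ 0.5, coverage ≥ 0.3), because heavy corruption can
destroy every exact seed; this assignment is used only for redundancy
statistics and the discard ledger, never for orthology calls.

A transcript and an anchor gene are orthologs when each is the other's
unique top-scoring hit.  Score ties normally disqualify a query
(conservative: no arbitrary orthology), with one exception: ties among
byte-identical subject sequences are resolved to the lexicographically
smallest id, since identical isoforms are not alternative orthologs.  Per
anchor gene one representative transcript is selected: highest RBH score,
then longer CDS, then smallest id.

## Groups and categories

Orthology is transitive across the synteny table: a transcript RBH-linked
to anchor gene *g* joins the group of every syntenic ortholog of *g*.
Groups are strictly anchored on sorghum; rows without an anchor id are
skipped with a warning.  Each target species contributes at most its
single representative.  The category of a group is the number of target
species represented (0–3); only category-3 groups are aligned.

## WGD combination samples

The maize-like (Zea) and teff-like (Eragrostis) lineages carry
independent whole-genome duplications; a group may hold a retained
duplicate pair in either.  To keep a fixed number of leaves per tree,
each retained pair is sampled one copy at a time: 1, 2 or 4 combination
alignments per group (2^number of retained lineages).

## Codon alignment and block filtering

CDS sequences are translated (internal stops preserved as `*`), the
proteins aligned, and each gap expanded to a whole-codon gap; terminal
stop codons are appended as three trailing columns, so degapping any row
reproduces its input CDS exactly (asserted as a round-trip invariant).
The default protein aligner is an internal progressive profile aligner:
3-mer guide distances, average-linkage guide tree, profile–profile Gotoh
with BLOSUM62, gap open −11 / extend −1, and free terminal gaps (so
amino-terminally truncated sequences align as suffixes without penalty).
The `protein_aligner` argument accepts any drop-in replacement.

Block filtering operates on the protein projection with the classic
conserved-block defaults: a column is conserved when its majority residue
count reaches ⌊n/2⌋+1 and highly conserved at ⌈0.85·n⌉ (majority ties
count as nonconserved); any gap makes a column non-retainable; runs of
more than 8 contiguous nonconserved columns break blocks; block flanks
are trimmed back to highly conserved columns; blocks shorter than 10
columns are dropped.  Surviving protein columns expand to codon columns.
Masked length ≥ 900 nt (300 codons) defines the "long" subset; shorter
masked alignments stay in the all-genes census and are only flagged.

## Discard ledger

Groups are discarded before alignment when (a) any reference CDS in the
group translates with an internal stop, (b) any transcript assigned to
the group's loci has no stop codon in any of six frames, or (c) a synteny
cell's gene id has no sequence in the reference CDS set (covering both
deleted and renamed annotations).  `short_alignment` and
`outgroup_not_monophyletic` entries are bookkeeping, not discards from
the all-genes analysis.  On synthetic data the recovered entry set must
equal the planted defect set exactly, per reason.

## Trees, rooting, census, bootstrap

Pairwise Jukes–Cantor distances are computed over shared non-gap masked
columns, d = −3/4·ln(1 − 4p/3), with saturated distances (p ≥ 0.75, or no
shared sites) clamped at 5.0 substitutions/site.  Trees are built by
neighbor joining (`skbio.tree.nj`); the builder is deterministic and
pluggable, and an external maximum-likelihood adapter can be slotted in
without touching the rest of the chain.  A tree is accepted only if some
edge splits exactly {Oryza, Brachypodium} from all other taxa; the tree
is rooted on that edge (splitting its length evenly).  Rooted topologies
are canonicalized by stripping branch lengths and recursively sorting
children by their canonical strings; the census tallies canonical strings
and reports percentages *truncated* to one decimal, matching the
convention under which the study-design percentages (42.5, 6.2, 65.7,
54.2, 41.3, 17.5) are all exactly reproducible from their printed
numerators and denominators.

Bootstrap supports resample masked codon columns (codons, not single
sites) with replacement, rebuild and re-root trees, and score each branch
of an alignment's best tree by the fraction of replicates containing that
clade.  Groups are drawn from all accepted alignments without
replacement, then binned by their best tree's canonical topology;
supports are averaged within each bin.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed and
not tuned per experiment:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 200 | syntenic gene groups |
| `root_cds_codons` | 500 | root CDS length incl. terminal stop |
| `branch_length` | 0.05 | substitutions/site on every branch |
| `discord_rate` | 0.3 | probability a gene tree is NNI-perturbed |
| `nni_moves` | 1 | NNI moves per perturbed tree |
| `retention_prob_per_wgd_lineage` | 0.30 / 0.91 | maize-like / teff-like duplicate retention |
| `expression_dropout` | 0.39 | per-species probability a locus emits nothing |
| `isoform_mean` | 10 | Poisson mean; emitted isoforms = Poisson+1 |
| `truncation_prob` | 0.2 | probability an isoform loses a 5' fraction (uniform ≤ 50%) |
| `defect_rates` | 0.022 / 0.012 / 0.011 | internal stop / stop-free / missing annotation |

Retention, dropout, isoform redundancy and the defect shares mirror the
observed statistics of the modelled study (30% of syntenic maize genes
and 91% of teff genes retained as pairs; 9.3–12.1 consensus transcripts
per represented sorghum gene; discard reasons in proportion 113:61:57 of
5,139).  The branch length is a free parameter — the eleven-taxon panel
has no published divergence depths at this granularity — chosen so that
target-to-anchor CDS identity lands in the 0.75–0.85 band, comfortably
above the 0.70 orthology threshold yet far from saturation.

Sequences evolve by per-site Jukes–Cantor substitution, p = 3/4·(1 −
exp(−4b/3)) per branch of length b, with any mutation creating an
in-frame internal stop redrawn from the 61 sense codons; the terminal
stop is held fixed.  Gene-tree discordance is generated by NNI moves on
internal edges strictly inside the ingroup, so the outgroup pair is
monophyletic in every gene tree by construction — NNI was chosen over a
coalescent because it controls topological distance directly with no
population-size parameter.  WGD duplicates evolve independently along the
full terminal branch of the duplicated lineage.  Transcripts are the CDS
padded with 100 nt 5' and 150 nt 3' UTR; both UTRs carry a `TAACTAACTAA`
cassette (a stop in every frame wherever placed) adjacent to the CDS, so
the planted CDS is the longest ORF by construction.  The stop-free defect
recodes every `T` to `C` in one isoform — no stop codon survives in any
frame on either strand, while ~75% identity to the locus is kept so the
defective transcript remains assignable; it is planted only on loci with
at least two isoforms so the group itself still forms and exact ledger
recovery is well defined.  Determinism: all randomness derives from
(seed, stream, gene index) substreams, so outputs are byte-identical for
a given config and gene counts can grow without reshuffling earlier
genes.

What the generator does **not** emulate: indel evolution (alignments of
clean synthetic data are gap-free except truncation), realistic codon
usage or rate heterogeneity, PacBio error profiles, incomplete lineage
sorting (NNI discordance is topological, not coalescent), and correlated
expression dropout across species (real categories are not Binomial).
Passing tests therefore demonstrate that the *inference chain* is
correct under its stated model, not that real transcriptomes meet the
model's assumptions.

## Problem sizes and numerical choices

Test and acceptance runs use 10–200 gene groups with 500-codon CDS — the
scale at which every stage's behaviour (redundancy collapse, WGD
sampling, ledger recovery, census ranking) is fully exercised while the
whole suite stays desk-sized.  Tie-breaks are deterministic everywhere
(lexicographic ids, lowest frame, canonical string order for census rank
ties).  Degenerate inputs: empty hit tables are empty results, not
errors; a group below category 3 is a hard error for combination
enumeration; trees need ≥ 4 taxa and ≥ 1 masked codon; missing outgroup
taxa are a hard error while a non-monophyletic outgroup is a rejection.

## Known limitations

Neighbor joining replaces the original maximum-likelihood tree builder by
default; on concordant synthetic data with 500 codons the two agree in
essentially every replicate, but NJ support values and branch lengths are
not comparable to ML ones.  The internal progressive aligner is adequate
for closely related, mostly indel-free CDS sets, not for deep or
repeat-rich homology.  The seed prefilter assumes ≥ 70%-identity homologs
share exact 12-mers — true at this divergence, but an external aligner
adapter should be used for more divergent panels.  Synteny detection
itself is out of scope: the synteny table is consumed as given.
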