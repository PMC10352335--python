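# Methods

## The design problem

A bicistronic knock-in places a gene of interest (GOI) immediately after the
stop codon of an endogenous "driver" gene, separated by a short intergenic
linker (IGG) that permits translation re-initiation. The driver keeps its
promoter, coding sequence, stop codon and terminator; the GOI is expressed
from the same transcript at a level proportional to the driver's. The
package turns that wet-lab procedure into a deterministic design pipeline:
select drivers from proteomic abundance, find a Cas9 cut next to each
driver's stop codon, build a donor whose homology arms insert the linked GOI
at the junction, verify the edit in silico, and predict the resulting GOI
level.

## Coordinate model

All internal coordinates are 0-based half-open on the contig's plus strand;
GFF3 (1-based fully closed) is converted at the I/O boundary in both
directions. Each gene model carries a **junction**: the between-base
coordinate immediately 3′ of the stop codon in gene orientation (the
interval end of the stop codon for plus-strand genes, its interval start for
minus-strand genes). Every downstream computation — arm extraction, guide
distance, insertion — is defined relative to the junction, which eliminates
the usual off-by-one ambiguities in cut/junction arithmetic. Homology arms
and junctions are computed on genomic (unspliced) sequence, because that is
what HDR arms physically anneal to; 3′-terminal introns are effectively
absent in the yeast genes this emulates.

Multi-isoform genes use the first mRNA in file order (configurable to
longest CDS); gene models failing CDS invariants (frame, ATG start, terminal
stop, no internal stop, contig bounds) are excluded with a logged reason
rather than aborting a run. An arm containing N is rejected outright, since
it cannot be ordered as a primer.

## Guide model

SpCas9 with NGG PAM only. The blunt cut is placed 3 bp 5′ of the PAM
(between spacer positions 17/18) — the standard SpCas9 geometry. A
plus-strand site with PAM start `p` cuts at `p − 3`; a minus-strand site
appearing as CCN at plus-position `q` cuts at `q + 6`. The distance
constraint is `|cut − junction| ≤ 5` bp by default. The inclusive comparator
was chosen deliberately: the operative design figure describes the break as
falling "within" the bound, and the comparator is exposed (`max_dist`) for
users who want strict inequality. The distance is measured to the junction,
i.e. after the stop codon's last base.

The specificity screen counts exact spacer+NGG matches on both genome
strands and requires exactly one (the on-target site). Mismatch-tolerant
off-target scoring and on-target activity models are deliberately out of
scope — this screen answers only "is the 20-mer unique", which is the
minimal requirement for a markerless knock-in; users needing more should
export the guides and score them with a dedicated tool. GC bounds (0.2–0.8)
and the TTTT exclusion (Pol III terminator) are standard gRNA hygiene,
configurable and removable by flag.

## Donor grammar and primers

Two modes share one grammar machine:

* **pathway** (default, 60-bp arms): `UpTA · IGG · GOI · [tag] · goi_stop ·
  DownTA`, where UpTA ends with the driver's native stop codon.
* **library** (40-bp arms): `UpTA · FLAG · driver_stop · IGG · GOI ·
  goi_stop · DownTA`, where UpTA ends at the last sense codon and the stop
  is re-added after the FLAG epitope, so the driver protein gains a
  C-terminal FLAG for quantification.

The IGG linker sits flush against the stop codon — no spacer bases — and the
GOI's own terminal stop is stripped and replaced by a standardized stop part
(default TAA, configurable) so that a localization tag can be appended in
frame. The packaged IGG default is a clearly marked 9-bp placeholder with
the correct length; the real linker sequence is supplied by configuration.
The MDH3-style peroxisomal tag shipped for demos is likewise a synthetic
9-nt PTS1 (SKL) stand-in.

The primer derivation inverts the grammar: everything 5′ of the GOI becomes
the forward-primer tail, everything 3′ becomes the reverse-primer tail
(reverse-complemented), each followed by a 20-nt annealing region on the
GOI. The module's key invariant — checked for hundreds of random GOIs — is
that in-silico PCR of the bare GOI with the derived primers reconstructs the
donor byte-for-byte. Primers over 100 nt or with annealing-region GC outside
0.3–0.7 warn but do not fail; thermodynamic optimization (Tm, secondary
structure) is out of scope.

An optional `delete_downstream` (default 0) removes that many bp of 3′ UTR
at the junction, reproducing replacement-style constructs; the default
models the knock-in as a pure insertion.

## Edit simulation

HDR is modeled as exact, scarless arm-mediated replacement: both arms are
verified base-by-base against the genome (a mismatch names the offending
offset — this guards against stale annotations), then the donor replaces the
span between the arm-match regions. For pathway mode with no deletion this
is a pure insertion, and deleting the inserted interval restores the input
genome exactly — an identity the test suite checks across 500 random
designs, both strands. Transcription is abstracted: the bicistron is
represented by its coding content (driver ORF + stop + IGG + GOI(+tag) +
stop), translated with the standard nuclear code. The central promise — the
driver protein is untouched by the edit — is asserted for every simulated
design. The re-cut check searches the edited locus (±60 bp of the insert by
default, covering any guide within the 5-bp constraint plus arms) for the
guide's spacer+NGG on either strand; a surviving site is reported as a
design warning, not an error.

In-silico PCR anneals a primer where its 3′-terminal `min_anneal` nt
(default 18) match exactly, allows 5′ tails, and errors on zero or multiple
possible products. Mismatch-tolerant annealing is not modeled.

## Expression model

Two measured ratios parameterize prediction: coupling η = GOI:driver within
the bicistron (default 0.55, observed range 0.31–0.76) and retention ρ =
driver-in-bicistron vs. driver-alone (default 0.50, the midpoint of the
observed 0.38–0.64 range, which reports no single central value). The point
prediction `η·ρ·abundance` composes the two multiplicatively. This
composition is this package's modeling choice: the two ratios are measured
in separate strain comparisons, and multiplying them assumes the coupling
measured against the (already reduced) bicistronic driver level applies
unchanged — a first-order assumption the interval bounds (products of the
range extremes) are meant to dominate. `fit_coupling` is ordinary least
squares with intercept on (abundance, signal) pairs, reporting the squared
Pearson correlation; the regression flavor behind the published correlation
is unstated, so the most conventional one is used. The stability ratio is
simply generation-1 over generation-10 fluorescence; ≈1 means stable
integration.

## Multiplex planning

Greedy fill in input (priority) order at a per-round guide capacity,
default 4 — inferred from an 8-gene module completed in two multiplexed
rounds; the source protocol never states guides-per-round, so it is
configurable. Conflict checking is report-based (never raises): duplicate
drivers and duplicate spacers are errors; homology windows of two designs
overlapping on the genome is a warning.

## Synthetic data

`ToyGenomeSpec`/`build_toy_genome` generate an intronless single-contig
genome: per gene, 80-bp flanks around an ATG…stop CDS of 100–300 codons
(uniform), random strand, assembled with 60-bp intergenic gaps; abundances
are lognormal(μ=14, σ=1.5), placing most genes above the 5×10⁵ driver
threshold as a rich-medium exponential-phase proteome would. For a chosen
fraction of genes a PAM is planted 2 bp after the junction (cut 1 bp inside
the CDS, within the 5-bp bound); for the rest the locus is synthesized free
of GG/CC dinucleotides so no SpCas9 site can exist near the junction. After
assembly every locus is verified with the package's own scanner plus the
brute-force oracle in the test suite; collisions trigger resynthesis. The
generator is seed-deterministic.

What the toys do **not** emulate: introns, overlapping genes, repetitive
sequence (so off-target counts are almost always 1), biased codon usage and
GC content, UTR/terminator structure, and any relationship between abundance
and sequence. Passing tests therefore demonstrate coordinate and assembly
correctness and rule fidelity, not performance on repeat-rich real genomes —
on those, the uniqueness screen is expected to reject more candidates.

The packaged demo configuration mirrors the two validation modules — an
8-gene mevalonate/squalene module and a 5-gene mogrol module (13 genes
total) — with seed-deterministic placeholder CDSs standing in for the real
genes, 60-bp arms, pathway mode and the peroxisomal tag, plus three strain
variants mapping the three tunable mogrol genes to high/medium/low driver
tiers. Representative tier abundances (5×10⁶ / 1.2×10⁶ / 6×10⁵) were chosen
once to span typical high-to-borderline driver levels; the variants'
predicted module outputs are strictly ordered, emulating the observed
productivity ordering of the corresponding strains.

## Numerical and procedural choices

* Abundance threshold is strict `>` (5×10⁵ default), per its source wording.
* Tier quantiles use linear interpolation (`numpy.quantile` default); tiers
  0.9/0.5 are invented defaults — the source gives only qualitative tiers.
* Scan ordering: ascending cut distance, plus strand first on ties, then
  ascending cut coordinate; the "best guide" in the pipeline is simply the
  first passing hit in this order.
* Driver/GOI pairing in `run_design`: an explicit map wins; otherwise GOIs
  are assigned in input order to the highest-ranked drivers that have a
  passing guide. Drivers without a passing guide are reported "abandoned",
  never silently dropped.
* Ties in `filter_drivers` break lexicographically by gene id; ties in
  `select_driver_for_target` prefer the more abundant driver, then gene id.
* Reports are byte-deterministic for a given config (sorted-key JSON, no
  timestamps).

## Problem sizes

The default test suite and the acceptance script run entirely on synthetic
data at desk scale: toy genomes of 8–50 genes (≈7–45 kb), 500 random
integration designs, 200 random GOIs for PCR reconstruction, exhaustive
round-planning laws for n ≤ 12, and a 65-point regression recovery. These
sizes exercise every code path (both strands, both modes, variable arms)
while keeping the full suite in a few seconds.

## Known limitations

* Exact-match uniqueness is not an off-target safety assessment.
* No thermodynamics anywhere (primers anneal by exact string match).
* HDR is assumed perfect; NHEJ/indel outcomes are not modeled.
* Translation re-initiation is taken as given with a fixed efficiency; η is
  not modeled as a function of driver strength, linker context or mRNA
  length.
* GFF3 support covers gene/mRNA/CDS graphs only.
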