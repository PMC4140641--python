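# Methods

## Pausing index and classification

Footprint data are reduced to one count per read at a single nucleotide.
The default assignment rule is the footprint center, `floor((start+end-1)/2)`
for a 0-based half-open alignment interval; a fixed 3′-offset rule
(strand-aware, default 12 nt) is available for protocols where the 3′ end is
the better anchor. On uniform coverage the two rules give identical codon
vectors, so the choice only matters at sharp peaks. Counts are then summed
in consecutive 3-nt bins along the coding strand (codon 1 of a minus-strand
gene is the bin at the genomic 3′ end); the codon vector includes the stop
codon position.

The pausing index of a site is the mean count over its 3-codon window
(P₋₁, P_P, X_A) divided by the gene-mean count over the whole ORF. The
window *mean* (not max) is the default statistic, since a stall elevates
ribosome density over the region spanning both proline positions and the
A-site codon; `window_mode="max"` is config-exposed. The gene mean includes
the peak itself and all codons — no end-trimming — which is what makes the
closed form below exact; it also means the index of a strong pause is
self-deflated on short genes (see Limitations).

Thresholds: strong ≥ 10 (inclusive; "at least 10-fold above the gene
average"), elevated > 2, non-pausing ≤ 1, neutral between. EF-P dependence
additionally requires a ≥ 3-fold rise of the Δefp index over WT, because a
site can be strong in both strains without being EF-P dependent; both the
fold threshold and the classification thresholds are config keys. Fold
changes against a WT index below the pseudocount (default 0.1) add the
pseudocount to both numerator and denominator and flag the call, preserving
the raw zero in the output. Indices are computed per replicate and then
averaged arithmetically; replicate pairs disagreeing by more than 5-fold
(or zero vs positive) are flagged.

Coverage gate: a gene enters the analysis when its mean coverage is at
least 3 reads/codon (inclusive) in every sample present, so that the same
gene set underlies every strain comparison. The gate is a gene-average
criterion; per-codon zeros are ubiquitous in real footprint data, so a
per-codon requirement would be far stricter than intended.

## Motif enumeration

A PPX site exists at every position i with residues (P, P, X) at
(i, i+1, i+2); a run of L ≥ 2 prolines followed by X therefore emits L−1
sites (IPPPE → PPP and PPE), which reproduces the double-listing of
triproline motifs with upstream strings offset by one residue. A proline
run at the protein C terminus emits nothing: there is no A-site residue,
and the stop codon is never X (the A site would hold release factor).
Context fields are read at fixed offsets from the P-site proline
(Z₋₂ = two before, Z₋₃ = three before) and the 20 residues upstream of
P₋₁ are recorded, left-'-'-padded near the N terminus. Residue classes:
acidic {D,E}, basic {K,R,H}, amide {N,Q}, hydroxy {S,T,Y}, proline,
glycine, hydrophobic/aromatic {A,V,L,I,M,F,W,C}. Grouping cysteine with
the hydrophobics is an assumption; no standard class assignment exists
for it in this context.

## aSD duplex model

Upstream windows are scored against the anti-Shine-Dalgarno 8-mer
5′-CACCUCCU-3′ with a duplex-only nearest-neighbor model: the minimum,
over all antiparallel registers and all contiguous runs of ≥ 2 base pairs
(Watson–Crick and GU), of the summed stack free energies at 37 °C. A
positive optimum is reported as 0 kcal/mol (no favorable duplex). The
packaged table uses the published Watson–Crick ΔG°₃₇ stack values; several
GU-wobble stacks are representative approximations (marked in the data
file) constrained so that no wobble stack outcompetes its Watson–Crick
counterpart — this guarantees the perfect complement AGGAGGUG is the strict
global optimum among equal-length windows, verified exhaustively over all
4⁸ 8-mers. Duplex initiation and terminal-AU penalties are omitted by
default; they are constants or near-constants across the short windows
scanned here, and the weak (−2 kcal/mol) and SD-like (−4 kcal/mol)
cutoffs are calibrated to this convention. Intramolecular mRNA structure,
bulges and internal loops are out of model: the scan is a short
hybridization screen, not a folding prediction. The positional scan
anchors offset 0 at the third nucleotide of the X codon and reports the
whole profile from −20 to −5; the summary band −9…−7 reflects the
geometry of an SD-like element positioned 7–9 nt upstream of that anchor,
but any band can be read from the profile.

## Codon rarity

A-site codons are annotated from a packaged *E. coli* K-12 usage table
(frequencies per 1000 codons; user-replaceable via TSV). "Rare" means
below the bottom quartile of the 61 sense codons. This frequency proxy
stands in for tRNA abundance, which it tracks only approximately.

## Synthetic data generator

The generator emulates the count structure the pausing index assumes:
per-codon footprint counts proportional to gene expression × codon dwell
time, with a planted dwell multiplier m over the 3-codon stall window in
the efp-deletion condition. Counts are negative-binomial
(mean = depth × expression × dwell, size = dispersion, gamma–Poisson
parameterization), spread multinomially over the codon's 3 nucleotides.
Per-gene expression is log-normal (σ = 1) and shared across conditions and
replicates, so replicate pairs differ only by counting noise. Defaults:
200 genes of 250–450 codons, depth 20 reads/codon at expression 1,
dispersion 10 (variance = μ + μ²/10, a moderate overdispersion typical of
bacterial ribo-seq), 2 replicates for WT, Δefp and complemented
conditions; 30 planted stalls with m = 15 in Δefp (1.5 in the complemented
strain, emulating partial restoration) and 100 neutral decoy PPX sites.
Proteins are drawn without incidental prolines so the planted truth is the
exact PPX site list; back-translation uses highest-frequency codons, with a
flag to force rare A-site codons. Everything is deterministic under the
spec seed (per-sample streams are derived from it), and two runs produce
byte-identical files.

With the gene mean including the inflated window, the expected index of a
planted stall is

    m / (1 + (w/L)(m − 1)),   w = 3, L = codons in the ORF,

which the pipeline recovers within a few percent at the default depth.

What the generator does **not** emulate: ribosome queueing upstream of
stalls and the loss of closely stacked ribosomes during footprint
isolation, ligation/sequence bias, rRNA contamination, footprint-length
variation, and multi-pause interactions within a gene. Passing tests on
synthetic data therefore validate the estimator and the bookkeeping —
binning, strand handling, normalization, thresholds, truth recovery under
the assumed count model — not the biological fidelity of real libraries.
The full-scale replicate correlations and motif counts of a real
experiment additionally depend on alignment and offset choices outside
this package's scope.

## Numerical and design choices

- Internal coordinates are 0-based half-open; GFF3 I/O converts to/from
  1-based inclusive. Minus-strand CDS is the reverse complement of the
  genomic slice.
- Codons containing N translate to X and never match motif patterns;
  duplicate gene_ids keep the longest CDS.
- The strong threshold is inclusive (≥ 10); the boundary classification
  of an index of exactly 10 follows the "at least 10-fold" reading.
- De-novo pause windows are maximal runs of consecutive codons with
  normalized occupancy ≥ threshold, merged into one window with peak value
  and position; windows overlapping a PPX 3-codon window are
  cross-annotated.
- Ratio orientation: protein-abundance tables in the WT/Δefp orientation
  are inverted on input so both concordance axes compare Δefp/WT; the
  0.5–2 band defines "unchanged" on each axis, footprint-only changes get
  their own bins, and any remaining mixed pattern is "discordant".
- Histogram bins are left-inclusive, right-exclusive, default edges
  (0, 1, 2, 5, 10, 20, 50, ∞), configurable.
- Tests and the acceptance script run the generator at the default study
  size (200 genes, depth 20), which completes in seconds while leaving
  narrow confidence intervals around the planted truth.

## Known limitations

- The pausing index is biased low for stalls on short genes or genes with
  several stalls (the gene mean absorbs the peaks), and undefined for
  uncovered genes; such sites are dropped with a log entry rather than
  imputed.
- The coverage gate intersects across all samples; a gene undetectable in
  one strain is excluded everywhere.
- The duplex model's absolute energies depend on the packaged table;
  comparisons should be read relative to the −2/−4 kcal/mol cutoffs
  calibrated to it, not against other tools' absolute outputs.
- Footprint reads overlapping two genes are counted for every gene
  containing the assigned nucleotide; overlapping CDS are processed
  independently.
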